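"""Published per-model separability statistics used as desk-check inputs.

Twelve (crop dataset, backbone) rows of within-class distance (icD),
between-class distance (bcD), the separability ratio FEP = bcD/icD, and
the resulting ensemble weight in percent, as reported for VGG11,
ResNet18 and MobileNet_v3 feature spaces on four crop-leaf datasets.
The icD/bcD columns are inputs; FEP and weight are the printed values
our arithmetic must reproduce.
"""

# (crop, model, icD, bcD, FEP, weight %)
SEPARABILITY_TABLE = [
    ("apple", "VGG11", 2.051201, 1.807103, 0.880997, 14.371),
    ("apple", "ResNet18", 8.251477, 23.11970, 2.801886, 45.706),
    ("apple", "MobileNet_v3", 6.055690, 14.82056, 2.447378, 39.923),
    ("corn", "VGG11", 1.335760, 2.818918, 2.110348, 20.023),
    ("corn", "ResNet18", 4.639691, 20.89895, 4.504383, 42.738),
    ("corn", "MobileNet_v3", 4.316191, 16.94026, 3.924816, 37.239),
    ("grape", "VGG11", 1.756650, 1.635504, 0.931035, 13.523),
    ("grape", "ResNet18", 6.790820, 20.96166, 3.086765, 44.833),
    ("grape", "MobileNet_v3", 3.948179, 11.32035, 2.867232, 41.644),
    ("rice", "VGG11", 2.27075, 0.979885, 0.431525, 10.061),
    ("rice", "ResNet18", 11.52429, 22.49176, 1.951684, 45.504),
    ("rice", "MobileNet_v3", 8.528134, 16.25342, 1.905859, 44.435),
]

CROPS = ("apple", "corn", "grape", "rice")


def crop_rows(crop):
    return [row for row in SEPARABILITY_TABLE if row[0] == crop]
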