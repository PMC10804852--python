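# elcdr — ensemble crop-disease recognition weighted by class separability

Automatic recognition of crop leaf diseases is usually done with
convolutional networks, and ensembles of several networks beat any single
one — but classical majority voting treats a weak member and a strong
member as equals, and can even return *no* decision when every member
votes for a different disease. `elcdr` implements an ensemble strategy
that instead weights each member model by how well it separates the
disease classes in its own feature space, measured on the training set
alone, with no held-out validation split.

It is aimed at practitioners who already train image classifiers (for
plant pathology or any multi-class problem) and want a principled,
training-free way to fuse them. The package never touches images or
network weights: members participate by exporting two plain tables — the
feature vectors of the training samples (e.g. pooling-layer embeddings)
and the softmax probabilities of the evaluation samples.

## The statistic

For one model, let the `t` training vectors fall into `k` classes with
class centroids `cen_p` (the mean vector of class `p`). Define

- **icD** (in-category distance): the average Euclidean distance of every
  vector to its own class centroid,
  `icD = Σ_p Σ_i ‖vector_i^p − cen_p‖ / t`;
- **bcD** (between-categories distance): the average distance over all
  `k(k−1)/2` centroid pairs, `bcD = Σ_{p<q} ‖cen_p − cen_q‖ / C(k,2)`;
- **FEP** (feature-extraction performance): `FEP = bcD / icD`.

Tight clusters far apart ⇒ large FEP. With `n` member models the ensemble
weights are `w_g = FEP_g / Σ_i FEP_i`, and the fused probability row for a
sample is `sf_final = Σ_i w_i · sf_i`; the predicted class is its argmax.
Baselines included: **average weighting** (`w_i = 1/n`) and **majority
voting**, where a sample with no strict plurality of votes is `INVALID`
(scored as incorrect).

FEP is invariant under rotation, translation and uniform scaling of a
model's feature space, so models with embeddings of different overall
magnitude are comparable.

## Worked example

Simulate three member models of ranked embedding quality (Gaussian class
clusters at separations 4, 2, 0.8 with unit spread; a centroid-distance
softmax stands in for each member's classifier head), then weight, fuse
and score:

```sh
elcdr simulate --out demo/fix --seed 7 --classes 4 --dim 12 \
    --per-class-train 100 --per-class-test 50 \
    --model resnet_like:4:1 --model mobilenet_like:2:1 --model vgg_like:0.8:1
elcdr weights demo/fix/resnet_like_features.csv \
    demo/fix/mobilenet_like_features.csv demo/fix/vgg_like_features.csv \
    --out demo/weights.json
```

```
INFO weights: {'resnet_like': 0.578789575265603, 'mobilenet_like': 0.3047191185771236, 'vgg_like': 0.1164913061572734}
```

The best-separated feature space (FEP 1.666) takes 57.9 % of the weight;
the weakest (FEP 0.335) gets 11.6 %. Fusing and evaluating each strategy
(`elcdr ensemble --strategy ... --model id:features:softmax ...`, then
`elcdr evaluate predictions.csv truth.csv`) prints:

```
[elcdr]   accuracy 100.00%, precision 100.00%, recall 100.00%, F1 100.00% (200 samples, 0 invalid)
[average] accuracy  99.50%, precision  99.51%, recall  99.50%, F1  99.50% (200 samples, 0 invalid)
[voting]  accuracy  85.00%, precision  93.71%, recall  85.00%, F1  89.14% (200 samples, 18 invalid)
```

Separability weighting recovers the quality ranking and beats both
baselines; voting loses 18 of 200 samples to invalid (all-distinct) votes.
The same operations are available as library calls
(`elcdr.feature_extraction_performance`, `elcdr.ensemble_weights`,
`elcdr.fuse_weighted`, …); see `docs/methods.md` for the model and its
assumptions.

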