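# Methods

## Model and assumptions

`elcdr` fuses the softmax outputs of `n` multi-class classifiers with
weights derived from the geometry of each classifier's training-set
feature vectors. The underlying assumption is that a model whose
embedding places same-class samples in tight clusters and different-class
centroids far apart ("good feature extraction") is also the more reliable
voter, so its probabilities deserve more mass in the fused decision. The
weight is computed on the training set only; no validation split or
held-out accuracy estimate is involved, which is the method's practical
appeal and also its main assumption — a model that overfits its training
embedding could earn more weight than its test behaviour merits.

Definitions (per model `g`):

- centroid `cen_p` = mean of class `p`'s vectors. The centroid is
  implemented as the arithmetic mean, not a raw sum: only the mean gives
  the scale covariance below and matches the "average vector" semantics.
- `icD = Σ_p Σ_i ‖vector_i^p − cen_p‖ / t` — mean distance to own
  centroid over all `t` training vectors.
- `bcD = mean over the k(k−1)/2 centroid pairs of ‖cen_p − cen_q‖`.
- `FEP_g = bcD_g / icD_g`; ensemble weight `w_g = FEP_g / Σ_i FEP_i`.

Fusion strategies:

- **weighted** (the method): `sf_final = Σ_i w_i · sf_i`, predict the
  argmax class.
- **average**: the `w_i = 1/n` special case.
- **voting**: each model votes its argmax; a strict plurality wins.
  Absent a strict plurality — including the all-distinct case — the
  prediction is the `INVALID` sentinel. `INVALID` is scored as incorrect.
  The original formulation discusses invalidity only for three models all
  disagreeing; "no strict plurality ⇒ INVALID" is the natural
  generalisation adopted here, and an optional fallback resolves such
  samples by average fusion instead.

Mathematical properties (all enforced by tests): weights are positive and
sum to 1, preserving the FEP rank order; FEP is invariant under rigid
transforms and uniform positive scaling of a model's feature space (icD
and bcD are both 1-homogeneous); fused rows of the weighted/average
strategies remain probability distributions; a unanimous sample is
predicted identically by all three strategies.

## Tunable parameters

| parameter | where | default | meaning |
|---|---|---|---|
| `icd_epsilon` | `feature_extraction_performance`, CLI `--icd-epsilon` | off | floor for a vanishing icD; by default perfectly collapsed clusters raise `DegenerateGeometryError` rather than produce an infinite FEP that would corrupt the weight normalisation |
| argmax tie-break | `predict_argmax` | lowest class index | deterministic; ties are measure-zero on real softmax outputs |
| row-sum tolerance | `SoftmaxTable` | 1e-6 | rows off by more are rejected, not silently renormalised; CLI `--renormalize` opts in to rescaling |
| `average` | `classification_metrics`, CLI `--averaging` | macro | macro averaging makes recall coincide with accuracy on class-balanced test sets, matching how the published evaluation tables behave; micro and support-weighted variants are available |
| `--voting-fallback average` | CLI | off | resolve invalid votes by average fusion |

Class ordering is by first appearance in the label column unless an
explicit class list is given; every output reports class identifiers,
never bare ordinals. Feature vectors are used as supplied — no
normalisation is applied before distance computation (FEP's scale
invariance makes a global rescaling irrelevant anyway; per-feature
standardisation would be a different statistic).

## Synthetic ensemble generator

The generator (`elcdr.synthdata`) stands in for the image-and-CNN stage
so the full pipeline is exercisable without training. Per simulated
model, class means are placed at distance `separation` from the origin
along random orthonormal directions (all pairwise mean distances
`separation·√2` when `k ≤ d`; independent random unit directions when
orthogonality is impossible, i.e. `k > d`), and samples are isotropic
Gaussians of standard deviation `spread` around them. The member's
classifier is a centroid-distance softmax, `p_j ∝ exp(−‖x − cen_j‖/T)`
with temperature `T`, computed from the *training-split* centroids —
this ties classification quality to the same geometry the weight
measures, which is precisely the premise of the method.

Defaults emulate a four-disease crop dataset of 2000 images split 3:2:
`k = 4`, 300 training and 200 test samples per class, `d = 16`, and three
members with separations (6, 3, 1) at unit spread — one strong, one
middling, one weak feature extractor. Train and test splits are fresh
independent draws from the same class means (not a partition), keeping
per-class counts exact; the test truth labels are shared across models,
each model embedding "the same sample" as an independent draw with the
same label. Everything is driven by `numpy` `SeedSequence` spawning, so
identical config + seed reproduces byte-identical fixture files.

What the generator does **not** emulate: correlated errors between
members (real CNNs trained on the same images make correlated mistakes;
simulated members are conditionally independent given the label),
anisotropic or heavy-tailed class clusters, class imbalance, label noise,
and miscalibrated softmax heads. Passing tests therefore demonstrate the
arithmetic and the geometry–accuracy coupling, not performance on real
leaf images.

## Numerical choices

- Distances via `numpy.linalg.norm` / `scipy.spatial.distance.pdist` in
  float64; the naive-loop oracle agreement demanded in tests is 1e-12 on
  small instances.
- The simulated softmax is computed in log space shifted by the row
  minimum, so tiny temperatures saturate to a delta instead of 0/0.
- Weights are renormalised once after division to absorb accumulated
  rounding on long model lists (sum-to-1 is asserted at 1e-9).
- Tables are written with `%.17g` floats: write→read round trips are
  exact and repeated runs byte-identical (the run manifest carries the
  only timestamp).
- Desk verification of the published per-model separability table is at
  5e-6 relative, the printed 6-significant-figure precision.

## Problem sizes in tests and the acceptance script

Randomised oracle checks use 100 instances with `t ≤ 50`, `d ≤ 8`,
`k ≤ 5`, `n ≤ 4`. The weight-recovery study uses 20 replicates at
`k = 4`, `d = 16`, 50 samples per class with separations (6, 3, 1) and
requires the weight ordering to match the separation ordering in at least
19; the acceptance script's pipeline run uses the full default
300/200-per-class conditions. These sizes make the whole suite run in a
few seconds while keeping centroid-estimation noise well below the
separation gaps being detected.

## Known limitations

- The weight is a global statistic: a model that separates three classes
  superbly but confuses two gets one scalar weight, not per-class
  weights (per-class weighting is explicitly out of scope).
- FEP compares models on *their own* feature spaces; it is meaningful as
  a relative score only when all members were trained on the same
  training set.
- Voting's fused "probabilities" are vote shares, provided for a uniform
  result type; they are not calibrated probabilities.
- No stacking/meta-learning, no temperature calibration, no image
  handling: members are consumed entirely through their exported feature
  and softmax tables.
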