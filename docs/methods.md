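# Methods

This note records the model implemented by `fundusgcn`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Model

An image is scored against N lesion labels jointly.  The model has two
branches coupled only at the final inner product:

* **Image branch.**  A convolutional backbone maps the RGB image to feature
  maps `C × h × w`; two 3×3 stride-2 convolutions (padding 1, channel
  preserving, each followed by a leaky rectifier) downsample them twice; a
  per-channel spatial maximum (adaptive max-pool to 1×1) yields `F ∈ R^D`.
* **Label branch.**  Each label name is embedded as the mean of its tokens'
  word vectors (d = 300 for real GloVe vectors; smaller in the synthetic
  experiments), giving `X ∈ R^{N×d}`.  A stack of graph convolutions
  `H^{l+1} = σ(Â H^l W^l)` (LeakyReLU slope 0.2; no activation after the
  last layer) maps `X` to `Z ∈ R^{N×D}`, one linear classifier per label.

Raw scores are `y = F Zᵀ`; a label is predicted present when its sigmoid
confidence strictly exceeds 0.5, i.e. when its raw score is strictly
positive.

## Label-graph construction

From binary training annotations only (never validation/test):
`M = YᵀY`, `P_ij = M_ij / M_jj` (requires every label to occur at least
once; a never-seen label is an error, not a silent zero).  Stages:

* **Binarization** `A′_ij = 1[P_ij ≥ τ]`, τ = 0.3, ties count as edges.
  Applied uniformly including the diagonal, which the next stage overwrites.
* **Re-weighting** distributes p = 0.25 across each row's surviving edges
  and sets the diagonal to 1 − p.  Entries binarization zeroed stay zero —
  the re-weighting is applied multiplicatively to `A′` — otherwise the
  thresholding stage would have no effect.  A row with no edges keeps only
  its 1 − p diagonal (row sum 1 − p, not renormalized); connected rows sum
  to exactly 1.
* **Normalization** `Â = D^{−1/2} A D^{−1/2}` with `D` the diagonal of row
  sums.  No identity is added: the diagonal is already populated.  Since
  `P` (and hence `A`) is in general asymmetric, `Â` may be asymmetric; the
  label graph is directed and is deliberately never symmetrized.

τ controls sparsity (higher τ, fewer edges); p controls how much a label's
classifier listens to its neighbours versus its own embedding.  The defaults
(0.3, 0.25) are the reference operating point for the 8-label task.

## Loss, optimization, splitting

The loss is the multi-label one-versus-all logistic loss: per sample,
`−(1/N) Σ_i [y_i log σ(x_i) + (1−y_i) log(1−σ(x_i))]`, averaged over the
batch, evaluated in the softplus form `max(x,0) − xy + log(1+e^{−|x|})` so
it is exact at extreme scores.  At all-zero scores it equals ln 2.

SGD uses momentum 0.9 and L2 weight decay 1e−4 with two parameter groups:
backbone convolutions at learning rate 0.01, the downsampling convolutions
and GCN weights at 0.1 — the usual arrangement when the backbone is a
pretrained network being fine-tuned.  Defaults: 30 epochs, batch size 8,
constant rates.  The best-validation-CF1 weights are kept.

Datasets are split 70/15/15 by seeded shuffle and contiguous cut; the
partition is exact and disjoint.  The split is per image; because patients
contribute two eyes, the manifests carry `patient_id` so callers can group
before splitting if leakage across eyes is a concern.

## Evaluation

OF1 pools TP/FP/FN over all classes before forming precision/recall; CF1
averages per-class precision and recall first; both F1 values are harmonic
means.  Precision or recall with an empty denominator is 0 (common
multi-label convention for rare classes).  Per-class accuracy is
`(TP+TN)/n`.  AUC is the Mann-Whitney statistic (mid-ranks; tied
positive-negative pairs count one half); a class without both outcomes has
no defined AUC and is reported as missing — never coerced to 0, 1 or 0.5 —
and excluded from summary means with a warning.

## Synthetic data generator

Annotations are drawn from a mixture of patient profiles: profile k has
weight `w_k` and per-label Bernoulli probabilities `q_k`; within a profile
labels are independent.  This makes every pairwise conditional probability
available in closed form,

    P(L_i | L_j) = Σ_k w_k q_ki q_kj / Σ_k w_k q_kj,

so graph construction can be tested for exact parameter recovery rather
than merely for plausibility.  The default mixture has three profiles over
the eight lesion labels — a mostly-healthy background population, a
proliferative-retinopathy profile and a vascular-aging profile — with
marginal prevalences resembling a hospital screening population
(arteriosclerosis ≈ 0.37, hemorrhages ≈ 0.28, hard exudates ≈ 0.25, laser
scars ≈ 0.04).  A two-profile, four-label mixture with strong block
structure drives the scaled-down training experiments.

Images are cartoon renderings: a warm circular fundus-like background plus
one visually distinct primitive per active label (tiny red dots for
microaneurysms, bright yellow blobs for hard exudates, dark blotches for
hemorrhages, pale fuzzy patches for soft exudates, a pale dot-ring for
laser scars, yellow specks for drusen, an enlarged bright inner disc for
cup-disc ratio, thick dark strokes for arteriosclerosis), light Gaussian
noise, 64 px by default.  Each label draws from its own random substream,
so toggling one label never changes another's appearance, and rendering is
byte-reproducible from (labels, spec, seed).

What the generator does **not** emulate: photorealistic texture, vessel
anatomy, illumination and camera variation, annotator disagreement,
within-patient correlation beyond the paired-eye bookkeeping, or lesions
that are genuinely hard to see at low resolution.  Passing the end-to-end
experiments therefore demonstrates that the pipeline is implemented
correctly and can learn label-encoding visual structure — not that this
architecture reaches clinical performance on real fundus photographs.

## Numerical and engineering choices

* The whole trainable model is implemented directly in NumPy with
  hand-derived gradients (im2col convolutions, explicit backward passes);
  a gradient-checked compact implementation keeps every operation
  inspectable and the dependency surface minimal.
* Backbone activations are LeakyReLU with slope 0.01 rather than plain
  ReLU: with momentum SGD on small batches a plain-ReLU image branch can
  die irreversibly (all activations clamp at zero, the image gradient
  vanishes and training collapses to predicting marginals).  Slope 0
  restores plain ReLU via `BackboneConfig.activation_slope`.
* GCN weights initialise uniform ±1/√fan-in, seeded; whether to activate
  the final GCN layer is configurable and off by default (classifier
  weights must span negative values).
* The backbone is pluggable: the scaled-down preset is a 3-stage CNN on
  64 px inputs (stride 8, D = 64); `fundus1024_config` documents the
  production-scale shape contract (1024 px → 2048 × 32 × 32 maps → 8 × 8 →
  `F ∈ R^2048`).  At that scale one would substitute a pretrained deep
  backbone; the preset carries randomly initialised weights and is used
  for shape verification.
* One global seed fans out through `SeedSequence` into independent
  sub-seeds for data generation, splitting, initialisation and batch
  shuffling; all artifacts (manifests, PNGs, graph TSVs, checkpoints,
  reports) are byte-reproducible given config + seed.
* Problem sizes for the bundled experiments were chosen to keep a full run
  on one CPU in the tens of seconds: 600 images at 64 px with 4 labels for
  the end-to-end experiment (held-out CF1 ≈ 0.95–1.0 across seeds), 2000
  samples for marginal checks, 20000 for conditional-probability recovery.

## Known limitations

* Conditional probabilities conditioned on rare labels are noisy: with the
  default mixture's rarest label near 3–4 % prevalence, a 2000-sample
  annotation matrix yields a sup-norm recovery error typically between
  0.05 and 0.12 — the rare-label columns are estimated from only ~60–80
  positive samples.  The error falls below 0.05 around n ≈ 20000, which is
  what the recovery test uses.  This is sampling noise, not estimator
  bias.
* `Â` is used as a fixed operator; the graph is not learned, and no
  attention or edge re-weighting during training is provided.
* The NumPy implementation is single-threaded matrix algebra: adequate for
  the 64 px experiments, not for 1024 px training.
* Image-level splitting is the default even though patients contribute two
  eyes; patient-level grouping is the caller's responsibility via
  `patient_id`.
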