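# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the limits of what the tests demonstrate.

## Bag classification model

A slide is a bag of `k` patch embeddings `z_j ∈ R^d` with one slide-level
label (NSMP = 0, p53abn = 1). The representation is attention pooling with a
variance channel:

- attention `a_j = softmax_j(Wᵀ tanh(V z_j))` with `V ∈ R^{q×d}`, `W ∈ R^q`
  (default `q = 128`); the softmax subtracts the maximum score first, so
  scores spanning hundreds of units cannot overflow;
- weighted mean `z̄ = Σ a_j z_j` and bias-corrected weighted variance
  `z_σ = k/(k−1) Σ a_j (z_j − z̄)²`; for `k = 1` the correction factor is
  undefined and `z_σ` is defined as the zero vector (a single observation
  has no dispersion);
- head: MLP `2d → 128 → 2` with ReLU, softmax output. With the variance
  channel disabled the model degrades to attention-mean pooling and the head
  input is `d`.

Patches are reordered into a canonical (lexicographic) order before the
pooling sums, which makes the bag representation *bitwise* invariant to
patch order; returned attention weights are mapped back to input order.

Training: the feature extractor is outside the model (two-step training —
embeddings are frozen inputs; any map patch → R^d plugs in, and a frozen
random-projection featurizer over pixel statistics is provided for
image-based fixtures). Attention and head are trained by per-bag Adam on
cross-entropy with decoupled weight decay. Defaults: learning rate 1e-5,
weight decay 1e-4, class-balanced per-epoch bag sampling, learning rate
halved after 5 epochs without validation improvement, stop after 10, cap at
150 epochs, best-validation parameters returned. Gradients are hand-derived;
the variance term's direct dependence on `z̄` contributes nothing because
`Σ a_j (z_j − z̄) = 0` identically. The listed image-stage augmentations
(flips, color jitter, size jitter, rotation, Cutout) apply only to the image
pathway and are no-ops on precomputed embedding bags.

## Ensemble consensus refinement

Patients are split into 10 disjoint groups, stratified by molecular label;
classifier `i` tests on groups `{i, i+1}`, validates on `{i+2, i+3}` (mod
10) and trains on the remaining six — one concrete realization of ten
60/20/20 splits in which each group is tested exactly twice and all slides
of a patient stay together (no leakage). All ten classifiers vote on every
case by default; argmax ties count as NSMP (conservative: fewer false
p53abn-like calls). A molecularly-NSMP case with strictly more than τ = 7
p53abn votes becomes *p53abn-like NSMP*; symmetrically for *NSMP-like
p53abn* (the symmetric rule is this package's extension; only the NSMP-side
threshold is externally specified). A `test_only` mode restricts voting to
the two classifiers that never saw the case, scaling the threshold to the
same fraction of actual voters; it is off by default because the published
procedure lets all ten classifiers label every case, but consensus that
includes in-training cases is statistically optimistic — both modes are
kept for exactly that reason. Multi-slide patients aggregate per classifier
by majority over slides, ties toward NSMP.

## Tile planning and tumor-patch selection

Tiles are `patch_size` squares (default 512 px at a nominal 20x) anchored at
stride `floor(patch_size · (1 − overlap))`; flooring guarantees at least the
requested overlap (default 0.6 at inference, 0 for annotated-region
extraction), and the boundary-anchored final position is appended per axis
so the grid covers the image. Coordinates are 0-based half-open pixel
intervals. Mask filtering keeps tiles whose in-mask fraction meets a floor
(integral-image sums). The tumor-probability threshold 0.90 is inclusive
("minimum threshold" read as ≥); scorer probabilities are used raw, with no
calibration step. The 200-patch cap is a uniform random subset and applies
to training extraction only, not inference tiling.

## Stain normalization

Beer–Lambert optical densities `OD = −log10(max(I,1)/I0)` with `I0 = 255`;
pixels with OD norm < 0.15 are background and excluded from estimation. The
3×2 stain matrix is fitted by sparse NMF,
`min ‖X − C Sᵀ‖² + λ‖C‖₁` over `C ≥ 0`, `S ≥ 0`, `‖s_k‖ ≤ 1`, with λ = 0.1.
Initialization is by extreme angles in the top-2 OD principal plane; the
concentration step is an exact nonnegative lasso (vectorized coordinate
descent over pixels, convex), the dictionary step is projected block
coordinate descent, and the objective is non-increasing across alternations
(asserted in tests). Because the L1 shrinkage biases the columns slightly
toward the data mass, the sparse solution is debiased by ten penalty-free
alternations before the final column normalization — without this, pure
pixels fall just outside the fitted stain cone and self-normalization errs
by several intensity levels. Columns are ordered hematoxylin first
(descending blue-channel absorbance). Normalization rescales per-stain
concentrations (exact two-stain NNLS) by the ratio of 99th-percentile
concentrations and reconstructs in the target basis; a source stain with
p99 = 0 passes the image through with a warning. Models are fitted per
image; a fitted model can be cached and reused per slide.

Identifiability caveat: stain separation (any NMF) needs near-pure pixels
per stain. Synthetic images whose every pixel mixes both stains recover the
stain *plane* but not the exact columns, and a fraction of a percent of
pixels can fall outside the fitted cone; the round-trip guarantees are
therefore stated for H&E-like images with near-pure regions, which is what
the relevant fixtures generate.

## Survival and group statistics

KM, log-rank (two-sided) and Cox proportional hazards are computed through
lifelines; Cox uses partial likelihood with Efron tie handling and reports
Wald CIs. Fisher's exact (two-sided hypergeometric; sample odds ratio
reported) and Mann–Whitney U (exact null when min(n, m) ≤ 8 and no ties,
otherwise normal approximation with tie and continuity correction; the
switch point is configurable only by editing the call because the rule is
deliberate) come from scipy. No multiple-testing correction is applied;
p < 0.05 is the working significance level. FGA is the length fraction of
segments flagged altered or with |log2 ratio| ≥ 0.2 (the common
copy-number-portal convention; the threshold is an argument). Cohort
summaries print "n (p%)" cells with column percentages rounded half-up to
two decimals, Unknown levels included in totals. Records with missing
endpoints are expected to be dropped by the caller with a logged count.

Risk-group reassignment: a p53abn-like NSMP case is re-risked as if p53abn —
Low, Intermediate and High-intermediate move to High; High and Advanced
metastatic are unchanged; tumors without myometrial invasion are not
upstaged by p53abn status and keep their group. This encodes the observed
upstaging transitions under the 2021 European (ESGO/ESTRO/ESP) risk schema
rather than re-deriving the full risk table.

## Synthetic cohorts

The generator emulates a two-subtype cohort with a latent subgroup:

- **Embeddings.** Bag size uniform on [30, 60]; `⌈signal_fraction · k⌉`
  patches from `N(μ_group, I)`, the rest from `N(μ_bg, I)` with μ_bg at the
  midpoint of the class means, so `signal_fraction` (default 0.5) is the
  sole knob for bag-level separability. Class means sit `class_separation`
  (default 2) apart in units of per-dimension noise s.d., `d = 16`.
  p53abn-like bags are identical in law to p53abn bags while the molecular
  label stays NSMP — the defining premise of the planted subgroup. The
  separation default is a modeling choice: no external estimate exists for
  how separable the latent subgroup is in feature space.
- **Survival.** Exponential event times (closed-form oracles for every
  test), hazards per year 0.03 / 0.09 / 0.10 for NSMP / p53abn-like /
  p53abn, censoring uniform on [0, 10] years; PFS and DSS drawn
  independently with the same hazards. Note the power consequence: at the
  default cohort size (40 planted vs 160 NSMP) this censoring yields only
  ~36 expected PFS events, so the p53abn-like-vs-NSMP log-rank test has
  roughly 60–80 % power at α = 0.01 — individual realizations can and do
  fail to reach significance even though recovery of the planted cases is
  essentially perfect.
- **Copy number.** A fixed synthetic genome (22 chromosomes × 100 bins of
  1 Mb, half-open coordinates, partition asserted) with the altered fraction
  drawn per patient from group Beta distributions: (2, 18), (3.5, 6.5),
  (5.5, 4.5) — means 0.10 / 0.35 / 0.55, ordered as the biology suggests
  (p53abn-like between NSMP and p53abn). Altered bins get |log2| ≥ 0.25,
  unaltered bins stay inside (−0.19, 0.19).
- **Covariates.** Grade/stage/histotype/age sampled with group-dependent
  rates loosely matching published clinicopathologic tables, the
  p53abn-like group enriched for high grade and stage.
- **Randomness.** One root seed expands to per-patient substreams via
  `SeedSequence(seed, spawn_key=(patient, stream))`, so cohorts are
  bit-reproducible regardless of generation order.
- **Images.** Two-stain Beer–Lambert renderings of Gaussian-blob (or
  explicit) concentration fields with the ground-truth stain matrix
  retained for recovery tests.

What passing tests show — and do not. The generator produces exchangeable
Gaussian bags, exponential hazards and exact planted structure; it does not
mimic H&E texture statistics, nuclear morphology, scanner or site effects,
or label noise beyond the planted subgroup itself. Pipeline results on it
demonstrate correctness of the machinery (no leakage, calibrated tests,
recoverable planted signal), not clinical performance on real slides.

## Problem sizes

Default experiment scale is chosen so the full pipeline (cohort of 300
patients, ten classifiers, consensus, survival and FGA analyses) completes
in about a minute on one CPU; unit fixtures are smaller. The Cox
calibration check uses 200 simulated null datasets of n = 100.
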