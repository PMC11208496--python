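# ecmil

Ensemble multiple-instance-learning (MIL) refinement of endometrial
carcinoma (EC) molecular subtypes from H&E histopathology.

Molecular classification of EC assigns most tumors to one of four subtypes;
the largest, NSMP ("no specific molecular profile"), is defined by exclusion
and hides substantial outcome heterogeneity, while p53abn (abnormal p53
immunohistochemistry) carries the worst prognosis. This package implements
an image-analysis strategy for finding the poor-prognosis outliers inside
NSMP: train an ensemble of p53abn-vs-NSMP slide classifiers under
patient-grouped cross-validation, let all classifiers vote on every case,
and relabel the molecularly-NSMP cases that most classifiers call p53abn as
**p53abn-like NSMP** (and symmetrically, discordant p53abn cases as
NSMP-like p53abn). Downstream analyses — Kaplan–Meier / log-rank / Cox
survival stratification, fraction genome altered (FGA) from copy-number
segments, clinicopathologic summary tables and clinical risk-group
reassignment — quantify whether the discovered subgroup behaves like p53abn.

Because the slide cohorts such a study uses are proprietary, the package
ships a first-class synthetic-cohort generator with a *planted* p53abn-like
subgroup (bags drawn from the p53abn embedding distribution, survival drawn
with an elevated hazard, elevated FGA), so the whole pipeline is testable
end to end from nothing but a seed.

## The bag classifier

A slide is a bag `Z = {z_1, …, z_k}` of patch embeddings (`z_j ∈ R^d`).
The classifier is variance-aware attention MIL (VarMIL): softmax attention
scores each patch, and the bag representation concatenates the
attention-weighted mean with a bias-corrected attention-weighted variance,

    a_j  = exp(Wᵀ tanh(V z_j)) / Σ_t exp(Wᵀ tanh(V z_t))
    z̄    = Σ_j a_j z_j
    z_σ  = k/(k−1) · Σ_j a_j (z_j − z̄)²
    z    = z̄ ⊕ z_σ,      ŷ = F_FC(z)

with an MLP head producing P(p53abn). Pooling is exactly permutation
invariant, overflow-safe, and trained with Adam on cross-entropy with
validation-driven learning-rate decay and early stopping. Around it:

- `ecmil.slideprep` — deterministic tile-grid planning (512 px patches, 60 %
  overlap at inference), mask filtering, pluggable tumor-patch scoring with
  the ≥ 0.90 probability rule and the 200-patch training cap;
- `ecmil.stainnorm` — Vahadane-style stain normalization: sparse
  non-negative factorization of optical densities into a 3×2 H&E stain
  matrix plus concentrations, rescaled to a target basis;
- `ecmil.consensus` — patient-grouped 10-fold ensemble (60/20/20 splits),
  vote counting, and the "more than 7 of 10" refinement rule;
- `ecmil.outcomes` — KM/log-rank/Cox (via lifelines, Efron ties), Fisher's
  exact and Mann–Whitney U (via scipy), FGA, Table-1-style summaries, and
  risk-group reassignment counting.

## Worked example

```python
from ecmil import synth, consensus, outcomes
from ecmil.varmil import TrainConfig

cohort = synth.gen_cohort(synth.SynthConfig(seed=1))   # 200 NSMP (20% planted) + 100 p53abn
labels = cohort.molecular_labels()
plan   = consensus.make_group_folds([r.patient_id for r in cohort.records], labels, seed=1)
models = consensus.train_ensemble(cohort.bags, labels, plan, TrainConfig(seed=1))
votes  = consensus.refine_labels(consensus.build_vote_table(models, cohort.bags, labels), tau=7)
print(consensus.evaluate_ensemble(models, plan, cohort.bags, labels).mean_balanced_accuracy)
```

At seed 1 this run finds 38 of the 200 molecularly-NSMP patients to be
p53abn-like (a 19.0 % rate), recovering the 40 planted cases with
sensitivity 0.95 and specificity 1.00; the ten classifiers average 88.25 %
balanced accuracy and AUROC 0.90 on their held-out test folds. The
discovered subgroup shows 10-year progression-free survival of 54.0 %
versus 63.1 % for the remaining NSMP cases, and its median fraction genome
altered (0.36) sits between NSMP (0.08) and p53abn (0.56), Mann–Whitney
p ≈ 2×10⁻²⁰ — the planted poor-prognosis biology, read back out of the
images alone.

A thin CLI mirrors the library: `ecmil synth-cohort`, `ecmil pipeline`,
`ecmil stainnorm-fit/apply`, `ecmil fga` (see `ecmil --help`).

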