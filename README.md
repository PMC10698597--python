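# embaudit

Subgroup bias audits for frozen image-model feature representations.

Large pretrained ("foundation") imaging models are increasingly reused as
frozen feature extractors: a hospital trains only a small classification
head on the embeddings the backbone assigns to each scan. If those
embeddings encode protected patient characteristics — biologic sex, racial
identity — alongside disease signal, the convenience of transfer learning
can quietly import performance disparities into every downstream model.
`embaudit` is a pipeline for auditing exactly that, given nothing but a
per-scan metadata table (CSV) and the embedding matrix of any backbone. It
is aimed at ML researchers and clinical-AI evaluators who have embeddings
and demographics but no access to the backbone itself.

## What it computes

**Feature-space shift audit.** Embeddings are projected onto their leading
principal-component modes. On a subsample balanced to *n* patients per
racial group (one scan per patient), each pair of subgroups is compared on
each of the first *k* modes (default 4) with a two-sample
Kolmogorov–Smirnov test,

    D = sup_x | F̂_a(x) − F̂_b(x) | ,

with asymptotic p-values at effective size n_a·n_b/(n_a+n_b). All p-values
of one audit are adjusted as a single family by the Benjamini–Yekutieli
procedure (FDR control under arbitrary dependence),

    p̃_(i) = min( 1, min_{j≥i} p_(j) · m · c(m) / j ),   c(m) = Σ_{k=1}^m 1/k ,

and flagged at α = 0.05. A t-SNE view of the modes retaining ≥ 99% of the
variance and independently normalized marginal densities support
qualitative inspection (no statistics are computed on t-SNE coordinates).

**Downstream performance audit.** Heads of three capacities (`linear`,
`mlp3`, `mlp5`) are trained on the frozen embeddings with validation-based
model selection, and evaluated on a test set resampled with replacement so
every (group × label-status × age-bin) stratum is equally represented. A
single decision threshold τ per model and label is calibrated so the
*pooled* false-positive rate is 0.20; per-subgroup TPR, FPR, the Youden J
statistic

    J = TPR − FPR   (at the fixed τ),

and AUC are reported with 95% percentile-bootstrap confidence intervals
(2000 resamples, patient-level resampling unit). Disparities are summarized
as relative changes (J_g − J̄)/J̄ against the unweighted subgroup mean of
each characteristic.

A synthetic cohort generator with known ground truth (configurable subgroup
shifts, per-group disease effect sizes, repeated scans per patient) drives
all validation; see `docs/methods.md` for the model and its limits.

## Worked example

One YAML config drives the whole audit. With a synthetic backbone whose
embeddings carry a strong sex shift (1.5 noise-SD) on top of disease
signal:

```yaml
# demo.yaml
seed: 7
synthetic: {n_patients: 4000, embed_dim: 32, sex_shift: 1.5,
            group_shift: [0.0, 1.0, 0.4], seed: 7}
audit:     {per_group_subsample: 300, n_modes_tested: 4, seed: 7}
heads:     [{name: linear}]
labels:    [no_finding, pleural_effusion]
balancing: {age_bins: [18, 55, 70, 100], n_per_cell: 150, n_boot: 500}
paths:     {out_dir: demo_out}
```

```bash
embaudit simulate -c demo.yaml     # cohort.csv, embeddings.csv, ground_truth.json
embaudit inspect  -c demo.yaml     # shift_tests.csv, marginal plots
embaudit train-heads -c demo.yaml  # head_linear.joblib
embaudit audit    -c demo.yaml     # performance_*.csv, disparity.csv
embaudit report   -c demo.yaml     # disparity bar charts
```

`inspect` logs the significance tally —

```
shift audit: 3 of 20 tests significant
  disease: 2 of 4
  group: 0 of 12
  sex: 1 of 4
```

— and `shift_tests.csv` shows where: the injected sex shift dominates mode 1
(D = 0.502, adjusted p < 1e-4), while the race comparisons stay
non-significant because the milder group shift ranks below the four tested
modes. That is the intended reading of the audit: it tests the modes that
carry the most variance, where disease separation lives.

`audit` calibrates the pooled operating point (`linear/pleural_effusion:
pooled FPR 0.199 at threshold 0.2949`) and writes per-subgroup metrics;
for `pleural_effusion`:

```
characteristic subgroup   tpr   fpr  youden_j   auc   J 95% CI
           sex   female 0.685 0.219     0.465 0.819  [0.395, 0.544]
           sex     male 0.675 0.181     0.494 0.831  [0.412, 0.567]
         group    asian 0.698 0.202     0.496 0.840  [0.390, 0.615]
         group    black 0.709 0.200     0.509 0.834  [0.396, 0.615]
         group    white 0.633 0.196     0.438 0.802  [0.357, 0.522]
```

`disparity.csv` turns these into relative changes against each
characteristic's mean: female patients sit 3.0% below the sex-panel mean J
and white patients 8.9% below the race-panel mean, with the panel's
relative changes summing to zero by construction. On real embeddings the
same tables localize which subgroups a frozen representation shortchanges.

The library surface mirrors the CLI (`generate_cohort`, `run_shift_audit`,
`train_head`, `audit_label`, …) and the heads/PCA are scikit-learn
estimators (`ClassificationHead`, `EmbeddingPCA`) that compose with
sklearn pipelines.

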