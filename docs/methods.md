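# Methods

`embaudit` measures two things about a frozen image-model feature
representation, given only a per-scan embedding matrix and a demographic
metadata table: whether the embedding distribution differs across protected
subgroups, and whether classifiers built on the frozen features perform
unequally across those subgroups. This note describes the statistical
procedures, the synthetic data model used to validate them, the defaults and
the reasoning behind them, and known limitations.

## Feature-space shift audit

**Projection.** Embeddings are centered (not scaled) and decomposed by a
full SVD; the leading principal-component modes capture the directions of
largest variation, which for a disease-detection representation are expected
to separate disease status first. The sign of each mode is fixed by making
its largest-magnitude loading positive — the sign of a principal axis is
mathematically arbitrary, and a deterministic convention is required for
reproducible reports. When a cumulative-variance target is given (as for the
t-SNE input, default 0.99), the minimal number of leading modes meeting the
target is retained.

**Balanced subsample.** Shift tests are run on a subsample with an equal
number of patients per racial group (default 1000 per group), one scan
chosen uniformly per sampled patient. Sampling patients rather than scans
avoids within-patient clustering in the test statistics; sampling is without
replacement unless a group is smaller than the requested count, in which
case replacement is used and flagged in the output.

**Two-sample tests.** For each requested subgroup pair and each of the
first `n_modes_tested` modes (default 4), a two-sample Kolmogorov–Smirnov
test compares the marginal distributions. The statistic is
D = sup_x |F̂_a(x) − F̂_b(x)| evaluated at the pooled sample points
(right-continuous ECDF convention; projections of continuous embeddings make
ties measure-zero, but the convention is fixed so results are exactly
reproducible). The p-value uses the two-sided asymptotic Kolmogorov
distribution with effective sample size n_a·n_b/(n_a+n_b); at the default
subsample sizes (~1000 per side) the asymptotic form is accurate and fast.

**Multiplicity.** All tests of one audit — every comparison × every tested
mode — are adjusted as a single family with the Benjamini–Yekutieli
procedure: adj_(i) = min(1, min_{j≥i} p_(j)·m·c(m)/j), c(m) = Σ_{k≤m} 1/k.
BY controls the false discovery rate under arbitrary dependence, which
matters because modes of the same embedding and overlapping subgroup pairs
are dependent. Pooling everything into one family (rather than one family
per characteristic) is the most conservative reading; the report records the
family definition in its metadata. Significance is flagged at α = 0.05.

**Subgroup pairs.** Sex and racial-group pairs are resolved against the
metadata columns. A pair of label names is treated as a disease contrast:
rows positive for exactly one of the two labels are compared, which fixes an
overlap convention for co-occurring labels.

**Qualitative views.** A t-SNE embedding (perplexity 30, seeded,
PCA-initialized) of the variance-retaining PCA coordinates, and per-subgroup
Gaussian-KDE marginal densities normalized independently to 1 (so subgroup
base rates drop out), are produced for visual inspection only. No statistics
are computed on t-SNE coordinates: its distances are not calibrated for
inference.

## Downstream performance audit

**Heads.** Three multilabel probabilistic heads of increasing capacity are
trained on the frozen embeddings: a single fully connected layer (`linear`)
and MLPs with three and five hidden layers (`mlp3`, `mlp5`; rectifier
activation, default width 256 — architecture details beyond the layer counts
are free choices here). The loss is independent per-label binary
cross-entropy; the frozen-backbone contract is absolute (no operation
modifies the embeddings). The linear head is convex and fit to convergence
per label; the MLPs are optimized by Adam in short epochs with the parameter
state achieving the best mean validation AUC (over non-degenerate labels)
retained. Labels constant in training are excluded from the selection
metric with a warning and predicted at their base rate by the linear head.

**Balanced test set.** Evaluation uses resampling with replacement so that
every (group × label-status × age-bin) stratum contributes equally (decade
age bins by default, edges 18,30,…,90,100), removing racial imbalance,
age differences, and prevalence differences from the comparison by
construction. The per-cell count defaults to roughly the original test-split
size divided by the number of strata, keeping bootstrap CI widths comparable
to an unbalanced evaluation. Strata with no members are a hard error that
names the offending cells — silently dropping them would silently unbalance
the design. Cohorts whose age distribution leaves decade tails empty should
pass coarser bins; the validation experiments use (18, 55, 70, 100).

**Operating point.** A single decision threshold τ per (model, label) is
calibrated on the pooled balanced sample to a target false-positive rate of
0.20: predictions are positive when score > τ, and τ is the smallest value
whose pooled FPR does not exceed the target (the conservative side; an exact
0.20 is generally unattainable on finite samples, so the achieved FPR is
always reported — for continuous scores it is within 1/n_neg of the
target). The threshold is then held fixed for every subgroup, so subgroup
TPR/FPR deviations are directly attributable to the model, not to
per-subgroup recalibration.

**Metrics.** Per subgroup: TPR and FPR at τ, the Youden J statistic
J = TPR − FPR as the single-number summary at the operating point, and the
threshold-free AUC. Subgroups missing a class get NaN with the metric
flagged as undefined, never silently dropped.

**Uncertainty.** 95% confidence intervals are percentile bootstrap with
2000 resamples of the evaluation rows, with τ held fixed (the uncertainty of
the operating point itself is not propagated — the audited quantity is
performance *at* the fixed threshold). The resampling unit is the patient:
all of a patient's drawn rows move together, so repeated scans do not
artificially narrow the intervals. Replicates on which a metric is undefined
are redrawn and counted. Percentile (rather than BCa) intervals are the
simplest method consistent with the design; coverage for a subgroup TPR at
n = 200 measures ≈ 0.95 in simulation.

**Disparity summary.** For each characteristic (sex audited against sex
subgroups, race against racial subgroups) the disparity measure is the
relative change (m_g − m̄)/m̄ against the unweighted mean m̄ over that
characteristic's subgroups; relative changes sum to zero by construction.
The mean-zero baseline fails when m̄ = 0 (e.g. a chance-level model), which
is raised as an error rather than reported as an unstable ratio.

## Synthetic cohort generator

The generator produces cohorts with the structure the audit assumes and
known ground truth, enabling recovery tests. Patients receive a racial
group (default three groups at 0.25/0.15/0.60 — imbalanced, as clinical
cohorts are), sex (0.55/0.45 male/female), age (normal 63 ± 17 years
truncated to [18, 100]; mean±SD-style summaries are how such cohorts are
reported), and a patient-level train/validation/test split (0.6/0.1/0.3; no
patient straddles splits). Each patient contributes 1–3 scans (uniform),
which exercises the one-scan-per-patient sensitivity path, and each scan
draws four binary condition labels with per-(group, label) prevalence.

Embeddings follow an additive linear effect model: each positive label
displaces the scan's feature vector along a label-specific direction by a
per-(group, label) effect size; sex and group membership add their own
displacements; a patient-level Gaussian random effect (SD 0.5 by default)
is shared across a patient's scans; isotropic Gaussian noise (SD 1) is
added per scan. All displacement magnitudes are expressed in units of the
noise SD. Direction vectors are mutually orthonormalized (Gram–Schmidt, in
the order disease labels → sex → groups) so injected effects are
statistically separable and ground truth unambiguous; user-supplied unit
vectors are orthogonalized in the same order, so a supplied vector late in
the order is rotated slightly — recovery checks should measure along the
*realized* directions returned by `effect_directions`.

Each operation draws from its own seeded RNG stream (config seed plus a
fixed per-operation offset), so cohort sampling, direction drawing, and
embedding noise are reproducible independently. All outputs are
bit-identical under a fixed seed.

**What the generator does and does not emulate.** It reproduces subgroup
imbalance, subgroup-dependent prevalence, repeated scans, and controllable
feature-space shifts. It does not model label co-occurrence structure,
acquisition/site effects, nonlinear or interaction encodings of demographics,
or any claim about how real networks encode protected attributes. Passing
recovery tests therefore show that the audit detects shifts and disparities
*of the injected additive form* at the configured sizes — not that it would
detect every mechanism present in real data.

## Validation experiments

`embaudit.experiments` packages the end-to-end checks (also run by
`scripts/acceptance.py` and the acceptance tests):

- pooled-FPR calibration on a ~10,000-scan synthetic test split hits 0.20
  within 1/n_neg;
- the t-SNE input retains ≥ 99% cumulative explained variance;
- the KS statistic matches an O(n²) brute-force sup exactly on 1000 random
  instances (n ≤ 200, including ties);
- the BY adjustment matches the step-down formula to 1e-12 on 1000 random
  p-vectors (m ≤ 50) and dominates Benjamini–Hochberg everywhere;
- under a zero-shift null (200 replicates × 16 tests) the BY-significant
  fraction stays far below α = 0.05;
- an injected pure sex shift δ reproduces the analytic Gaussian KS distance
  2Φ(δ/2) − 1 within 0.02 at 5000 per group;
- injected per-group disease effects (2.0σ, 1.0σ, 1.5σ) are recovered in
  ordering by the full train→balance→calibrate→J→relative-change pipeline in
  ≥ 90% of 20 seeded runs (measured: 20/20);
- the percentile bootstrap CI for a subgroup TPR covers the truth ≈ 95% of
  the time (300 replicates, n_boot = 500);
- structural identities hold exactly: J = TPR − FPR per row, relative
  changes sum to zero per panel, AUC equals the Mann–Whitney pairwise count,
  PCA variance ratios are non-increasing and match a dense
  eigendecomposition to 1e-8.

## Numerical and degenerate-input conventions

- KS p-values are clipped to (tiny, 1]; D = 0 gives p = 1 exactly.
- `calibrate_threshold` with target 1 returns a finite threshold just below
  the minimum score (achieved FPR 1); target 0 returns the maximum score.
- Constant embedding matrices, empty samples, p-values outside (0, 1],
  empty strata, subgroups with one class, and zero-mean disparity baselines
  all raise informative errors rather than returning NaN silently.
- KDE marginals are renormalized by trapezoid integration over the padded
  common grid, so each curve integrates to 1 by construction.

## Limitations

- The audit detects distributional differences; it cannot attribute them to
  population versus acquisition causes.
- The pooled BY family is conservative; per-characteristic families would
  have more power and can be composed from `adjust_benjamini_yekutieli`
  directly if wanted.
- Head hyperparameters (width, learning rate, budget) are exposed defaults,
  not tuned values; the audit's comparisons are between capacities under a
  shared budget.
- No bias *mitigation* is included — the package measures disparities, it
  does not correct them.
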