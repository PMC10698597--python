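"""Self-contained validation experiments for the audit pipeline.

Each function runs one end-to-end check of the package against an
independent oracle (analytic formula, brute-force enumeration, or
simulation with known ground truth) and returns the measured quantity.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .audit import bootstrap_ci, calibrate_threshold, relative_change, subgroup_metrics
from .config import AuditConfig, SyntheticConfig
from .heads import HeadSpec, train_head
from .inspection import adjust_benjamini_yekutieli, fit_pca, ks_two_sample, run_shift_audit
from .pipeline import audit_label
from .synthetic import effect_directions, generate_cohort, generate_embeddings

__all__ = [
    "calibration_experiment",
    "variance_retention_experiment",
    "ks_oracle_experiment",
    "by_formula_experiment",
    "null_calibration_experiment",
    "analytic_ks_experiment",
    "disparity_recovery_experiment",
    "bootstrap_coverage_experiment",
    "identity_experiment",
]

_COARSE_AGE_BINS = (18, 55, 70, 100)


def _null_config(seed: int, n_patients: int, embed_dim: int = 8) -> SyntheticConfig:
    """Zero-shift configuration: embeddings carry no subgroup information."""
    return SyntheticConfig(
        n_patients=n_patients,
        scans_per_patient=1,
        embed_dim=embed_dim,
        disease_effect_size=((0.0,) * 4,) * 3,
        sex_shift=0.0,
        group_shift=(0.0, 0.0, 0.0),
        patient_effect_sd=0.0,
        group_proportions=(1 / 3, 1 / 3, 1 / 3),
        sex_proportions=(0.5, 0.5),
        seed=seed,
    )


# ---------------------------------------------------------------------------
def calibration_experiment(seed: int, n_patients: int = 18000) -> dict:
    """Calibrate the pooled operating point on a large synthetic test split.

    Trains a linear head on the train split, scores the test split, and
    calibrates the decision threshold to a target pooled FPR of 0.20.
    Returns the achieved pooled FPR and the test-split size.
    """
    cfg = SyntheticConfig(n_patients=n_patients, embed_dim=32, seed=seed)
    cohort = generate_cohort(cfg)
    emb = generate_embeddings(cohort, cfg)
    tr = (cohort["split"] == "train").to_numpy()
    va = (cohort["split"] == "validation").to_numpy()
    te = (cohort["split"] == "test").to_numpy()
    Y = cohort[list(cfg.label_names)].to_numpy()
    head = train_head(emb[tr], Y[tr], emb[va], Y[va], HeadSpec("linear"), seed=seed)
    j = list(cfg.label_names).index("pleural_effusion")
    scores = head.predict_proba(emb[te])[:, j]
    y = Y[te, j]
    op = calibrate_threshold(scores[y == 0], target_fpr=0.20)
    return {"achieved_fpr": op.achieved_fpr, "n_test_scans": int(te.sum())}


def variance_retention_experiment(seed: int, n_patients: int = 1500) -> dict:
    """Check the t-SNE input retains the target 99% of embedding variance."""
    cfg = SyntheticConfig(n_patients=n_patients, embed_dim=32, seed=seed)
    cohort = generate_cohort(cfg)
    emb = generate_embeddings(cohort, cfg)
    proj = fit_pca(emb, n_modes=0.99)
    return {
        "retained_pct": 100.0 * proj.cumulative_variance,
        "n_modes": proj.n_modes,
        "n_scans": emb.shape[0],
    }


def ks_oracle_experiment(seed: int, n_instances: int = 1000) -> dict:
    """KS statistic vs an O(n^2) brute-force sup over pooled points."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for i in range(n_instances):
        na, nb = rng.integers(1, 201, size=2)
        a = rng.standard_normal(na)
        b = rng.standard_normal(nb) + rng.uniform(-1, 1)
        if i % 3 == 0:  # ties
            a, b = np.round(a, 1), np.round(b, 1)
        d, _ = ks_two_sample(a, b)
        pooled = np.concatenate([a, b])
        fa = (a[:, None] <= pooled[None, :]).mean(axis=0)
        fb = (b[:, None] <= pooled[None, :]).mean(axis=0)
        max_err = max(max_err, abs(d - float(np.max(np.abs(fa - fb)))))
    return {"max_abs_diff": max_err, "n_instances": n_instances}


def by_formula_experiment(seed: int, n_vectors: int = 1000) -> dict:
    """BY adjustment vs the naive step-down formula; dominance over BH."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    dominates = True
    for _ in range(n_vectors):
        m = int(rng.integers(1, 51))
        p = rng.uniform(1e-8, 1.0, size=m)
        adj = adjust_benjamini_yekutieli(p)
        order = np.argsort(p, kind="stable")
        c = sum(1.0 / k for k in range(1, m + 1))
        sp = p[order]
        expected = np.empty(m)
        for i in range(m):
            expected[order[i]] = min(
                1.0, min(sp[j] * m * c / (j + 1) for j in range(i, m))
            )
        max_err = max(max_err, float(np.max(np.abs(adj - expected))))
        # Benjamini-Hochberg: same step-down without the c(m) inflation
        bh = np.empty(m)
        scaled = sp * m / np.arange(1, m + 1)
        bh[order] = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        dominates = dominates and bool(np.all(adj >= bh - 1e-12))
    return {"max_abs_err": max_err, "dominates_bh": dominates, "n_vectors": n_vectors}


_NULL_COMPARISONS = [
    ("male", "female"),
    ("asian", "black"),
    ("asian", "white"),
    ("black", "white"),
]


def null_calibration_experiment(seed: int, n_reps: int = 200) -> dict:
    """Familywise behaviour of the shift audit under the simulated null.

    Zero-shift embeddings, 4 subgroup comparisons x 4 PCA modes per
    replicate, all BY-adjusted as one family at alpha = 0.05.  Returns the
    fraction of significant tests over all replicates; the BY procedure
    should keep it at or below alpha (it is conservative in practice).
    """
    audit_cfg_base = AuditConfig(n_modes_tested=4, per_group_subsample=100, alpha=0.05)
    n_sig = 0
    n_tests = 0
    for r in range(n_reps):
        cfg = _null_config(seed + 10_000 + r, n_patients=360)
        cohort = generate_cohort(cfg)
        emb = generate_embeddings(cohort, cfg)
        rep = run_shift_audit(
            emb, cohort, _NULL_COMPARISONS, audit_cfg_base.replace(seed=seed + 20_000 + r)
        )
        n_sig += rep.n_significant
        n_tests += len(rep.results)
    return {"significant_fraction": n_sig / n_tests, "n_tests": n_tests, "n_reps": n_reps}


def analytic_ks_experiment(seed: int, delta: float, n_per_group: int = 5000) -> dict:
    """Empirical KS distance of a pure Gaussian sex shift vs 2*Phi(d/2)-1."""
    cfg = _null_config(seed, n_patients=2 * n_per_group, embed_dim=16).replace(sex_shift=delta)
    cohort = generate_cohort(cfg)
    emb = generate_embeddings(cohort, cfg)
    axis = emb @ effect_directions(cfg)["sex"]
    male = cohort["sex"].to_numpy() == "male"
    d_hat, _ = ks_two_sample(axis[male], axis[~male])
    return {
        "d_hat": d_hat,
        "expected": float(2 * stats.norm.cdf(delta / 2) - 1),
        "n_per_group": n_per_group,
    }


def disparity_recovery_experiment(seed: int, n_runs: int = 20, n_patients: int = 8400) -> dict:
    """Recovery of an injected per-group disparity ordering by the pipeline.

    The audited label's disease displacement is 2.0 sigma for the first
    group, 1.0 for the second, and 1.5 for the third, so the per-group
    Youden J at the pooled threshold should order first > third > second.
    Each run executes the full chain: generate, train a linear head,
    balance the test set, calibrate the pooled threshold, compute subgroup
    J, and take relative changes.  Returns the fraction of runs whose
    relative-change ordering matches the injected one.
    """
    label = "pleural_effusion"
    recovered = 0
    for r in range(n_runs):
        cfg = SyntheticConfig(
            n_patients=n_patients,
            embed_dim=32,
            group_proportions=(1 / 3, 1 / 3, 1 / 3),
            disease_effect_size=(
                (1.0, 2.0, 1.0, 1.0),
                (1.0, 1.0, 1.0, 1.0),
                (1.0, 1.5, 1.0, 1.0),
            ),
            sex_shift=0.0,
            group_shift=(0.0, 0.0, 0.0),
            seed=seed + 1000 * r,
        )
        cohort = generate_cohort(cfg)
        emb = generate_embeddings(cohort, cfg)
        tr = (cohort["split"] == "train").to_numpy()
        va = (cohort["split"] == "validation").to_numpy()
        Y = cohort[list(cfg.label_names)].to_numpy()
        head = train_head(emb[tr], Y[tr], emb[va], Y[va], HeadSpec("linear"), seed=seed + r)
        result = audit_label(
            cohort,
            emb,
            head,
            label,
            cfg.label_names,
            characteristics=("group",),
            age_bins=_COARSE_AGE_BINS,
            n_boot=20,
            seed=seed + 500 + r,
        )
        rel = result.disparities["group"].relative_change
        if rel["asian"] > rel["white"] > rel["black"]:
            recovered += 1
    return {"recovery_rate": recovered / n_runs, "n_runs": n_runs}


def bootstrap_coverage_experiment(
    seed: int, n_reps: int = 300, n_boot: int = 500, n_rows: int = 200, true_tpr: float = 0.8
) -> dict:
    """Coverage of the percentile bootstrap CI for a subgroup TPR.

    Each replicate draws 200 positive scans classified correctly with
    probability 0.8 and checks whether the 95% percentile interval of the
    empirical TPR covers the true value.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for r in range(n_reps):
        hits = (rng.random(n_rows) < true_tpr).astype(float)

        def tpr_fn(idx, hits=hits):
            return float(hits[idx].mean())

        lo, hi, _ = bootstrap_ci(tpr_fn, n_rows, n_boot=n_boot, level=0.95, seed=seed + 777 + r)
        if lo <= true_tpr <= hi:
            covered += 1
    return {"coverage": covered / n_reps, "n_reps": n_reps}


def identity_experiment(seed: int, n_patients: int = 2500) -> dict:
    """Structural identities of one full audit report.

    Checks, on a single end-to-end run: J = TPR - FPR in every report row;
    relative changes sum to zero per characteristic; subgroup AUC equals the
    brute-force Mann-Whitney count on a small instance; and PCA
    explained-variance ratios are non-increasing and match a dense
    eigendecomposition.
    """
    cfg = SyntheticConfig(n_patients=n_patients, embed_dim=16, seed=seed)
    cohort = generate_cohort(cfg)
    emb = generate_embeddings(cohort, cfg)
    tr = (cohort["split"] == "train").to_numpy()
    va = (cohort["split"] == "validation").to_numpy()
    Y = cohort[list(cfg.label_names)].to_numpy()
    head = train_head(emb[tr], Y[tr], emb[va], Y[va], HeadSpec("linear"), seed=seed)
    result = audit_label(
        cohort, emb, head, "cardiomegaly", cfg.label_names,
        age_bins=_COARSE_AGE_BINS, n_boot=50, seed=seed,
    )
    frame = result.performance_frame()
    j_err = float(np.max(np.abs(frame["youden_j"] - (frame["tpr"] - frame["fpr"]))))
    rel_err = max(
        abs(sum(rep.relative_change.values())) for rep in result.disparities.values()
    )

    rng = np.random.default_rng(seed)
    y = rng.binomial(1, 0.5, 80)
    y[:2] = [0, 1]
    s = np.round(rng.random(80), 2)
    op = calibrate_threshold(s[y == 0], 0.2)
    auc = subgroup_metrics(s, y, np.repeat("all", 80), op)[0].auc
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc_err = abs(auc - wins / (pos.size * neg.size))

    x = rng.standard_normal((300, 6)) @ rng.standard_normal((6, 6))
    proj = fit_pca(x)
    eig = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1]
    pca_err = float(np.max(np.abs(proj.explained_variance_ratio - eig / eig.sum())))
    nonincreasing = bool(np.all(np.diff(proj.explained_variance_ratio) <= 1e-12))

    return {
        "youden_identity_max_abs_err": j_err,
        "relative_change_sum_max_abs": float(rel_err),
        "auc_brute_force_abs_err": float(auc_err),
        "pca_eigendecomposition_max_abs_err": pca_err,
        "pca_ratios_nonincreasing": nonincreasing,
        "n_report_rows": len(frame),
    }
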