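"""Tests of PCA projection, KS testing, BY adjustment, and the shift audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from embaudit import (
    AuditConfig,
    SyntheticConfig,
    adjust_benjamini_yekutieli,
    balanced_subsample,
    fit_pca,
    generate_cohort,
    generate_embeddings,
    ks_two_sample,
    normalized_marginals,
    run_shift_audit,
    tsne_view,
)

from conftest import by_hand_formula, ks_brute_force


class TestFitPCA:
    def test_rank_one_data(self):
        t = np.linspace(-1, 1, 50)
        x = np.column_stack([t, 2 * t])
        proj = fit_pca(x)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0)
        assert proj.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_ratios_near_uniform(self, rng):
        x = rng.standard_normal((10000, 8))
        proj = fit_pca(x)
        assert np.allclose(proj.explained_variance_ratio, 1 / 8, atol=0.02)

    def test_ratios_sum_to_one_and_nonincreasing(self, small_embeddings):
        proj = fit_pca(small_embeddings)
        r = proj.explained_variance_ratio
        assert r.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0) & (r <= 1))

    def test_components_orthonormal_and_reconstruction(self, small_embeddings):
        proj = fit_pca(small_embeddings)
        v = proj.component_vectors
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-6)
        recon = proj.coordinates @ v.T + proj.mean_vector
        assert np.allclose(recon, small_embeddings, atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        x = rng.standard_normal((200, 6)) @ rng.standard_normal((6, 6))
        proj = fit_pca(x)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1]
        assert np.allclose(proj.explained_variance_ratio, eigvals / eigvals.sum(), atol=1e-8)

    def test_variance_fraction_target_is_minimal(self, rng):
        scales = np.array([5.0, 3.0, 1.0, 0.5, 0.1, 0.01])
        x = rng.standard_normal((2000, 6)) * scales
        full = fit_pca(x)
        cum = np.cumsum(full.explained_variance_ratio)
        target = 0.9
        proj = fit_pca(x, n_modes=target)
        k = proj.n_modes
        assert cum[k - 1] >= target
        assert k == 1 or cum[k - 2] < target

    def test_deterministic_sign_convention(self, rng):
        x = rng.standard_normal((100, 4))
        a, b = fit_pca(x), fit_pca(x.copy())
        assert np.array_equal(a.component_vectors, b.component_vectors)
        idx = np.argmax(np.abs(a.component_vectors), axis=0)
        assert np.all(a.component_vectors[idx, np.arange(a.n_modes)] > 0)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            fit_pca(np.ones((10, 3)))  # constant matrix
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((3, 5)), n_modes=4)  # fewer rows than modes


class TestBalancedSubsample:
    def test_counts_per_group(self, small_cohort):
        sub = balanced_subsample(small_cohort, per_group_n=40, seed=0)
        assert len(sub.indices) == 40 * 3
        groups = small_cohort.iloc[sub.indices]["group"].astype(str)
        assert groups.value_counts().eq(40).all()

    def test_one_scan_per_sampled_patient_without_replacement(self, small_cohort):
        sub = balanced_subsample(small_cohort, per_group_n=30, seed=1)
        assert all(not v for v in sub.with_replacement.values())
        picked = small_cohort.iloc[sub.indices]
        assert picked["patient_id"].is_unique

    def test_zero_request_gives_empty_list(self, small_cohort):
        assert balanced_subsample(small_cohort, per_group_n=0, seed=0).indices.size == 0

    def test_deterministic(self, small_cohort):
        a = balanced_subsample(small_cohort, per_group_n=25, seed=9)
        b = balanced_subsample(small_cohort, per_group_n=25, seed=9)
        assert np.array_equal(a.indices, b.indices)

    def test_replacement_flagged_when_group_small(self, small_cohort):
        n_black = small_cohort.drop_duplicates("patient_id")["group"].eq("black").sum()
        sub = balanced_subsample(small_cohort, per_group_n=n_black + 10, seed=2)
        assert sub.with_replacement["black"] is True
        counts = small_cohort.iloc[sub.indices]["group"].astype(str).value_counts()
        assert counts["black"] == n_black + 10

    def test_empty_group_errors(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["group"] = cohort["group"].cat.add_categories(["ghost"])
        with pytest.raises(ValueError, match="empty group"):
            balanced_subsample(cohort, per_group_n=5, seed=0)


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0
        assert p == 1

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2], [10, 11])
        assert d == 1

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(60) + 0.3
        assert ks_two_sample(a, b) == ks_two_sample(b, a)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_sup(self, trial):
        rng = np.random.default_rng(trial)
        na, nb = rng.integers(1, 200, size=2)
        a = rng.standard_normal(na)
        b = rng.standard_normal(nb) + rng.uniform(-1, 1)
        if trial % 3 == 0:  # exercise ties
            a = np.round(a, 1)
            b = np.round(b, 1)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(ks_brute_force(a, b), abs=1e-14)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBenjaminiYekutieli:
    def test_single_p_is_identity(self):
        assert adjust_benjamini_yekutieli([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        c4 = 1 + 1 / 2 + 1 / 3 + 1 / 4  # 25/12
        raw = [p_i * 4 * c4 / i for p_i, i in zip(p, [1, 2, 3, 4])]
        # step-down: each adjusted value is the min of scaled values from its rank up
        expected = [min(raw[i:]) for i in range(4)]
        assert np.allclose(adjust_benjamini_yekutieli(p), np.minimum(1, expected), atol=1e-15)

    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_formula_and_dominates_bh(self, p):
        adj = adjust_benjamini_yekutieli(p)
        assert np.allclose(adj, by_hand_formula(p), atol=1e-12)
        bh = multipletests(p, method="fdr_bh")[1]
        by_sm = multipletests(p, method="fdr_by")[1]
        assert np.all(adj >= bh - 1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.allclose(adj, by_sm, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_benjamini_yekutieli([0.0, 0.5])
        with pytest.raises(ValueError):
            adjust_benjamini_yekutieli([0.5, 1.5])


def _null_cfg(seed, n_patients=400, embed_dim=8):
    return SyntheticConfig(
        n_patients=n_patients,
        scans_per_patient=1,
        embed_dim=embed_dim,
        disease_effect_size=((0.0,) * 4,) * 3,
        sex_shift=0.0,
        group_shift=(0.0, 0.0, 0.0),
        patient_effect_sd=0.0,
        group_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=seed,
    )


COMPARISONS = [("male", "female"), ("asian", "black"), ("asian", "white"), ("black", "white")]


class TestRunShiftAudit:
    def test_empty_comparisons_give_empty_report(self, small_cohort, small_embeddings):
        rep = run_shift_audit(small_embeddings, small_cohort, [], AuditConfig(per_group_subsample=30))
        assert rep.results == []
        assert rep.to_frame().empty

    def test_report_shape_and_flags(self, small_cohort, small_embeddings):
        cfg = AuditConfig(n_modes_tested=3, per_group_subsample=40, seed=4)
        rep = run_shift_audit(small_embeddings, small_cohort, COMPARISONS, cfg)
        df = rep.to_frame()
        assert len(df) == len(COMPARISONS) * 3
        assert (df["p_adjusted"] >= df["p_raw"] - 1e-15).all()
        assert (df["significant"] == (df["p_adjusted"] < cfg.alpha)).all()
        total = rep.significance_summary()["n_tests"].sum()
        assert total == len(df)

    def test_unknown_subgroup_errors(self, small_cohort, small_embeddings):
        with pytest.raises(ValueError, match="resolve"):
            run_shift_audit(
                small_embeddings, small_cohort, [("martian", "female")],
                AuditConfig(per_group_subsample=20),
            )

    def test_injected_sex_shift_detected(self):
        cfg = _null_cfg(77, n_patients=2500).replace(sex_shift=1.0)
        cohort = generate_cohort(cfg)
        emb = generate_embeddings(cohort, cfg)
        rep = run_shift_audit(
            emb, cohort, COMPARISONS, AuditConfig(per_group_subsample=500, seed=1)
        )
        df = rep.to_frame()
        sex = df[df["characteristic"] == "sex"]
        assert sex["significant"].any()
        # race comparisons carry no injected shift
        race = df[df["characteristic"] == "group"]
        assert race["significant"].sum() <= 1

    def test_disease_contrast_uses_exclusive_positives(self, small_cohort, small_embeddings):
        rep = run_shift_audit(
            small_embeddings,
            small_cohort,
            [("no_finding", "pleural_effusion")],
            AuditConfig(n_modes_tested=2, per_group_subsample=50, seed=3),
        )
        assert all(r.characteristic == "disease" for r in rep.results)


class TestQualitativeViews:
    def test_tsne_shape_and_determinism(self, rng):
        x = rng.standard_normal((120, 6))
        proj = fit_pca(x, n_modes=0.99)
        cfg = AuditConfig(tsne_perplexity=10, seed=5)
        a = tsne_view(proj, cfg)
        b = tsne_view(proj, cfg)
        assert a.shape == (120, 2)
        assert np.array_equal(a, b)

    def test_tsne_separates_distant_clusters(self, rng):
        labels = np.repeat([0, 1], 100)
        x = rng.standard_normal((200, 5))
        x[labels == 1, 0] += 10.0
        coords = tsne_view(fit_pca(x, n_modes=0.99), AuditConfig(tsne_perplexity=15, seed=0))
        assert silhouette_score(coords, labels) > 0.5

    def test_tsne_needs_two_modes(self):
        t = np.linspace(0, 1, 50)
        proj = fit_pca(np.column_stack([t, 2 * t]), n_modes=1)
        with pytest.raises(ValueError):
            tsne_view(proj, AuditConfig())

    def test_marginals_integrate_to_one(self, rng):
        grid, dens = normalized_marginals(
            {"a": rng.standard_normal(300), "b": rng.standard_normal(500) + 1}
        )
        for d in dens.values():
            assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-3)

    def test_identical_subgroups_identical_densities(self, rng):
        v = rng.standard_normal(200)
        _, dens = normalized_marginals({"a": v, "b": v.copy()})
        assert np.array_equal(dens["a"], dens["b"])

    def test_gaussian_density_at_zero(self, rng):
        v = rng.standard_normal(5000)
        grid, dens = normalized_marginals({"x": v})
        at0 = np.interp(0.0, grid, dens["x"])
        assert at0 == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.05)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            normalized_marginals({"a": [1.0]})
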