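"""Tests of the synthetic cohort and embedding generator."""

import numpy as np
import pytest
from scipy import stats

from embaudit import (
    ConfigError,
    SyntheticConfig,
    effect_directions,
    generate_cohort,
    generate_embeddings,
    ks_two_sample,
)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SyntheticConfig(group_proportions=(0.5, 0.2, 0.2))

    def test_group_list_mismatch(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(group_names=("a", "b"), group_proportions=(0.3, 0.3, 0.4))

    def test_embed_dim_must_fit_directions(self):
        # 4 labels + sex + 3 groups = 8 direction vectors
        with pytest.raises(ConfigError, match="direction"):
            SyntheticConfig(embed_dim=5)

    def test_non_unit_direction_rejected(self):
        v = np.zeros(16)
        v[0] = 2.0
        with pytest.raises(ConfigError, match="unit norm"):
            SyntheticConfig(embed_dim=16, sex_direction=tuple(v))

    def test_negative_effect_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(sex_shift=-0.1)

    def test_roundtrip_through_dict(self):
        cfg = SyntheticConfig(n_patients=10, seed=3)
        assert SyntheticConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateCohort:
    def test_group_counts_within_binomial_band(self):
        """With equal proportions, each group count falls in the 99% binomial band."""
        cfg = SyntheticConfig(
            n_patients=3000,
            group_proportions=(1 / 3, 1 / 3, 1 / 3),
            seed=0,
        )
        cohort = generate_cohort(cfg)
        per_patient = cohort.drop_duplicates("patient_id")
        lo = stats.binom.ppf(0.005, 3000, 1 / 3)
        hi = stats.binom.ppf(0.995, 3000, 1 / 3)
        counts = per_patient["group"].value_counts()
        for g in cfg.group_names:
            assert lo <= counts[g] <= hi

    def test_zero_prevalence_gives_all_negative_labels(self):
        cfg = SyntheticConfig(
            n_patients=200, prevalence=((0.0,) * 4,) * 3, seed=1
        )
        cohort = generate_cohort(cfg)
        assert (cohort[list(cfg.label_names)].to_numpy() == 0).all()

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_patients=150, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.to_csv() == b.to_csv()

    def test_patients_do_not_straddle_splits(self, small_cohort):
        per_patient = small_cohort.groupby("patient_id", observed=True)["split"].nunique()
        assert (per_patient == 1).all()

    def test_scan_ids_unique_and_ages_in_range(self, small_cohort):
        assert small_cohort["scan_id"].is_unique
        assert small_cohort["age"].between(18, 100).all()

    def test_prevalence_converges(self):
        cfg = SyntheticConfig(n_patients=8000, seed=11)
        cohort = generate_cohort(cfg)
        prev = np.asarray(cfg.prevalence)
        for g_idx, g in enumerate(cfg.group_names):
            sub = cohort[cohort["group"] == g]
            emp = sub[list(cfg.label_names)].mean().to_numpy()
            assert np.allclose(emp, prev[g_idx], atol=0.03)


class TestGenerateEmbeddings:
    def test_deterministic_given_seed(self, small_config, small_cohort):
        a = generate_embeddings(small_cohort, small_config)
        b = generate_embeddings(small_cohort, small_config)
        assert np.array_equal(a, b)

    def test_directions_are_orthonormal(self, small_config):
        dirs = effect_directions(small_config)
        stacked = np.vstack([dirs["disease"], dirs["sex"][None, :], dirs["group"]])
        gram = stacked @ stacked.T
        assert np.allclose(gram, np.eye(len(stacked)), atol=1e-9)

    def test_null_embeddings_are_isotropic(self):
        """All shifts zero: rows are i.i.d. N(0, noise_sd^2 I)."""
        cfg = SyntheticConfig(
            n_patients=4000,
            scans_per_patient=1,
            embed_dim=8,
            disease_effect_size=((0.0,) * 4,) * 3,
            sex_shift=0.0,
            group_shift=(0.0, 0.0, 0.0),
            patient_effect_sd=0.0,
            seed=5,
        )
        cohort = generate_cohort(cfg)
        x = generate_embeddings(cohort, cfg)
        assert abs(x.mean()) < 0.02
        cov = np.cov(x.T)
        assert np.allclose(cov, np.eye(8), atol=0.08)

    def test_sex_shift_matches_analytic_ks_distance(self):
        """Pure Gaussian mean shift delta: population D = 2*Phi(delta/2) - 1."""
        delta = 1.0
        d = 16
        sex_dir = np.zeros(d)
        sex_dir[0] = 1.0
        cfg = SyntheticConfig(
            n_patients=10000,
            scans_per_patient=1,
            embed_dim=d,
            disease_effect_size=((0.0,) * 4,) * 3,
            sex_shift=delta,
            sex_direction=tuple(sex_dir),
            group_shift=(0.0, 0.0, 0.0),
            patient_effect_sd=0.0,
            sex_proportions=(0.5, 0.5),
            seed=17,
        )
        cohort = generate_cohort(cfg)
        x = generate_embeddings(cohort, cfg)
        male = cohort["sex"].to_numpy() == "male"
        # project onto the realized (orthogonalized) sex direction
        axis = x @ effect_directions(cfg)["sex"]
        d_hat, _ = ks_two_sample(axis[male], axis[~male])
        expected = 2 * stats.norm.cdf(delta / 2) - 1
        assert abs(d_hat - expected) < 0.02

    def test_patient_effect_correlates_same_patient_scans(self):
        cfg = SyntheticConfig(
            n_patients=500,
            scans_per_patient=2,
            embed_dim=16,
            disease_effect_size=((0.0,) * 4,) * 3,
            sex_shift=0.0,
            group_shift=(0.0, 0.0, 0.0),
            patient_effect_sd=1.0,
            seed=23,
        )
        cohort = generate_cohort(cfg)
        x = generate_embeddings(cohort, cfg)
        first = cohort.drop_duplicates("patient_id").index.to_numpy()
        same = [np.corrcoef(x[i], x[i + 1])[0, 1] for i in first]
        diff = [np.corrcoef(x[i], x[j + 1])[0, 1] for i, j in zip(first[:-1], first[1:])]
        # within-patient correlation ~ 1/(1+1) = 0.5; across patients ~ 0
        assert np.mean(same) > 0.3
        assert abs(np.mean(diff)) < 0.1

    def test_dimension_mismatch_raises(self, small_cohort):
        other = SyntheticConfig(label_names=("only_label",), prevalence=((0.5,), (0.5,), (0.5,)),
                                disease_effect_size=((1.0,), (1.0,), (1.0,)), embed_dim=16)
        with pytest.raises(ConfigError):
            generate_embeddings(small_cohort.drop(columns=["no_finding"]), other)
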