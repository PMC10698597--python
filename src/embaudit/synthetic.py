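"""Synthetic cohort and embedding generator with known ground truth.

Emulates the statistical structure a representation-bias audit assumes in a
multi-site imaging cohort: imbalanced demographic subgroups, subgroup-
dependent disease prevalence, repeated scans per patient, and a feature
(embedding) space in which disease status, biologic sex, and group
membership each displace the distribution along known directions by
configurable amounts.

The embedding model is additive and linear: for a scan of patient ``p`` in
group ``g`` with binary labels ``y``,

    x = noise_sd * ( sum_l y_l * effect[g, l] * d_l
                     + 1[male] * sex_shift * d_sex
                     + group_shift[g] * d_group[g] )
        + u_p + eps,

with ``eps ~ N(0, noise_sd^2 I)`` i.i.d. per scan and a patient-level random
effect ``u_p ~ N(0, patient_effect_sd^2 I)`` shared across a patient's
scans.  Shift magnitudes are therefore expressed in units of the noise SD.
Direction vectors are mutually orthonormalized before use so the injected
effects are statistically separable; this is a deliberate simplification —
no claim is made about how demographic attributes are actually encoded in
real learned features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, SyntheticConfig

__all__ = [
    "generate_cohort",
    "generate_embeddings",
    "effect_directions",
    "SPLITS",
]

SPLITS = ("train", "validation", "test")

# fixed per-operation offsets on config.seed: reproducible streams that do
# not couple cohort sampling, direction drawing, and embedding noise
_SEED_COHORT = 1
_SEED_EMBED = 2
_SEED_DIRECTIONS = 3


def _orthonormalize(vectors: np.ndarray) -> np.ndarray:
    """Gram–Schmidt orthonormalization of stacked row vectors."""
    q, r = np.linalg.qr(vectors.T)
    # fix signs so each output vector keeps a positive projection on its input
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs).T


def effect_directions(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Resolve the orthonormal effect directions used by the generator.

    Returns a dict with keys ``disease`` (n_labels, d), ``sex`` (d,), and
    ``group`` (n_groups, d).  User-supplied directions are orthogonalized in
    the order disease labels, sex, groups; missing ones are drawn from a
    seeded Gaussian before orthogonalization.
    """
    rng = np.random.default_rng(config.seed + _SEED_DIRECTIONS)
    d = config.embed_dim
    blocks = []
    if config.disease_directions is not None:
        blocks.append(np.asarray(config.disease_directions, dtype=float))
    else:
        blocks.append(rng.standard_normal((config.n_labels, d)))
    if config.sex_direction is not None:
        blocks.append(np.asarray(config.sex_direction, dtype=float)[None, :])
    else:
        blocks.append(rng.standard_normal((1, d)))
    if config.group_directions is not None:
        blocks.append(np.asarray(config.group_directions, dtype=float))
    else:
        blocks.append(rng.standard_normal((config.n_groups, d)))
    stacked = np.vstack(blocks)
    ortho = _orthonormalize(stacked)
    nl = config.n_labels
    return {
        "disease": ortho[:nl],
        "sex": ortho[nl],
        "group": ortho[nl + 1 :],
    }


def _truncated_normal_ages(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a per-scan metadata table.

    Patients are assigned a group, sex, age (normal, truncated to
    ``config.age_range``), and a train/validation/test split at the patient
    level (no patient straddles splits).  Each patient contributes a number
    of scans drawn uniformly from ``config.scans_per_patient``, and each
    scan draws its binary labels independently with the configured
    per-(group, label) prevalence.

    Returns a DataFrame with columns ``patient_id``, ``scan_id``, ``sex``,
    ``group``, ``age``, ``split``, and one 0/1 column per label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _SEED_COHORT)
    n = config.n_patients

    group_idx = rng.choice(config.n_groups, size=n, p=np.asarray(config.group_proportions))
    sex = np.where(rng.random(n) < config.sex_proportions[0], "male", "female")
    ages = np.empty(n)
    for g, (mu, sd) in enumerate(config.age_mean_sd_per_group):
        mask = group_idx == g
        if mask.any():
            ages[mask] = _truncated_normal_ages(
                rng, mu, sd, config.age_range[0], config.age_range[1], int(mask.sum())
            )
    split = rng.choice(SPLITS, size=n, p=np.asarray(config.split_fractions))
    n_scans = rng.choice(np.asarray(config.scans_per_patient_choices), size=n)

    patient_rows = np.repeat(np.arange(n), n_scans)
    total = patient_rows.size
    prev = np.asarray(config.prevalence, dtype=float)
    scan_prev = prev[group_idx[patient_rows]]  # (total, n_labels)
    labels = (rng.random((total, config.n_labels)) < scan_prev).astype(np.int8)

    table = pd.DataFrame(
        {
            "patient_id": [f"p{i:06d}" for i in patient_rows],
            "scan_id": [f"s{i:07d}" for i in range(total)],
            "sex": pd.Categorical(sex[patient_rows], categories=["male", "female"]),
            "group": pd.Categorical(
                np.asarray(config.group_names)[group_idx[patient_rows]],
                categories=list(config.group_names),
            ),
            "age": ages[patient_rows],
            "split": pd.Categorical(split[patient_rows], categories=list(SPLITS)),
        }
    )
    for j, name in enumerate(config.label_names):
        table[name] = labels[:, j]
    return table


def generate_embeddings(cohort: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Generate the scan-aligned embedding matrix for a cohort.

    Applies the additive linear effect model described in the module
    docstring.  With all shifts and effect sizes zero the rows are i.i.d.
    isotropic Gaussian with SD ``sqrt(noise_sd^2 + patient_effect_sd^2)``.
    Deterministic given ``config.seed``.
    """
    required = {"patient_id", "group", "sex", *config.label_names}
    missing = required - set(cohort.columns)
    if missing:
        raise ConfigError(f"cohort is missing columns required by the config: {sorted(missing)}")
    observed_groups = set(cohort["group"].unique())
    if not observed_groups <= set(config.group_names):
        raise ConfigError(
            f"cohort groups {sorted(observed_groups)} not covered by config groups "
            f"{list(config.group_names)}"
        )

    rng = np.random.default_rng(config.seed + _SEED_EMBED)
    dirs = effect_directions(config)
    d = config.embed_dim
    n = len(cohort)

    group_idx = pd.Categorical(cohort["group"], categories=list(config.group_names)).codes
    male = (cohort["sex"].to_numpy() == "male").astype(float)
    y = cohort[list(config.label_names)].to_numpy(dtype=float)
    eff = np.asarray(config.disease_effect_size, dtype=float)

    mean = (y * eff[group_idx]) @ dirs["disease"]
    mean += male[:, None] * config.sex_shift * dirs["sex"][None, :]
    mean += np.asarray(config.group_shift)[group_idx, None] * dirs["group"][group_idx]
    mean *= config.noise_sd

    # patient random effect, shared across a patient's scans
    patients, patient_pos = np.unique(cohort["patient_id"].to_numpy(), return_inverse=True)
    u = rng.standard_normal((patients.size, d)) * config.patient_effect_sd
    eps = rng.standard_normal((n, d)) * config.noise_sd
    x = mean + u[patient_pos] + eps
    if not np.all(np.isfinite(x)):  # pragma: no cover - defensive
        raise FloatingPointError("non-finite values in generated embeddings")
    return x
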