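"""Balanced evaluation-set construction and patient-level de-duplication.

Subgroup performance estimates computed on a raw test split confound model
behaviour with cohort composition: racial groups differ in size, age
profile, and disease prevalence.  ``balance_test_set`` removes these
confounders by construction — it resamples with replacement so every
(group × label-status × age-bin) stratum contributes the same number of
rows, giving equal group frequencies, equal prevalence across groups, and
matched age profiles in the evaluation set.

``one_scan_per_patient`` supports the sensitivity analysis that removes
within-patient clustering from cohorts with repeated scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BalancedIndex", "balance_test_set", "one_scan_per_patient", "DEFAULT_AGE_BINS"]

# decade bins spanning adult ages; the first bin is wider to keep young
# strata populated
DEFAULT_AGE_BINS = (18, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass
class BalancedIndex:
    """Row indices of a stratum-balanced resample, with provenance."""

    indices: np.ndarray  # positional row indices, repetition allowed
    strata: pd.DataFrame  # one row per index: group, label status, age bin
    label: str
    age_bins: tuple[float, ...]
    n_per_cell: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        out = self.strata.copy()
        out.insert(0, "row_index", self.indices)
        return out


def balance_test_set(
    cohort: pd.DataFrame,
    label: str,
    age_bins=DEFAULT_AGE_BINS,
    n_per_cell: int = 50,
    seed: int = 0,
    group_col: str = "group",
) -> BalancedIndex:
    """Resample with replacement to equalize (group × status × age-bin) strata.

    Every stratum contributes exactly ``n_per_cell`` draws, so the balanced
    set has equal group frequencies, 50% prevalence of ``label`` in every
    group, and identical age-bin profiles across groups.  Strata with no
    members make balancing impossible; they are reported in the error.
    """
    if label not in cohort.columns:
        raise ValueError(f"label {label!r} not in cohort columns")
    age_bins = tuple(float(b) for b in age_bins)
    if len(age_bins) < 2 or any(b2 <= b1 for b1, b2 in zip(age_bins, age_bins[1:])):
        raise ValueError("age_bins must be strictly increasing with at least 2 edges")
    if n_per_cell < 0:
        raise ValueError("n_per_cell must be nonnegative")

    groups = sorted(cohort[group_col].astype(str).unique())
    status = cohort[label].to_numpy().astype(int)
    age_bin = pd.cut(cohort["age"], bins=list(age_bins), include_lowest=True)
    bin_labels = list(age_bin.cat.categories)

    rng = np.random.default_rng(seed)
    group_vals = cohort[group_col].astype(str).to_numpy()
    bin_codes = age_bin.cat.codes.to_numpy()

    empty_cells = []
    picks, stratum_rows = [], []
    for g in groups:
        for s in (0, 1):
            for b_code, b in enumerate(bin_labels):
                cell = np.flatnonzero((group_vals == g) & (status == s) & (bin_codes == b_code))
                if cell.size == 0:
                    empty_cells.append((g, s, str(b)))
                    continue
                draw = rng.choice(cell, size=n_per_cell, replace=True)
                picks.append(draw)
                stratum_rows.extend(
                    {"group": g, "label_status": s, "age_bin": str(b)} for _ in range(n_per_cell)
                )
    if empty_cells:
        raise ValueError(
            "cannot balance: empty (group, label-status, age-bin) strata: "
            + ", ".join(map(str, empty_cells))
        )
    indices = np.concatenate(picks) if picks else np.empty(0, dtype=int)
    return BalancedIndex(
        indices=indices.astype(int),
        strata=pd.DataFrame(stratum_rows),
        label=label,
        age_bins=age_bins,
        n_per_cell=n_per_cell,
        seed=seed,
    )


def one_scan_per_patient(cohort: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Select exactly one scan per patient, uniformly at random.

    Returns sorted positional row indices; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    patients = cohort["patient_id"].to_numpy()
    order = pd.Series(np.arange(len(cohort))).groupby(patients)
    chosen = [int(rows.iloc[rng.integers(len(rows))]) for _, rows in order]
    return np.sort(np.asarray(chosen, dtype=int))
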