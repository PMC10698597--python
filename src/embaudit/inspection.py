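"""Feature-space subgroup shift detection.

The audit projects scan embeddings onto their leading principal-component
modes, draws a demographically balanced patient subsample, and compares the
marginal distribution of each tested mode between pairs of subgroups with
two-sample Kolmogorov–Smirnov tests.  All p-values of one audit form a
single family and are adjusted with the Benjamini–Yekutieli procedure,
which controls the false discovery rate under arbitrary dependence — the
conservative choice given that PCA modes of the same embedding are not
independent.

A t-SNE view (on the PCA modes retaining a target fraction of variance) and
independently normalized marginal densities are provided for qualitative
inspection only; no statistics are computed on the t-SNE coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.utils.validation import check_is_fitted

from .config import AuditConfig

__all__ = [
    "EmbeddingPCA",
    "ProjectionResult",
    "ShiftTestResult",
    "ShiftTestReport",
    "BalancedSubsample",
    "fit_pca",
    "balanced_subsample",
    "ks_two_sample",
    "adjust_benjamini_yekutieli",
    "run_shift_audit",
    "tsne_view",
    "normalized_marginals",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------
class EmbeddingPCA(TransformerMixin, BaseEstimator):
    """PCA of embedding matrices with a deterministic sign convention.

    Features are centered but not scaled; components come from a full SVD of
    the centered matrix.  The sign of each component is fixed by making its
    largest-magnitude loading positive, so repeated fits of the same data
    yield identical modes (the sign of a principal axis is otherwise
    arbitrary).

    Parameters
    ----------
    n_modes : int or float, default=None
        Number of leading modes to keep.  A float in (0, 1] is a cumulative
        explained-variance target: the minimal number of leading modes whose
        cumulative explained variance ratio meets the target is kept.
        ``None`` keeps all modes.
    """

    def __init__(self, n_modes: int | float | None = None):
        self.n_modes = n_modes

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("embedding matrix contains non-finite values")
        if np.allclose(X, X[0], atol=0):
            raise ValueError("embedding matrix is constant (zero variance)")
        max_modes = min(X.shape)
        if isinstance(self.n_modes, (int, np.integer)):
            if self.n_modes < 1:
                raise ValueError("n_modes must be positive")
            if self.n_modes > max_modes:
                raise ValueError(
                    f"requested {self.n_modes} modes but only {max_modes} are available "
                    f"for a matrix of shape {X.shape}"
                )
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X)
        components = pca.components_
        # deterministic sign: largest-|loading| entry of each mode positive
        flip = np.sign(components[np.arange(len(components)), np.argmax(np.abs(components), axis=1)])
        flip[flip == 0] = 1.0
        components = components * flip[:, None]

        ratios = pca.explained_variance_ratio_
        if self.n_modes is None:
            k = components.shape[0]
        elif isinstance(self.n_modes, (int, np.integer)):
            k = int(self.n_modes)
        else:
            target = float(self.n_modes)
            if not (0 < target <= 1):
                raise ValueError("variance-fraction target must lie in (0, 1]")
            k = int(np.searchsorted(np.cumsum(ratios), target - 1e-12) + 1)
            k = min(k, components.shape[0])
        self.components_ = components[:k]
        self.explained_variance_ratio_ = ratios[:k]
        self.all_explained_variance_ratio_ = ratios
        self.mean_ = pca.mean_
        self.n_modes_ = k
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, coords):
        check_is_fitted(self, "components_")
        return np.asarray(coords) @ self.components_ + self.mean_


@dataclass
class ProjectionResult:
    """PCA modes, explained-variance ratios, and projected coordinates."""

    component_vectors: np.ndarray  # (embed_dim, n_modes), columns orthonormal
    explained_variance_ratio: np.ndarray  # (n_modes,)
    coordinates: np.ndarray  # (n_scans, n_modes)
    mean_vector: np.ndarray  # (embed_dim,)
    all_explained_variance_ratio: np.ndarray = None  # full spectrum

    @property
    def n_modes(self) -> int:
        return self.component_vectors.shape[1]

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


def fit_pca(embeddings, n_modes: int | float | None = None) -> ProjectionResult:
    """Fit PCA and project; thin functional wrapper over :class:`EmbeddingPCA`.

    ``n_modes`` may be an integer count or a variance-fraction target in
    (0, 1] (minimal leading modes meeting the target are returned).
    """
    est = EmbeddingPCA(n_modes=n_modes).fit(embeddings)
    return ProjectionResult(
        component_vectors=est.components_.T.copy(),
        explained_variance_ratio=est.explained_variance_ratio_.copy(),
        coordinates=est.transform(embeddings),
        mean_vector=est.mean_.copy(),
        all_explained_variance_ratio=est.all_explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# balanced subsampling
# ---------------------------------------------------------------------------
@dataclass
class BalancedSubsample:
    """Row indices of a per-group balanced patient subsample."""

    indices: np.ndarray  # positional row indices into the cohort
    with_replacement: dict[str, bool]  # per group: was replacement needed?
    per_group_n: int
    seed: int


def balanced_subsample(
    cohort: pd.DataFrame,
    per_group_n: int,
    seed: int,
    group_col: str = "group",
) -> BalancedSubsample:
    """Sample ``per_group_n`` patients per group, one scan each.

    The sampling unit is the patient: patients are drawn without replacement
    where the group is large enough (with replacement otherwise, flagged in
    the output), and one of each sampled patient's scans is chosen uniformly
    at random.  Returns positional row indices into ``cohort``.
    """
    if group_col not in cohort.columns:
        raise ValueError(f"cohort has no column {group_col!r}")
    rng = np.random.default_rng(seed)
    group_vals = cohort[group_col].astype(str).to_numpy()
    patient_vals = cohort["patient_id"].to_numpy()
    indices: list[int] = []
    with_replacement: dict[str, bool] = {}
    if isinstance(cohort[group_col].dtype, pd.CategoricalDtype):
        declared = [str(c) for c in cohort[group_col].dtype.categories]
        empty = [g for g in declared if (group_vals == g).sum() == 0]
        if empty:
            raise ValueError(f"empty group(s): {empty}")
        groups = sorted(declared)
    else:
        groups = sorted({g for g in group_vals if g != "nan"})
    for g in groups:
        pos = np.flatnonzero(group_vals == g)
        patients = pd.unique(patient_vals[pos])
        if patients.size == 0:
            raise ValueError(f"group {g!r} is empty")
        replace = patients.size < per_group_n
        with_replacement[g] = bool(replace)
        chosen = rng.choice(patients, size=per_group_n, replace=replace)
        # map patient -> row positions once, then pick one scan per patient
        scans_of = pd.Series(pos).groupby(patient_vals[pos]).apply(np.asarray).to_dict()
        for p in chosen:
            scans = scans_of[p]
            indices.append(int(scans[rng.integers(scans.size)]))
    return BalancedSubsample(
        indices=np.asarray(indices, dtype=int),
        with_replacement=with_replacement,
        per_group_n=per_group_n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# KS test and BY adjustment
# ---------------------------------------------------------------------------
def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    ``D`` is the supremum of the absolute empirical-CDF difference over the
    pooled sample points; the p-value comes from the two-sided asymptotic
    Kolmogorov distribution evaluated at ``sqrt(n_a n_b / (n_a + n_b)) * D``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d = float(stats.ks_2samp(a, b, method="asymp").statistic)
    ne = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(ne) * d))
    return d, min(max(p, np.finfo(float).tiny), 1.0)


def adjust_benjamini_yekutieli(p_values) -> np.ndarray:
    """Benjamini–Yekutieli FDR adjustment, valid under arbitrary dependence.

    With order statistics ``p_(1) <= ... <= p_(m)`` the adjusted value is

        adj_(i) = min(1, min_{j >= i} p_(j) * m * c(m) / j),   c(m) = sum_{k<=m} 1/k,

    returned in the input order.  Adjusted values dominate both the raw
    p-values and the Benjamini–Hochberg adjustment (which omits ``c(m)``).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    scaled = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# shift audit
# ---------------------------------------------------------------------------
@dataclass
class ShiftTestResult:
    """One subgroup comparison on one PCA mode."""

    comparison: tuple[str, str]
    characteristic: str  # "sex", "group", or "disease"
    mode_index: int  # 1-based
    ks_statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False


@dataclass
class ShiftTestReport:
    """All subgroup × mode KS tests of one audit, jointly BY-adjusted."""

    results: list[ShiftTestResult]
    explained_variance_ratio: np.ndarray
    alpha: float
    n_modes_tested: int
    subsample: BalancedSubsample | None = None
    adjustment: str = "benjamini-yekutieli (single pooled family)"

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: comparison × mode with D, raw/adjusted p, flag."""
        return pd.DataFrame(
            {
                "characteristic": [r.characteristic for r in self.results],
                "comparison": [f"{r.comparison[0]} vs {r.comparison[1]}" for r in self.results],
                "mode": [r.mode_index for r in self.results],
                "ks_statistic": [r.ks_statistic for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "p_adjusted": [r.p_adjusted for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )

    def significance_summary(self) -> pd.DataFrame:
        """Per-characteristic tally of significant tests ("k of n" style)."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(columns=["characteristic", "n_significant", "n_tests"])
        g = df.groupby("characteristic", sort=True)["significant"]
        return (
            pd.DataFrame({"n_significant": g.sum().astype(int), "n_tests": g.count()})
            .reset_index()
        )

    @property
    def n_significant(self) -> int:
        return int(sum(r.significant for r in self.results))


def _resolve_comparison(cohort: pd.DataFrame, pair: tuple[str, str], label_names) -> tuple[str, np.ndarray, np.ndarray]:
    """Map a subgroup pair to boolean row masks and a characteristic name.

    A pair of label-column names is a disease contrast: rows positive for
    exactly one of the two labels are compared.  Otherwise both levels must
    be categories of a single demographic column (sex or group).
    """
    a, b = pair
    if a in label_names and b in label_names:
        ya = cohort[a].to_numpy().astype(bool)
        yb = cohort[b].to_numpy().astype(bool)
        return "disease", ya & ~yb, yb & ~ya
    for col in ("sex", "group"):
        if col in cohort.columns:
            levels = set(map(str, cohort[col].dtype.categories)) if isinstance(
                cohort[col].dtype, pd.CategoricalDtype
            ) else set(map(str, cohort[col].unique()))
            if a in levels and b in levels:
                vals = cohort[col].astype(str).to_numpy()
                return col, vals == a, vals == b
    raise ValueError(f"cannot resolve comparison {pair!r} against cohort columns")


def run_shift_audit(
    embeddings,
    cohort: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    config: AuditConfig,
    label_names: tuple[str, ...] | None = None,
) -> ShiftTestReport:
    """Run the full feature-space shift audit.

    Pipeline: fit PCA on all embeddings, draw a balanced per-group patient
    subsample, then for every requested subgroup comparison and every tested
    mode run a two-sample KS test on the mode's marginal.  All p-values are
    adjusted together as one Benjamini–Yekutieli family and flagged at
    ``config.alpha``.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if len(cohort) != embeddings.shape[0]:
        raise ValueError(
            f"cohort has {len(cohort)} rows but embeddings have {embeddings.shape[0]}"
        )
    if label_names is None:
        known = {"patient_id", "scan_id", "sex", "group", "age", "split"}
        label_names = tuple(c for c in cohort.columns if c not in known)

    n_modes = config.n_modes_tested
    projection = fit_pca(embeddings, n_modes=None)
    if projection.n_modes < n_modes:
        raise ValueError(
            f"only {projection.n_modes} PCA modes available, {n_modes} requested"
        )
    sub = balanced_subsample(cohort, config.per_group_subsample, seed=config.seed)
    coords = projection.coordinates[sub.indices]
    sub_cohort = cohort.iloc[sub.indices].reset_index(drop=True)

    results: list[ShiftTestResult] = []
    for pair in comparisons:
        characteristic, mask_a, mask_b = _resolve_comparison(sub_cohort, tuple(pair), label_names)
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ValueError(f"comparison {pair!r} has an empty side in the balanced subsample")
        for mode in range(n_modes):
            d, p = ks_two_sample(coords[mask_a, mode], coords[mask_b, mode])
            results.append(
                ShiftTestResult(
                    comparison=tuple(pair),
                    characteristic=characteristic,
                    mode_index=mode + 1,
                    ks_statistic=d,
                    p_raw=p,
                )
            )
    if results:
        adjusted = adjust_benjamini_yekutieli([r.p_raw for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = float(p_adj)
            r.significant = bool(p_adj < config.alpha)
    return ShiftTestReport(
        results=results,
        explained_variance_ratio=projection.all_explained_variance_ratio,
        alpha=config.alpha,
        n_modes_tested=n_modes,
        subsample=sub,
    )


# ---------------------------------------------------------------------------
# qualitative views
# ---------------------------------------------------------------------------
def tsne_view(projection: ProjectionResult, config: AuditConfig) -> np.ndarray:
    """2-D t-SNE of the retained PCA coordinates (qualitative use only).

    The projection should retain the configured variance fraction (default
    99%).  Deterministic given ``config.seed``; perplexity is clamped below
    the sample count as t-SNE requires.
    """
    if projection.n_modes < 2:
        raise ValueError("need at least 2 retained PCA modes for a t-SNE view")
    n = projection.coordinates.shape[0]
    perplexity = min(config.tsne_perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=config.seed,
        max_iter=500,
    )
    return tsne.fit_transform(projection.coordinates)


def normalized_marginals(
    values_by_subgroup: dict[str, np.ndarray],
    grid_size: int = 512,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-subgroup Gaussian-KDE densities on a common grid.

    Each subgroup's density is normalized independently (so subgroup base
    rates drop out of the comparison) and integrates to 1 over the returned
    grid.  Requires at least 2 values per subgroup.
    """
    if not values_by_subgroup:
        raise ValueError("no subgroups given")
    cleaned = {}
    for name, v in values_by_subgroup.items():
        v = np.asarray(v, dtype=float).ravel()
        if v.size < 2:
            raise ValueError(f"subgroup {name!r} has fewer than 2 values")
        cleaned[name] = v
    lo = min(v.min() for v in cleaned.values())
    hi = max(v.max() for v in cleaned.values())
    span = hi - lo if hi > lo else 1.0
    grid = np.linspace(lo - 0.5 * span, hi + 0.5 * span, grid_size)
    densities = {}
    for name, v in cleaned.items():
        if np.ptp(v) == 0:  # degenerate: all values equal; KDE undefined
            raise ValueError(f"subgroup {name!r} has zero variance")
        kde = stats.gaussian_kde(v)
        dens = kde(grid)
        dens = dens / np.trapezoid(dens, grid)
        densities[name] = dens
    return grid, densities
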