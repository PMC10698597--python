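"""Subgroup performance and disparity metrics at a fixed operating point.

The operating point is a decision threshold calibrated once on the pooled
evaluation sample so the pooled false-positive rate meets a target (default
0.20), and then held fixed for every subgroup — deviations of a subgroup's
TPR/FPR from the pooled rates are then directly interpretable as
performance disparities.  The single-number summary at the threshold is the
Youden J statistic, J = TPR − FPR.  AUC is reported threshold-free.

Confidence intervals are percentile bootstrap over resampled evaluation
rows with the threshold held fixed; the resampling unit is the patient, so
within-patient correlation between repeated scans does not narrow the
intervals.  Disparities are summarized as the relative change of each
subgroup's metric against the unweighted mean over the audited subgroups of
one characteristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "OperatingPoint",
    "SubgroupPerformance",
    "DisparityReport",
    "calibrate_threshold",
    "subgroup_metrics",
    "bootstrap_ci",
    "relative_change",
]


@dataclass(frozen=True)
class OperatingPoint:
    """A fixed decision threshold with its pooled-sample FPR."""

    threshold: float
    target_fpr: float
    achieved_fpr: float
    n_neg: int
    label: str | None = None


def calibrate_threshold(negative_scores, target_fpr: float = 0.20, label: str | None = None) -> OperatingPoint:
    """Smallest threshold whose pooled FPR does not exceed the target.

    Predictions are positive when ``score > threshold``.  On finite samples
    the target is generally not attainable exactly; the threshold admitting
    the largest FPR not exceeding it is chosen and the achieved FPR
    reported.  For continuous scores ``|achieved - target| <= 1/n_neg``.
    """
    s = np.asarray(negative_scores, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("no negative scores to calibrate on")
    if not np.all(np.isfinite(s)):
        raise ValueError("negative scores must be finite")
    if not (0 <= target_fpr <= 1):
        raise ValueError("target_fpr must lie in [0, 1]")
    n = s.size
    desc = np.sort(s)[::-1]
    k = int(np.floor(target_fpr * n))  # admissible false positives
    if k >= n:
        tau = float(np.nextafter(desc[-1], -np.inf))
    else:
        tau = float(desc[k])
    achieved = float(np.mean(s > tau))
    return OperatingPoint(
        threshold=tau, target_fpr=float(target_fpr), achieved_fpr=achieved, n_neg=n, label=label
    )


@dataclass
class SubgroupPerformance:
    """Per-subgroup metrics at the pooled operating point."""

    subgroup: str
    label: str | None
    tpr: float
    fpr: float
    youden_j: float
    auc: float
    n_pos: int
    n_neg: int
    undefined: tuple[str, ...] = ()
    ci: dict = field(default_factory=dict)  # metric -> (lower, upper)

    def as_dict(self) -> dict:
        d = {
            "subgroup": self.subgroup,
            "label": self.label,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "youden_j": self.youden_j,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "undefined": ";".join(self.undefined),
        }
        for metric, (lo, hi) in self.ci.items():
            d[f"{metric}_ci_lower"] = lo
            d[f"{metric}_ci_upper"] = hi
        return d


def _rates(scores, y, tau):
    pos = y == 1
    neg = y == 0
    tpr = float(np.mean(scores[pos] > tau)) if pos.any() else np.nan
    fpr = float(np.mean(scores[neg] > tau)) if neg.any() else np.nan
    return tpr, fpr, int(pos.sum()), int(neg.sum())


def subgroup_metrics(scores, labels, subgroup_assignment, op: OperatingPoint, label_name: str | None = None) -> list[SubgroupPerformance]:
    """TPR, FPR, Youden J, and AUC per subgroup at the pooled threshold.

    The threshold is *not* recalibrated per subgroup.  A subgroup missing a
    class gets NaN for the affected metrics with the metric names flagged in
    ``undefined`` (never silently dropped).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    groups = np.asarray(subgroup_assignment).astype(str).ravel()
    if not (scores.size == y.size == groups.size):
        raise ValueError("scores, labels, and subgroup assignment must be row-aligned")
    out = []
    for g in sorted(np.unique(groups)):
        m = groups == g
        tpr, fpr, n_pos, n_neg = _rates(scores[m], y[m], op.threshold)
        undefined = []
        if n_pos == 0:
            undefined.append("tpr")
        if n_neg == 0:
            undefined.append("fpr")
        if n_pos == 0 or n_neg == 0:
            undefined.append("auc")
            auc = np.nan
        else:
            auc = float(roc_auc_score(y[m], scores[m]))
        j = tpr - fpr
        if "tpr" in undefined or "fpr" in undefined:
            undefined.append("youden_j")
        out.append(
            SubgroupPerformance(
                subgroup=g,
                label=label_name if label_name is not None else op.label,
                tpr=tpr,
                fpr=fpr,
                youden_j=j,
                auc=auc,
                n_pos=n_pos,
                n_neg=n_neg,
                undefined=tuple(undefined),
            )
        )
    return out


def bootstrap_ci(
    metric_fn,
    n_rows: int,
    patient_ids=None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, float, int]:
    """Percentile bootstrap interval for a row-resampling metric.

    ``metric_fn`` maps an integer row-index array to a scalar; it is called
    on ``n_boot`` resamples drawn with replacement.  The resampling unit is
    the patient when ``patient_ids`` is given (all of a patient's rows move
    together), otherwise the row.  Replicates on which the metric is
    undefined (NaN) are redrawn and counted; the count is returned.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if n_rows < 1:
        raise ValueError("need at least one evaluation row")
    rng = np.random.default_rng(seed)
    if patient_ids is not None:
        pids = np.asarray(patient_ids)
        if pids.size != n_rows:
            raise ValueError("patient_ids must align with rows")
        uniq, inv = np.unique(pids, return_inverse=True)
        rows_of = [np.flatnonzero(inv == i) for i in range(uniq.size)]
        n_units = uniq.size
    else:
        rows_of = None
        n_units = n_rows

    stats_ = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            units = rng.integers(0, n_units, size=n_units)
            idx = (
                np.concatenate([rows_of[u] for u in units]) if rows_of is not None else units
            )
            val = metric_fn(idx)
            if np.isfinite(val):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("metric undefined on every redrawn bootstrap replicate")
        stats_[b] = val
    alpha = 1 - level
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi), n_redrawn


@dataclass
class DisparityReport:
    """Relative change of each subgroup's metric against the subgroup mean."""

    metric_name: str
    label: str | None
    values: dict[str, float]
    relative_change: dict[str, float]
    mean: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subgroup": list(self.values),
                "metric": self.metric_name,
                "label": self.label,
                "value": [self.values[g] for g in self.values],
                "relative_change": [self.relative_change[g] for g in self.values],
            }
        )


def relative_change(values: dict[str, float], metric_name: str = "youden_j", label: str | None = None) -> DisparityReport:
    """(metric_g − mean) / mean against the unweighted subgroup mean.

    The baseline is the unweighted mean over the audited subgroups of one
    characteristic (sex is audited against sex subgroups, race against
    racial subgroups).  Outputs sum to zero by construction.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 subgroups")
    vals = np.asarray([values[g] for g in values], dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("all subgroup metrics must be finite")
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("subgroup mean is 0; relative change undefined")
    rel = {g: (values[g] - mean) / mean for g in values}
    return DisparityReport(
        metric_name=metric_name, label=label, values=dict(values), relative_change=rel, mean=mean
    )
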