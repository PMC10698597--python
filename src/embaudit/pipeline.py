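"""End-to-end orchestration of the performance audit.

Order of operations for one (head, label) pair: score the test split with
the frozen-feature head, build a demographically balanced evaluation set by
stratified resampling, calibrate the decision threshold to the target
pooled FPR on that balanced set, compute per-subgroup TPR/FPR/Youden-J/AUC
at the fixed threshold with patient-level bootstrap CIs, and summarize
disparities as relative changes against the per-characteristic subgroup
mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audit import (
    DisparityReport,
    OperatingPoint,
    SubgroupPerformance,
    bootstrap_ci,
    calibrate_threshold,
    relative_change,
    subgroup_metrics,
)
from .heads import ClassificationHead
from .resampling import DEFAULT_AGE_BINS, balance_test_set

__all__ = ["PerformanceAuditResult", "audit_label", "score_label"]


@dataclass
class PerformanceAuditResult:
    """Everything the audit produces for one (head, label) pair."""

    label: str
    head_name: str
    operating_point: OperatingPoint
    performances: dict[str, list[SubgroupPerformance]]  # characteristic -> rows
    disparities: dict[str, DisparityReport]  # characteristic -> report

    def performance_frame(self) -> pd.DataFrame:
        rows = []
        for characteristic, perfs in self.performances.items():
            for p in perfs:
                d = p.as_dict()
                d["characteristic"] = characteristic
                d["head"] = self.head_name
                d["threshold"] = self.operating_point.threshold
                d["achieved_pooled_fpr"] = self.operating_point.achieved_fpr
                rows.append(d)
        return pd.DataFrame(rows)

    def disparity_frame(self) -> pd.DataFrame:
        frames = []
        for characteristic, rep in self.disparities.items():
            f = rep.to_frame()
            f.insert(0, "characteristic", characteristic)
            f.insert(0, "head", self.head_name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def score_label(head: ClassificationHead, embeddings, label_names, label: str) -> np.ndarray:
    """Probability scores of one label column from a trained head."""
    j = list(label_names).index(label)
    return head.predict_proba(np.asarray(embeddings, dtype=float))[:, j]


def audit_label(
    cohort: pd.DataFrame,
    embeddings,
    head: ClassificationHead,
    label: str,
    label_names,
    head_name: str = "head",
    characteristics: tuple[str, ...] = ("sex", "group"),
    target_fpr: float = 0.20,
    age_bins=DEFAULT_AGE_BINS,
    n_per_cell: int | None = None,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    split: str | None = "test",
) -> PerformanceAuditResult:
    """Audit one label end to end on the (balanced) test split.

    ``n_per_cell`` defaults to roughly the original test-split size divided
    by the number of strata, so the balanced set is about as large as the
    split it replaces and bootstrap CI widths stay comparable.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if split is not None:
        mask = (cohort["split"].astype(str) == split).to_numpy()
        eval_cohort = cohort.loc[mask].reset_index(drop=True)
        eval_emb = embeddings[mask]
    else:
        eval_cohort = cohort.reset_index(drop=True)
        eval_emb = embeddings

    n_groups = eval_cohort["group"].astype(str).nunique()
    n_strata = n_groups * 2 * (len(age_bins) - 1)
    if n_per_cell is None:
        n_per_cell = max(1, int(round(len(eval_cohort) / n_strata)))

    balanced = balance_test_set(
        eval_cohort, label, age_bins=age_bins, n_per_cell=n_per_cell, seed=seed
    )
    rows = balanced.indices
    scores_all = score_label(head, eval_emb, label_names, label)
    scores = scores_all[rows]
    y = eval_cohort[label].to_numpy().astype(int)[rows]
    patients = eval_cohort["patient_id"].to_numpy()[rows]

    op = calibrate_threshold(scores[y == 0], target_fpr=target_fpr, label=label)

    performances: dict[str, list[SubgroupPerformance]] = {}
    disparities: dict[str, DisparityReport] = {}
    for characteristic in characteristics:
        assignment = eval_cohort[characteristic].astype(str).to_numpy()[rows]
        perfs = subgroup_metrics(scores, y, assignment, op, label_name=label)
        for k, perf in enumerate(perfs):
            m = assignment == perf.subgroup
            sub_scores, sub_y, sub_pids = scores[m], y[m], patients[m]

            def make_fn(metric):
                def fn(idx):
                    s, yy = sub_scores[idx], sub_y[idx]
                    if metric == "tpr":
                        return np.mean(s[yy == 1] > op.threshold) if (yy == 1).any() else np.nan
                    if metric == "fpr":
                        return np.mean(s[yy == 0] > op.threshold) if (yy == 0).any() else np.nan
                    if metric == "youden_j":
                        if not ((yy == 1).any() and (yy == 0).any()):
                            return np.nan
                        return np.mean(s[yy == 1] > op.threshold) - np.mean(
                            s[yy == 0] > op.threshold
                        )
                    if metric == "auc":
                        if len(np.unique(yy)) < 2:
                            return np.nan
                        from sklearn.metrics import roc_auc_score

                        return roc_auc_score(yy, s)
                    raise ValueError(metric)

                return fn

            for mi, metric in enumerate(("tpr", "fpr", "youden_j", "auc")):
                lo, hi, _ = bootstrap_ci(
                    make_fn(metric),
                    n_rows=int(m.sum()),
                    patient_ids=sub_pids,
                    n_boot=n_boot,
                    level=ci_level,
                    seed=seed + 1000 * k + mi,
                )
                perf.ci[metric] = (lo, hi)
        performances[characteristic] = perfs
        disparities[characteristic] = relative_change(
            {p.subgroup: p.youden_j for p in perfs}, metric_name="youden_j", label=label
        )
    return PerformanceAuditResult(
        label=label,
        head_name=head_name,
        operating_point=op,
        performances=performances,
        disparities=disparities,
    )
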