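"""Tabular and graphical output of audit results.

All tabular outputs are CSV with fixed headers and deterministic float
formatting so that re-running a subcommand with the same config reproduces
the files byte-identically.  Every run directory carries a manifest
recording the config hash and all seeds, because an audit tool should
itself be auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import config_hash
from .inspection import ShiftTestReport, normalized_marginals

__all__ = [
    "write_csv",
    "write_shift_report",
    "write_manifest",
    "plot_marginals",
    "plot_disparities",
]

_FLOAT_FMT = "%.10g"


def write_csv(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_shift_report(report: ShiftTestReport, out_dir) -> dict[str, Path]:
    """Write the KS-test table, the per-mode variance ratios, and the tally."""
    out_dir = Path(out_dir)
    paths = {
        "tests": write_csv(report.to_frame(), out_dir / "shift_tests.csv"),
        "summary": write_csv(report.significance_summary(), out_dir / "shift_summary.csv"),
        "variance": write_csv(
            pd.DataFrame(
                {
                    "mode": np.arange(1, len(report.explained_variance_ratio) + 1),
                    "explained_variance_ratio": report.explained_variance_ratio,
                }
            ),
            out_dir / "explained_variance.csv",
        ),
    }
    return paths


def write_manifest(out_dir, config, seeds: dict[str, int], extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "seeds": seeds,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def plot_marginals(
    coordinates: np.ndarray,
    cohort: pd.DataFrame,
    characteristic: str,
    modes: tuple[int, ...] = (1, 2, 3, 4),
    out_path=None,
):
    """Independently normalized per-subgroup marginal densities per mode."""
    groups = sorted(cohort[characteristic].astype(str).unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(3.2 * len(modes), 2.8), squeeze=False)
    for ax, mode in zip(axes[0], modes):
        values = {
            g: coordinates[(cohort[characteristic].astype(str) == g).to_numpy(), mode - 1]
            for g in groups
        }
        grid, densities = normalized_marginals(values)
        for g in groups:
            ax.plot(grid, densities[g], label=g, lw=1.2)
        ax.set_title(f"mode {mode}")
        ax.set_yticks([])
    axes[0, 0].legend(fontsize=7)
    fig.suptitle(f"normalized marginals by {characteristic}")
    fig.tight_layout()
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return out_path
    return fig


def plot_disparities(disparity_frame: pd.DataFrame, out_path=None):
    """Bar chart of relative Youden-J change per subgroup, per characteristic."""
    characteristics = disparity_frame["characteristic"].unique()
    fig, axes = plt.subplots(
        1, len(characteristics), figsize=(4.0 * len(characteristics), 3.0), squeeze=False
    )
    for ax, ch in zip(axes[0], characteristics):
        sub = disparity_frame[disparity_frame["characteristic"] == ch]
        ax.bar(sub["subgroup"], 100 * sub["relative_change"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("relative change vs subgroup mean (%)")
        ax.set_title(str(ch))
    fig.tight_layout()
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return out_path
    return fig
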