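"""Summary tables, recovery diagnostics and figures.

Figures are conveniences; every number behind a figure is also written as
CSV by the CLI, which is the actual interface.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def treatment_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean T_imm with t-based 95% confidence intervals.

    Censored subjects (NaN timm_s) are excluded per group and counted. A
    single-subject group gets no interval (NaN bounds, noted in the log).
    """
    rows = []
    for treatment, grp in results.groupby("treatment", sort=True):
        timm = grp["timm_s"].dropna().to_numpy(dtype=float)
        n = timm.size
        mean = float(timm.mean()) if n else float("nan")
        if n >= 2:
            half = float(stats.t.ppf(0.975, n - 1) * timm.std(ddof=1) / np.sqrt(n))
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
            logger.warning(
                "treatment %r has %d uncensored subject(s); CI omitted", treatment, n
            )
        rows.append(
            {
                "treatment": treatment,
                "n": n,
                "n_censored": int(grp["timm_s"].isna().sum()),
                "mean_timm_s": mean,
                "ci95_low_s": lo,
                "ci95_high_s": hi,
            }
        )
    return pd.DataFrame(rows)


def recovery_diagnostics(results: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """How well estimated T_imm recovers the simulator's true T*.

    Returns Pearson correlation, mean bias (estimate minus truth, s) and
    RMSE (s) over uncensored subjects.
    """
    merged = results.merge(truth[["subject_id", "true_t_star_s"]], on="subject_id")
    merged = merged.dropna(subset=["timm_s"])
    if len(merged) < 2:
        raise ValueError("recovery diagnostics need at least two uncensored subjects")
    est = merged["timm_s"].to_numpy(dtype=float)
    true = merged["true_t_star_s"].to_numpy(dtype=float)
    err = est - true
    return {
        "n": int(len(merged)),
        "pearson_r": float(stats.pearsonr(est, true)[0]),
        "bias_s": float(err.mean()),
        "rmse_s": float(np.sqrt((err**2).mean())),
    }


def plot_r2_surface(
    surface: pd.DataFrame,
    path: str | Path,
    optimum: tuple[float, int] | None = None,
    max_plot_v_thresh: float | None = None,
) -> None:
    """Heatmap of R-squared over (v_thresh, w), optimum marked.

    ``max_plot_v_thresh`` truncates the displayed threshold axis (the upper
    part of the grid is often flat and uninformative to look at); the full
    surface is always in the CSV.
    """
    df = surface[surface["valid"]].copy()
    if max_plot_v_thresh is not None:
        df = df[df["v_thresh"] <= max_plot_v_thresh]
    if df.empty:
        raise ValueError("nothing to plot: no valid cells in range")
    pivot = df.pivot_table(index="w", columns="v_thresh", values="r_squared")
    fig, ax = plt.subplots(figsize=(7, 5))
    mesh = ax.pcolormesh(
        pivot.columns.to_numpy(),
        pivot.index.to_numpy(),
        pivot.to_numpy(),
        shading="nearest",
        cmap="viridis",
    )
    fig.colorbar(mesh, ax=ax, label="$R^2$")
    if optimum is not None:
        ax.plot(optimum[0], optimum[1], "r*", markersize=14, label="optimum")
        ax.legend(loc="upper right")
    ax.set_xlabel("$V_{thresh}$ (mm/s)")
    ax.set_ylabel("$w$ (observations)")
    ax.set_title("Variance in $T_{imm}$ explained by treatment + size")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timm_vs_size(results: pd.DataFrame, path: str | Path) -> None:
    """Scatter of T_imm against body size, one colour per treatment."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for treatment, grp in results.groupby("treatment", sort=True):
        sub = grp.dropna(subset=["timm_s", "body_size_mm"])
        ax.scatter(sub["body_size_mm"], sub["timm_s"], s=12, alpha=0.7, label=str(treatment))
    ax.set_xlabel("body size (mm)")
    ax.set_ylabel("$T_{imm}$ (s)")
    ax.legend(title="treatment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_treatment_means(summary: pd.DataFrame, path: str | Path) -> None:
    """Group mean T_imm with 95% CIs across treatments."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    x = np.arange(len(summary))
    yerr = np.vstack(
        [
            summary["mean_timm_s"] - summary["ci95_low_s"],
            summary["ci95_high_s"] - summary["mean_timm_s"],
        ]
    )
    ax.errorbar(x, summary["mean_timm_s"], yerr=np.nan_to_num(yerr), fmt="o", capsize=4)
    ax.set_xticks(x, summary["treatment"].astype(str))
    ax.set_xlabel("treatment")
    ax.set_ylabel("mean $T_{imm}$ (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
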