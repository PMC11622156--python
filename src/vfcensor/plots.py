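"""Optional matplotlib figures: threshold heatmap, agreement scatter, Bland-Altman."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .agreement import BAResult, FitResult
from .threshold_search import ThresholdGridResult

__all__ = ["plot_heatmap", "plot_scatter", "plot_bland_altman"]


def plot_heatmap(result: ThresholdGridResult, path: str | Path) -> None:
    """Heatmap of the mean censored TD difference over the threshold grid."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        result.mean_diff,
        origin="lower",
        aspect="auto",
        cmap="RdBu_r",
        vmin=-np.nanmax(np.abs(result.mean_diff)),
        vmax=np.nanmax(np.abs(result.mean_diff)),
        extent=(
            result.grid_V[0] - 0.5,
            result.grid_V[-1] + 0.5,
            result.grid_III[0] - 0.5,
            result.grid_III[-1] + 0.5,
        ),
    )
    ax.plot(result.best.threshold_V, result.best.threshold_III, "k*", ms=12)
    ax.set_xlabel("size V censoring threshold (dB)")
    ax.set_ylabel("size III censoring threshold (dB)")
    fig.colorbar(im, ax=ax, label="mean censored TD difference (dB)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(point_pairs: pd.DataFrame, fit: FitResult, path: str | Path) -> None:
    """TD_III vs TD_V scatter with the line of unity and the OLS fit."""
    fig, ax = plt.subplots(figsize=(6, 6))
    cen = point_pairs["pair_censored"]
    for mask, color, label in ((~cen, "tab:blue", "uncensored"), (cen, "tab:orange", "censored")):
        ax.plot(
            point_pairs.loc[mask, "td_iii_db"],
            point_pairs.loc[mask, "td_v_db"],
            ".", color=color, alpha=0.1, ms=3, label=label,
        )
    lims = np.array(ax.get_xlim())
    ax.plot(lims, lims, "g:", label="line of unity (y = x)")
    ax.plot(lims, fit.intercept + fit.slope * lims, "k-",
            label=f"fit: y = {fit.intercept:.2f} + {fit.slope:.2f}x (r² = {fit.r_squared:.2f})")
    ax.set_xlabel("size III TD (dB)")
    ax.set_ylabel("size V TD (dB)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(ba: BAResult, table: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["mean_db"], table["diff_db"], ".", color="tab:blue", alpha=0.1, ms=3)
    ax.axhline(ba.mean_diff, color="gray", ls="--", label=f"mean {ba.mean_diff:.2f} dB")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="red", ls="--")
    ax.set_xlabel("mean of TD pair (dB)")
    ax.set_ylabel("TD_V − TD_III (dB)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
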