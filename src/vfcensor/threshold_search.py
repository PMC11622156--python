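"""Exhaustive grid search for the censoring-threshold pair.

For each candidate pair (t_III, t_V) the search censors the raw
sensitivities, converts to TDs, restricts to the censored point pairs
(those where at least one raw value fell below its threshold) and records
the mean and SD of d = TD_V - TD_III.  The optimum is the cell whose mean
censored difference is closest to zero — the pair of thresholds at which
the two stimuli, after clamping away their noise-dominated sub-floor
ranges, read the same on the TD scale.

The objective is |mean| alone; the SD enters only to resolve ties.  A
"tie" is judged at the resolution the data supports: every cell whose
|mean| lies within ``tie_se_factor`` standard errors (of the argmin
cell's mean) of the minimal |mean| is considered statistically
indistinguishable from the optimum, and the tied set resolves to the
lowest SD, then the lower t_III, then the lower t_V.  With exact
arithmetic (hand-built toys) this reduces to exact-equality ties; on
finite noisy cohorts it keeps the selection from flipping between cells
whose means differ by less than their own sampling error, preferring the
most stable of them.  Cells whose censored subset is smaller than
``min_count`` are excluded so the argmin cannot land on noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .censoring import CensorConfig, PairMatrix
from .io import FieldPair
from .normative import NormativeTable

logger = logging.getLogger("vfcensor.threshold_search")

__all__ = ["CellStats", "ThresholdGridResult", "evaluate_cell", "grid_search"]

DEFAULT_GRID = tuple(range(15, 31))  # brackets the debated 17-25 dB range


@dataclass(frozen=True)
class CellStats:
    """Censored-pair difference statistics at one threshold pair."""

    mean_diff: float  # NaN when no pair is censored
    sd_diff: float  # sample SD (n-1); NaN when n < 2
    n_censored: int

    @property
    def empty(self) -> bool:
        return self.n_censored == 0


@dataclass
class ThresholdGridResult:
    grid_III: np.ndarray
    grid_V: np.ndarray
    mean_diff: np.ndarray  # shape (len(grid_III), len(grid_V))
    sd_diff: np.ndarray
    n_censored: np.ndarray
    best: CensorConfig
    objective_at_best: float
    min_count: int = 0

    def heatmap_frame(self) -> pd.DataFrame:
        """mean_diff as a DataFrame (rows = t_III, columns = t_V)."""
        return pd.DataFrame(
            self.mean_diff,
            index=pd.Index(self.grid_III, name="t_III"),
            columns=pd.Index(self.grid_V, name="t_V"),
        )

    def to_dict(self) -> dict:
        return {
            "grid_III": [float(t) for t in self.grid_III],
            "grid_V": [float(t) for t in self.grid_V],
            "mean_diff": [[None if np.isnan(v) else float(v) for v in row] for row in self.mean_diff],
            "sd_diff": [[None if np.isnan(v) else float(v) for v in row] for row in self.sd_diff],
            "n_censored": self.n_censored.astype(int).tolist(),
            "best": {
                "threshold_III": float(self.best.threshold_III),
                "threshold_V": float(self.best.threshold_V),
            },
            "objective_at_best": float(self.objective_at_best),
            "min_count": int(self.min_count),
        }

    def write(self, json_path: str | Path, heatmap_csv_path: str | Path | None = None) -> None:
        Path(json_path).write_text(json.dumps(self.to_dict(), indent=2))
        if heatmap_csv_path is not None:
            self.heatmap_frame().to_csv(heatmap_csv_path)


def _cell_from_arrays(diff: np.ndarray, mask: np.ndarray) -> CellStats:
    vals = diff[mask]
    n = vals.size
    if n == 0:
        return CellStats(float("nan"), float("nan"), 0)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n >= 2 else float("nan")
    return CellStats(mean, sd, n)


def evaluate_cell(
    pairs: Sequence[FieldPair],
    t_III: float,
    t_V: float,
    norm_III: NormativeTable,
    norm_V: NormativeTable,
) -> CellStats:
    """Mean/SD of d = TD_V - TD_III over censored point pairs at one cell."""
    if not pairs:
        raise ValueError("evaluate_cell requires at least one FieldPair")
    m = PairMatrix(pairs, norm_III, norm_V)
    return _cell_from_arrays(*m.diffs_at(t_III, t_V))


def grid_search(
    pairs: Sequence[FieldPair],
    norm_III: NormativeTable,
    norm_V: NormativeTable,
    grid_III: Sequence[float] = DEFAULT_GRID,
    grid_V: Sequence[float] = DEFAULT_GRID,
    min_count: int = 30,
    tie_se_factor: float = 2.0,
) -> ThresholdGridResult:
    """Evaluate every (t_III, t_V) cell and return the argmin of |mean diff|.

    Cells whose |mean| is within ``tie_se_factor`` standard errors of the
    minimal |mean| count as tied with it; ties break to the lower SD, then
    lower t_III, then lower t_V (tie-break path logged).  Raises if no
    cell reaches ``min_count`` censored pairs.
    """
    if len(grid_III) == 0 or len(grid_V) == 0:
        raise ValueError("threshold grids must be non-empty")
    grid_III = np.asarray(sorted(grid_III), dtype=float)
    grid_V = np.asarray(sorted(grid_V), dtype=float)
    m = PairMatrix(pairs, norm_III, norm_V)

    shape = (len(grid_III), len(grid_V))
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    n_cen = np.zeros(shape, dtype=int)
    for i, a in enumerate(grid_III):
        for j, b in enumerate(grid_V):
            cell = _cell_from_arrays(*m.diffs_at(a, b))
            mean[i, j], sd[i, j], n_cen[i, j] = cell.mean_diff, cell.sd_diff, cell.n_censored

    eligible = n_cen >= min_count
    if not eligible.any():
        raise ValueError(
            f"no grid cell has >= {min_count} censored pairs; "
            "use a larger cohort or a wider threshold grid"
        )
    i, j = select_best(mean, sd, n_cen, eligible, grid_III, grid_V, tie_se_factor)
    best = CensorConfig(float(grid_III[i]), float(grid_V[j]))
    return ThresholdGridResult(
        grid_III=grid_III,
        grid_V=grid_V,
        mean_diff=mean,
        sd_diff=sd,
        n_censored=n_cen,
        best=best,
        objective_at_best=float(mean[i, j]),
        min_count=min_count,
    )


def select_best(
    mean: np.ndarray,
    sd: np.ndarray,
    n_cen: np.ndarray,
    eligible: np.ndarray,
    grid_III: np.ndarray,
    grid_V: np.ndarray,
    tie_se_factor: float,
) -> tuple[int, int]:
    """Argmin of |mean| with the SE-resolution tie rule.

    The tolerance is ``tie_se_factor`` times the standard error
    (sd/sqrt(n)) of the argmin cell's own mean; with sd = 0 or undefined
    the tolerance is 0 and the rule degenerates to exact-equality ties.
    """
    obj = np.where(eligible, np.abs(mean), np.inf)
    bi, bj = np.unravel_index(np.argmin(obj), obj.shape)
    best_obj = obj[bi, bj]
    se = 0.0
    if np.isfinite(sd[bi, bj]) and n_cen[bi, bj] > 0:
        se = sd[bi, bj] / np.sqrt(n_cen[bi, bj])
    tied = np.argwhere(obj <= best_obj + tie_se_factor * se)
    if len(tied) > 1:
        keys = [
            (sd[i, j] if np.isfinite(sd[i, j]) else np.inf, grid_III[i], grid_V[j], i, j)
            for i, j in tied
        ]
        keys.sort()
        i, j = keys[0][3], keys[0][4]
        logger.info(
            "%d cells statistically tied on |mean diff|; "
            "broke by (SD, t_III, t_V) to (%g, %g)",
            len(tied), grid_III[i], grid_V[j],
        )
        return int(i), int(j)
    return int(bi), int(bj)
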