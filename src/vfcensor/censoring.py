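"""Censoring rule and construction of pointwise TD pairs.

Censoring replaces every raw sensitivity strictly below a threshold with
the threshold value, removing the noise-dominated sub-floor range before
total-deviation conversion.  A point pair is "censored" when the raw
sensitivity of *at least one* stimulus fell below its threshold; the flag
refers to the raw sensitivity (the quantity actually censored), never to
the TD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FieldPair
from .normative import NormativeTable, expected_vector

__all__ = [
    "CensorConfig",
    "censor_value",
    "make_point_pairs",
    "write_point_pairs",
    "POINT_PAIR_COLUMNS",
]

POINT_PAIR_COLUMNS = [
    "subject_id",
    "session_id",
    "cohort",
    "x_deg",
    "y_deg",
    "td_iii_db",
    "td_v_db",
    "censored_iii",
    "censored_v",
    "pair_censored",
]


@dataclass(frozen=True)
class CensorConfig:
    """Censoring thresholds (dB) for the two stimulus sizes."""

    threshold_III: float
    threshold_V: float

    def __post_init__(self) -> None:
        for name, t in (("threshold_III", self.threshold_III), ("threshold_V", self.threshold_V)):
            if not 0 <= t <= 40:
                raise ValueError(f"{name} = {t} outside [0, 40] dB")


def censor_value(sensitivity: float, threshold: float) -> tuple[float, bool]:
    """Clamp one sensitivity at the threshold.

    Returns ``(max(sensitivity, threshold), sensitivity < threshold)``.
    Equality to the threshold is not censored (strictly "below").
    """
    if sensitivity < 0:
        raise ValueError(f"sensitivity must be >= 0 dB, got {sensitivity}")
    return max(sensitivity, threshold), sensitivity < threshold


class PairMatrix:
    """Raw sensitivities and normative expectations for a list of pairs,
    as (n_pairs, 52) arrays aligned on each eye's grid order.

    Building this once lets the threshold grid search evaluate hundreds of
    candidate threshold cells with pure array arithmetic.
    """

    def __init__(
        self,
        pairs: Sequence[FieldPair],
        norm_III: NormativeTable,
        norm_V: NormativeTable,
    ):
        if norm_III.stimulus != "III" or norm_V.stimulus != "V":
            raise ValueError("normative tables must be (III, V) in that order")
        n = len(pairs)
        self.raw_iii = np.empty((n, 52))
        self.raw_v = np.empty((n, 52))
        self.exp_iii = np.empty((n, 52))
        self.exp_v = np.empty((n, 52))
        self.x = np.empty((n, 52), dtype=int)
        self.y = np.empty((n, 52), dtype=int)
        meta = []
        for i, pair in enumerate(pairs):
            locs = pair.field_III.locations
            self.raw_iii[i] = pair.field_III.values()
            self.raw_v[i] = pair.field_V.values()
            self.exp_iii[i] = expected_vector(norm_III, locs, pair.age_years)
            self.exp_v[i] = expected_vector(norm_V, locs, pair.age_years)
            self.x[i] = [x for x, _ in locs]
            self.y[i] = [y for _, y in locs]
            meta.append((pair.subject_id, pair.session_id, pair.cohort, pair.eye))
        self.meta = pd.DataFrame(
            meta, columns=["subject_id", "session_id", "cohort", "eye"]
        )

    @property
    def n_pairs(self) -> int:
        return len(self.meta)

    def diffs_at(self, t_iii: float, t_v: float):
        """(diff, censored_mask) arrays for one threshold pair.

        diff = TD_V - TD_III with censor-then-convert semantics;
        censored_mask flags points where at least one raw value is below
        its threshold.
        """
        c_iii = np.maximum(self.raw_iii, t_iii)
        c_v = np.maximum(self.raw_v, t_v)
        diff = (c_v - self.exp_v) - (c_iii - self.exp_iii)
        mask = (self.raw_iii < t_iii) | (self.raw_v < t_v)
        return diff, mask


def make_point_pairs(
    pairs: Sequence[FieldPair],
    cfg: CensorConfig,
    norm_III: NormativeTable,
    norm_V: NormativeTable,
) -> pd.DataFrame:
    """Pointwise TD pairs with censorship flags, one row per location per pair.

    Columns: :data:`POINT_PAIR_COLUMNS` plus ``eye`` and the convenience
    column ``diff_db = td_v_db - td_iii_db``.  Always yields exactly
    ``52 * len(pairs)`` rows.
    """
    m = PairMatrix(pairs, norm_III, norm_V)
    cen_iii = m.raw_iii < cfg.threshold_III
    cen_v = m.raw_v < cfg.threshold_V
    td_iii = np.maximum(m.raw_iii, cfg.threshold_III) - m.exp_iii
    td_v = np.maximum(m.raw_v, cfg.threshold_V) - m.exp_v

    rep = m.meta.loc[m.meta.index.repeat(52)].reset_index(drop=True)
    df = pd.DataFrame(
        {
            "subject_id": rep["subject_id"],
            "session_id": rep["session_id"],
            "cohort": rep["cohort"],
            "eye": rep["eye"],
            "x_deg": m.x.ravel(),
            "y_deg": m.y.ravel(),
            "td_iii_db": td_iii.ravel(),
            "td_v_db": td_v.ravel(),
            "censored_iii": cen_iii.ravel(),
            "censored_v": cen_v.ravel(),
        }
    )
    df["pair_censored"] = df["censored_iii"] | df["censored_v"]
    df["diff_db"] = df["td_v_db"] - df["td_iii_db"]
    return df


def write_point_pairs(df: pd.DataFrame, path: str | Path) -> None:
    """Write the TD point-pair table (spec schema columns only)."""
    df[POINT_PAIR_COLUMNS].to_csv(path, index=False)
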