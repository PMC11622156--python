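"""Agreement battery on pooled TD point pairs.

Everything operates on the point-pair table produced by
:func:`vfcensor.censoring.make_point_pairs`: per-subgroup means and SDs of
d = TD_V - TD_III, a paired t-test of d against zero, an ordinary
least-squares fit of TD_V on TD_III compared with the line of unity
(y = x), and a Bland-Altman analysis with limits of agreement at
mean(d) +/- k * SD(d).

Point pairs are treated as independent observations, matching how the
agreement statistics are usually reported for pooled pointwise data; the
52 points of a field and repeated sessions of a subject are of course
correlated, so the p-values are anti-conservative.  A cluster bootstrap
resampling whole test sessions is provided as an optional robustness
check (:func:`cluster_bootstrap_mean_diff`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitResult",
    "BAResult",
    "AgreementSummary",
    "summarize_diffs",
    "fit_line",
    "bland_altman",
    "analyze",
    "cluster_bootstrap_mean_diff",
]


def _diffs(df: pd.DataFrame) -> np.ndarray:
    return (df["td_v_db"] - df["td_iii_db"]).to_numpy(dtype=float)


def _mean_sd(vals: np.ndarray) -> tuple[float, float]:
    if vals.size == 0:
        return float("nan"), float("nan")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    return mean, sd


@dataclass(frozen=True)
class FitResult:
    """OLS fit of TD_V (y) on TD_III (x)."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class BAResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    k_sd: float


@dataclass(frozen=True)
class AgreementSummary:
    n_total: int
    n_censored: int
    n_uncensored: int
    prop_censored: float
    mean_diff_all: float
    sd_diff_all: float
    mean_diff_censored: float
    sd_diff_censored: float
    mean_diff_uncensored: float
    sd_diff_uncensored: float
    t_statistic: float  # NaN when the diffs have zero variance
    df: int
    p_value: float
    fit: FitResult | None = None
    bland_altman: BAResult | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def summarize_diffs(point_pairs: pd.DataFrame) -> AgreementSummary:
    """Subgroup means/SDs of d = TD_V - TD_III and the paired t-test.

    The paired t-test is the one-sample two-sided t of d against 0 with
    df = n_total - 1.  With zero variance the t statistic is undefined and
    reported as NaN.
    """
    d = _diffs(point_pairs)
    n_total = d.size
    if n_total < 2:
        raise ValueError(f"need at least 2 point pairs, got {n_total}")
    cen = point_pairs["pair_censored"].to_numpy(dtype=bool)
    mean_all, sd_all = _mean_sd(d)
    mean_c, sd_c = _mean_sd(d[cen])
    mean_u, sd_u = _mean_sd(d[~cen])
    if sd_all == 0:
        t_stat, p_val = float("nan"), float("nan")
    else:
        res = stats.ttest_1samp(d, popmean=0.0)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return AgreementSummary(
        n_total=n_total,
        n_censored=int(cen.sum()),
        n_uncensored=int((~cen).sum()),
        prop_censored=float(cen.mean()),
        mean_diff_all=mean_all,
        sd_diff_all=sd_all,
        mean_diff_censored=mean_c,
        sd_diff_censored=sd_c,
        mean_diff_uncensored=mean_u,
        sd_diff_uncensored=sd_u,
        t_statistic=t_stat,
        df=n_total - 1,
        p_value=p_val,
    )


def fit_line(point_pairs: pd.DataFrame) -> FitResult:
    """Ordinary least squares of y = TD_V on x = TD_III.

    The axis roles are fixed: size III on x, size V on y, so the slope
    answers "how does a size V TD move per dB of size III TD" and is
    compared against the line of unity.
    """
    x = point_pairs["td_iii_db"].to_numpy(dtype=float)
    y = point_pairs["td_v_db"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 point pairs for a fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all TD_III values identical: slope undefined")
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def bland_altman(point_pairs: pd.DataFrame, k_sd: float = 2.0):
    """Bland-Altman analysis of TD_III vs TD_V.

    Per point: mean m = (TD_III + TD_V)/2 and difference d = TD_V - TD_III;
    limits of agreement at mean(d) +/- k_sd * SD(d).  ``k_sd`` defaults to
    2 (not 1.96).  Returns ``(BAResult, per-point DataFrame)``.
    """
    x = point_pairs["td_iii_db"].to_numpy(dtype=float)
    y = point_pairs["td_v_db"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 point pairs, got {x.size}")
    d = y - x
    m = (x + y) / 2.0
    mean_d, sd_d = _mean_sd(d)
    table = pd.DataFrame({"mean_db": m, "diff_db": d})
    return (
        BAResult(
            mean_diff=mean_d,
            sd_diff=sd_d,
            loa_low=mean_d - k_sd * sd_d,
            loa_high=mean_d + k_sd * sd_d,
            k_sd=k_sd,
        ),
        table,
    )


def analyze(point_pairs: pd.DataFrame, k_sd: float = 2.0) -> AgreementSummary:
    """Full battery: subgroup summaries + t-test + OLS fit + Bland-Altman."""
    summary = summarize_diffs(point_pairs)
    fit = fit_line(point_pairs)
    ba, _ = bland_altman(point_pairs, k_sd=k_sd)
    return AgreementSummary(**{**summary.to_dict(), "fit": fit, "bland_altman": ba})


def write_summary(summary: AgreementSummary, path: str | Path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    Path(path).write_text(json.dumps(clean(summary.to_dict()), indent=2))


def cluster_bootstrap_mean_diff(
    point_pairs: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Percentile CI for the mean difference, resampling whole sessions.

    Robustness check for the independence assumption of the pooled
    t-test: sessions (subject_id, session_id) are the resampling unit, so
    within-field correlation is respected.
    """
    rng = np.random.default_rng(seed)
    groups = [g for _, g in point_pairs.groupby(["subject_id", "session_id"], sort=True)]
    sizes = np.array([len(g) for g in groups])
    diffs = [_diffs(g) for g in groups]
    n = len(groups)
    means = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        total = np.concatenate([diffs[i] for i in idx])
        means[b] = total.mean()
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return {
        "mean_diff": float(np.concatenate(diffs).mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_sessions": n,
        "n_boot": n_boot,
        "mean_session_size": float(sizes.mean()),
    }
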