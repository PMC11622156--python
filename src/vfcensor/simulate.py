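"""Seeded generator of paired size III / size V 24-2 visual fields.

The generator emulates the statistical structure the censoring analysis
assumes, not any particular instrument:

* One underlying disease deficit field D(p) >= 0 dB per eye drives both
  stimuli; the stimuli differ only through their normative expectations,
  their noise floors and their retest variability.  True sensitivity for
  stimulus s is ``max(N_s(p, age) - D(p), 0)``.
* Deficit patterns follow the classic topographies: NAION produces an
  altitudinal (hemifield) defect with a smooth transition band across the
  horizontal meridian; glaucoma produces an arcuate defect concentrated
  in the Bjerrum region (10-21 degrees eccentricity) of one hemifield,
  optionally with a nasal step and a mild diffuse component.
* Observation noise is heteroscedastic: above the stimulus's useful
  dynamic-range floor, Gaussian with an SD that grows from ``sigma_low``
  at 30 dB to ``sigma_high`` at the floor (published pointwise retest
  SDs: 1.3-3.0 dB for size III, 1.2-2.0 dB for size V); below the floor
  the response is noise-dominated and, in the default ``uniform`` mode,
  drawn uniformly from the integers [0, floor).  This sub-floor regime is
  what makes the floors recoverable by the threshold grid search.

All draws flow from a single integer seed; the same seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .grid import analysis_locations
from .io import FieldPair, VisualField
from .normative import NormativeTable, expected_vector, synthesize_normative

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "true_deficit_field",
    "observe_field",
    "generate_cohort",
    "generate_combined",
    "default_norms",
]

BJERRUM_ECC_DEG = (10.0, 21.0)


@dataclass(frozen=True)
class NoiseModel:
    """Stimulus-specific measurement-noise regime.

    ``sigma_low``/``sigma_high`` are retest SDs in dB at 30 dB sensitivity
    and at the floor respectively; ``floor`` is the bottom of the useful
    dynamic range.  ``sub_floor_mode`` is ``"uniform"`` (noise-dominated:
    observations uniform on the integers [0, floor)) or ``"clamp"``
    (Gaussian noise with no special sub-floor regime, for exploring the
    optimizer's behaviour when no noise floor exists).
    """

    sigma_low_III: float = 1.3
    sigma_high_III: float = 3.0
    sigma_low_V: float = 1.2
    sigma_high_V: float = 2.0
    floor_III: float = 21.0
    floor_V: float = 24.0
    sub_floor_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.sigma_low_III > self.sigma_high_III or self.sigma_low_V > self.sigma_high_V:
            raise ValueError("sigma_low must not exceed sigma_high")
        for f in (self.floor_III, self.floor_V):
            if not 10 <= f <= 30:
                raise ValueError(f"floor {f} outside [10, 30] dB")
        if self.sub_floor_mode not in ("uniform", "clamp"):
            raise ValueError(f"unknown sub_floor_mode {self.sub_floor_mode!r}")

    def params_for(self, stimulus: str) -> tuple[float, float, float]:
        if stimulus == "III":
            return self.sigma_low_III, self.sigma_high_III, self.floor_III
        if stimulus == "V":
            return self.sigma_low_V, self.sigma_high_V, self.floor_V
        raise ValueError(f"unknown stimulus {stimulus!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for one simulated cohort.

    Defaults mirror the demographic structure of the two source cohorts:
    glaucoma 120 participants contributing 1053 same-day pairs
    (age 67.8 +/- 9.3 y), NAION 586 participants contributing 939 pairs
    (age 61.3 +/- 7.7 y); ages truncated to [19, 90].  ``severity`` is the
    peak deficit depth in dB, drawn per session.
    """

    cohort: str
    n_pairs: int
    n_participants: int
    age_mean: float
    age_sd: float
    severity_mean: float
    severity_sd: float
    seed: int = 0
    transition_width_deg: float = 4.0  # NAION hemifield border softness
    nasal_step: bool = True  # glaucoma only
    diffuse_fraction: float = 0.0  # glaucoma: mild diffuse loss, as fraction of severity

    def __post_init__(self) -> None:
        if self.cohort not in ("GLAUCOMA", "NAION"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def glaucoma_default(cls, **overrides) -> "CohortSpec":
        base = dict(
            cohort="GLAUCOMA",
            n_pairs=1053,
            n_participants=120,
            age_mean=67.8,
            age_sd=9.3,
            severity_mean=24.0,
            severity_sd=5.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def naion_default(cls, **overrides) -> "CohortSpec":
        base = dict(
            cohort="NAION",
            n_pairs=939,
            n_participants=586,
            age_mean=61.3,
            age_sd=7.7,
            severity_mean=20.0,
            severity_sd=5.0,
        )
        base.update(overrides)
        return cls(**base)


def default_norms() -> tuple[NormativeTable, NormativeTable]:
    """The surrogate hill-of-vision normative tables for both stimuli."""
    return synthesize_normative("III"), synthesize_normative("V")


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    a = (19.0 - spec.age_mean) / spec.age_sd
    b = (90.0 - spec.age_mean) / spec.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd,
        size=spec.n_participants, random_state=rng,
    )


def true_deficit_field(
    cohort: str,
    severity: float,
    locations: Sequence[tuple[int, int]],
    eye: str,
    rng: np.random.Generator,
    *,
    transition_width_deg: float = 4.0,
    nasal_step: bool = True,
    diffuse_fraction: float = 0.0,
    affected_superior: bool | None = None,
) -> np.ndarray:
    """Disease deficit D(p) >= 0 dB at each location.

    NAION: altitudinal — one hemifield (chosen at random unless
    ``affected_superior`` is given) depressed by ``severity`` with a
    linear transition ramp of width ``transition_width_deg`` across the
    horizontal meridian (width 0 = hard step).

    GLAUCOMA: arcuate — full ``severity`` inside the Bjerrum annulus of
    one hemifield, plus (optionally) a nasal step at 60% severity and a
    mild diffuse component at ``diffuse_fraction * severity`` everywhere.
    """
    x = np.array([p[0] for p in locations], dtype=float)
    y = np.array([p[1] for p in locations], dtype=float)
    if affected_superior is None:
        affected_superior = bool(rng.integers(0, 2))
    sign = 1.0 if affected_superior else -1.0

    if cohort == "NAION":
        if transition_width_deg <= 0:
            w = (sign * y > 0).astype(float)
        else:
            w = np.clip(sign * y / transition_width_deg + 0.5, 0.0, 1.0)
        deficit = severity * w
    elif cohort == "GLAUCOMA":
        r = np.hypot(x, y)
        arcuate = (
            (r >= BJERRUM_ECC_DEG[0]) & (r <= BJERRUM_ECC_DEG[1]) & (sign * y > 0)
        )
        deficit = np.where(arcuate, severity, diffuse_fraction * severity)
        if nasal_step:
            nasal_x = -x if eye.upper() == "OD" else x  # nasal field side
            step = (nasal_x >= 15) & (sign * y > 0) & ~arcuate
            deficit = np.where(step, 0.6 * severity, deficit)
    else:
        raise ValueError(f"unknown cohort {cohort!r}")
    return np.maximum(deficit, 0.0)


def _sigma(true_sens: np.ndarray, lo: float, hi: float, floor: float) -> np.ndarray:
    # hi at the floor, lo at 30 dB, linear between, clamped outside
    if floor >= 30:
        return np.full_like(true_sens, hi)
    t = np.clip((true_sens - floor) / (30.0 - floor), 0.0, 1.0)
    return hi + (lo - hi) * t


def observe_field(
    true_sens: np.ndarray,
    stimulus: str,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated integer-dB sensitivities for one test of one stimulus."""
    true_sens = np.asarray(true_sens, dtype=float)
    if ((true_sens < 0) | (true_sens > 50)).any():
        raise ValueError("true sensitivities must lie in [0, 50] dB")
    lo, hi, floor = noise.params_for(stimulus)
    eps = rng.normal(0.0, 1.0, size=true_sens.shape) * _sigma(true_sens, lo, hi, floor)
    obs = np.rint(true_sens + eps)
    if noise.sub_floor_mode == "uniform":
        sub = true_sens < floor
        # noise-dominated regime: the response carries no signal
        uniform = rng.integers(0, int(floor), size=true_sens.shape)
        obs = np.where(sub, uniform, obs)
    return np.clip(obs, 0, 50).astype(int)


def generate_cohort(
    spec: CohortSpec,
    noise: NoiseModel | None = None,
    norm_III: NormativeTable | None = None,
    norm_V: NormativeTable | None = None,
) -> list[FieldPair]:
    """Simulate ``spec.n_pairs`` same-day size III / size V field pairs.

    Sessions are distributed round-robin over ``spec.n_participants``
    participants (ages are participant-level); eye, severity and deficit
    pattern are drawn per session, with sessions treated as independent.
    Fully deterministic given ``spec.seed``.
    """
    noise = noise or NoiseModel()
    if norm_III is None or norm_V is None:
        d_iii, d_v = default_norms()
        norm_III = norm_III or d_iii
        norm_V = norm_V or d_v
    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(spec, rng)

    locs_by_eye = {e: analysis_locations(e) for e in ("OD", "OS")}
    tag = spec.cohort[:3].lower()
    pairs = []
    for k in range(spec.n_pairs):
        pidx = k % spec.n_participants
        subject_id = f"{tag}-{pidx:04d}"
        session_id = f"s{k:05d}"
        age = float(ages[pidx])
        eye = "OD" if rng.integers(0, 2) == 0 else "OS"
        severity = float(np.clip(rng.normal(spec.severity_mean, spec.severity_sd), 0.0, 40.0))
        locs = locs_by_eye[eye]
        deficit = true_deficit_field(
            spec.cohort,
            severity,
            locs,
            eye,
            rng,
            transition_width_deg=spec.transition_width_deg,
            nasal_step=spec.nasal_step,
            diffuse_fraction=spec.diffuse_fraction,
        )
        fields = {}
        for stim, norm in (("III", norm_III), ("V", norm_V)):
            true_sens = np.clip(expected_vector(norm, locs, age) - deficit, 0.0, 50.0)
            obs = observe_field(true_sens, stim, noise, rng)
            fields[stim] = VisualField(
                subject_id=subject_id,
                cohort=spec.cohort,
                eye=eye,
                session_id=session_id,
                stimulus=stim,
                age_years=round(age, 2),
                sensitivities=dict(zip(locs, (int(v) for v in obs))),
            )
        pairs.append(FieldPair(fields["III"], fields["V"]))
    return pairs


def generate_combined(
    n_pairs: int,
    seed: int,
    noise: NoiseModel | None = None,
    norm_III: NormativeTable | None = None,
    norm_V: NormativeTable | None = None,
) -> list[FieldPair]:
    """Mixed glaucoma + NAION cohort in the source studies' ~53/47 ratio.

    Participant counts scale with the per-cohort sessions-per-participant
    ratios (~8.8 for glaucoma, ~1.6 for NAION).
    """
    n_gla = round(n_pairs * 1053 / 1992)
    n_nai = n_pairs - n_gla
    specs = []
    if n_gla:
        specs.append(
            CohortSpec.glaucoma_default(
                n_pairs=n_gla,
                n_participants=max(1, round(n_gla * 120 / 1053)),
                seed=seed,
            )
        )
    if n_nai:
        specs.append(
            CohortSpec.naion_default(
                n_pairs=n_nai,
                n_participants=max(1, round(n_nai * 586 / 939)),
                seed=seed + 1,
            )
        )
    pairs = []
    for s in specs:
        pairs.extend(generate_cohort(s, noise, norm_III, norm_V))
    return pairs
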