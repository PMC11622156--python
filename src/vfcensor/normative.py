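"""Per-stimulus normative sensitivity model and total-deviation conversion.

Total deviation (TD) at a location is the measured sensitivity minus the
expected normal sensitivity for an observer of the same age at that
location.  Expected sensitivity is modelled per stimulus as a location
mean at a reference age plus a linear age slope (dB per decade):

    N_s(p, age) = mean_ref_s(p) + slope_s(p) * (age - reference_age) / 10

The proprietary normative databases shipped with clinical perimeters are
not publicly available, so :func:`synthesize_normative` provides a
parametric "hill of vision" surrogate (peak sensitivity at fixation
falling off linearly with eccentricity, size V uniformly more sensitive
than size III by a spatial-summation offset).  Any table with the same
schema can be loaded from CSV instead; every downstream statistic is
agnostic to which normative table is plugged in.

Normative tables are stored in the right-eye (OD) frame; left-eye
locations are mirrored in x for lookup, as perimetry software does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridPoint, analysis_locations
from .io import VisualField, normalize_stimulus

__all__ = [
    "NormativeTable",
    "TDField",
    "expected_sensitivity",
    "synthesize_normative",
    "compute_td",
    "read_normative",
    "write_normative",
]


@dataclass
class NormativeTable:
    """Expected normal sensitivities for one stimulus size.

    ``values`` maps each OD-frame analysis location to
    ``(mean_sensitivity_ref_db, age_slope_db_per_decade)``.
    """

    stimulus: str
    reference_age: float
    values: dict[tuple[int, int], tuple[float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        self.stimulus = normalize_stimulus(self.stimulus)
        expected = set(analysis_locations("OD"))
        if set(self.values) != expected:
            raise ValueError(
                "normative table must cover exactly the 52 OD analysis locations"
            )
        for loc, (mean_ref, slope) in self.values.items():
            if not 10 <= mean_ref <= 45:
                raise ValueError(f"mean_sensitivity_ref {mean_ref} at {loc} outside [10, 45] dB")
            if not -2 <= slope <= 0:
                raise ValueError(f"age_slope {slope} at {loc} outside [-2, 0] dB/decade")

    def lookup(self, x_deg: int, y_deg: int) -> tuple[float, float]:
        """(mean_ref, age_slope) at a location in either eye's frame."""
        key = (x_deg, y_deg)
        if key in self.values:
            return self.values[key]
        mirrored = (-x_deg, y_deg)
        if mirrored in self.values:
            return self.values[mirrored]
        raise KeyError(f"location {key} not covered by the normative table")


def expected_sensitivity(norm: NormativeTable, location: GridPoint, age_years: float) -> float:
    """Expected normal sensitivity (dB) at one location and age."""
    if location.is_blind_spot:
        raise ValueError(f"location {location.location} is a blind-spot point")
    if not 10 <= age_years <= 110:
        raise ValueError(f"age_years {age_years} outside [10, 110]")
    mean_ref, slope = norm.lookup(location.x_deg, location.y_deg)
    return mean_ref + slope * (age_years - norm.reference_age) / 10.0


def expected_vector(
    norm: NormativeTable, locations: list[tuple[int, int]], age_years: float
) -> np.ndarray:
    """Expected sensitivities for a list of locations (vectorised lookup)."""
    out = np.empty(len(locations))
    shift = (age_years - norm.reference_age) / 10.0
    for i, (x, y) in enumerate(locations):
        mean_ref, slope = norm.lookup(x, y)
        out[i] = mean_ref + slope * shift
    return out


def synthesize_normative(
    stimulus: str,
    *,
    peak_db: float = 34.0,
    ecc_slope_db_per_deg: float = 0.25,
    v_offset_db: float = 3.0,
    age_slope_db_per_decade: float = -0.7,
    reference_age: float = 45.0,
) -> NormativeTable:
    """Parametric hill-of-vision normative table.

    mean_ref(p) = peak - ecc_slope * sqrt(x^2 + y^2), plus ``v_offset_db``
    uniformly for stimulus V (larger stimuli recruit more spatial
    summation and read several dB more sensitive).
    """
    if peak_db <= 0:
        raise ValueError(f"peak_db must be positive, got {peak_db}")
    stimulus = normalize_stimulus(stimulus)
    offset = v_offset_db if stimulus == "V" else 0.0
    values = {}
    for (x, y) in analysis_locations("OD"):
        mean_ref = peak_db - ecc_slope_db_per_deg * math.hypot(x, y) + offset
        values[(x, y)] = (mean_ref, age_slope_db_per_decade)
    return NormativeTable(stimulus=stimulus, reference_age=reference_age, values=values)


@dataclass
class TDField:
    """Per-location total deviations for one field.

    TD is kept at floating precision: pointwise means of interest are
    sub-dB.  ``censor_threshold`` records the threshold applied to the raw
    sensitivities before conversion (None = uncensored).
    """

    stimulus: str
    age_years: float
    censor_threshold: float | None
    td: dict[tuple[int, int], float] = field(repr=False)
    subject_id: str = ""
    session_id: str = ""


def compute_td(
    field_: VisualField, norm: NormativeTable, censor_threshold: float | None = None
) -> TDField:
    """Censor raw sensitivities, then convert to age-corrected TDs.

    Censoring (clamping values below the threshold up to the threshold) is
    applied to raw sensitivities *before* subtracting the normative
    expectation; the order matters because the threshold is defined on the
    sensitivity scale, not the TD scale.
    """
    if norm.stimulus != field_.stimulus:
        raise ValueError(
            f"normative table is for stimulus {norm.stimulus}, "
            f"field is stimulus {field_.stimulus}"
        )
    t = -math.inf if censor_threshold is None else censor_threshold
    shift = (field_.age_years - norm.reference_age) / 10.0
    td = {}
    for loc, s in field_.sensitivities.items():
        mean_ref, slope = norm.lookup(*loc)
        td[loc] = max(s, t) - (mean_ref + slope * shift)
    return TDField(
        stimulus=field_.stimulus,
        age_years=field_.age_years,
        censor_threshold=censor_threshold,
        td=td,
        subject_id=field_.subject_id,
        session_id=field_.session_id,
    )


def write_normative(norm: NormativeTable, path: str | Path) -> None:
    """CSV writer; reference age rides along in a header comment line."""
    with open(path, "w") as fh:
        fh.write(f"# reference_age={norm.reference_age}\n")
        fh.write("stimulus,x_deg,y_deg,mean_sensitivity_ref_db,age_slope_db_per_decade\n")
        for (x, y), (mean_ref, slope) in sorted(norm.values.items()):
            fh.write(f"{norm.stimulus},{x},{y},{mean_ref!r},{slope!r}\n")


def read_normative(path: str | Path) -> NormativeTable:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# reference_age="):
        raise ValueError(f"{path}: expected '# reference_age=' header comment")
    reference_age = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    stimuli = df["stimulus"].unique()
    if len(stimuli) != 1:
        raise ValueError(f"{path}: expected a single stimulus, got {list(stimuli)}")
    values = {
        (int(r.x_deg), int(r.y_deg)): (
            float(r.mean_sensitivity_ref_db),
            float(r.age_slope_db_per_decade),
        )
        for r in df.itertuples(index=False)
    }
    return NormativeTable(stimulus=str(stimuli[0]), reference_age=reference_age, values=values)
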