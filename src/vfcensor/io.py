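"""Visual-field data model and long-format CSV readers/writers.

One CSV row per tested location::

    subject_id,cohort,eye,session_id,stimulus,age_years,x_deg,y_deg,sensitivity_db

Sensitivities are perimetric decibels (attenuation of maximum luminance;
higher = more sensitive).  Instruments report ``<0`` for responses below
the 0 dB floor; those tokens are parsed as 0 dB.  Blind-spot rows, if
present, are dropped with a logged count.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .grid import analysis_locations, make_24_2_grid

logger = logging.getLogger("vfcensor.io")

__all__ = [
    "VisualField",
    "FieldPair",
    "ReadConfig",
    "read_fields",
    "write_fields",
    "pair_same_day",
]

COHORTS = ("GLAUCOMA", "NAION")
_STIMULUS_TOKENS = {"iii": "III", "3": "III", "v": "V", "5": "V"}

CSV_COLUMNS = [
    "subject_id",
    "cohort",
    "eye",
    "session_id",
    "stimulus",
    "age_years",
    "x_deg",
    "y_deg",
    "sensitivity_db",
]


def normalize_stimulus(token: str | int) -> str:
    key = str(token).strip().lower()
    if key not in _STIMULUS_TOKENS:
        raise ValueError(
            f"unknown stimulus token {token!r}; expected one of III, 3, V, 5"
        )
    return _STIMULUS_TOKENS[key]


@dataclass
class VisualField:
    """One eye's 24-2 test with a single stimulus size.

    ``sensitivities`` maps each non-blind-spot (x_deg, y_deg) location to a
    raw sensitivity in dB (integer-valued as reported by the perimeter,
    floor at 0).  All 52 analysis locations of the eye's grid must be
    present.
    """

    subject_id: str
    cohort: str
    eye: str
    session_id: str
    stimulus: str
    age_years: float
    sensitivities: dict[tuple[int, int], float] = field(repr=False)

    def __post_init__(self) -> None:
        self.eye = self.eye.upper()
        self.cohort = self.cohort.upper()
        self.stimulus = normalize_stimulus(self.stimulus)
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not self.age_years > 0:
            raise ValueError(f"age_years must be positive, got {self.age_years}")
        expected = set(analysis_locations(self.eye))
        got = set(self.sensitivities)
        missing = expected - got
        if missing:
            raise ValueError(
                f"field {self.subject_id}/{self.session_id}/{self.stimulus} is "
                f"missing location(s) {sorted(missing)}"
            )
        extra = got - expected
        if extra:
            raise ValueError(
                f"field {self.subject_id}/{self.session_id}/{self.stimulus} has "
                f"unexpected location(s) {sorted(extra)}"
            )
        for loc, s in self.sensitivities.items():
            if not 0 <= s <= 50:
                raise ValueError(
                    f"sensitivity {s} dB at {loc} outside [0, 50] in field "
                    f"{self.subject_id}/{self.session_id}/{self.stimulus}"
                )

    @property
    def locations(self) -> list[tuple[int, int]]:
        """The 52 analysis locations in deterministic grid order."""
        return analysis_locations(self.eye)

    def values(self) -> list[float]:
        """Sensitivities in grid order."""
        return [self.sensitivities[loc] for loc in self.locations]


@dataclass
class FieldPair:
    """Same-day size III / size V fields for one eye of one subject."""

    field_III: VisualField
    field_V: VisualField

    def __post_init__(self) -> None:
        a, b = self.field_III, self.field_V
        if a.stimulus != "III" or b.stimulus != "V":
            raise ValueError("FieldPair requires (III, V) stimuli in that order")
        for attr in ("subject_id", "eye", "session_id", "cohort"):
            if getattr(a, attr) != getattr(b, attr):
                raise ValueError(
                    f"FieldPair fields disagree on {attr}: "
                    f"{getattr(a, attr)!r} != {getattr(b, attr)!r}"
                )
        if a.age_years != b.age_years:
            raise ValueError("FieldPair fields disagree on age_years")

    @property
    def subject_id(self) -> str:
        return self.field_III.subject_id

    @property
    def session_id(self) -> str:
        return self.field_III.session_id

    @property
    def cohort(self) -> str:
        return self.field_III.cohort

    @property
    def eye(self) -> str:
        return self.field_III.eye

    @property
    def age_years(self) -> float:
        return self.field_III.age_years


@dataclass
class ReadConfig:
    """Schema options for :func:`read_fields`.

    ``reliability_filter`` is a hook for excluding unreliable tests (e.g. on
    fixation losses or false positives) when such metadata is available; it
    receives each assembled :class:`VisualField` and returns False to drop
    it.  No filter is applied by default.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    reliability_filter: Callable[[VisualField], bool] | None = None

    def col(self, name: str) -> str:
        return self.columns.get(name, name)


def _parse_sensitivity(token) -> float:
    text = str(token).strip()
    if text.startswith("<"):
        # below the instrument's 0 dB reporting floor
        return 0.0
    return float(text)


def read_fields(table_path: str | Path, config: ReadConfig | None = None) -> list[VisualField]:
    """Read a long-format CSV into a list of :class:`VisualField`.

    Blind-spot rows are dropped (count logged).  ``<0`` sensitivity tokens
    map to 0 dB.  A missing or duplicated location within a field raises
    :class:`ValueError` naming the field and location.
    """
    config = config or ReadConfig()
    df = pd.read_csv(table_path, dtype=str)
    missing_cols = [config.col(c) for c in CSV_COLUMNS if config.col(c) not in df.columns]
    if missing_cols:
        raise ValueError(f"{table_path}: missing column(s) {missing_cols}")

    blind_by_eye = {
        e: {p.location for p in make_24_2_grid(e) if p.is_blind_spot}
        for e in ("OD", "OS")
    }
    groups: dict[tuple, dict] = {}
    n_blind = 0
    for row in df.itertuples(index=False):
        get = lambda c: getattr(row, config.col(c))
        eye = str(get("eye")).upper()
        stimulus = normalize_stimulus(get("stimulus"))
        loc = (int(get("x_deg")), int(get("y_deg")))
        if loc in blind_by_eye.get(eye, set()):
            n_blind += 1
            continue
        key = (str(get("subject_id")), eye, str(get("session_id")), stimulus)
        g = groups.setdefault(
            key,
            {
                "cohort": str(get("cohort")),
                "age_years": float(get("age_years")),
                "sens": {},
            },
        )
        if loc in g["sens"]:
            raise ValueError(
                f"duplicate location {loc} in field "
                f"{key[0]}/{key[2]}/stimulus {stimulus}"
            )
        g["sens"][loc] = _parse_sensitivity(get("sensitivity_db"))
    if n_blind:
        logger.info("dropped %d blind-spot rows", n_blind)

    fields = []
    for (subject_id, eye, session_id, stimulus), g in groups.items():
        vf = VisualField(
            subject_id=subject_id,
            cohort=g["cohort"],
            eye=eye,
            session_id=session_id,
            stimulus=stimulus,
            age_years=g["age_years"],
            sensitivities=g["sens"],
        )
        if config.reliability_filter is not None and not config.reliability_filter(vf):
            logger.info("reliability filter dropped field %s/%s/%s", subject_id, session_id, stimulus)
            continue
        fields.append(vf)
    return fields


def fields_to_frame(fields: Sequence[VisualField]) -> pd.DataFrame:
    """Long-format DataFrame with one row per tested location."""
    records = []
    for vf in fields:
        for (x, y) in vf.locations:
            records.append(
                (
                    vf.subject_id,
                    vf.cohort,
                    vf.eye,
                    vf.session_id,
                    vf.stimulus,
                    vf.age_years,
                    x,
                    y,
                    vf.sensitivities[(x, y)],
                )
            )
    return pd.DataFrame.from_records(records, columns=CSV_COLUMNS)


def write_fields(fields: Sequence[VisualField], table_path: str | Path) -> None:
    """Write fields to the long-format CSV schema read by :func:`read_fields`."""
    fields_to_frame(fields).to_csv(table_path, index=False)


def pair_same_day(fields: Sequence[VisualField]) -> list[FieldPair]:
    """Match size III and size V fields sharing subject, eye and session.

    Fields without a partner are excluded with a logged count.  Two fields
    of the same stimulus in one session make the pairing ambiguous and
    raise :class:`ValueError`.
    """
    sessions: dict[tuple, dict[str, VisualField]] = defaultdict(dict)
    for vf in fields:
        key = (vf.subject_id, vf.eye, vf.session_id)
        if vf.stimulus in sessions[key]:
            raise ValueError(
                f"two size-{vf.stimulus} fields in session "
                f"{vf.subject_id}/{vf.eye}/{vf.session_id}: pairing is ambiguous"
            )
        sessions[key][vf.stimulus] = vf

    pairs, orphans = [], 0
    for key, by_stim in sessions.items():
        if "III" in by_stim and "V" in by_stim:
            pairs.append(FieldPair(by_stim["III"], by_stim["V"]))
        else:
            orphans += 1
    if orphans:
        logger.info("excluded %d session(s) with an unpaired field", orphans)
    return pairs
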