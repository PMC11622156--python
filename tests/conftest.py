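"""Shared fixtures: hand-buildable fields and flat normative tables.

The flat normative table (same expectation at every location, no age
slope, no stimulus offset) makes TDs equal to ``sensitivity - 30`` so
toy examples stay hand-computable.
"""

from __future__ import annotations

import pytest

from vfcensor import (
    FieldPair,
    VisualField,
    analysis_locations,
    synthesize_normative,
)


def make_field(
    stimulus: str,
    value: float = 30,
    overrides: dict | None = None,
    subject_id: str = "p1",
    session_id: str = "d1",
    cohort: str = "GLAUCOMA",
    eye: str = "OD",
    age_years: float = 45.0,
) -> VisualField:
    """A field with constant sensitivity ``value`` except for ``overrides``
    (mapping location -> dB)."""
    sens = {loc: value for loc in analysis_locations(eye)}
    if overrides:
        sens.update(overrides)
    return VisualField(
        subject_id=subject_id,
        cohort=cohort,
        eye=eye,
        session_id=session_id,
        stimulus=stimulus,
        age_years=age_years,
        sensitivities=sens,
    )


def make_pair(
    value_III: float = 30,
    value_V: float = 30,
    overrides_III: dict | None = None,
    overrides_V: dict | None = None,
    **kwargs,
) -> FieldPair:
    return FieldPair(
        make_field("III", value_III, overrides_III, **kwargs),
        make_field("V", value_V, overrides_V, **kwargs),
    )


@pytest.fixture(scope="session")
def flat_norms():
    """Normative tables with expectation 30 dB everywhere, both stimuli."""
    kw = dict(peak_db=30.0, ecc_slope_db_per_deg=0.0, v_offset_db=0.0,
              age_slope_db_per_decade=0.0, reference_age=45.0)
    return synthesize_normative("III", **kw), synthesize_normative("V", **kw)


@pytest.fixture(scope="session")
def default_norm_pair():
    from vfcensor import default_norms

    return default_norms()
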