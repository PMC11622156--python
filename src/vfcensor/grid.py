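"""24-2 test-grid geometry.

The 24-2 pattern of standard automated perimetry tests 54 locations on a
6-degree lattice offset 3 degrees from both meridians, spanning the central
24 degrees (27 degrees on the temporal side, where two extra points sit at
``x = 27`` on the horizontal rows).  Two of the 54 locations fall on the
physiologic blind spot (~15 degrees temporal, straddling the horizontal
meridian) and are excluded from every statistic.

Coordinates are in degrees of visual angle.  ``x`` is positive toward the
right of the field chart and ``y`` is positive superiorly, so for a right
eye (OD) temporal is positive ``x``; the left-eye (OS) grid is the mirror
image in ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["GridPoint", "make_24_2_grid", "analysis_locations", "mirror_x"]

# Row layout of the right-eye 24-2 grid, superior to inferior.  Within each
# row, x runs nasal to temporal for OD (ascending).
_OD_ROWS: list[tuple[int, list[int]]] = [
    (21, [-9, -3, 3, 9]),
    (15, [-15, -9, -3, 3, 9, 15]),
    (9, [-21, -15, -9, -3, 3, 9, 15, 21]),
    (3, [-21, -15, -9, -3, 3, 9, 15, 21, 27]),
    (-3, [-21, -15, -9, -3, 3, 9, 15, 21, 27]),
    (-9, [-21, -15, -9, -3, 3, 9, 15, 21]),
    (-15, [-15, -9, -3, 3, 9, 15]),
    (-21, [-9, -3, 3, 9]),
]

_OD_BLIND_SPOT = {(15, 3), (15, -3)}


@dataclass(frozen=True)
class GridPoint:
    """One 24-2 test location.

    Attributes
    ----------
    x_deg, y_deg
        Eccentricity in degrees (x positive rightward on the chart,
        y positive superior).
    is_blind_spot
        True for the two locations overlying the optic nerve head; these
        carry no usable sensitivity and are dropped from analysis.
    """

    x_deg: int
    y_deg: int
    is_blind_spot: bool = False

    @property
    def location(self) -> tuple[int, int]:
        return (self.x_deg, self.y_deg)

    @property
    def eccentricity_deg(self) -> float:
        return float((self.x_deg**2 + self.y_deg**2) ** 0.5)


def make_24_2_grid(eye: str = "OD") -> list[GridPoint]:
    """Return the 54 test locations of the 24-2 pattern for one eye.

    Ordering is deterministic: row-major from the superior-most row down,
    nasal to temporal within each row.  For OS the grid is the OD grid
    mirrored in ``x``, with the blind-spot flags at ``(-15, +/-3)``.
    """
    eye = eye.upper()
    if eye not in ("OD", "OS"):
        raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")
    sign = 1 if eye == "OD" else -1
    points = []
    for y, xs in _OD_ROWS:
        for x in xs:
            points.append(
                GridPoint(sign * x, y, is_blind_spot=(x, y) in _OD_BLIND_SPOT)
            )
    return points


def analysis_locations(eye: str = "OD") -> list[tuple[int, int]]:
    """The 52 non-blind-spot (x, y) locations for one eye, in grid order."""
    return [p.location for p in make_24_2_grid(eye) if not p.is_blind_spot]


def mirror_x(locations: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Mirror locations across the vertical meridian (OD <-> OS frame)."""
    return [(-x, y) for x, y in locations]
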