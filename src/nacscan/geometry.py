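"""Pure vector geometry for near-attack-conformation screening.

Distances and angles in Angstrom and degrees.  The Bürgi–Dunitz angle is the
nucleophile approach angle at the carbonyl carbon: the angle between the
vector C→Nu (attacking water oxygen) and the vector C→O (carbonyl oxygen),
~105–107° for productive attack on an sp2 carbonyl.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AngleWindow",
    "DegenerateGeometryError",
    "distance",
    "angle",
    "burgi_dunitz",
    "water_oxygen_first",
]


class DegenerateGeometryError(ValueError):
    """An angle was requested with a zero-length arm."""


@dataclass(frozen=True)
class AngleWindow:
    """A closed (by default) angular interval in degrees."""

    min_deg: float
    max_deg: float
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_deg <= self.max_deg <= 180.0):
            raise ValueError(
                f"angle window must satisfy 0 <= min <= max <= 180, "
                f"got [{self.min_deg}, {self.max_deg}]"
            )

    def contains(self, value_deg: float) -> bool:
        if self.inclusive:
            return self.min_deg <= value_deg <= self.max_deg
        return self.min_deg < value_deg < self.max_deg


def distance(p: Sequence[float], q: Sequence[float], box: Sequence[float] | None = None) -> float:
    """Euclidean distance; minimum-image distance when an orthorhombic box is given."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    if box is not None:
        b = np.asarray(box, dtype=float)
        d -= b * np.round(d / b)
    return float(np.linalg.norm(d))


def angle(a: Sequence[float], vertex: Sequence[float], b: Sequence[float]) -> float:
    """Angle a–vertex–b in degrees, in [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle arm has zero length")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def burgi_dunitz(
    nucleophile_o: Sequence[float],
    carbonyl_c: Sequence[float],
    carbonyl_o: Sequence[float],
) -> float:
    """Bürgi–Dunitz approach angle Nu···C=O, measured at the carbonyl carbon."""
    return angle(nucleophile_o, carbonyl_c, carbonyl_o)


def water_oxygen_first(
    carbonyl_c: Sequence[float],
    water_o: Sequence[float],
    water_hs: Sequence[Sequence[float]],
    box: Sequence[float] | None = None,
) -> bool:
    """True iff the water oxygen is strictly the atom of the water nearest the carbon.

    This is the orientation test for a productive attack: the lone-pair side
    of the water faces the electrophilic carbon, i.e. the O–C distance is
    strictly below every H–C distance.  Ties fail.
    """
    if len(water_hs) == 0:
        raise ValueError("water has no hydrogen positions; orientation test is undefined")
    d_o = distance(carbonyl_c, water_o, box=box)
    return all(d_o < distance(carbonyl_c, h, box=box) for h in water_hs)
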