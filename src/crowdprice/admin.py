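"""Administrative units (country / state / LGA) and point-in-polygon lookup."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry


@dataclass
class AdminUnit:
    """One administrative polygon with its population.

    Levels follow the common COD-AB convention: 0 = country, 1 = state,
    2 = Local Government Area (LGA), the stratum unit of the post-sampling
    procedure.
    """

    code: str
    name: str
    level: int
    polygon: BaseGeometry
    population: float
    area: float = field(default=0.0)  # m^2

    def __post_init__(self):
        if self.population < 0:
            raise ValueError(f"population of {self.code} must be >= 0")
        if not self.polygon.is_valid:
            raise ValueError(f"polygon of {self.code} is not a valid geometry")
        if self.area == 0.0:
            self.area = float(self.polygon.area)


def units_at_level(frame: Sequence[AdminUnit], level: int) -> list[AdminUnit]:
    """Units of one level, sorted by code (the tie-break order for lookups)."""
    return sorted((u for u in frame if u.level == level), key=lambda u: u.code)


def locate_points(
    frame: Sequence[AdminUnit], lon: np.ndarray, lat: np.ndarray, level: int = 2
) -> np.ndarray:
    """Assign each (lon, lat) point the code of the containing unit.

    Boundary-touching points go to the unit whose code sorts first; points
    inside no unit get ``None``.  Returns an object array of codes.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    codes = np.full(lon.shape, None, dtype=object)
    unassigned = np.ones(lon.shape, dtype=bool)
    for unit in units_at_level(frame, level):
        if not unassigned.any():
            break
        hit = unassigned & shapely.intersects_xy(unit.polygon, lon, lat)
        codes[hit] = unit.code
        unassigned &= ~hit
    return codes
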