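"""Per-coccolith morphometric records.

A :class:`MorphoRecord` holds the quantities measured for (or generated into)
one coccolith: mass ``m`` (pg), shield full axes ``a, b`` (µm), grid full
axes ``a_g, b_g`` (µm), peripheral grid perimeter ``p`` (µm), segment count
``n`` (``None`` when the inter-segment frontier is unresolved), average
segment width ``w = p/n`` (µm), proximal rim length ``L`` (µm), tube
thickness (out-of-plane height) ``t`` (µm), shield inclinations
``alpha_major, alpha_minor`` (degrees) and the shield/grid eccentricities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["MorphoRecord", "records_to_frame", "CSV_COLUMNS"]

#: exact column order of the morphometrics CSV
CSV_COLUMNS = [
    "id", "m_pg", "a_um", "b_um", "ag_um", "bg_um", "p_um", "n", "w_um",
    "L_um", "t_um", "alpha_major_deg", "alpha_minor_deg", "e_shield",
    "e_grid", "flags",
]


@dataclass
class MorphoRecord:
    """Measured (or ground-truth) quantities for one coccolith."""

    m: float = math.nan                 # mass, pg
    a: float = math.nan                 # shield full major axis, µm
    b: float = math.nan                 # shield full minor axis, µm
    a_g: float = math.nan               # grid full major axis, µm
    b_g: float = math.nan               # grid full minor axis, µm
    p: float = math.nan                 # grid perimeter, µm
    n: int | None = None                # segment count
    L: float = math.nan                 # proximal rim length, µm
    t: float = math.nan                 # tube thickness (height), µm
    alpha_major: float = math.nan       # shield inclination, degrees
    alpha_minor: float = math.nan       # shield inclination, degrees
    coccolith_id: int = 0
    flags: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def w(self) -> float:
        """Average segment width p/n, µm (nan when n is unresolved)."""
        if self.n is None or self.n <= 0 or not np.isfinite(self.p):
            return math.nan
        return self.p / self.n

    @property
    def e_shield(self) -> float:
        return _eccentricity(self.a, self.b)

    @property
    def e_grid(self) -> float:
        return _eccentricity(self.a_g, self.b_g)

    def to_row(self) -> dict:
        return {
            "id": self.coccolith_id,
            "m_pg": self.m,
            "a_um": self.a,
            "b_um": self.b,
            "ag_um": self.a_g,
            "bg_um": self.b_g,
            "p_um": self.p,
            "n": self.n if self.n is not None else np.nan,
            "w_um": self.w,
            "L_um": self.L,
            "t_um": self.t,
            "alpha_major_deg": self.alpha_major,
            "alpha_minor_deg": self.alpha_minor,
            "e_shield": self.e_shield,
            "e_grid": self.e_grid,
            "flags": ";".join(self.flags),
        }

    def to_dict(self) -> dict:
        return asdict(self)


def _eccentricity(a: float, b: float) -> float:
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0:
        return math.nan
    r = min(b / a, 1.0)
    return math.sqrt(max(0.0, 1.0 - r * r))


def records_to_frame(records: list[MorphoRecord]) -> pd.DataFrame:
    """Stack records into the canonical CSV-ordered DataFrame."""
    return pd.DataFrame([r.to_row() for r in records], columns=CSV_COLUMNS)
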