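"""Tissue-cage geometry: diffusible surface area, lumen volume, SA/V.

A tissue cage is a sealed silicone cylinder implanted subcutaneously and
perforated with a fixed number of biopsy-punch holes.  Drug exchange with the
surrounding tissue happens only through the fenestrations, so the diffusible
surface area is the summed area of the punch holes — it does not grow with
cage length.  The lumen volume does grow with length, which is how a series
of cages of identical tubing but different lengths spans a range of
surface-area-to-volume (SA/V) ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "CageSpec",
    "InvalidCageError",
    "fenestration_area",
    "lumen_volume",
    "surface_to_volume",
    "cage_table",
]


class InvalidCageError(ValueError):
    """Raised when a cage specification is physically impossible."""


@dataclass(frozen=True)
class CageSpec:
    """Physical description of one silicone tissue cage.

    Parameters
    ----------
    length_cm
        Cage length in cm (>= 0; zero length is allowed as a degenerate
        cylinder of zero volume).
    outer_diameter_mm
        Outer diameter of the silicone tubing, mm.
    wall_thickness_mm
        Tubing wall thickness, mm.  The lumen diameter is
        ``outer_diameter_mm - 2 * wall_thickness_mm``.
    n_holes
        Number of fenestrations punched through the wall.
    punch_diameter_mm
        Diameter of the biopsy punch used for the fenestrations, mm.
    """

    length_cm: float
    outer_diameter_mm: float = 17.0
    wall_thickness_mm: float = 1.0
    n_holes: int = 24
    punch_diameter_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.length_cm < 0:
            raise InvalidCageError(f"length_cm must be >= 0, got {self.length_cm}")
        if self.outer_diameter_mm <= 0:
            raise InvalidCageError("outer_diameter_mm must be > 0")
        if self.wall_thickness_mm <= 0:
            raise InvalidCageError("wall_thickness_mm must be > 0")
        if self.punch_diameter_mm <= 0:
            raise InvalidCageError("punch_diameter_mm must be > 0")
        if not (isinstance(self.n_holes, int) and self.n_holes >= 0):
            raise InvalidCageError(f"n_holes must be a non-negative integer, got {self.n_holes!r}")
        if self.lumen_diameter_mm <= 0:
            raise InvalidCageError(
                "wall thickness leaves no lumen: "
                f"OD {self.outer_diameter_mm} mm, wall {self.wall_thickness_mm} mm"
            )

    @property
    def lumen_diameter_mm(self) -> float:
        return self.outer_diameter_mm - 2.0 * self.wall_thickness_mm


def fenestration_area(spec: CageSpec) -> float:
    """Total diffusible surface area of the fenestrations, cm².

    Each punch hole is treated as a flat circle; tube-wall curvature is
    ignored.  Independent of cage length by construction.
    """
    r_cm = spec.punch_diameter_mm / 2.0 / 10.0
    return spec.n_holes * math.pi * r_cm**2


def lumen_volume(spec: CageSpec) -> float:
    """Internal (lumen) volume of the cage, mL.

    The full nominal cylinder is counted: pi * (lumen radius)^2 * length.
    """
    r_cm = spec.lumen_diameter_mm / 2.0 / 10.0
    return math.pi * r_cm**2 * spec.length_cm


def surface_to_volume(spec: CageSpec) -> float:
    """Surface-area-to-volume ratio, cm⁻¹ (fenestration area / lumen volume)."""
    vol = lumen_volume(spec)
    if vol <= 0:
        raise InvalidCageError("surface_to_volume undefined for zero-volume cage")
    return fenestration_area(spec) / vol


def cage_table(
    lengths_cm: Sequence[float],
    *,
    decimals: int | None = None,
    **spec_kwargs,
) -> pd.DataFrame:
    """Tabulate area, volume, and SA/V for a series of cage lengths.

    Parameters
    ----------
    lengths_cm
        Non-empty sequence of cage lengths in cm.
    decimals
        If given, round the displayed values to this many decimals
        (computations always use full precision).
    **spec_kwargs
        Overrides forwarded to :class:`CageSpec` (tubing dimensions etc.).
    """
    if len(lengths_cm) == 0:
        raise ValueError("lengths_cm must be non-empty")
    rows = []
    for length in lengths_cm:
        spec = CageSpec(length_cm=float(length), **spec_kwargs)
        rows.append(
            {
                "length_cm": spec.length_cm,
                "area_cm2": fenestration_area(spec),
                "volume_ml": lumen_volume(spec),
                "sav_per_cm": surface_to_volume(spec),
            }
        )
    table = pd.DataFrame(rows)
    if decimals is not None:
        table[["area_cm2", "volume_ml", "sav_per_cm"]] = table[
            ["area_cm2", "volume_ml", "sav_per_cm"]
        ].round(decimals)
    return table
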