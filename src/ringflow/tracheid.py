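"""Per-tracheid hydraulics: lumen, wall (pit) and total resistance.

A tracheid's axial flow resistance is the series sum of its lumen
resistance and its wall resistance.  The lumen is treated as a rectangular
Hagen–Poiseuille conduit of radial diameter ``L`` and tangential diameter
``T = TD − 2·WT`` over an effective length ``β·l`` (water crosses into the
next cell after travelling a fraction β of the tracheid).  The wall
resistance is the parallel combination of all bordered pits on the two
radial walls: with ``N_pit`` pits of identical resistance ``R_pit`` split
evenly between the two walls, and water crossing one wall on entry and one
on exit,

    R_wall = 2 · R_pit / N_pit.

Cells are classed as earlywood or latewood by Mork's rule
(earlywood iff ``L > 2·WT``); the tie goes to latewood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable
import math

from .errors import InputDomainError
from .isometry import PitGeometry, derive_pit_geometry
from .params import ModelParams
from .pit import PitResistance, pit_resistance, unity_pore_interaction
from .units import um_to_mm

__all__ = [
    "TracheidRecord",
    "TracheidHydraulics",
    "make_record",
    "hydraulic_diameter",
    "lumen_resistance",
    "pit_count",
    "tracheid_resistance",
    "default_wt_law",
    "linear_wt_law",
]

EARLYWOOD = "earlywood"
LATEWOOD = "latewood"


def linear_wt_law(slope: float, intercept: float) -> Callable[[float], float]:
    """Return a linear wall-thickness law WT(L) = slope·L + intercept (µm)."""
    def law(L: float) -> float:
        return slope * L + intercept
    return law


#: Wall-thickness law used for the single-tracheid resistance curves:
#: WT declines linearly from 10 µm at L→0 to ~5.4 µm at L=40 µm.
default_wt_law = linear_wt_law(-8.0 / 70.0, 10.0)


@dataclass(frozen=True)
class TracheidRecord:
    """One measured cell of a tracheidogram plus derived cross-section.

    ``i`` is the 1-based position from pith to bark; ``L`` and ``WT`` are
    the measured radial lumen diameter and wall thickness (µm); ``T`` is
    the tangential lumen diameter (µm), ``Dh`` the hydraulic diameter
    (µm) and ``wood_class`` the Mork classification.
    """

    i: int
    L: float
    WT: float
    T: float
    Dh: float
    wood_class: str


@dataclass(frozen=True)
class TracheidHydraulics:
    """Hydraulic outputs for one tracheid.

    Resistances in MPa s mm^-3, conductance in MPa^-1 s^-1 mm^3, cell-wall
    cross-sectional area ``CWA`` in µm².  ``Npit`` is the real-valued pit
    count (rounding to integers is presentation-only).
    """

    record: TracheidRecord
    geometry: PitGeometry
    pit: PitResistance
    Npit: float
    Rlum: float
    Rwall: float
    R: float
    K: float
    CWA: float


def make_record(i: int, L: float, WT: float, params: ModelParams) -> TracheidRecord:
    """Validate a measured cell and derive its cross-sectional quantities.

    Raises :class:`InputDomainError` if ``L`` or ``WT`` is non-positive or
    if the wall is so thick that no tangential lumen remains
    (``WT >= TD/2``).
    """
    if not (L > 0 and math.isfinite(L)):
        raise InputDomainError("lumen diameter must be positive and finite",
                               field="L", position=i)
    if not (WT > 0 and math.isfinite(WT)):
        raise InputDomainError("wall thickness must be positive and finite",
                               field="WT", position=i)
    T = params.TD - 2.0 * WT
    if not T > 0:
        raise InputDomainError(
            f"wall thickness WT={WT} leaves no tangential lumen (TD={params.TD})",
            field="WT", position=i)
    wood_class = EARLYWOOD if L > 2.0 * WT else LATEWOOD
    return TracheidRecord(i=i, L=L, WT=WT, T=T,
                          Dh=hydraulic_diameter(L, T), wood_class=wood_class)


def hydraulic_diameter(L: float, T: float) -> float:
    """Hydraulic diameter of a rectangular lumen: 2LT/(L+T) (µm)."""
    if not (L > 0 and T > 0):
        raise InputDomainError(f"lumen sides must be positive, got L={L}, T={T}")
    return 2.0 * L * T / (L + T)


def lumen_resistance(L: float, T: float, params: ModelParams) -> float:
    """Hagen–Poiseuille resistance of the rectangular lumen, MPa s mm^-3.

        R_lum = 8·µ·β·l·(L+T)^4 / (π·L^4·T^4)

    with L, T converted to mm.  For a square lumen (L = T = d) this is
    algebraically identical to the circular formula 128·µ·β·l/(π·Dh^4)
    evaluated at the hydraulic diameter Dh = d.
    """
    if not (L > 0 and T > 0):
        raise InputDomainError(f"lumen sides must be positive, got L={L}, T={T}")
    Lmm = um_to_mm(L)
    Tmm = um_to_mm(T)
    return (8.0 * params.mu * params.beta * params.l * (Lmm + Tmm) ** 4
            / (math.pi * Lmm ** 4 * Tmm ** 4))


def pit_count(L: float, params: ModelParams) -> float:
    """Number of pits on the two radial walls of a tracheid (real-valued).

    The radial wall area is ``l × L``; multiplying by the pit density α
    gives  N_pit = α·L·l.  Kept unrounded in all resistance formulas;
    reports round to the nearest integer for display only.
    """
    if not L > 0:
        raise InputDomainError(f"lumen diameter must be positive, got {L}")
    return params.alpha_per_mm2 * um_to_mm(L) * params.l


def tracheid_resistance(
    rec: TracheidRecord,
    params: ModelParams,
    *,
    dpe_fn: Callable[[float], float] | None = None,
    pore_interaction: Callable[[float], float] = unity_pore_interaction,
) -> TracheidHydraulics:
    """Assemble the full hydraulic budget of one tracheid.

    Series sum of the lumen resistance and the pit-parallel wall
    resistance; conductance is the reciprocal.  Geometry errors are
    re-raised with the cell position attached.
    """
    try:
        geom = derive_pit_geometry(rec.L, rec.WT, params,
                                   dpe_fn=dpe_fn, position=rec.i)
        pit = pit_resistance(geom, params, pore_interaction=pore_interaction)
    except InputDomainError:
        raise
    except Exception as exc:
        raise InputDomainError(f"pit geometry failed: {exc}",
                               position=rec.i) from exc
    npit = pit_count(rec.L, params)
    rlum = lumen_resistance(rec.L, rec.T, params)
    rwall = 2.0 * pit.R_pit / npit
    r = rlum + rwall
    cwa = (rec.L + 2.0 * rec.WT) * (rec.T + 2.0 * rec.WT) - rec.L * rec.T
    return TracheidHydraulics(record=rec, geometry=geom, pit=pit, Npit=npit,
                              Rlum=rlum, Rwall=rwall, R=r, K=1.0 / r, CWA=cwa)
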