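"""Hydraulic resistance of a single bordered pit.

Water crossing from one tracheid to its neighbour passes, in series,
through an aperture, a canal through the wall, the porous margo of the pit
membrane, and then the second canal and aperture.  The pit resistance is
therefore the series sum

    R_pit = R_margo + 2·R_canal + 2·R_aperture

with each term a low-Reynolds-number creeping-flow expression: the margo is
a perforated plate of ``N_po`` equal circular pores of equivalent diameter
``D_pe`` (Sampson–Roscoe orifice flow, corrected by a pluggable
pore-interaction factor f(ε)); each canal is a Hagen–Poiseuille tube of
length ``t_a`` (the wall thickness) and diameter ``D_a``; each aperture is
an orifice of diameter ``D_a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable
import math

from .errors import DegenerateGeometryError
from .params import ModelParams
from .units import um_to_mm

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .isometry import PitGeometry

__all__ = [
    "PitResistance",
    "margo_pore_count",
    "pit_resistance",
    "unity_pore_interaction",
]


def unity_pore_interaction(epsilon: float) -> float:
    """Default pore-interaction correction: no interaction, f(ε) = 1.

    Alternative corrections (accounting for the merging of flow streams
    through neighbouring margo pores) may be substituted; any such
    function must be monotone in ε with f(0) = 1.
    """
    return 1.0


@dataclass(frozen=True)
class PitResistance:
    """Series breakdown of one bordered pit's resistance, MPa s mm^-3.

    ``R_canals`` and ``R_apertures`` are the doubled terms (one canal and
    one aperture on each side of the membrane), so the components sum
    exactly to ``R_pit``.
    """

    R_margo: float
    R_canals: float
    R_apertures: float
    R_pit: float


def margo_pore_count(Dmc: float, Dpo: float, t_f: float) -> float:
    """Number of pores in the margo (real-valued, not rounded).

    The margo annulus — the circle of diameter ``Dmc`` whose area equals
    membrane area minus torus area — is tiled by pores of diameter ``Dpo``
    separated by strands of thickness ``t_f``:

        N_po = Dmc^2 / (0.63·Dpo + t_f)^2

    All lengths in µm (the ratio is dimensionless).
    """
    if not Dmc > 0:
        raise DegenerateGeometryError(f"Dmc must be positive, got {Dmc!r}")
    if not Dpo > 0:
        raise DegenerateGeometryError(f"Dpo must be positive, got {Dpo!r}")
    if t_f < 0:
        raise DegenerateGeometryError(f"t_f must be non-negative, got {t_f!r}")
    return Dmc ** 2 / (0.63 * Dpo + t_f) ** 2


def pit_resistance(
    geom: "PitGeometry",
    params: ModelParams,
    *,
    pore_interaction: Callable[[float], float] = unity_pore_interaction,
) -> PitResistance:
    """Series resistance of one bordered pit, MPa s mm^-3.

    Parameters
    ----------
    geom : PitGeometry
        Derived pit morphology (µm lengths and the margo pore count).
    params : ModelParams
        Supplies viscosity ``mu`` (MPa·s) and ``epsilon``.
    pore_interaction : callable, optional
        Correction f(ε) applied to the margo term; defaults to unity.
    """
    if not geom.Da > 0:
        raise DegenerateGeometryError(f"aperture diameter Da={geom.Da!r}")
    if not geom.Npo > 0:
        raise DegenerateGeometryError(f"margo pore count Npo={geom.Npo!r}")
    mu = params.mu
    Dpe = um_to_mm(geom.Dpe)
    Da = um_to_mm(geom.Da)
    t_a = um_to_mm(geom.t_a)
    f_eps = pore_interaction(params.epsilon)
    if not f_eps > 0:
        raise DegenerateGeometryError(
            f"pore interaction correction must be positive, got {f_eps!r}")

    r_margo = 24.0 * mu / (geom.Npo * Dpe ** 3 * f_eps)
    r_canals = 2.0 * 128.0 * t_a * mu / (math.pi * Da ** 4)
    r_apertures = 2.0 * 24.0 * mu / Da ** 3
    return PitResistance(
        R_margo=r_margo,
        R_canals=r_canals,
        R_apertures=r_apertures,
        R_pit=r_margo + r_canals + r_apertures,
    )
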