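"""Bordered-pit geometry from tracheid lumen diameter by isometric scaling.

In the Pinaceae, pit morphology scales linearly with the size of the
tracheid that carries it: membrane diameter is proportional to the radial
lumen diameter up to a species-level cap (wide tracheids build more pits,
not indefinitely larger ones), and torus, aperture and margo-pore
diameters are fixed fractions of the membrane diameter.  This module turns
a single measured cell (lumen diameter ``L``, wall thickness ``WT``) into
the full pit geometry the hydraulic formulas need, so pits never have to
be measured directly.

Default coefficients (central literature values):

    D_m  = 0.70 · L   capped at max_Dm
    D_t  = 0.50 · D_m
    D_a  = 0.25 · D_m
    D_po = 0.03030 · D_m
    t_a  = WT

The margo annulus diameter ``D_mc`` satisfies the area identity
``π(D_mc/2)² = π(D_m/2)² − π(D_t/2)²``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable
import math

from .errors import InputDomainError
from .params import ModelParams
from .pit import margo_pore_count

__all__ = ["PitGeometry", "derive_pit_geometry"]


@dataclass(frozen=True)
class PitGeometry:
    """Derived morphology of the bordered pits of one tracheid (µm).

    Attributes
    ----------
    Dm, Dt, Da, Dpo : float
        Membrane, torus, aperture and margo-pore diameters.
    Dpe : float
        Equivalent margo-pore diameter used in the margo resistance term;
        equals ``Dpo`` unless a custom mapping is supplied.
    Dmc : float
        Diameter of the circle whose area is membrane minus torus area.
    t_a : float
        Pit canal length; equals the wall thickness of the owning cell.
    Npo : float
        Real-valued pore count in the margo.
    capped : bool
        Whether the membrane diameter hit the ``max_Dm`` cap.
    """

    Dm: float
    Dt: float
    Da: float
    Dpo: float
    Dpe: float
    Dmc: float
    t_a: float
    Npo: float
    capped: bool


def derive_pit_geometry(
    L: float,
    WT: float,
    params: ModelParams,
    *,
    dpe_fn: Callable[[float], float] | None = None,
    position: int | None = None,
) -> PitGeometry:
    """Derive the pit geometry of a tracheid from its cross-section.

    Parameters
    ----------
    L, WT : float
        Radial lumen diameter and radial wall thickness, µm.
    params : ModelParams
        Isometric coefficients and the membrane cap ``max_Dm``.
    dpe_fn : callable, optional
        Maps the margo pore diameter ``Dpo`` to the equivalent pore
        diameter ``Dpe``; the default is the identity (``Dpe = Dpo``).
    position : int, optional
        Tracheidogram position, attached to error messages.

    Raises
    ------
    InputDomainError
        If ``L`` or ``WT`` is not strictly positive.
    """
    if not (L > 0 and math.isfinite(L)):
        raise InputDomainError("lumen diameter must be positive and finite",
                               field="L", position=position)
    if not (WT > 0 and math.isfinite(WT)):
        raise InputDomainError("wall thickness must be positive and finite",
                               field="WT", position=position)

    uncapped = params.c_Dm * L
    capped = uncapped >= params.max_Dm
    Dm = params.max_Dm if capped else uncapped
    Dt = params.c_Dt * Dm
    Da = params.c_Da * Dm
    Dpo = params.c_Dpo * Dm
    Dpe = Dpo if dpe_fn is None else dpe_fn(Dpo)
    Dmc = math.sqrt(Dm ** 2 - Dt ** 2)
    Npo = margo_pore_count(Dmc, Dpo, params.t_f)
    return PitGeometry(Dm=Dm, Dt=Dt, Da=Da, Dpo=Dpo, Dpe=Dpe, Dmc=Dmc,
                       t_a=WT, Npo=Npo, capped=capped)
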