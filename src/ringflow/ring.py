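"""Ring-level integration of per-tracheid hydraulics.

The annual ring is represented by one representative radial file
(tracheidogram).  Because a tracheid exchanges water mainly with its
tangential neighbours, the cells of the file are treated as isolated
parallel resistances: ring conductance is the plain sum of per-cell
conductances, and ring resistance its reciprocal.  From the same cells the
module derives the pit contribution to ring resistance (by rebuilding the
ring from lumens only), the cumulative-conductance profile from pith to
bark, the earlywood/latewood conductance split, and the lumen diameter at
which wall and lumen resistance cross over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InputDomainError
from .params import ModelParams
from .tracheid import (LATEWOOD, TracheidHydraulics, default_wt_law,
                       lumen_resistance, make_record, tracheid_resistance)
from .units import conductance_mm3_to_m3

__all__ = [
    "RingHydraulics",
    "integrate_ring",
    "pit_contribution",
    "wood_class_shares",
    "crossover_diameter",
    "compute_ring",
]


@dataclass(frozen=True)
class RingHydraulics:
    """Ring-level hydraulic summary.

    ``K_ring_mm3`` is in MPa^-1 s^-1 mm^3 and ``K_ring_m3`` mirrors it in
    MPa^-1 s^-1 m^3 (factor 1e-9); both are carried explicitly so no
    consumer ever has to guess the base.  ``cum_K`` is the per-cell
    cumulative conductance proportion in tracheidogram order (pith to
    bark), non-decreasing and ending at 1.  ``ring_width_um`` is the
    context-only proxy Σ(L + 2·WT).
    """

    ring_id: str
    n_cells: int
    K_ring_mm3: float
    K_ring_m3: float
    R_ring: float
    R_onlylum: float
    pit_contribution: float
    cum_K: np.ndarray = field(repr=False)
    latewood_share: float = 0.0
    earlywood_share: float = 1.0
    ring_width_um: float = 0.0


def integrate_ring(cells: Sequence[TracheidHydraulics],
                   ring_id: str = "ring") -> RingHydraulics:
    """Integrate an ordered tracheidogram into ring-level hydraulics.

    Raises :class:`InputDomainError` on an empty tracheidogram.
    """
    if len(cells) == 0:
        raise InputDomainError("cannot integrate an empty tracheidogram",
                               source=ring_id)
    K = np.array([c.K for c in cells], dtype=float)
    k_ring = float(K.sum())
    cum_K = np.cumsum(K) / k_ring
    r_ring = 1.0 / k_ring
    r_onlylum = 1.0 / float(sum(1.0 / c.Rlum for c in cells))
    shares = wood_class_shares(cells)
    width = float(sum(c.record.L + 2.0 * c.record.WT for c in cells))
    return RingHydraulics(
        ring_id=ring_id,
        n_cells=len(cells),
        K_ring_mm3=k_ring,
        K_ring_m3=conductance_mm3_to_m3(k_ring),
        R_ring=r_ring,
        R_onlylum=r_onlylum,
        pit_contribution=1.0 - r_onlylum / r_ring,
        cum_K=cum_K,
        latewood_share=shares[LATEWOOD],
        earlywood_share=shares["earlywood"],
        ring_width_um=width,
    )


def pit_contribution(cells: Sequence[TracheidHydraulics],
                     ring: RingHydraulics) -> float:
    """Fraction of ring resistance attributable to pits.

    Rebuilds the ring as parallel lumens only (R_onlylum) and returns
    ``1 − R_onlylum / R_ring``; zero when every wall resistance is zero.
    """
    r_onlylum = 1.0 / float(sum(1.0 / c.Rlum for c in cells))
    return 1.0 - r_onlylum / ring.R_ring


def wood_class_shares(cells: Sequence[TracheidHydraulics],
                      ring: RingHydraulics | None = None) -> dict[str, float]:
    """Earlywood/latewood fractions of ring conductance (sum to 1)."""
    k_total = sum(c.K for c in cells)
    k_lw = sum(c.K for c in cells if c.record.wood_class == LATEWOOD)
    return {"earlywood": (k_total - k_lw) / k_total,
            LATEWOOD: k_lw / k_total}


def crossover_diameter(
    params: ModelParams,
    wt_law: Callable[[float], float] = default_wt_law,
    *,
    L_min: float = 4.0,
    L_max: float = 40.0,
    step: float = 0.1,
) -> float:
    """Lumen diameter (µm) at which wall and lumen resistance are equal.

    Scans L on a uniform grid (``step`` ≤ 0.1 µm), locates the sign change
    of ``Rwall − Rlum`` and linearly interpolates within the bracketing
    interval.  ``wt_law`` must give valid wall thicknesses over the range.

    Raises :class:`InputDomainError` if the difference does not change
    sign over the scan range.
    """
    if step > 0.1:
        step = 0.1
    grid = np.arange(L_min, L_max + step / 2.0, step)

    def diff(L: float) -> float:
        rec = make_record(1, L, wt_law(L), params)
        h = tracheid_resistance(rec, params)
        return h.Rwall - h.Rlum

    values = np.array([diff(L) for L in grid])
    sign_change = np.nonzero(np.diff(np.sign(values)) != 0)[0]
    if sign_change.size == 0:
        raise InputDomainError(
            f"Rwall - Rlum does not change sign on [{L_min}, {L_max}] µm; "
            "widen the scan range or check the wall-thickness law")
    j = int(sign_change[0])
    x0, x1 = grid[j], grid[j + 1]
    y0, y1 = values[j], values[j + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def compute_ring(
    rows: Sequence[tuple[int, float, float]],
    params: ModelParams,
    ring_id: str = "ring",
    **kwargs,
) -> tuple[list[TracheidHydraulics], RingHydraulics]:
    """Convenience pipeline: (position, L, WT) rows → cells + ring summary.

    Extra keyword arguments (``dpe_fn``, ``pore_interaction``) are passed
    through to :func:`ringflow.tracheid.tracheid_resistance`.
    """
    cells = [tracheid_resistance(make_record(i, L, WT, params), params, **kwargs)
             for i, L, WT in rows]
    return cells, integrate_ring(cells, ring_id=ring_id)
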