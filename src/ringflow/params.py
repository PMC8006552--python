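"""Model constants, tunable parameters and named calibration profiles.

The model treats a conifer tree ring as a representative radial file of
tracheids.  Everything it needs beyond the measured lumen diameter ``L``
and wall thickness ``WT`` of each cell is collected in
:class:`ModelParams`: water viscosity, tracheid length and tangential
diameter, pit density, the tracheid-overlap factor, and the isometric
coefficients that map lumen diameter to bordered-pit morphology.

Unit system
-----------
Hydraulics are computed in MPa, s and mm (see :mod:`ringflow.units`), so
the dynamic viscosity of water at 20 °C is expressed as
``mu = 1.002e-9 MPa·s``.  Anatomical lengths (``t_f``, ``TD``, ``max_Dm``)
are in µm because that is how they are measured; the axial tracheid length
``l`` is in mm; pit density ``alpha`` is in m^-2 as conventionally
reported.  Conversions happen inside the hydraulic formulas, never at the
parameter level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace as _dc_replace
from pathlib import Path

from .errors import ConfigError

__all__ = ["ModelParams", "PROFILES", "get_profile"]


@dataclass(frozen=True)
class ModelParams:
    """All constants and tunables of the tree-ring hydraulic model.

    Parameters
    ----------
    mu : float
        Dynamic viscosity of water at 20 °C, MPa·s.
    t_f : float
        Mean thickness of margo strands, µm.
    l : float
        Axial tracheid length, mm.  Constant within a run.
    TD : float
        Outer tangential tracheid diameter, µm; the tangential lumen
        diameter of a cell is ``T = TD - 2*WT``.
    alpha : float
        Bordered-pit density per unit radial wall area, m^-2.
    beta : float
        Tracheid-overlap factor: the fraction of the tracheid length a
        water molecule travels before crossing into the next cell.
    max_Dm : float
        Maximum pit-membrane diameter, µm.  Membrane diameter scales
        isometrically with lumen diameter up to this cap.
    c_Dm, c_Dt, c_Da, c_Dpo : float
        Isometric coefficients: membrane/lumen, torus/membrane,
        aperture/membrane and margo-pore/membrane diameter ratios.
    epsilon : float
        Fraction of margo area occupied by pores; consumed by the
        pluggable pore-interaction correction (default correction is
        unity, see :func:`ringflow.pit.unity_pore_interaction`).
    """

    mu: float = 1.002e-9
    t_f: float = 0.140
    l: float = 2.2
    TD: float = 30.0
    alpha: float = 6.5e8
    beta: float = 0.5
    max_Dm: float = 25.0
    c_Dm: float = 0.70
    c_Dt: float = 0.50
    c_Da: float = 0.25
    c_Dpo: float = 0.03030
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        positive = ("mu", "t_f", "l", "TD", "alpha", "max_Dm",
                    "c_Dm", "c_Dt", "c_Da", "c_Dpo")
        for name in positive:
            if name == "t_f":
                if self.t_f < 0:
                    raise ConfigError("t_f must be non-negative")
                continue
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")
        if not 0 < self.beta <= 1:
            raise ConfigError(f"beta must be in (0, 1], got {self.beta!r}")
        if not 0 <= self.epsilon < 1:
            raise ConfigError(f"epsilon must be in [0, 1), got {self.epsilon!r}")
        # aperture narrower than torus narrower than membrane
        if not self.c_Da < self.c_Dt < 1:
            raise ConfigError(
                f"require c_Da < c_Dt < 1, got c_Da={self.c_Da!r}, c_Dt={self.c_Dt!r}")

    @property
    def alpha_per_mm2(self) -> float:
        """Pit density converted to mm^-2."""
        return self.alpha * 1e-6

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return _dc_replace(self, **changes)

    # -- flat key/value (JSON) serialization --------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        try:
            values = {k: float(v) for k, v in d.items()}
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"non-numeric parameter value: {exc}") from exc
        return cls(**values)

    def to_config(self, path: str | Path) -> None:
        """Write the parameter set as a flat JSON key/value file."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ModelParams":
        """Read a flat JSON key/value file written by :meth:`to_config`."""
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"config {path} must hold a flat JSON object")
        return cls.from_dict(d)


#: Named calibration profiles.  The two differ only in the membrane cap:
#: ``pinaceae_22`` is the generic Pinaceae calibration (22 µm cap) used for
#: single-tracheid and single-pit resistance curves; ``larix_25`` raises the
#: cap to 25 µm for mature Larix sibirica, whose dominant trees build wider
#: pits, and is the profile behind the bundled Siberian larch worked example.
PROFILES: dict[str, ModelParams] = {
    "pinaceae_22": ModelParams(max_Dm=22.0),
    "larix_25": ModelParams(max_Dm=25.0),
}


def get_profile(name: str) -> ModelParams:
    """Look up a named parameter profile."""
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}") from None
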