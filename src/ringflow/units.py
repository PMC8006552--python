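"""Explicit unit conversions for the MPa-s-mm unit system.

All hydraulics inside the package are computed with pressures in MPa,
times in s and lengths in mm, so resistances come out in MPa s mm^-3 and
conductances in MPa^-1 s^-1 mm^3.  The published literature usually prints
resistances on an m^3 base (MPa s m^-3) or, for per-cell tables, in
10^-3 MPa s mm^-3 (equivalently kPa s mm^-3).  Because a silent factor of
10^9 between the mm^3 and m^3 bases is the dominant failure mode when
comparing hydraulic numbers, every conversion here is an explicit, named
helper; nothing in the package converts implicitly.
"""

MM_PER_UM = 1e-3
#: 1 mm^-3 = 1e9 m^-3
RESISTANCE_MM3_TO_M3 = 1e9
#: 1 mm^3 = 1e-9 m^3
CONDUCTANCE_MM3_TO_M3 = 1e-9
#: MPa s mm^-3 -> 10^-3 MPa s mm^-3 (= kPa s mm^-3), the per-cell table scale
RESISTANCE_MM3_TO_KPA = 1e3


def um_to_mm(x: float) -> float:
    """Convert a length from µm to mm."""
    return x * MM_PER_UM


def resistance_mm3_to_m3(r: float) -> float:
    """Convert a resistance from MPa s mm^-3 to MPa s m^-3."""
    return r * RESISTANCE_MM3_TO_M3


def conductance_mm3_to_m3(k: float) -> float:
    """Convert a conductance from MPa^-1 s^-1 mm^3 to MPa^-1 s^-1 m^3."""
    return k * CONDUCTANCE_MM3_TO_M3


def resistance_mm3_to_kpa_scale(r: float) -> float:
    """Convert MPa s mm^-3 to the kPa s mm^-3 scale used in per-cell reports."""
    return r * RESISTANCE_MM3_TO_KPA
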