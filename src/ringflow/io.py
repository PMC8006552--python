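"""Tracheidogram input/output and the bundled Larix worked-example data.

Input is delimited text (CSV/TSV/semicolon) with one row per cell and
header-mapped columns for the ring identifier, the 1-based position, the
radial lumen diameter and the radial wall thickness — the table shape that
cell-anatomy pipelines (ROXAS → RAPTOR → tracheidogram standardisation)
export.  Lengths are µm throughout; there is no unit autodetection, since
silent unit errors are the dominant failure mode with anatomical tables.

Output mirrors the field's per-cell table layout (position, wood class,
inputs, pit geometry, resistance budget, conductance, cumulative
conductance), with the resistance columns on the 10^-3 MPa s mm^-3 scale
conventional for per-cell values, plus a per-ring summary CSV and a JSON
run manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputDomainError
from .ring import RingHydraulics
from .tracheid import TracheidHydraulics
from .units import resistance_mm3_to_kpa_scale

__all__ = [
    "Tracheidogram",
    "read_tracheidograms",
    "write_tracheidograms",
    "write_cell_report",
    "write_ring_report",
    "write_manifest",
    "load_reference_tracheidograms",
    "load_reference_table",
]

# Accepted (normalised) header spellings for each required column.
_COLUMN_ALIASES = {
    "ring": {"ring", "ring_id", "id", "tree_ring"},
    "pos": {"pos", "position", "i", "cell"},
    "L": {"l", "l_um", "lumen", "lumen_diameter", "lumen_diameter_um", "ld"},
    "WT": {"wt", "wt_um", "wall", "wall_thickness", "wall_thickness_um", "cwt"},
}


@dataclass(frozen=True)
class Tracheidogram:
    """One ring's ordered radial file: (position, L µm, WT µm) triples."""

    ring_id: str
    cells: tuple[tuple[int, float, float], ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.cells)


def _normalise(name: str) -> str:
    return str(name).strip().lower()


def _map_columns(columns, source: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        hits = [c for c in columns if _normalise(c) in aliases]
        if not hits:
            raise InputDomainError(
                f"missing required column for {canonical!r} "
                f"(accepted names: {sorted(aliases)})", source=source)
        mapping[canonical] = hits[0]
    return mapping


def read_tracheidograms(path: str | Path, *, delimiter: str | None = None,
                        TD: float = 30.0) -> list[Tracheidogram]:
    """Read tracheidograms from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV/TSV/semicolon-delimited table; ``#`` lines are comments.
    delimiter : str, optional
        Force a delimiter; by default comma/tab/semicolon are sniffed.
    TD : float
        Outer tangential diameter (µm) used to reject rows whose wall
        thickness leaves no tangential lumen (``WT >= TD/2``).

    Returns
    -------
    list of :class:`Tracheidogram`, one per ring identifier, rows sorted
    by position.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    source = str(path)
    content_lines = [ln for ln in path.read_text().splitlines()
                     if ln.strip() and not ln.lstrip().startswith("#")]
    if not content_lines:
        warnings.warn(f"{source}: no tracheidogram rows found", stacklevel=2)
        return []
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python", comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{source}: no tracheidogram rows found", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{source}: no tracheidogram rows found", stacklevel=2)
        return []

    cols = _map_columns(df.columns, source)
    out: list[Tracheidogram] = []
    for ring_id, group in df.groupby(cols["ring"], sort=False):
        cells: list[tuple[int, float, float]] = []
        for row_idx, row in group.iterrows():
            where = f"{source} (data row {row_idx + 1}, ring {ring_id})"
            try:
                pos = int(row[cols["pos"]])
                L = float(row[cols["L"]])
                WT = float(row[cols["WT"]])
            except (TypeError, ValueError) as exc:
                raise InputDomainError(f"non-numeric value: {exc}",
                                       source=where) from exc
            if not (np.isfinite(L) and L > 0):
                raise InputDomainError("lumen diameter must be positive",
                                       field="L", position=pos, source=where)
            if not (np.isfinite(WT) and WT > 0):
                raise InputDomainError("wall thickness must be positive",
                                       field="WT", position=pos, source=where)
            if WT >= TD / 2.0:
                raise InputDomainError(
                    f"wall thickness {WT} µm leaves no tangential lumen "
                    f"(TD = {TD} µm)", field="WT", position=pos, source=where)
            cells.append((pos, L, WT))
        cells.sort(key=lambda c: c[0])
        positions = [c[0] for c in cells]
        if len(set(positions)) != len(positions):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise InputDomainError(
                f"duplicate position(s) {dupes}",
                source=f"{source} (ring {ring_id})")
        if positions != list(range(1, len(positions) + 1)):
            raise InputDomainError(
                f"positions must be consecutive from 1, got {positions}",
                source=f"{source} (ring {ring_id})")
        out.append(Tracheidogram(ring_id=str(ring_id), cells=tuple(cells),
                                 provenance=source))
    return out


def write_tracheidograms(tracheidograms: Sequence[Tracheidogram],
                         path: str | Path) -> None:
    """Write tracheidograms in the input format, values at full precision.

    A file written here reads back bit-exactly (the full-precision echo
    that makes write→read a lossless round trip).
    """
    path = Path(path)
    rows = [{"ring": tg.ring_id, "pos": i, "L_um": L, "WT_um": WT}
            for tg in tracheidograms for i, L, WT in tg.cells]
    df = pd.DataFrame(rows, columns=["ring", "pos", "L_um", "WT_um"])
    df.to_csv(path, index=False, float_format="%.17g")


#: (column, decimals) layout of the per-cell report; resistances are on the
#: 10^-3 MPa s mm^-3 (kPa s mm^-3) scale and rounded to integers like the
#: conventional per-cell tables; geometry columns carry 2 decimals.
CELL_REPORT_COLUMNS: tuple[tuple[str, int | None], ...] = (
    ("pos", None), ("wood_class", None), ("L_um", 2), ("WT_um", 2),
    ("CWA_um2", 2), ("N_pit", 0), ("Dm_um", 2), ("Da_um", 2), ("Dt_um", 2),
    ("Rwall_kPa_s_mm3", 0), ("Rlum_kPa_s_mm3", 0), ("R_kPa_s_mm3", 0),
    ("K_MPa_s_mm3", 2), ("cum_K", 2),
)


def cell_report_frame(cells: Sequence[TracheidHydraulics]) -> pd.DataFrame:
    """Per-cell report rows (unformatted floats) in tracheidogram order."""
    k = np.array([c.K for c in cells], dtype=float)
    cum = np.cumsum(k) / k.sum() if len(cells) else np.array([])
    rows = []
    for c, cum_k in zip(cells, cum):
        rows.append({
            "pos": c.record.i,
            "wood_class": c.record.wood_class,
            "L_um": c.record.L,
            "WT_um": c.record.WT,
            "CWA_um2": c.CWA,
            "N_pit": c.Npit,
            "Dm_um": c.geometry.Dm,
            "Da_um": c.geometry.Da,
            "Dt_um": c.geometry.Dt,
            "Rwall_kPa_s_mm3": resistance_mm3_to_kpa_scale(c.Rwall),
            "Rlum_kPa_s_mm3": resistance_mm3_to_kpa_scale(c.Rlum),
            "R_kPa_s_mm3": resistance_mm3_to_kpa_scale(c.R),
            "K_MPa_s_mm3": c.K,
            "cum_K": cum_k,
        })
    return pd.DataFrame(rows, columns=[name for name, _ in CELL_REPORT_COLUMNS])


def write_cell_report(cells: Sequence[TracheidHydraulics],
                      path: str | Path, *, sep: str = ",") -> None:
    """Write the per-cell report with the documented per-column rounding.

    ``N_pit`` is rounded to the nearest integer here and only here; all
    internal computation uses the real-valued count.  An empty cell list
    produces a header-only file.
    """
    df = cell_report_frame(cells)
    for name, decimals in CELL_REPORT_COLUMNS:
        if decimals is None or df.empty:
            continue
        if decimals == 0:
            df[name] = df[name].round().astype("int64")
        else:
            df[name] = df[name].round(decimals)
    df.to_csv(Path(path), index=False, sep=sep)


RING_REPORT_COLUMNS = (
    "ring_id", "n_cells", "K_ring_MPa_s_mm3", "K_ring_MPa_s_m3",
    "R_ring_MPa_s_mm3", "pit_contribution", "latewood_share",
    "ring_width_um",
)


def write_ring_report(rings: Sequence[RingHydraulics],
                      path: str | Path, *, sep: str = ",") -> None:
    """Write one summary row per ring (both conductance unit bases)."""
    rows = [{
        "ring_id": r.ring_id,
        "n_cells": r.n_cells,
        "K_ring_MPa_s_mm3": r.K_ring_mm3,
        "K_ring_MPa_s_m3": r.K_ring_m3,
        "R_ring_MPa_s_mm3": r.R_ring,
        "pit_contribution": r.pit_contribution,
        "latewood_share": r.latewood_share,
        "ring_width_um": r.ring_width_um,
    } for r in rings]
    pd.DataFrame(rows, columns=list(RING_REPORT_COLUMNS)).to_csv(
        Path(path), index=False, sep=sep, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(path: str | Path, *, params: dict, profile: str | None,
                   inputs: Sequence[str | Path] = (), seed: int | None = None,
                   command: str = "", extra: dict | None = None) -> None:
    """Write a JSON run manifest sufficient to reproduce the run."""
    from . import __version__
    manifest = {
        "software": "ringflow",
        "version": __version__,
        "command": command,
        "profile": profile,
        "params": params,
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _data_path(name: str):
    return resources.files("ringflow").joinpath("data", name)


def load_reference_tracheidograms() -> list[Tracheidogram]:
    """The two bundled Larix sibirica tracheidograms (tree T10, Shira)."""
    with resources.as_file(_data_path("larix_t10_tracheidograms.csv")) as p:
        return read_tracheidograms(p)


def load_reference_table() -> pd.DataFrame:
    """The published per-cell hydraulic table for the bundled rings.

    See the header of ``data/larix_t10_reference.csv`` for the unit
    reading and the single transcription correction.
    """
    with resources.as_file(_data_path("larix_t10_reference.csv")) as p:
        return pd.read_csv(p, comment="#")
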