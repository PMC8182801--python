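"""Minimal CIF ingestion: unit cell, temperature, pressure and R-factor only.

The survey is metric-only, so all that is read from a CIF is
``_cell_length_*``, ``_cell_angle_*``, ``_diffrn_ambient_temperature``,
``_diffrn_ambient_pressure`` and an R-factor tag; everything else in the
file is ignored.  Parsing is delegated to gemmi.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import gemmi

from .cells import UnitCell
from .families import CsdEntry

__all__ = ["read_cif_entry"]

_R_FACTOR_TAGS = (
    "_refine_ls_R_factor_gt",
    "_refine_ls_R_factor_obs",
    "_refine_ls_R_factor_all",
)

# ambient pressure in kPa; anything clearly above one atmosphere is flagged
_AMBIENT_PRESSURE_KPA = 200.0


def _get_number(block: gemmi.cif.Block, tag: str) -> Optional[float]:
    raw = block.find_value(tag)
    if raw is None:
        return None
    raw = raw.strip()
    if raw in ("?", "."):
        return None
    try:
        return gemmi.cif.as_number(raw)
    except (ValueError, RuntimeError):
        return None


def read_cif_entry(path: str | Path, refcode: Optional[str] = None) -> CsdEntry:
    """Build a survey entry from the first data block of a CIF file.

    ``refcode`` defaults to the block name.  Temperature and R-factor are
    None when absent; the pressure flag is set when
    ``_diffrn_ambient_pressure`` is present and clearly above ambient.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block() if len(doc) == 1 else doc[0]
    values = {}
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        v = _get_number(block, tag)
        if v is None:
            raise ValueError(f"{path}: missing required tag {tag}")
        values[tag] = v
    cell = UnitCell(
        values["_cell_length_a"], values["_cell_length_b"], values["_cell_length_c"],
        values["_cell_angle_alpha"], values["_cell_angle_beta"], values["_cell_angle_gamma"],
    )
    temperature = _get_number(block, "_diffrn_ambient_temperature")
    pressure = _get_number(block, "_diffrn_ambient_pressure")
    r_factor = None
    for tag in _R_FACTOR_TAGS:
        r_factor = _get_number(block, tag)
        if r_factor is not None:
            break
    return CsdEntry(
        refcode=refcode or block.name or Path(path).stem,
        cell=cell,
        temperature=temperature,
        r_factor=r_factor,
        pressure_flag=bool(pressure is not None and pressure > _AMBIENT_PRESSURE_KPA),
    )
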