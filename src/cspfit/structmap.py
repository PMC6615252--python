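"""Write per-residue CSP values onto a PDB structure's B-factor column.

Molecular viewers colour by B-factor, so replacing that column with
per-residue CSP (or differential-CSP) values turns any ribbon rendering
into a perturbation map. Residues without data get a sentinel (−1.00 by
default, rendered as a distinct "no data" colour class) or are left
untouched under the ``skip`` policy.

The edit is a fixed-width text rewrite of columns 61–66 of ATOM/HETATM
records only; every other byte of the file is preserved, so the output
remains a valid PDB with identical coordinates and atom count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import math

from .shift_io import NumberingOffset

__all__ = ["ResidueValueMap", "map_to_bfactor"]

_POLICIES = ("gray-sentinel", "skip")


@dataclass(frozen=True)
class ResidueValueMap:
    """Residue → value (ppm) map plus the policy for unmapped residues."""

    values: Mapping[int, float]
    missing_policy: str = "gray-sentinel"
    sentinel: float = -1.0

    def __post_init__(self) -> None:
        if self.missing_policy not in _POLICIES:
            raise ValueError(f"missing_policy must be one of {_POLICIES}")
        for r, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"value for residue {r} must be finite and >= 0")


def map_to_bfactor(
    structure_path: str | Path,
    value_map: ResidueValueMap,
    chain: str,
    out_path: str | Path,
    offset: NumberingOffset = NumberingOffset(0),
    scale: str = "max",
) -> Path:
    """Rewrite B-factors of one chain from a residue-value map.

    ``offset`` converts the map's residue numbering to the structure's
    (structure resid = residue_index + offset). With ``scale="max"``
    values are scaled linearly to [0, 99.99] by the map maximum; with
    ``scale="raw"`` they are written as-is (clipped to the PDB field).
    """
    if scale not in ("max", "raw"):
        raise ValueError("scale must be 'max' or 'raw'")
    if not value_map.values:
        raise ValueError("no residue overlap: value map is empty")
    structure_path = Path(structure_path)
    lines = structure_path.read_text(encoding="utf-8").splitlines(keepends=True)

    vmax = max(value_map.values.values())
    if scale == "max" and vmax > 0:
        scaled = {r: v / vmax * 99.99 for r, v in value_map.values.items()}
    else:
        scaled = {r: min(v, 999.99) for r, v in value_map.values.items()}
    by_struct_resid = {offset.apply(r): b for r, b in scaled.items()}

    chains_seen: set[str] = set()
    mapped_resids: set[int] = set()
    out: list[str] = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
            ch = line[21]
            chains_seen.add(ch)
            if ch == chain:
                resid = int(line[22:26])
                if resid in by_struct_resid:
                    b = by_struct_resid[resid]
                    mapped_resids.add(resid)
                elif value_map.missing_policy == "gray-sentinel":
                    b = value_map.sentinel
                else:  # skip: leave original bytes
                    out.append(line)
                    continue
                line = line[:60] + f"{b:6.2f}" + line[66:]
        out.append(line)

    if chain not in chains_seen:
        raise ValueError(f"chain {chain!r} not found in {structure_path}")
    if not mapped_resids:
        raise ValueError(
            f"no residue overlap between the value map and chain {chain!r} "
            "after offset correction"
        )
    out_path = Path(out_path)
    out_path.write_text("".join(out), encoding="utf-8")
    return out_path
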