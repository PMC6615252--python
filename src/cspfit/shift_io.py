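"""Chemical-shift tables and titration-series manifests.

One :class:`ShiftTable` holds the per-residue backbone amide shifts
(¹H_N and ¹⁵N, ppm) extracted from a single 2D ¹H-¹⁵N HSQC spectrum.
A :class:`TitrationSeries` is the ordered set of such tables recorded at
increasing ligand concentration, starting from the ligand-free (apo)
reference.

Two CSV dialects are supported:

* ``long-csv`` — header ``residue_index,residue_type,atom,shift_ppm``
  with one row per residue/atom pair, ``atom`` in ``{H, N}``;
* ``wide-csv`` — header ``residue_index,residue_type,shift_H_ppm,shift_N_ppm``
  with one row per residue.

Empty shift fields denote genuinely missing data (prolines, overlapped or
exchange-broadened peaks) and are preserved as ``None`` — never coerced to
zero, since 0 ppm is a legal chemical shift.

Residue numbering offsets between assignment sources (e.g. a deposited
assignment numbered one residue off from the construct used in a titration)
are handled by :class:`NumberingOffset`, applied at import time.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "AMINO_ACIDS",
    "NumberingOffset",
    "ShiftRecord",
    "ShiftTable",
    "TitrationPoint",
    "TitrationSeries",
    "read_shift_table",
    "write_shift_table",
    "read_series_manifest",
    "write_series_manifest",
]

#: The 20 standard one-letter amino-acid codes plus 'X' for unknown.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_FORMATS = ("long-csv", "wide-csv")


@dataclass(frozen=True)
class NumberingOffset:
    """Signed offset added to residue indices on import.

    Handles renumbering between assignment sources, e.g. a deposited
    assignment whose T30 corresponds to T31 in the construct at hand
    (offset +1).
    """

    offset: int = 0

    def apply(self, residue_index: int) -> int:
        return residue_index + self.offset

    def invert(self) -> "NumberingOffset":
        return NumberingOffset(-self.offset)


@dataclass(frozen=True)
class ShiftRecord:
    """Backbone amide shifts of one residue.

    ``shift_H``/``shift_N`` are in ppm; ``None`` means the peak was not
    observed (missing assignment, overlap, or — for proline — no backbone
    amide proton at all).
    """

    residue_index: int
    residue_type: str
    shift_H: Optional[float] = None
    shift_N: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(
                f"residue_index must be >= 1, got {self.residue_index}"
            )
        if self.residue_type not in AMINO_ACIDS:
            raise ValueError(
                f"unknown residue type {self.residue_type!r} at residue "
                f"{self.residue_index}"
            )
        if self.residue_type == "P" and not (
            self.shift_H is None and self.shift_N is None
        ):
            raise ValueError(
                f"proline {self.residue_index} has no backbone amide; "
                "both shifts must be missing"
            )
        for name, v in (("shift_H", self.shift_H), ("shift_N", self.shift_N)):
            if v is not None and not math.isfinite(v):
                raise ValueError(
                    f"{name} of residue {self.residue_index} is not finite"
                )

    @property
    def complete(self) -> bool:
        """True when both the ¹H and ¹⁵N shift are present."""
        return self.shift_H is not None and self.shift_N is not None


@dataclass
class ShiftTable:
    """Per-residue shift list for one sample condition (one HSQC)."""

    label: str
    records: list[ShiftRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"shift table {self.label!r} is empty")
        seen: set[int] = set()
        for rec in self.records:
            if rec.residue_index in seen:
                raise ValueError(
                    f"duplicate residue index {rec.residue_index} in table "
                    f"{self.label!r}"
                )
            seen.add(rec.residue_index)
        self.records = sorted(self.records, key=lambda r: r.residue_index)

    def __len__(self) -> int:
        return len(self.records)

    def by_residue(self) -> dict[int, ShiftRecord]:
        return {rec.residue_index: rec for rec in self.records}

    @property
    def residue_indices(self) -> list[int]:
        return [rec.residue_index for rec in self.records]

    def with_offset(self, offset: NumberingOffset) -> "ShiftTable":
        """Return a copy with the offset applied to every residue index."""
        if offset.offset == 0:
            return ShiftTable(self.label, list(self.records))
        return ShiftTable(
            self.label,
            [
                ShiftRecord(
                    offset.apply(r.residue_index), r.residue_type,
                    r.shift_H, r.shift_N,
                )
                for r in self.records
            ],
        )


@dataclass
class TitrationPoint:
    """One titration point: concentrations plus the measured shift table.

    ``ligand_conc`` may be given explicitly or derived as
    ``molar_ratio * protein_conc``; if both are given they must agree to a
    relative tolerance of 1e-6. Concentrations are in mM.
    """

    table: ShiftTable
    protein_conc: float
    molar_ratio: Optional[float] = None
    ligand_conc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")
        if self.molar_ratio is None and self.ligand_conc is None:
            raise ValueError("need molar_ratio or ligand_conc")
        if self.molar_ratio is not None and self.molar_ratio < 0:
            raise ValueError("molar_ratio must be >= 0")
        if self.ligand_conc is None:
            self.ligand_conc = self.molar_ratio * self.protein_conc
        elif self.ligand_conc < 0:
            raise ValueError("ligand_conc must be >= 0")
        if self.molar_ratio is None:
            self.molar_ratio = self.ligand_conc / self.protein_conc
        expected = self.molar_ratio * self.protein_conc
        if not math.isclose(self.ligand_conc, expected, rel_tol=1e-6, abs_tol=1e-12):
            raise ValueError(
                f"ligand_conc {self.ligand_conc} inconsistent with "
                f"molar_ratio x protein_conc = {expected}"
            )

    @property
    def is_apo(self) -> bool:
        return self.ligand_conc == 0


@dataclass
class TitrationSeries:
    """Ordered titration of one protein with one peptide ligand.

    Points are sorted by ligand concentration (stable sort, so constructing
    from already-sorted points is the identity); the first point must be the
    apo reference and at least three points are required for K_D fitting.
    """

    protein_name: str
    ligand_sequence: str
    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.ligand_conc)
        if len(self.points) < 3:
            raise ValueError(
                f"at least 3 titration points required, got {len(self.points)}"
            )
        if not self.points[0].is_apo:
            raise ValueError("apo reference required (no point with ligand_conc = 0)")
        if not self.common_residues():
            raise ValueError("titration tables share no residue index")
        self._warn_type_mismatches()

    def _warn_type_mismatches(self) -> None:
        ref = self.points[0].table.by_residue()
        for pt in self.points[1:]:
            for rec in pt.table.records:
                other = ref.get(rec.residue_index)
                if other is not None and other.residue_type != rec.residue_type:
                    warnings.warn(
                        f"residue {rec.residue_index} typed "
                        f"{other.residue_type!r} in {self.points[0].table.label!r} "
                        f"but {rec.residue_type!r} in {pt.table.label!r}",
                        stacklevel=3,
                    )

    @property
    def apo(self) -> TitrationPoint:
        return self.points[0]

    def common_residues(self) -> set[int]:
        """Residue indices present in every table of the series."""
        common = set(self.points[0].table.residue_indices)
        for pt in self.points[1:]:
            common &= set(pt.table.residue_indices)
        return common

    def ligand_concs(self) -> list[float]:
        return [p.ligand_conc for p in self.points]


# ---------------------------------------------------------------------------
# CSV I/O

def _parse_float(text: str, row_num: int, path: Path) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric shift {text!r} on row {row_num}"
        ) from None


def _parse_int(text: str, row_num: int, path: Path) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"{path}: non-integer residue index {text!r} on row {row_num}"
        ) from None


def read_shift_table(
    path: str | Path,
    format: str = "wide-csv",
    offset: NumberingOffset = NumberingOffset(0),
    label: Optional[str] = None,
) -> ShiftTable:
    """Read a shift table in either CSV dialect, applying a numbering offset.

    Raises ``ValueError`` naming the offending residue index on duplicates
    and the row number on non-numeric shifts; missing shifts stay ``None``.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if label is None:
        label = path.stem
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        rows = [(i, row) for i, row in enumerate(reader, start=2) if row]

    records: list[ShiftRecord] = []
    if format == "wide-csv":
        _expect_header(header, ["residue_index", "residue_type", "shift_H_ppm", "shift_N_ppm"], path)
        seen: set[int] = set()
        for row_num, row in rows:
            if len(row) != 4:
                raise ValueError(f"{path}: expected 4 fields on row {row_num}")
            idx = _parse_int(row[0], row_num, path)
            if idx in seen:
                raise ValueError(f"{path}: duplicate residue index {idx}")
            seen.add(idx)
            records.append(
                ShiftRecord(
                    offset.apply(idx),
                    row[1].strip(),
                    _parse_float(row[2], row_num, path),
                    _parse_float(row[3], row_num, path),
                )
            )
    else:  # long-csv
        _expect_header(header, ["residue_index", "residue_type", "atom", "shift_ppm"], path)
        acc: dict[int, dict] = {}
        order: list[int] = []
        for row_num, row in rows:
            if len(row) != 4:
                raise ValueError(f"{path}: expected 4 fields on row {row_num}")
            idx = _parse_int(row[0], row_num, path)
            rtype = row[1].strip()
            atom = row[2].strip().upper()
            if atom not in ("H", "N"):
                raise ValueError(f"{path}: atom must be H or N on row {row_num}")
            value = _parse_float(row[3], row_num, path)
            if idx not in acc:
                acc[idx] = {"type": rtype, "H": None, "N": None, "seen": set()}
                order.append(idx)
            entry = acc[idx]
            if entry["type"] != rtype:
                raise ValueError(
                    f"{path}: residue {idx} typed both {entry['type']!r} and "
                    f"{rtype!r} (row {row_num})"
                )
            if atom in entry["seen"]:
                raise ValueError(
                    f"{path}: duplicate residue index {idx} (atom {atom}, row {row_num})"
                )
            entry["seen"].add(atom)
            entry[atom] = value
        for idx in order:
            entry = acc[idx]
            records.append(
                ShiftRecord(offset.apply(idx), entry["type"], entry["H"], entry["N"])
            )
    return ShiftTable(label, records)


def _expect_header(header: Sequence[str], expected: Sequence[str], path: Path) -> None:
    if [h.strip() for h in header] != list(expected):
        raise ValueError(
            f"{path}: bad header {header!r}; expected {','.join(expected)}"
        )


def _fmt(v: Optional[float]) -> str:
    # repr round-trips exactly; ppm precision >= 4 decimals guaranteed
    return "" if v is None else repr(float(v))


def write_shift_table(table: ShiftTable, path: str | Path, format: str = "wide-csv") -> None:
    """Write a shift table; ``read_shift_table`` inverts this exactly."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if format == "wide-csv":
            writer.writerow(["residue_index", "residue_type", "shift_H_ppm", "shift_N_ppm"])
            for rec in table.records:
                writer.writerow(
                    [rec.residue_index, rec.residue_type, _fmt(rec.shift_H), _fmt(rec.shift_N)]
                )
        else:
            writer.writerow(["residue_index", "residue_type", "atom", "shift_ppm"])
            for rec in table.records:
                writer.writerow([rec.residue_index, rec.residue_type, "H", _fmt(rec.shift_H)])
                writer.writerow([rec.residue_index, rec.residue_type, "N", _fmt(rec.shift_N)])


# ---------------------------------------------------------------------------
# Series manifest

def read_series_manifest(path: str | Path) -> TitrationSeries:
    """Load a titration series from a YAML manifest.

    The manifest declares ``protein_name``, ``ligand_sequence``,
    ``protein_conc_mM`` and a list of points, each with ``molar_ratio`` or
    ``ligand_conc_mM`` plus a ``table`` path (relative to the manifest);
    optional keys: ``numbering_offset``, ``table_format``, per-point
    ``protein_conc_mM`` override.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    for key in ("protein_name", "ligand_sequence", "protein_conc_mM", "points"):
        if key not in doc:
            raise ValueError(f"{path}: manifest missing required key {key!r}")
    offset = NumberingOffset(int(doc.get("numbering_offset", 0)))
    fmt = doc.get("table_format", "wide-csv")
    protein_conc = float(doc["protein_conc_mM"])
    points = []
    for entry in doc["points"]:
        table_path = Path(entry["table"])
        if not table_path.is_absolute():
            table_path = path.parent / table_path
        if not table_path.exists():
            raise FileNotFoundError(f"{path}: table file not found: {table_path}")
        table = read_shift_table(table_path, format=fmt, offset=offset)
        points.append(
            TitrationPoint(
                table=table,
                protein_conc=float(entry.get("protein_conc_mM", protein_conc)),
                molar_ratio=(
                    float(entry["molar_ratio"]) if "molar_ratio" in entry else None
                ),
                ligand_conc=(
                    float(entry["ligand_conc_mM"]) if "ligand_conc_mM" in entry else None
                ),
            )
        )
    if len(points) < 3:
        raise ValueError(f"{path}: at least 3 titration points required")
    if not any(p.is_apo for p in points):
        raise ValueError(f"{path}: apo reference required (no 1:0 point)")
    return TitrationSeries(
        protein_name=str(doc["protein_name"]),
        ligand_sequence=str(doc["ligand_sequence"]),
        points=points,
    )


def write_series_manifest(
    series: TitrationSeries,
    directory: str | Path,
    table_format: str = "wide-csv",
    manifest_name: str = "manifest.yaml",
) -> Path:
    """Write a series as a manifest plus one table CSV per point."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pt in enumerate(series.points):
        fname = f"point_{i:02d}_{pt.table.label}.csv"
        write_shift_table(pt.table, directory / fname, format=table_format)
        entries.append(
            {
                "molar_ratio": float(pt.molar_ratio),
                "protein_conc_mM": float(pt.protein_conc),
                "table": fname,
            }
        )
    manifest = {
        "protein_name": series.protein_name,
        "ligand_sequence": series.ligand_sequence,
        "protein_conc_mM": float(series.apo.protein_conc),
        "table_format": table_format,
        "points": entries,
    }
    out = directory / manifest_name
    with open(out, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
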