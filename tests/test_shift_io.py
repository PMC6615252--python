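"""Shift-table CSV dialects, manifests, and numbering offsets."""

import math

import pytest
import yaml
from hypothesis import given, strategies as st

from cspfit import (
    NumberingOffset,
    ShiftRecord,
    ShiftTable,
    TitrationPoint,
    TitrationSeries,
    read_series_manifest,
    read_shift_table,
    write_series_manifest,
    write_shift_table,
)

ppm = st.floats(min_value=-50, max_value=200, allow_nan=False, allow_infinity=False)


@st.composite
def shift_tables(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    indices = draw(
        st.lists(st.integers(1, 500), min_size=n, max_size=n, unique=True)
    )
    records = []
    for idx in indices:
        rtype = draw(st.sampled_from("ACDEFGHIKLMNPQRSTVWYX"))
        if rtype == "P":
            records.append(ShiftRecord(idx, rtype, None, None))
        else:
            records.append(
                ShiftRecord(
                    idx,
                    rtype,
                    draw(st.one_of(st.none(), ppm)),
                    draw(st.one_of(st.none(), ppm)),
                )
            )
    return ShiftTable("t", records)


class TestShiftRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ShiftRecord(0, "A", 8.0, 115.0)
        with pytest.raises(ValueError):
            ShiftRecord(1, "B", 8.0, 115.0)
        with pytest.raises(ValueError):
            ShiftRecord(1, "P", 8.0, None)  # proline has no backbone amide
        with pytest.raises(ValueError):
            ShiftRecord(1, "A", float("nan"), 115.0)

    def test_duplicate_index_names_residue(self):
        with pytest.raises(ValueError, match="12"):
            ShiftTable("t", [ShiftRecord(12, "A", 8, 115), ShiftRecord(12, "G", 8, 110)])


class TestCSVDialects:
    def test_long_csv_pairs_rows_into_one_record(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "residue_index,residue_type,atom,shift_ppm\n"
            "19,L,H,8.21\n19,L,N,121.4\n"
        )
        table = read_shift_table(p, "long-csv")
        assert len(table) == 1
        rec = table.records[0]
        assert (rec.residue_index, rec.residue_type) == (19, "L")
        assert rec.shift_H == 8.21 and rec.shift_N == 121.4

    def test_offset_applied_on_import(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "residue_index,residue_type,atom,shift_ppm\n19,L,H,8.21\n19,L,N,121.4\n"
        )
        table = read_shift_table(p, "long-csv", offset=NumberingOffset(1))
        assert table.records[0].residue_index == 20

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "residue_index,residue_type,shift_H_ppm,shift_N_ppm\n"
            "12,A,8.0,115.0\n12,A,8.1,116.0\n"
        )
        with pytest.raises(ValueError, match="duplicate residue index 12"):
            read_shift_table(p, "wide-csv")

    def test_non_numeric_shift_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "residue_index,residue_type,shift_H_ppm,shift_N_ppm\n"
            "1,A,8.0,115.0\n2,G,oops,110.0\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_shift_table(p, "wide-csv")

    def test_missing_fields_stay_missing(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "residue_index,residue_type,shift_H_ppm,shift_N_ppm\n5,P,,\n6,G,7.5,\n"
        )
        table = read_shift_table(p, "wide-csv")
        assert table.records[0].shift_H is None and table.records[0].shift_N is None
        assert table.records[1].shift_H == 7.5 and table.records[1].shift_N is None

    @pytest.mark.parametrize("fmt", ["wide-csv", "long-csv"])
    @given(table=shift_tables())
    def test_round_trip_identity(self, fmt, table, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        path = tmp / "t.csv"
        write_shift_table(table, path, fmt)
        assert read_shift_table(path, fmt, label="t") == table

    @given(table=shift_tables())
    def test_dialect_conversion_preserves_values(self, table, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("conv")
        write_shift_table(table, tmp / "w.csv", "wide-csv")
        write_shift_table(table, tmp / "l.csv", "long-csv")
        wide = read_shift_table(tmp / "w.csv", "wide-csv", label="t")
        long_ = read_shift_table(tmp / "l.csv", "long-csv", label="t")
        assert wide == long_


class TestOffset:
    @given(st.integers(-100, 100), st.integers(1, 1000))
    def test_offset_invertible(self, off, idx):
        o = NumberingOffset(off)
        assert o.invert().apply(o.apply(idx)) == idx

    def test_offset_changes_only_indices(self):
        t = ShiftTable("t", [ShiftRecord(5, "A", 8.0, 115.0)])
        shifted = t.with_offset(NumberingOffset(3))
        assert shifted.records[0].residue_index == 8
        assert shifted.records[0].shift_H == 8.0
        assert shifted.with_offset(NumberingOffset(-3)) == t


def _write_point(tmp_path, name, indices=(1, 2, 3)):
    p = tmp_path / name
    rows = [f"{i},A,{8.0 + 0.01 * i},{115.0 + 0.1 * i}" for i in indices]
    p.write_text(
        "residue_index,residue_type,shift_H_ppm,shift_N_ppm\n" + "\n".join(rows) + "\n"
    )
    return name


def _manifest(tmp_path, ratios, protein_conc=0.25):
    points = [
        {"molar_ratio": r, "table": _write_point(tmp_path, f"p{k}.csv")}
        for k, r in enumerate(ratios)
    ]
    doc = {
        "protein_name": "PDZ2",
        "ligand_sequence": "KRHSGSYLVTSV",
        "protein_conc_mM": protein_conc,
        "points": points,
    }
    mp = tmp_path / "manifest.yaml"
    mp.write_text(yaml.safe_dump(doc))
    return mp


class TestManifest:
    def test_standard_schedule_ligand_concs(self, tmp_path):
        series = read_series_manifest(_manifest(tmp_path, [0, 1, 3, 5, 10, 20, 30]))
        assert len(series.points) == 7
        assert series.ligand_concs() == pytest.approx(
            [0, 0.25, 0.75, 1.25, 2.5, 5.0, 7.5]
        )

    def test_out_of_order_ratios_sorted(self, tmp_path):
        series = read_series_manifest(_manifest(tmp_path, [5, 0, 30, 1]))
        assert series.ligand_concs() == sorted(series.ligand_concs())
        assert series.points[0].is_apo

    def test_missing_apo_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="apo reference required"):
            read_series_manifest(_manifest(tmp_path, [1, 3, 5]))

    def test_too_few_points_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="3 titration points"):
            read_series_manifest(_manifest(tmp_path, [0, 1]))

    def test_unreadable_table_rejected(self, tmp_path):
        mp = _manifest(tmp_path, [0, 1, 3])
        (tmp_path / "p1.csv").unlink()
        with pytest.raises(FileNotFoundError):
            read_series_manifest(mp)

    def test_write_read_round_trip(self, tmp_path):
        series = read_series_manifest(_manifest(tmp_path, [0, 1, 3, 5]))
        out = tmp_path / "ds"
        mp = write_series_manifest(series, out)
        again = read_series_manifest(mp)
        assert again.ligand_concs() == series.ligand_concs()
        assert [p.table.records for p in again.points] == [
            p.table.records for p in series.points
        ]


class TestSeriesInvariants:
    def test_sorting_is_idempotent(self, tmp_path):
        series = read_series_manifest(_manifest(tmp_path, [0, 1, 3, 5]))
        resorted = TitrationSeries(
            series.protein_name, series.ligand_sequence, list(series.points)
        )
        assert resorted.ligand_concs() == series.ligand_concs()

    def test_ligand_conc_consistency_tolerance(self):
        t = ShiftTable("t", [ShiftRecord(1, "A", 8.0, 115.0)])
        TitrationPoint(table=t, protein_conc=0.25, molar_ratio=10, ligand_conc=2.5)
        with pytest.raises(ValueError, match="inconsistent"):
            TitrationPoint(table=t, protein_conc=0.25, molar_ratio=10, ligand_conc=2.6)

    def test_type_mismatch_warns_not_raises(self):
        a = ShiftTable("apo", [ShiftRecord(1, "A", 8.0, 115.0)])
        b = ShiftTable("b", [ShiftRecord(1, "G", 8.1, 115.5)])
        c = ShiftTable("c", [ShiftRecord(1, "A", 8.2, 116.0)])
        pts = [
            TitrationPoint(table=a, protein_conc=0.25, molar_ratio=0),
            TitrationPoint(table=b, protein_conc=0.25, molar_ratio=1),
            TitrationPoint(table=c, protein_conc=0.25, molar_ratio=3),
        ]
        with pytest.warns(UserWarning, match="typed"):
            TitrationSeries("p", "AAA", pts)
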