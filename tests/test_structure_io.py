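import numpy as np
import pytest

from alphastrand import (
    BackboneSpec,
    ExperimentMethod,
    build_backbone,
    ideal_alpha_strand,
    read_report,
    read_structures,
    write_report,
    write_structure_pdb,
)
from alphastrand.strand_scan import HitList, StrandHit
from alphastrand.structure_io import (
    DihedralTableError,
    StructureParseError,
    method_from_header,
    read_dihedral_table,
)
from alphastrand.trajectory_analysis import WindowSummary


MULTI_MODEL_PDB = """\
EXPDTA    SOLUTION NMR
MODEL        1
ATOM      1  N   VAL A  24       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  VAL A  24       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   VAL A  24       2.009   1.421   0.000  1.00  0.00           C
ATOM      4  N   GLY A  25       1.251   2.462   0.330  1.00  0.00           N
ATOM      5  CA  GLY A  25       1.703   3.835   0.521  1.00  0.00           C
ATOM      6  C   GLY A  25       2.425   4.343   1.767  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   VAL A  24       0.000   0.000   0.500  1.00  0.00           N
ATOM      2  CA  VAL A  24       1.458   0.000   0.500  1.00  0.00           C
ATOM      3  C   VAL A  24       2.009   1.421   0.500  1.00  0.00           C
ATOM      4  N   GLY A  25       1.251   2.462   0.830  1.00  0.00           N
ATOM      5  CA  GLY A  25       1.703   3.835   1.021  1.00  0.00           C
ATOM      6  C   GLY A  25       2.425   4.343   2.267  1.00  0.00           C
ENDMDL
END
"""

NUCLEIC_PDB = """\
ATOM      1  P    DA A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  O5'  DA A   1       1.500   0.000   0.000  1.00  0.00           O
ATOM      3  P    DT A   2       4.000   0.000   0.000  1.00  0.00           P
END
"""

ALTLOC_PDB = """\
EXPDTA    X-RAY DIFFRACTION
ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N
ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60  0.00           N
ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      4  C   ALA A   1       2.009   1.421   0.000  1.00  0.00           C
END
"""


class TestReadStructures:
    def test_multi_model_file_gives_one_model_each(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(MULTI_MODEL_PDB)
        models = read_structures(p)
        assert len(models) == 2
        assert [m.model_index for m in models] == [1, 2]
        for m in models:
            assert m.method is ExperimentMethod.NMR
            assert [r.res_seq for r in m.chains["A"]] == [24, 25]
            assert [r.one_letter for r in m.chains["A"]] == ["V", "G"]

    def test_nucleic_only_file_flagged_non_protein(self, tmp_path):
        p = tmp_path / "dna.pdb"
        p.write_text(NUCLEIC_PDB)
        assert read_structures(p) == []

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        (model,) = read_structures(p)
        res = model.chains["A"][0]
        assert res.coords_N[0] == pytest.approx(9.0)  # occupancy 0.60 wins
        assert model.method is ExperimentMethod.XRAY

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structures(tmp_path / "absent.pdb")

    def test_sequence_gap_recorded_as_break(self, tmp_path):
        # residues 24 and 26: author-number jump marks a break
        text = MULTI_MODEL_PDB.replace("GLY A  25", "GLY A  26")
        p = tmp_path / "gap.pdb"
        p.write_text(text)
        models = read_structures(p)
        assert models[0].breaks("A") == frozenset({0})


class TestWriteReadRoundTrip:
    def test_backbone_roundtrip_coordinates_and_identities(self, tmp_path):
        model = ideal_alpha_strand("VGSNK", first_res_seq=24)
        path = tmp_path / "strand.pdb"
        write_structure_pdb(model, path)
        (back,) = read_structures(path)
        ours, theirs = model.chains["A"], back.chains["A"]
        assert [r.name3 for r in ours] == [r.name3 for r in theirs]
        assert [r.res_seq for r in ours] == [r.res_seq for r in theirs]
        for a, b in zip(ours, theirs):
            for attr in ("coords_N", "coords_CA", "coords_C", "coords_O"):
                assert np.max(np.abs(getattr(a, attr) - getattr(b, attr))) < 1e-3

    def test_multi_model_roundtrip(self, tmp_path):
        m1 = build_backbone(BackboneSpec("AAAA", [(-60, -45, 180)] * 4))
        m2 = build_backbone(BackboneSpec("AAAA", [(60, 45, 180)] * 4))
        m2.model_index = 2
        path = tmp_path / "pair.pdb"
        write_structure_pdb([m1, m2], path)
        back = read_structures(path)
        assert [m.model_index for m in back] == [1, 2]


class TestDihedralTable:
    def test_frames_inferred_from_label_recurrence(self, tmp_path):
        lines = ["# comment", "@ legend"]
        for f in range(4):
            for label in ("VAL-24", "GLY-25", "SER-26"):
                lines.append(f"{-60 + f} {-45 + f} {label}")
        p = tmp_path / "rama.xvg"
        p.write_text("\n".join(lines) + "\n")
        rows = read_dihedral_table(p, stride_ps=2.0)
        assert len(rows) == 12
        assert sorted({r.frame_index for r in rows}) == [0, 1, 2, 3]
        assert rows[3].frame_index == 1 and rows[3].time_ps == 2.0

    def test_angle_wrapped_into_range(self, tmp_path):
        p = tmp_path / "t.xvg"
        p.write_text("-181.0 10.0 VAL-24\n")
        (row,) = read_dihedral_table(p)
        assert row.phi_deg == pytest.approx(179.0)

    def test_comments_only_gives_empty_table(self, tmp_path):
        p = tmp_path / "t.xvg"
        p.write_text("@ title\n@ legend\n# note\n")
        assert read_dihedral_table(p) == []

    def test_non_numeric_angle_names_row(self, tmp_path):
        p = tmp_path / "t.xvg"
        p.write_text("-60 -45 VAL-24\nbogus -45 GLY-25\n")
        with pytest.raises(DihedralTableError, match="row 2"):
            read_dihedral_table(p)

    def test_out_of_range_angle_rejected(self, tmp_path):
        p = tmp_path / "t.xvg"
        p.write_text("-400.0 10.0 VAL-24\n")
        with pytest.raises(DihedralTableError):
            read_dihedral_table(p)

    def test_explicit_frame_column(self, tmp_path):
        p = tmp_path / "t.xvg"
        p.write_text("0 -60 -45 VAL-24\n7 -60 -45 VAL-24\n")
        rows = read_dihedral_table(p, stride_ps=2.0)
        assert [r.frame_index for r in rows] == [0, 7]
        assert rows[1].time_ps == 14.0


class TestReportRoundTrip:
    def _hits(self):
        return HitList(
            [
                StrandHit("1IYT", 5, "A", 24, 3, "RLR", "VGS"),
                StrandHit("1Z0Q", 15, "A", 24, 5, "RLRLR", "VGSNK"),
            ]
        )

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_strandhit_list_roundtrip(self, tmp_path, fmt):
        hits = self._hits()
        path = tmp_path / f"hits.{fmt}"
        write_report(hits, path, fmt)
        assert read_report(HitList, path, fmt) == hits

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_window_summary_roundtrip(self, tmp_path, fmt):
        ws = WindowSummary(
            window=(24, 25, 26),
            pattern_string="RLR",
            match_mask=np.array([False, True, True, False]),
            frame_count=2,
            event_count=1,
            first_appearance_ps=2.0,
            occupancy_fraction=0.5,
        )
        path = tmp_path / f"ws.{fmt}"
        write_report(ws, path, fmt)
        assert read_report(WindowSummary, path, fmt) == ws

    def test_tsv_has_header_and_data_rows(self, tmp_path):
        path = tmp_path / "hits.tsv"
        write_report(self._hits(), path, "tsv")
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("entry_id\t")
        assert len(lines) == 3


def test_method_from_header_mapping():
    assert method_from_header("X-RAY DIFFRACTION") is ExperimentMethod.XRAY
    assert method_from_header("SOLUTION NMR") is ExperimentMethod.NMR
    assert method_from_header("ELECTRON MICROSCOPY") is ExperimentMethod.OTHER
    assert method_from_header(None) is ExperimentMethod.UNKNOWN
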