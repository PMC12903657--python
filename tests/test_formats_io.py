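"""Parsers, writers and the validation layer for every input dialect."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from popgenviz import formats_io as fio
from popgenviz import synthgen as sg


# ---------------------------------------------------------------------------
# genome index
# ---------------------------------------------------------------------------


class TestGenomeIndex:
    def test_parses_two_columns_in_file_order(self, tmp_path):
        p = tmp_path / "g.idx"
        p.write_text("1 1000\n2 500\n")
        idx = fio.read_genome_index(p)
        assert idx.entries == [("1", 1000), ("2", 500)]

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "g.idx"
        p.write_text("# assembly v2\n\n1 1000\n")
        assert fio.read_genome_index(p).entries == [("1", 1000)]

    @pytest.mark.parametrize("content,match", [
        ("1 0\n", "non-positive length"),
        ("1 -5\n", "non-positive length"),
        ("1 xx\n", "non-integer"),
        ("1 100\n1 200\n", "duplicate chromosome"),
        ("1 100 3\n", "expected 2 columns"),
    ])
    def test_malformed_rows_name_the_row(self, tmp_path, content, match):
        p = tmp_path / "g.idx"
        p.write_text(content)
        with pytest.raises(fio.FormatError, match=match):
            fio.read_genome_index(p)

    def test_31_row_autosome_index_round_trips(self, tmp_path):
        # scale of a horse autosome index
        entries = [(str(i + 1), 1_000_000 * (i + 3)) for i in range(31)]
        idx = fio.GenomeIndex(entries)
        path = fio.write_genome_index(idx, tmp_path / "horse.idx")
        back = fio.read_genome_index(path)
        assert back.entries == entries


# ---------------------------------------------------------------------------
# PLINK .map
# ---------------------------------------------------------------------------


class TestPlinkMap:
    def test_basic_records(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1 rs1 0 5\n1 rs2 0 12\n")
        m = fio.read_plink_map(p)
        assert len(m) == 2
        assert m.records[0] == fio.MapRecord("1", "rs1", 0.0, 5)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("")
        with pytest.raises(fio.FormatError, match="no marker records"):
            fio.read_plink_map(p)

    @pytest.mark.parametrize("content,match", [
        ("1 rs1 0\n", "expected 4 columns"),
        ("1 rs1 0 abc\n", "non-integer bp"),
        ("1 rs1 0 0\n", "bp position must be >= 1"),
    ])
    def test_malformed_rows(self, tmp_path, content, match):
        p = tmp_path / "m.map"
        p.write_text(content)
        with pytest.raises(fio.FormatError, match=match):
            fio.read_plink_map(p)

    def test_generated_thousand_marker_file_round_trips(self, tmp_path):
        cfg = sg.SynthConfig(seed=7, n_markers=1000)
        res = sg.gen_map_and_index(cfg, tmp_path)
        m = fio.read_plink_map(res.map_path)
        assert len(m) == 1000
        # order preserved on rewrite
        p2 = fio.write_plink_map(m, tmp_path / "copy.map")
        assert fio.read_plink_map(p2).records == m.records


# ---------------------------------------------------------------------------
# interval table
# ---------------------------------------------------------------------------


class TestIntervalTable:
    def test_single_record(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("POP1 A 1 100 200\n")
        t = fio.read_interval_table(p)
        assert t.records == [fio.IntervalRecord("POP1", "A", "1", 100, 200)]

    def test_header_auto_detected(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("pop id chr start end\nPOP1 A 1 100 200\n")
        assert len(fio.read_interval_table(p)) == 1

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("POP1 A 1 300 200\n")
        with pytest.raises(fio.FormatError, match="start 300 > end 200"):
            fio.read_interval_table(p)

    def test_missing_field_rejected(self, tmp_path):
        p = tmp_path / "iv.txt"
        p.write_text("POP1 A 1 100\n")
        with pytest.raises(fio.FormatError, match="expected 5 columns"):
            fio.read_interval_table(p)

    def test_round_trip_preserves_order(self, tmp_path):
        recs = [fio.IntervalRecord("P2", "B", "2", 50, 60),
                fio.IntervalRecord("P1", "A", "1", 10, 20),
                fio.IntervalRecord("P1", "A", "1", 5, 8)]
        t = fio.IntervalTable(recs)
        path = fio.write_interval_table(t, tmp_path / "iv.txt")
        assert fio.read_interval_table(path).records == recs


# ---------------------------------------------------------------------------
# relationship matrix
# ---------------------------------------------------------------------------


def _write_ids(tmp_path, ids, groups=None):
    groups = groups or ["G"] * len(ids)
    p = tmp_path / "ids.txt"
    p.write_text("".join(f"{g}\t{s}\n" for g, s in zip(groups, ids)))
    return p


class TestRelationshipMat:
    def test_square_grid(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"])
        p = tmp_path / "r.mat"
        p.write_text("1 0.2\n0.2 1\n")
        m = fio.read_relationship(p, "mat", ids)
        assert m.sample_ids == ["A", "B"]
        np.testing.assert_allclose(m.values, [[1, 0.2], [0.2, 1]])

    def test_non_square_grid_is_dimensional_error(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"])
        p = tmp_path / "r.mat"
        p.write_text("1 0.2 0.3\n0.2 1 0.1\n")
        with pytest.raises(fio.FormatError, match="dimensional consistency"):
            fio.read_relationship(p, "mat", ids)

    def test_ids_count_mismatch(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B", "C"])
        p = tmp_path / "r.mat"
        p.write_text("1 0.2 0.3\n0.2 1 0.1\n")
        with pytest.raises(fio.FormatError, match="dimensional consistency"):
            fio.read_relationship(p, "mat", ids)

    def test_pop_file_overrides_group_labels(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"], groups=["F1", "F1"])
        pops = tmp_path / "pops.txt"
        pops.write_text("A\tNorth\nB\tSouth\n")
        p = tmp_path / "r.mat"
        p.write_text("1 0.2\n0.2 1\n")
        m = fio.read_relationship(p, "mat", ids, pop_path=pops)
        assert m.pop_labels == ["North", "South"]


class TestRelationshipCol:
    def test_lower_triangle_mirrors_to_grid(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"])
        p = tmp_path / "r.col"
        p.write_text("A A 1\nB B 1\nB A 0.2\n")
        m = fio.read_relationship(p, "col", ids)
        np.testing.assert_allclose(m.values, [[1, 0.2], [0.2, 1]])

    def test_unknown_sample_is_label_matching_error(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"])
        p = tmp_path / "r.col"
        p.write_text("A A 1\nB B 1\nZ A 0.2\n")
        with pytest.raises(fio.FormatError, match="sample-label matching"):
            fio.read_relationship(p, "col", ids)

    def test_missing_diagonal_rejected(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"])
        p = tmp_path / "r.col"
        p.write_text("A A 1\nB A 0.2\n")
        with pytest.raises(fio.FormatError, match="missing diagonal"):
            fio.read_relationship(p, "col", ids)

    def test_conflicting_duplicate_rejected(self, tmp_path):
        ids = _write_ids(tmp_path, ["A", "B"])
        p = tmp_path / "r.col"
        p.write_text("A A 1\nB B 1\nB A 0.2\nA B 0.3\n")
        with pytest.raises(fio.FormatError, match="conflicting values"):
            fio.read_relationship(p, "col", ids)

    @given(st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_assembly_matches_fill_then_mirror_oracle(self, tmp_path_factory, n, seed):
        """col-format assembly equals a brute-force fill-then-mirror oracle."""
        tmp_path = tmp_path_factory.mktemp("col")
        rs = np.random.default_rng(seed)
        full = rs.normal(size=(n, n))
        full = (full + full.T) / 2  # ground-truth symmetric matrix
        ids = [f"s{i}" for i in range(n)]
        # emit each unordered pair once, random orientation
        lines = []
        oracle = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1):
                a, b = (i, j) if rs.random() < 0.5 else (j, i)
                lines.append(f"{ids[a]} {ids[b]} {float(full[i, j])!r}\n")
                oracle[a, b] = full[i, j]
        # oracle: fill then mirror
        mirrored = np.where(np.isnan(oracle), oracle.T, oracle)
        ids_path = _write_ids(tmp_path, ids)
        p = tmp_path / "r.col"
        p.write_text("".join(lines))
        m = fio.read_relationship(p, "col", ids_path)
        np.testing.assert_allclose(m.values, mirrored)


# ---------------------------------------------------------------------------
# eigen pair
# ---------------------------------------------------------------------------


class TestEigen:
    def _write(self, tmp_path, evec, evals):
        e1 = tmp_path / "p.evec"
        e2 = tmp_path / "p.eval"
        e1.write_text(evec)
        e2.write_text(evals)
        return e1, e2

    def test_three_samples_three_pcs(self, tmp_path):
        e1, e2 = self._write(tmp_path, "P A 1 2 3\nP B 4 5 6\nQ C 7 8 9\n", "3\n2\n1\n")
        d = fio.read_eigen(e1, e2)
        assert d.k == 3 and d.components.shape == (3, 3)
        assert d.pop_labels == ["P", "P", "Q"]

    def test_too_few_eigenvalues(self, tmp_path):
        e1, e2 = self._write(tmp_path, "P A 1 2 3\n", "3\n2\n")
        with pytest.raises(fio.FormatError, match="eigenvalues for 3 PC"):
            fio.read_eigen(e1, e2)

    def test_ragged_rows_rejected(self, tmp_path):
        e1, e2 = self._write(tmp_path, "P A 1 2 3\nP B 4 5\n", "3\n2\n1\n")
        with pytest.raises(fio.FormatError, match="ragged"):
            fio.read_eigen(e1, e2)

    def test_negative_eigenvalue_rejected(self, tmp_path):
        e1, e2 = self._write(tmp_path, "P A 1\n", "-1\n")
        with pytest.raises(fio.FormatError, match="negative eigenvalue"):
            fio.read_eigen(e1, e2)

    def test_120_sample_10_pc_fixture_shapes(self, tmp_path):
        cfg = sg.SynthConfig(seed=11, n_individuals=120, n_populations=2)
        res = sg.gen_eigen(cfg, tmp_path, n_pcs=10)
        d = fio.read_eigen(res.evec_path, res.eval_path)
        assert d.components.shape == (120, 10)
        assert d.eigenvalues.shape == (10,)


# ---------------------------------------------------------------------------
# ancestry table
# ---------------------------------------------------------------------------


class TestAncestry:
    def test_k2_record(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("P1 A 0.7 0.3\n")
        t = fio.read_ancestry(p)
        assert t.k == 2 and t.records[0].proportions == (0.7, 0.3)

    def test_bad_row_sum_rejected(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("P1 B 0.7 0.7\n")
        with pytest.raises(fio.FormatError, match="do not sum to 1"):
            fio.read_ancestry(p)

    def test_ragged_k_rejected(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("P1 A 0.7 0.3\nP1 B 0.5 0.3 0.2\n")
        with pytest.raises(fio.FormatError, match="dimensional consistency"):
            fio.read_ancestry(p)

    def test_dirichlet_fixture_rows_all_pass_tolerance(self, tmp_path):
        cfg = sg.SynthConfig(seed=13, n_individuals=50, n_populations=5, k_components=4)
        res = sg.gen_ancestry(cfg, tmp_path)
        t = fio.read_ancestry(res.path)
        assert len(t) == 50
        for r in t.records:
            assert abs(sum(r.proportions) - 1.0) <= 0.01


# ---------------------------------------------------------------------------
# association table
# ---------------------------------------------------------------------------


class TestAssoc:
    def test_two_records(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("1 100 0.5\n2 50 7.2\n")
        t = fio.read_assoc_table(p)
        assert [r.chrom for r in t.records] == ["1", "2"]

    def test_nan_value_rejected(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("1 100 NaN\n")
        with pytest.raises(fio.FormatError, match="non-finite"):
            fio.read_assoc_table(p)

    def test_header_auto_detected(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("chrom bp value\n1 100 0.5\n")
        assert len(fio.read_assoc_table(p)) == 1

    def test_ten_thousand_row_fixture_round_trips(self, tmp_path):
        cfg = sg.SynthConfig(seed=17, n_assoc_records=10_000)
        res = sg.gen_assoc(cfg, tmp_path)
        t = fio.read_assoc_table(res.path)
        assert len(t) == 10_000
        assert t.records == res.table.records


# ---------------------------------------------------------------------------
# validation layer
# ---------------------------------------------------------------------------


class TestValidate:
    def test_consistent_matrix_is_ok(self):
        m = fio.RelationshipMatrix(["A", "B"], ["P", "P"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        rep = fio.validate(m)
        assert rep.ok and rep.issues == []

    def test_asymmetry_beyond_tolerance_is_flagged(self):
        v = np.array([[1.0, 0.2], [0.2, 1.0]])
        v[0, 1] += 1e-3
        rep = fio.validate(fio.RelationshipMatrix(["A", "B"], ["P", "P"], v))
        assert not rep.ok
        assert any(i.code == "symmetry" for i in rep.errors())

    def test_unknown_chromosome_in_interval_table(self):
        idx = fio.GenomeIndex([("1", 1000)])
        t = fio.IntervalTable([fio.IntervalRecord("P", "A", "99", 1, 10)])
        rep = fio.validate(t, genome_index=idx)
        assert not rep.ok
        assert any(i.code == "unknown-chromosome" for i in rep.errors())

    def test_nan_cells_reported_as_missing_values(self):
        v = np.array([[1.0, np.nan], [np.nan, 1.0]])
        rep = fio.validate(fio.RelationshipMatrix(["A", "B"], ["P", "P"], v))
        assert any(i.code == "missing-values" for i in rep.errors())

    def test_report_ok_iff_no_errors(self):
        rep = fio.ValidationReport()
        rep.add("warning", "w", "just a warning")
        assert rep.ok
        rep.add("error", "e", "an error")
        assert not rep.ok
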