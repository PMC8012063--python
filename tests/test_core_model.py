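"""Domain types, readers/writers and shared statistics."""

import numpy as np
import pandas as pd
import pytest

from xte.core_model import (
    CountMatrix,
    FormatError,
    GeneSetCollection,
    P_CLAMP,
    TissuePanel,
    bh_fdr,
    intersect_catalogs,
    merge_tissue_panels,
    qc_sample_correlation,
    read_de_table,
    read_gmt,
    write_de_table,
    write_gmt,
    zero_filter,
)


def _bh_stepup_oracle(p):
    """Independent hand-rolled BH step-up, for cross-checking."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestReadDeTable:
    def test_well_formed_table(self, de_table_file):
        panel, report = read_de_table(de_table_file, "liver")
        assert panel.genes == ["A", "B", "C"]
        assert panel.tissues == ["liver"]
        assert report.n_accepted == 3 and report.n_rejected == 0
        np.testing.assert_allclose(panel.p[:, 0], [0.01, 0.2, 0.7])

    def test_out_of_range_p_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tpvalue\tlog2fc\tbase_mean\nA\t1.5\t0.1\t2\nB\t0.2\t0.1\t2\n")
        panel, report = read_de_table(path, "t")
        assert report.n_rejected == 1
        assert report.rejected_genes == ["A"]
        assert panel.genes == ["B"]

    def test_zero_p_clamped(self, tmp_path):
        path = tmp_path / "zero.tsv"
        path.write_text("gene\tpvalue\tlog2fc\tbase_mean\nSULT\t0.00E+00\t2.0\t9\n")
        panel, report = read_de_table(path, "t")
        assert report.n_clamped == 1
        assert panel.p[0, 0] == P_CLAMP

    def test_missing_column_names_column(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tpvalue\tbase_mean\nA\t0.5\t2\n")
        with pytest.raises(FormatError, match="log2fc"):
            read_de_table(path, "t")

    def test_duplicate_genes_listed(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("gene\tpvalue\tlog2fc\tbase_mean\nA\t0.5\t0\t2\nA\t0.4\t0\t2\n")
        with pytest.raises(FormatError, match="A"):
            read_de_table(path, "t")

    def test_na_p_carried_as_missing(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("gene\tpvalue\tlog2fc\tbase_mean\nA\t\t0.1\t2\nB\t0.2\t0.1\t2\n")
        panel, report = read_de_table(path, "t")
        assert report.n_rejected == 0
        assert np.isnan(panel.p[0, 0])

    def test_write_read_round_trip(self, toy_panel, tmp_path):
        path = tmp_path / "rt.tsv"
        write_de_table(toy_panel, path, tissue="liver", provenance="check")
        back, _ = read_de_table(path, "liver")
        np.testing.assert_array_equal(back.p[:, 0], toy_panel.p[:, 0])
        np.testing.assert_array_equal(back.log2fc[:, 0], toy_panel.log2fc[:, 0])


class TestMergePanels:
    def test_union_with_missing_flagged(self, tmp_path):
        f1 = tmp_path / "a.tsv"
        f1.write_text("gene\tpvalue\tlog2fc\tbase_mean\nA\t0.1\t1\t2\nB\t0.2\t1\t2\n")
        f2 = tmp_path / "b.tsv"
        f2.write_text("gene\tpvalue\tlog2fc\tbase_mean\nB\t0.3\t1\t2\nC\t0.4\t1\t2\n")
        merged = merge_tissue_panels([read_de_table(f1, "t1")[0], read_de_table(f2, "t2")[0]])
        assert merged.genes == sorted({"A", "B", "C"})  # set-union oracle
        assert merged.tissues == ["t1", "t2"]
        assert np.isnan(merged.p[merged.genes.index("A"), 1])
        assert merged.p[merged.genes.index("B"), 0] == 0.2
        assert merged.p[merged.genes.index("B"), 1] == 0.3

    def test_duplicate_tissue_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="more than one panel"):
            merge_tissue_panels([toy_panel, toy_panel])


class TestPanelInvariants:
    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            TissuePanel(genes=["A"], tissues=["t"], p=[[1.5]], log2fc=[[0.0]],
                        mean_expr=[[1.0]])

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TissuePanel(genes=["A", "A"], tissues=["t"], p=[[0.5], [0.5]],
                        log2fc=[[0.0], [0.0]], mean_expr=[[1.0], [1.0]])


class TestGmt:
    def test_dedup_within_set(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        coll = read_gmt(path)
        assert coll["S1"] == frozenset({"A", "B"})

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "e.gmt"
        path.write_text("")
        coll = read_gmt(path)
        assert len(coll) == 0

    def test_short_line_reports_lineno(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\tA\nS2\tonlydesc\n")
        with pytest.raises(FormatError, match=":2"):
            read_gmt(path)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(sets={"S1": frozenset({"A", "B"}),
                                       "S2": frozenset({"C"})},
                                 descriptions={"S1": "first", "S2": "second"})
        path = tmp_path / "rt.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions


class TestIntersectCatalogs:
    @pytest.mark.parametrize("a, b, expected", [
        (["A", "B", "C"], ["B", "C", "D"], ["B", "C"]),
        (["A"], ["Z"], []),
        ([" A ", "B"], ["A", "C"], ["A"]),  # whitespace stripped
    ])
    def test_examples(self, a, b, expected):
        assert intersect_catalogs(a, b) == expected

    def test_matches_brute_force_and_is_commutative(self):
        rng = np.random.default_rng(42)
        a = [f"G{i}" for i in rng.integers(0, 150, 100)]
        b = [f"G{i}" for i in rng.integers(0, 150, 100)]
        expected = sorted(set(a) & set(b))
        assert intersect_catalogs(a, b) == expected
        assert intersect_catalogs(b, a) == expected          # commutative
        assert intersect_catalogs(expected, expected) == expected  # idempotent


class TestBhFdr:
    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]),
                                   [0.04, 0.04, 0.04, 0.5])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_independent_oracle_on_uniforms(self):
        p = np.random.default_rng(7).random(1000)
        np.testing.assert_allclose(bh_fdr(p), _bh_stepup_oracle(p), rtol=0, atol=1e-12)

    def test_dominates_input_and_capped(self):
        p = np.random.default_rng(3).random(200)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


def _count_matrix(counts, statuses=None):
    n = counts.shape[1]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample": samples,
        "species": ["mech"] * n,
        "sex": ["f"] * n,
        "status": statuses or ["breeder"] * n,
        "tissue": ["liver"] * n,
    })
    return CountMatrix(genes=[f"g{i}" for i in range(counts.shape[0])],
                       samples=samples, counts=counts, metadata=meta)


class TestQcAndZeroFilter:
    def test_duplicated_samples_pass(self):
        col = np.random.default_rng(0).integers(0, 500, 100)
        cm = _count_matrix(np.column_stack([col, col]))
        rep = qc_sample_correlation(cm)
        assert rep["pass"].all()
        np.testing.assert_allclose(rep["min_r"], 1.0)

    def test_shuffled_sample_fails(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 2000, 300)
        near = base + rng.integers(0, 5, 300)
        shuffled = rng.permutation(base)
        cm = _count_matrix(np.column_stack([base, near, shuffled]))
        rep = qc_sample_correlation(cm, threshold=0.90).set_index("sample")
        assert not rep.loc["s2", "pass"]
        assert rep.loc["s2", "min_r"] < 0.90

    def test_singleton_group_untestable(self):
        counts = np.random.default_rng(2).integers(0, 100, (50, 3))
        cm = _count_matrix(counts, statuses=["breeder", "breeder", "nonbreeder"])
        rep = qc_sample_correlation(cm).set_index("sample")
        assert not rep.loc["s2", "testable"]
        assert rep.loc["s2", "pass"]  # untestable is not a failure

    def test_zero_filter_removes_all_zero_rows(self):
        counts = np.random.default_rng(3).integers(1, 10, (10, 4))
        counts[[2, 7]] = 0
        filtered, n_removed = zero_filter(_count_matrix(counts))
        assert n_removed == 2
        assert len(filtered.genes) == 8

    def test_zero_filter_identity_and_oracle(self):
        rng = np.random.default_rng(4)
        counts = (rng.random((60, 5)) < 0.1) * rng.integers(1, 9, (60, 5))
        cm = _count_matrix(counts.astype(int))
        filtered, _ = zero_filter(cm)
        expected = [g for g, row in zip(cm.genes, counts) if row.sum() > 0]
        assert filtered.genes == expected
        dense, n = zero_filter(_count_matrix(np.ones((5, 3), dtype=int)))
        assert n == 0 and len(dense.genes) == 5
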