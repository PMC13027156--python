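"""Count pre-filters, PAR_Y collapsing, DEG classification and overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmtquant import (
    CountMatrix,
    classify_degs,
    collapse_par_y,
    overlap_degs,
    prefilter_counts,
)
from fmtquant.counts import read_count_matrix, write_count_matrix


def _matrix(ids, rows, lengths, groups=None):
    counts = pd.DataFrame(rows, index=pd.Index(ids), columns=[f"s{i}" for i in range(len(rows[0]))])
    return CountMatrix(
        counts=counts,
        transcript_lengths=pd.Series(lengths, index=counts.index, dtype=float),
        sample_groups=groups,
    )


class TestCollapseParY:
    def test_duplicate_rows_are_summed(self):
        m = _matrix(["G1", "G1_PAR_Y"], [[3, 0, 2], [4, 1, 0]], [100.0, 200.0])
        out = collapse_par_y(m)
        assert out.counts.index.tolist() == ["G1"]
        assert out.counts.loc["G1"].tolist() == [7, 1, 2]

    def test_merged_length_is_count_weighted_mean(self):
        m = _matrix(["G1", "G1_PAR_Y"], [[3, 0, 2], [4, 1, 0]], [100.0, 200.0])
        out = collapse_par_y(m)
        # weights 5/10 and 5/10 -> 150
        assert out.transcript_lengths["G1"] == pytest.approx(150.0)

    def test_orphan_suffix_is_renamed_unchanged(self):
        m = _matrix(["G2_PAR_Y", "G3"], [[5, 5], [1, 1]], [80.0, 90.0])
        out = collapse_par_y(m)
        assert out.counts.index.tolist() == ["G2", "G3"]
        assert out.counts.loc["G2"].tolist() == [5, 5]
        assert out.transcript_lengths["G2"] == 80.0

    def test_no_suffix_is_identity(self):
        m = _matrix(["A", "B"], [[1, 2], [3, 4]], [50.0, 60.0])
        out = collapse_par_y(m)
        assert out.counts.equals(m.counts)
        assert out.transcript_lengths.tolist() == [50.0, 60.0]


class TestPrefilter:
    def test_low_count_boundary_is_strict(self):
        # 3 samples -> threshold 6: total 5 dropped, total 6 retained
        m = collapse_par_y(_matrix(["lo", "edge", "hi"],
                                   [[2, 2, 1], [2, 2, 2], [10, 10, 10]],
                                   [500.0, 500.0, 500.0]))
        out, report = prefilter_counts(m, return_report=True)
        assert out.counts.index.tolist() == ["edge", "hi"]
        assert report.n_low_count == 1

    def test_length_boundary_is_inclusive(self):
        m = collapse_par_y(_matrix(["short", "edge", "ok"],
                                   [[10, 10], [10, 10], [10, 10]],
                                   [19.0, 20.0, 21.0]))
        out, report = prefilter_counts(m, return_report=True)
        assert out.counts.index.tolist() == ["ok"]
        assert report.n_short_transcript == 2

    def test_requires_collapse_first(self):
        m = _matrix(["A"], [[9, 9]], [100.0])
        with pytest.raises(ValueError, match="collapse_par_y"):
            prefilter_counts(m)

    def test_adding_a_sample_raises_count_threshold_by_two(self):
        ids, lengths = ["g"], [500.0]
        m3 = collapse_par_y(_matrix(ids, [[2, 2, 2]], lengths))
        m4 = collapse_par_y(_matrix(ids, [[2, 2, 2, 0]], lengths))
        assert prefilter_counts(m3).n_genes == 1  # total 6 >= 2*3
        assert prefilter_counts(m4).n_genes == 0  # total 6 < 2*4


class TestClassifyDegs:
    @pytest.mark.parametrize(
        "lfc,fdr,significant,direction",
        [
            (1.2, 0.005, True, "up"),
            (-1.5, 1e-4, True, "down"),
            (1.0, 1e-6, False, "up"),     # |lfc| must exceed 1 strictly
            (2.0, 0.01, False, "up"),     # fdr must be below 0.01 strictly
            (0.5, 0.001, False, "up"),
        ],
    )
    def test_strict_thresholds(self, lfc, fdr, significant, direction):
        table = pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc], "fdr": [fdr]})
        (rec,) = classify_degs(table)
        assert rec.significant is significant
        assert rec.direction == direction

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            classify_degs(pd.DataFrame({"gene_id": ["g"], "log2fc": [1.0]}))

    def test_fdr_out_of_range_rejected(self):
        table = pd.DataFrame({"gene_id": ["g"], "log2fc": [1.0], "fdr": [1.5]})
        with pytest.raises(ValueError, match="fdr"):
            classify_degs(table)


def _degs(up=(), down=(), insig=()):
    recs = []
    table = []
    for g in up:
        table.append((g, 2.0, 1e-4))
    for g in down:
        table.append((g, -2.0, 1e-4))
    for g in insig:
        table.append((g, 0.1, 0.9))
    frame = pd.DataFrame(table, columns=["gene_id", "log2fc", "fdr"])
    return classify_degs(frame)


class TestOverlap:
    def test_common_up_intersection(self):
        s = overlap_degs(_degs(up=["g1", "g2", "g3"]), _degs(up=["g2", "g3", "g4"]))
        assert s.common_up == {"g2", "g3"}
        assert s.sizes["common_up"] == 2

    def test_disjoint_sets_give_empty_overlap(self):
        s = overlap_degs(_degs(up=["a"], down=["b"]), _degs(up=["c"], down=["d"]))
        assert s.sizes["common_up"] == 0 and s.sizes["common_down"] == 0

    def test_identical_lists_are_idempotent(self):
        a = _degs(up=["u1", "u2"], down=["d1"])
        s = overlap_degs(a, a)
        assert s.common_up == {"u1", "u2"} and s.common_down == {"d1"}

    def test_opposite_directions_counted_in_neither(self):
        s = overlap_degs(_degs(up=["g"]), _degs(down=["g"]))
        assert s.common_up == set() == s.common_down
        assert s.discordant == {"g"}

    def test_duplicate_ids_rejected(self):
        a = _degs(up=["g"]) + _degs(up=["g"])
        with pytest.raises(ValueError, match="duplicate"):
            overlap_degs(a, _degs(up=["g"]))

    def test_intersection_sizes_are_symmetric(self):
        a = _degs(up=["g1", "g2"], down=["d1", "d2", "d3"])
        b = _degs(up=["g2", "g3"], down=["d2"])
        ab, ba = overlap_degs(a, b), overlap_degs(b, a)
        assert ab.sizes["common_up"] == ba.sizes["common_up"]
        assert ab.sizes["common_down"] == ba.sizes["common_down"]


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    totals=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=8),
    n_samples=st.integers(min_value=1, max_value=5),
)
def test_low_count_rule_matches_direct_comparison(totals, n_samples):
    """The retained set is exactly {genes with total >= 2 * n_samples}."""
    ids = [f"g{i}" for i in range(len(totals))]
    rows = []
    for t in totals:
        row = [t // n_samples] * n_samples
        row[0] += t - sum(row)
        rows.append(row)
    m = collapse_par_y(_matrix(ids, rows, [500.0] * len(ids)))
    out = prefilter_counts(m)
    expected = {g for g, t in zip(ids, totals) if t >= 2 * n_samples}
    assert set(out.counts.index) == expected


def test_count_matrix_tsv_round_trip(tmp_path):
    from fmtquant import CountSimTruth, generate_count_matrix

    m = generate_count_matrix(30, 3, CountSimTruth(), seed=9)
    write_count_matrix(m, tmp_path / "c.tsv", tmp_path / "l.tsv", tmp_path / "g.tsv")
    back = read_count_matrix(tmp_path / "c.tsv", tmp_path / "l.tsv", tmp_path / "g.tsv")
    assert back.counts.equals(m.counts)
    assert np.allclose(back.transcript_lengths, m.transcript_lengths)
    assert (back.sample_groups == m.sample_groups).all()


def test_planted_de_genes_recovered_and_nulls_controlled():
    """End-to-end with the delegated DE engine: planted effects are called,
    null genes enter the significant set at far below the 1% FDR cut."""
    from fmtquant import CountSimTruth, generate_count_matrix
    from fmtquant.counts import run_default_de_engine

    planted = {f"G{i:05d}": (2.0 if i % 2 else -2.0) for i in range(40)}
    truth = CountSimTruth(true_log2fc=planted, dispersion=0.05)
    matrix = generate_count_matrix(800, 8, truth, seed=1)
    matrix = prefilter_counts(collapse_par_y(matrix))
    results = run_default_de_engine(matrix)
    records = classify_degs(results)
    sig = {r.gene_id for r in records if r.significant}
    true_pos = sig & set(planted)
    false_pos = sig - set(planted)
    assert len(true_pos) >= 0.8 * len(planted)
    assert len(false_pos) <= max(3, 0.01 * (matrix.n_genes - len(planted)))
    # direction bookkeeping matches the planted signs
    by_id = {r.gene_id: r for r in records}
    for g, fc in planted.items():
        if g in sig:
            assert by_id[g].direction == ("up" if fc > 0 else "down")
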