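"""DAG construction: promoter assignment, filters, merging, complexes."""

import warnings

import pandas as pd
import pytest

from pcunits.graphs import (
    ProteinCodingUnitDAG,
    add_complex_edges,
    assign_peaks_to_transcripts,
    build_unit_dags,
    demo_unit,
    merge_shared_peak_units,
)

DEMO_PT = pd.DataFrame(
    [("a1", "s1"), ("a2", "s2"), ("a2", "s3")], columns=["peak_id", "transcript_id"]
)
DEMO_TP = pd.DataFrame(
    [("s1", "p"), ("s2", "p"), ("s3", "p")], columns=["transcript_id", "protein_id"]
)


def bed(tmp_path, lines):
    f = tmp_path / "peaks.bed"
    f.write_text("\n".join(lines) + "\n")
    return f


def gtf(tmp_path, lines):
    f = tmp_path / "tx.gtf"
    f.write_text("\n".join(lines) + "\n")
    return f


def gtf_line(chrom, start1, end1, strand, tid):
    return (
        f"{chrom}\tsrc\ttranscript\t{start1}\t{end1}\t.\t{strand}\t.\t"
        f'gene_id "g"; transcript_id "{tid}";'
    )


class TestPromoterAssignment:
    def test_peak_containing_tss_is_associated(self, tmp_path):
        peaks = bed(tmp_path, ["chr1\t1000\t1200\tpk1"])
        txs = gtf(tmp_path, [gtf_line("chr1", 1101, 5000, "+", "t1")])  # TSS 1100
        out = assign_peaks_to_transcripts(peaks, txs)
        assert list(out.itertuples(index=False)) == [("pk1", "t1")]

    def test_peak_beyond_promoter_window_is_not(self, tmp_path):
        peaks = bed(tmp_path, ["chr1\t10000\t10200\tpk1"])
        txs = gtf(tmp_path, [gtf_line("chr1", 1101, 5000, "+", "t1")])
        assert assign_peaks_to_transcripts(peaks, txs).empty

    def test_window_edge_overlap_counts(self, tmp_path):
        # TSS 1000, halfwidth 3000: window reaches 4000; peak [3900, 4200)
        peaks = bed(tmp_path, ["chr1\t3900\t4200\tpk1"])
        txs = gtf(tmp_path, [gtf_line("chr1", 1001, 9000, "+", "t1")])
        out = assign_peaks_to_transcripts(peaks, txs)
        assert len(out) == 1

    def test_minus_strand_tss_is_transcript_end(self, tmp_path):
        # minus strand: TSS at the (1-based) end coordinate
        peaks = bed(tmp_path, ["chr1\t9500\t9600\tpk1", "chr1\t100\t200\tpk2"])
        txs = gtf(tmp_path, [gtf_line("chr1", 2000, 9000, "-", "t1")])  # TSS 8999
        out = assign_peaks_to_transcripts(peaks, txs)
        assert set(out.peak_id) == {"pk1"}

    def test_malformed_lines_report_position(self, tmp_path):
        peaks = bed(tmp_path, ["chr1\t100\tnotanumber\tpk1"])
        txs = gtf(tmp_path, [gtf_line("chr1", 1, 10, "+", "t1")])
        with pytest.raises(ValueError, match=":1:"):
            assign_peaks_to_transcripts(peaks, txs)


class TestBuildUnits:
    def test_demo_association_rows_reproduce_demo_unit(self):
        (d,) = build_unit_dags(DEMO_PT, DEMO_TP)
        assert set(d.g.edges) == set(demo_unit("p").g.edges)

    def test_non_coding_transcripts_dropped(self):
        (d,) = build_unit_dags(DEMO_PT, DEMO_TP, coding_flags={"s2": False})
        assert "s2" not in d.g
        assert "a2" in d.g  # still feeds s3

    def test_series_index_filter_drops_splices_and_orphan_peaks(self):
        idx = {"a1", "s1", "p"}
        (d,) = build_unit_dags(DEMO_PT, DEMO_TP, series_index=idx)
        assert sorted(d.g.nodes) == ["a1", "p", "s1"]

    def test_unit_with_no_surviving_splice_is_omitted(self):
        with pytest.warns(UserWarning, match="no surviving splice"):
            out = build_unit_dags(
                DEMO_PT, DEMO_TP, coding_flags={t: False for t in ("s1", "s2", "s3")}
            )
        assert out == []

    def test_empty_tables_give_empty_list(self):
        assert build_unit_dags(DEMO_PT.iloc[:0], DEMO_TP.iloc[:0]) == []


def two_units(shared_peak=True):
    pt = pd.DataFrame(
        [("aX", "u1_s1"), ("aY" if not shared_peak else "aX", "u2_s1")],
        columns=["peak_id", "transcript_id"],
    )
    tp = pd.DataFrame(
        [("u1_s1", "P1"), ("u2_s1", "P2")], columns=["transcript_id", "protein_id"]
    )
    return build_unit_dags(pt, tp)


class TestSharedPeakMerge:
    def test_sharing_units_merge_into_one_joint_dag(self):
        out = merge_shared_peak_units(two_units(shared_peak=True))
        assert len(out) == 1
        joint = out[0]
        assert joint.provenance == "shared-peak-joint"
        assert set(joint.proteins) == {"P1", "P2"}
        assert joint.peaks == ["aX"]
        assert joint.children("aX") == {"u1_s1", "u2_s1"}

    def test_no_sharing_passes_through(self):
        dags = two_units(shared_peak=False)
        out = merge_shared_peak_units(dags)
        assert [d.dag_id for d in out] == [d.dag_id for d in dags]
        assert all(d.provenance == "single-unit" for d in out)

    def test_transitive_sharing_forms_one_component(self):
        pt = pd.DataFrame(
            [("a1", "t1"), ("a12", "t1"), ("a12", "t2"), ("a23", "t2"), ("a23", "t3")],
            columns=["peak_id", "transcript_id"],
        )
        tp = pd.DataFrame(
            [("t1", "P1"), ("t2", "P2"), ("t3", "P3")],
            columns=["transcript_id", "protein_id"],
        )
        out = merge_shared_peak_units(build_unit_dags(pt, tp))
        assert len(out) == 1
        assert set(out[0].proteins) == {"P1", "P2", "P3"}

    def test_merge_idempotent_and_order_independent(self):
        dags = two_units(shared_peak=True) + two_units(shared_peak=False)
        once = merge_shared_peak_units(dags)
        twice = merge_shared_peak_units(once)
        rev = merge_shared_peak_units(dags[::-1])
        ids = lambda ds: [(d.dag_id, sorted(d.g.nodes)) for d in ds]
        assert ids(once) == ids(twice) == ids(rev)


class TestComplexEdges:
    def test_pair_present_creates_joint_mixed_graph(self):
        dags = two_units(shared_peak=False)
        pairs = pd.DataFrame([("P1", "P2")], columns=["protein_1", "protein_2"])
        out = add_complex_edges(dags, pairs)
        assert len(out) == 1
        assert out[0].provenance == "complex-joint"
        assert frozenset(("P1", "P2")) in out[0].undirected_pp
        assert out[0].is_adjacent("P1", "P2")

    def test_empty_pair_table_is_identity(self):
        dags = two_units(shared_peak=False)
        out = add_complex_edges(dags, pd.DataFrame(columns=["protein_1", "protein_2"]))
        assert [d.dag_id for d in out] == [d.dag_id for d in dags]
        assert all(not d.undirected_pp for d in out)

    def test_unknown_protein_skipped_with_warning(self):
        dags = two_units(shared_peak=False)
        pairs = pd.DataFrame([("P1", "NOPE")], columns=["protein_1", "protein_2"])
        with pytest.warns(UserWarning, match="NOPE"):
            out = add_complex_edges(dags, pairs)
        assert all(not d.undirected_pp for d in out)

    def test_pair_inside_existing_joint_dag_gets_edge_there(self):
        joint = merge_shared_peak_units(two_units(shared_peak=True))
        pairs = pd.DataFrame([("P1", "P2")], columns=["protein_1", "protein_2"])
        out = add_complex_edges(joint, pairs)
        assert len(out) == 1
        assert frozenset(("P1", "P2")) in out[0].undirected_pp


class TestStructuralContracts:
    def test_illegal_edge_rejected(self):
        d = ProteinCodingUnitDAG("X")
        d.add_node("a", "a", "X")
        d.add_node("p", "p", "X")
        with pytest.raises(ValueError, match="a->s or s->p"):
            d.add_edge("a", "p")

    def test_validate_flags_peakless_splice(self):
        d = ProteinCodingUnitDAG("X")
        d.add_node("s", "s", "X")
        d.add_node("p", "p", "X")
        d.add_edge("s", "p")
        with pytest.raises(ValueError, match="no peak parent"):
            d.validate()

    def test_layer_partition_preserved_by_merge(self):
        for d in merge_shared_peak_units(two_units(shared_peak=True)):
            for s in d.splices:
                assert any(d.layer(q) == "a" for q in d.parents(s))
            assert set(d.nodes_in_layer("a")) | set(d.nodes_in_layer("s")) | set(
                d.nodes_in_layer("p")
            ) == set(d.g.nodes)
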