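"""Protein-to-genome projection, motif scanning, and the hit store."""

import numpy as np
import pytest

import exont
from exont.annotation import (
    AnnotationError,
    AnnotationStore,
    ProteinFeature,
    annotate_exons,
    coding_index_of,
    map_feature_to_genome,
    project_to_exons,
    read_feature_table,
    scan_localization_motifs,
    term_frequency,
)
from exont.genome_model import TranscriptModel
from exont.intervals import total_length


def _tr(strand, segments_1based):
    """Transcript from 1-based inclusive CDS segments in coding order."""
    segs = [(s - 1, e) for s, e in segments_1based]
    return TranscriptModel("t", "g", "chr1", strand, segs)


def _enumerate_oracle(tr):
    """Independent per-nucleotide walk: coding index -> genomic position."""
    walk = []
    for s, e in tr.cds_segments:
        positions = range(s, e) if tr.strand == "+" else range(e - 1, s - 1, -1)
        walk.extend(positions)
    return walk


class TestMapFeatureToGenome:
    def test_plus_single_segment_two_aa(self):
        tr = _tr("+", [(101, 130)])
        got = map_feature_to_genome(ProteinFeature("t", "X", 1, 2), tr)
        assert got == [(100, 106)]  # genomic 101-106 1-based

    def test_plus_junction_codon_split(self):
        tr = _tr("+", [(101, 105), (201, 210)])
        got = map_feature_to_genome(ProteinFeature("t", "X", 2, 2), tr)
        assert got == [(103, 105), (200, 201)]  # 104-105 and 201-201

    def test_minus_strand_first_aa(self):
        tr = _tr("-", [(291, 300), (271, 280)])
        got = map_feature_to_genome(ProteinFeature("t", "X", 1, 1), tr)
        assert got == [(297, 300)]  # genomic 298-300

    def test_aa_end_beyond_cds_raises(self):
        tr = _tr("+", [(101, 130)])
        with pytest.raises(AnnotationError, match="beyond CDS"):
            map_feature_to_genome(ProteinFeature("t", "X", 1, 11), tr)

    def test_no_cds_raises(self):
        tr = TranscriptModel("t", "g", "chr1", "+", [])
        with pytest.raises(AnnotationError, match="no CDS"):
            map_feature_to_genome(ProteinFeature("t", "X", 1, 1), tr)

    def test_matches_per_nucleotide_enumeration_on_random_transcripts(self):
        """Every aa of random 1-3 segment transcripts maps to exactly the
        nucleotides an independent per-position walk assigns to it."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_seg = int(rng.integers(1, 4))
            strand = "+" if rng.random() < 0.5 else "-"
            cursor, segs = 100, []
            for _ in range(n_seg):
                length = int(rng.integers(1, 60))
                segs.append((cursor, cursor + length))
                cursor += length + int(rng.integers(20, 100))
            total = sum(e - s for s, e in segs)
            if total < 3:
                continue
            if strand == "-":
                segs = segs[::-1]  # coding order walks right-to-left
            tr = TranscriptModel("t", "g", "chr1", strand, segs)
            walk = _enumerate_oracle(tr)
            for aa in range(1, tr.aa_length + 1):
                got = map_feature_to_genome(ProteinFeature("t", "X", aa, aa), tr)
                expect = sorted(walk[3 * (aa - 1): 3 * aa])
                flat = [p for s, e in got for p in range(s, e)]
                assert sorted(flat) == expect
                assert total_length(got) == 3

    def test_round_trip_identity(self):
        """aa -> genome -> aa recovers the index for both strands."""
        for strand, segs in [("+", [(101, 105), (201, 210), (301, 310)]),
                             ("-", [(301, 310), (201, 210), (101, 105)])]:
            tr = _tr(strand, segs)
            for aa in range(1, tr.aa_length + 1):
                for s, e in map_feature_to_genome(ProteinFeature("t", "X", aa, aa), tr):
                    for pos in range(s, e):
                        assert coding_index_of(tr, pos) // 3 + 1 == aa

    def test_total_nt_is_three_per_aa(self):
        tr = _tr("+", [(101, 115), (201, 215)])
        f = ProteinFeature("t", "X", 2, 7)
        assert total_length(map_feature_to_genome(f, tr)) == 3 * 6


class TestProjectToExons:
    def test_feature_inside_one_exon(self, mini_models):
        tr = mini_models.transcripts["gplus.t1"]
        f = ProteinFeature("gplus.t1", "X", 1, 4)
        hits = project_to_exons(f, map_feature_to_genome(f, tr), mini_models)
        assert len(hits) == 1
        assert total_length(hits[0].intervals) == 12

    def test_junction_spanning_feature_conserves_length(self, mini_models):
        tr = mini_models.transcripts["gplus.t1"]
        # first coding exon holds 90 nt = 30 aa; span the junction
        f = ProteinFeature("gplus.t1", "X", 29, 32)
        hits = project_to_exons(f, map_feature_to_genome(f, tr), mini_models)
        assert len(hits) == 2
        assert sum(total_length(h.intervals) for h in hits) == 12

    def test_overlapping_same_term_features_union(self, mini_models):
        store = AnnotationStore()
        tr = mini_models.transcripts["gplus.t1"]
        for lo, hi in [(1, 10), (5, 14)]:
            f = ProteinFeature("gplus.t1", "X", lo, hi)
            for h in project_to_exons(f, map_feature_to_genome(f, tr), mini_models):
                store.add(h.exon_id, h.term_id, h.intervals)
        eid = next(e for e in mini_models.exons.values()
                   if e.gene_id == "gplus" and e.position_category == "first_coding").exon_id
        assert store.covered_nt(eid, "X") == 3 * 14  # union, not 3*20


class TestMotifScan:
    def test_monopartite_nls(self):
        got = scan_localization_motifs("AKKAKR", {"NLS": r"K[KR].[KR]"})
        assert [(f.aa_start, f.aa_end) for f in got] == [(2, 5)]

    def test_anchored_cterminal_pts1(self):
        got = scan_localization_motifs("MAAASKL", {"PTS1": r"[SAC][KRH][LM]$"})
        assert [(f.aa_start, f.aa_end) for f in got] == [(5, 7)]

    def test_no_match_empty(self):
        assert scan_localization_motifs("AAAA", {"NLS": r"K[KR].[KR]"}) == []

    def test_invalid_regex_is_config_error(self):
        with pytest.raises(AnnotationError, match="invalid regex"):
            scan_localization_motifs("AAAA", {"bad": r"[K"})

    def test_leftmost_nonoverlapping(self):
        got = scan_localization_motifs("KKAKKKAK", {"NLS": r"K[KR].[KR]"})
        assert [(f.aa_start, f.aa_end) for f in got] == [(1, 4), (5, 8)]


class TestStoreAndPropagation:
    def test_propagation_covers_ancestors_identically(self, mini_models, tmp_path):
        obo = (
            "format-version: 1.2\nontology: t\n\n"
            "[Term]\nid: R\nname: r\n\n"
            "[Term]\nid: P\nname: p\nis_a: R\n\n"
            "[Term]\nid: C\nname: c\nis_a: P\n"
        )
        (tmp_path / "t.obo").write_text(obo)
        (tmp_path / "m.tsv").write_text("R\tbinding\n")
        tree = exont.load_ontology(tmp_path / "t.obo", tmp_path / "m.tsv")
        feats = [ProteinFeature("gplus.t1", "C", 3, 8)]
        on = annotate_exons(feats, mini_models, tree, propagate=True)
        off = annotate_exons(feats, mini_models, tree, propagate=False)
        eid = [e for (e, t), _ in on.items() if t == "C"][0]
        assert on.intervals(eid, "C") == on.intervals(eid, "P") == on.intervals(eid, "R")
        assert off.intervals(eid, "P") == []

    def test_parent_coverage_geq_child_on_fixture(self, store, tree, pool):
        for exon in pool:
            for tid in store.terms:
                if tid not in tree:
                    continue
                for anc in tree.ancestors(tid):
                    assert store.covered_nt(exon.exon_id, anc) >= \
                        store.covered_nt(exon.exon_id, tid)

    def test_union_idempotence(self, mini_models):
        f = ProteinFeature("gplus.t1", "X", 1, 10)
        once = annotate_exons([f], mini_models, None, propagate=False)
        twice = annotate_exons([f, f], mini_models, None, propagate=False)
        assert {k: v for k, v in once.items()} == {k: v for k, v in twice.items()}

    def test_unknown_term_skipped_not_fatal(self, mini_models, tree):
        feats = [ProteinFeature("gplus.t1", "NOT:aterm", 1, 3)]
        store = annotate_exons(feats, mini_models, tree)
        assert store.terms == []


class TestTermFrequency:
    def test_fraction_denominator_is_universe(self, mini_models):
        pool = mini_models.control_pool("all_coding")
        store = AnnotationStore()
        store.add(pool.exons[0].exon_id, "X", [(0, 5)])
        freq = term_frequency(store, pool)
        assert freq["X"] == 1 / len(pool)

    def test_absent_term_zero(self, mini_models):
        pool = mini_models.control_pool("all_coding")
        freq = term_frequency(AnnotationStore(), pool)
        assert freq.get("X", 0.0) == 0.0

    def test_propagated_parent_freq_geq_child(self, store, tree, pool):
        freq = term_frequency(store, pool)
        for tid, f in freq.items():
            if tid not in tree:
                continue
            for anc in tree.ancestors(tid):
                assert freq.get(anc, 0.0) >= f - 1e-12


def test_feature_table_round_trip(fixture):
    feats = read_feature_table(fixture.paths["features"])
    assert feats and all(f.aa_start <= f.aa_end for f in feats)
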