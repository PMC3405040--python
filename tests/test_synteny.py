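"""Neighbor-family criterion, block assembly, read-through, orientation."""

import pytest

from paralogon.synteny import (
    build_blocks,
    detect_readthrough,
    interval_gap,
    neighbor_families,
    pair_orientation,
)
from paralogon.formats import TranscriptAlignment

from conftest import make_locus

MB = 1_000_000


def brute_force_supports(table, anchor_family, window_bp):
    """Independent all-pairs check of the anchor-support rule."""
    anchors = [g for g in table if g.family == anchor_family]
    supports = {}
    for g in table:
        if g.family == anchor_family:
            continue
        for a in anchors:
            if a.chromosome != g.chromosome or a.species != g.species:
                continue
            if a.end <= g.start:
                gap = g.start - a.end
            elif g.end <= a.start:
                gap = a.start - g.end
            else:
                gap = 0
            if gap < window_bp:
                supports.setdefault(g.family, set()).add(a.gene_id)
    return {f: len(s) for f, s in supports.items()}


@pytest.fixture
def three_anchor_table():
    """Anchors on three chromosomes; family F near all, G near two."""
    loci = [
        make_locus("palm1", "chr1", 1_000_000, 1_050_000),
        make_locus("palm2", "chr2", 10_000_000, 10_050_000),
        make_locus("palm3", "chr3", 5_000_000, 5_050_000),
        make_locus("f1", "chr1", 4 * MB, 4 * MB + 10_000, family="F"),
        make_locus("f2", "chr2", 14 * MB, 14 * MB + 10_000, family="F"),
        make_locus("f3", "chr3", 200_000, 210_000, family="F"),
        make_locus("g1", "chr1", 4 * MB, 4 * MB + 10_000, family="G"),
        make_locus("g2", "chr2", 14 * MB, 14 * MB + 10_000, family="G"),
    ]
    return loci


class TestNeighborFamilies:
    def test_three_supporting_anchors_selects(self, three_anchor_table):
        calls = {c.family: c for c in neighbor_families(three_anchor_table, "PALM")}
        oracle = brute_force_supports(three_anchor_table, "PALM", 5 * MB)
        assert calls["F"].selected and len(calls["F"].supporting_anchors) == 3
        assert oracle["F"] == 3

    def test_two_anchors_not_selected(self, three_anchor_table):
        calls = {c.family: c for c in neighbor_families(three_anchor_table, "PALM")}
        assert not calls["G"].selected
        assert len(calls["G"].supporting_anchors) == 2
        assert brute_force_supports(three_anchor_table, "PALM", 5 * MB)["G"] == 2

    def test_overlap_counts_as_distance_zero(self):
        table = [
            make_locus("palm1", "chr1", 1000, 2000),
            make_locus("h1", "chr1", 1500, 2500, family="H"),
        ]
        calls = neighbor_families(table, "PALM", window_bp=1, min_anchors=1)
        (call,) = calls
        assert call.selected
        assert call.supporting_anchors["palm1"] == ("h1", 0)

    def test_window_boundary_is_strict(self):
        # gap exactly == window  ->  not supported ("closer than")
        table = [
            make_locus("palm1", "chr1", 0, 1000),
            make_locus("h1", "chr1", 1000 + 5 * MB, 1000 + 5 * MB + 100, family="H"),
        ]
        (call,) = neighbor_families(table, "PALM", min_anchors=1)
        assert not call.selected
        table[1:] = [make_locus("h1", "chr1", 999 + 5 * MB, 999 + 5 * MB + 100, family="H")]
        (call,) = neighbor_families(table, "PALM", min_anchors=1)
        assert call.selected

    def test_monotone_in_window(self, three_anchor_table):
        small = {
            c.family
            for c in neighbor_families(three_anchor_table, "PALM", window_bp=2 * MB)
            if c.selected
        }
        large = {
            c.family
            for c in neighbor_families(three_anchor_table, "PALM", window_bp=8 * MB)
            if c.selected
        }
        assert small <= large

    def test_translation_invariance(self, three_anchor_table):
        shifted = [
            make_locus(
                g.gene_id, g.chromosome, g.start + 7 * MB, g.end + 7 * MB,
                g.strand, g.family, g.subtype,
            )
            for g in three_anchor_table
        ]
        orig = [(c.family, c.selected) for c in neighbor_families(three_anchor_table, "PALM")]
        moved = [(c.family, c.selected) for c in neighbor_families(shifted, "PALM")]
        assert orig == moved

    def test_absent_anchor_family_rejected(self, three_anchor_table):
        with pytest.raises(ValueError, match="anchor family"):
            neighbor_families(three_anchor_table, "NOPE")

    def test_midpoint_mode(self):
        table = [
            make_locus("palm1", "chr1", 0, 4 * MB),
            make_locus("h1", "chr1", 4 * MB + 1000, 4 * MB + 2000, family="H"),
        ]
        gap_call, = neighbor_families(table, "PALM", window_bp=MB, min_anchors=1)
        mid_call, = neighbor_families(
            table, "PALM", window_bp=MB, min_anchors=1, mode="midpoint"
        )
        assert gap_call.selected  # gap 1000 < 1 Mb
        assert not mid_call.selected  # midpoints ~2.0 vs ~4.0 Mb apart


class TestBuildBlocks:
    def test_single_cluster(self):
        table = [
            make_locus("palm1", "chr1", 2 * MB, 2 * MB + 10_000),
            make_locus("n1", "chr1", 0, 10_000, family="F"),
            make_locus("n2", "chr1", 3 * MB, 3 * MB + 10_000, family="G"),
            make_locus("n3", "chr1", 4 * MB, 4 * MB + 10_000, family="H"),
        ]
        (block,) = build_blocks(table, "PALM", ["F", "G", "H"])
        assert block.gene_ids() == ["n1", "palm1", "n2", "n3"]
        assert block.span == (0, 4 * MB + 10_000)

    def test_distant_anchors_make_two_blocks(self):
        table = [
            make_locus("palm1", "chr1", 0, 10_000),
            make_locus("n1", "chr1", MB, MB + 10_000, family="F"),
            make_locus("palm2", "chr1", 20 * MB, 20 * MB + 10_000),
            make_locus("n2", "chr1", 21 * MB, 21 * MB + 10_000, family="F"),
        ]
        blocks = build_blocks(table, "PALM", ["F"])
        assert [b.gene_ids() for b in blocks] == [["palm1", "n1"], ["palm2", "n2"]]

    def test_chromosome_without_anchor_dropped(self):
        table = [
            make_locus("palm1", "chr1", 0, 10_000),
            make_locus("n1", "chr2", 0, 10_000, family="F"),
        ]
        blocks = build_blocks(table, "PALM", ["F"])
        assert [b.chromosome for b in blocks] == ["chr1"]

    def test_empty_neighbor_list_warns_anchors_only(self, caplog):
        table = [make_locus("palm1", "chr1", 0, 10_000)]
        with caplog.at_level("WARNING"):
            blocks = build_blocks(table, "PALM", [])
        assert [b.gene_ids() for b in blocks] == [["palm1"]]
        assert any("anchors only" in r.message for r in caplog.records)


class TestReadthrough:
    def test_spanning_transcript_one_call(self):
        genes = [
            make_locus("A", "chr1", 50, 250, strand="+"),
            make_locus("B", "chr1", 950, 1200, strand="+", family="PDG"),
        ]
        t = TranscriptAlignment("est1", "Hsa", "chr1", "+", ((100, 200), (1000, 1100)))
        (call,) = detect_readthrough([t], genes)
        assert call.upstream_gene == "A" and call.downstream_gene == "B"
        assert call.same_strand

    def test_transcript_inside_single_gene_no_call(self):
        genes = [make_locus("A", "chr1", 50, 250)]
        t = TranscriptAlignment("est1", "Hsa", "chr1", "+", ((100, 200),))
        assert detect_readthrough([t], genes) == []

    def test_opposite_strand_pair_flagged(self):
        # PALMD-B / PDG4B-like arrangement: downstream gene inverted
        genes = [
            make_locus("palmdb", "chr1", 50, 250, strand="+", family="PALM"),
            make_locus("pdg4b", "chr1", 950, 1200, strand="-", family="PDG"),
        ]
        t = TranscriptAlignment("est1", "Dre", "chr1", "+", ((100, 200), (1000, 1100)))
        (call,) = detect_readthrough([t], [
            make_locus("palmdb", "chr1", 50, 250, strand="+", family="PALM", species="Dre"),
            make_locus("pdg4b", "chr1", 950, 1200, strand="-", family="PDG", species="Dre"),
        ])
        assert call.upstream_gene == "palmdb" and not call.same_strand

    def test_transcript_strand_must_match_upstream(self):
        genes = [
            make_locus("A", "chr1", 50, 250, strand="-"),
            make_locus("B", "chr1", 950, 1200, strand="+", family="PDG"),
        ]
        t = TranscriptAlignment("est1", "Hsa", "chr1", "+", ((100, 200), (1000, 1100)))
        # '+' transcript, upstream gene A is '-': no call
        assert detect_readthrough([t], genes) == []

    def test_minus_strand_transcript_reverses_order(self):
        genes = [
            make_locus("A", "chr1", 50, 250, strand="-"),
            make_locus("B", "chr1", 950, 1200, strand="-", family="PDG"),
        ]
        t = TranscriptAlignment("est1", "Hsa", "chr1", "-", ((100, 200), (1000, 1100)))
        (call,) = detect_readthrough([t], genes)
        assert call.upstream_gene == "B" and call.downstream_gene == "A"


class TestPairOrientation:
    def test_same_and_opposite_strand(self):
        table = [
            make_locus("a1", "chr1", 0, 10_000, strand="+", family="A"),
            make_locus("b1", "chr1", 20_000, 30_000, strand="+", family="B"),
            make_locus("a2", "chr2", 0, 10_000, strand="+", family="A"),
            make_locus("b2", "chr2", 20_000, 30_000, strand="-", family="B"),
        ]
        calls = pair_orientation(table, "A", "B")
        by_a = {c.gene_a: c for c in calls}
        assert by_a["a1"].same_strand and by_a["a1"].gap_bp == 10_000
        assert not by_a["a2"].same_strand

    def test_tie_resolves_downstream(self):
        table = [
            make_locus("a1", "chr1", 100_000, 110_000, family="A"),
            make_locus("b_up", "chr1", 80_000, 90_000, family="B"),
            make_locus("b_down", "chr1", 120_000, 130_000, family="B"),
        ]
        (call,) = pair_orientation(table, "A", "B")
        assert call.gene_b == "b_down" and call.gap_bp == 10_000

    def test_interval_gap_convention(self):
        assert interval_gap(0, 10, 10, 20) == 0  # abutting half-open: gap 0
        assert interval_gap(0, 10, 15, 20) == 5
        assert interval_gap(15, 20, 0, 10) == 5
        assert interval_gap(0, 10, 5, 20) == 0
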