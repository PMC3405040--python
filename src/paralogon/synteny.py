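"""Conserved-synteny criteria around an anchor gene family.

The core rule: a candidate gene family is a *neighbor family* of the
anchor family (e.g. the paralemmins) when it has members closer than a
window (default 5 Mb) to at least ``min_anchors`` (default 3) distinct
anchor genes in a reference genome.  Distances are measured as the gap
between nearest interval ends — overlapping intervals are at distance
0 — with "closer than" read as a strict inequality; a midpoint-to-
midpoint mode is available for sensitivity analysis.

Synteny blocks group anchor and neighbor-family genes per chromosome by
single-linkage clustering with the same gap threshold; blocks with no
anchor gene are discarded.  Read-through detection finds transcripts
whose aligned blocks overlap two distinct genes, the signature of a
fusion transcript running from a gene into its downstream neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .formats import GeneLocus, TranscriptAlignment

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 5_000_000
DEFAULT_MIN_ANCHORS = 3


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def locus_distance(a: GeneLocus, b: GeneLocus, mode: str = "gap") -> int | None:
    """Distance between two loci, or None when on different chromosomes."""
    if a.chromosome != b.chromosome or a.species != b.species:
        return None
    if mode == "gap":
        return interval_gap(a.start, a.end, b.start, b.end)
    if mode == "midpoint":
        return abs((a.start + a.end) // 2 - (b.start + b.end) // 2)
    raise ValueError(f"unknown distance mode {mode!r}")


@dataclass
class NeighborFamilyCall:
    """Whether one family satisfies the neighbor-family criterion."""

    family: str
    #: anchor gene_id -> (nearest family member gene_id, distance in bp)
    supporting_anchors: dict
    selected: bool
    window_bp: int
    min_anchors: int


def neighbor_families(
    gene_table: Sequence[GeneLocus],
    anchor_family: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    mode: str = "gap",
) -> list[NeighborFamilyCall]:
    """Apply the neighbor-family criterion in one reference genome.

    The table must hold a single species.  For each non-anchor family,
    an anchor gene supports it when some family member lies strictly
    closer than *window_bp* (overlap counts as distance 0); each
    distinct anchor gene counts once.  Calls are sorted by family name.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if min_anchors < 1:
        raise ValueError("min_anchors must be >= 1")
    species = {g.species for g in gene_table}
    if len(species) > 1:
        raise ValueError(
            f"gene table must hold one reference species, found {sorted(species)}"
        )
    anchors = [g for g in gene_table if g.family == anchor_family]
    if not anchors:
        raise ValueError(f"anchor family {anchor_family!r} absent from gene table")
    by_family: dict = {}
    for g in gene_table:
        if g.family != anchor_family:
            by_family.setdefault(g.family, []).append(g)
    calls = []
    for family in sorted(by_family):
        supporting: dict = {}
        for anchor in anchors:
            best = None
            for member in by_family[family]:
                dist = locus_distance(anchor, member, mode)
                if dist is None or dist >= window_bp:
                    continue
                if best is None or dist < best[1]:
                    best = (member.gene_id, dist)
            if best is not None:
                supporting[anchor.gene_id] = best
        calls.append(
            NeighborFamilyCall(
                family=family,
                supporting_anchors=supporting,
                selected=len(supporting) >= min_anchors,
                window_bp=window_bp,
                min_anchors=min_anchors,
            )
        )
    return calls


@dataclass
class SyntenyBlock:
    """Anchor and neighbor-family genes clustered on one chromosome."""

    species: str
    chromosome: str
    loci: list

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda g: (g.start, g.end, g.gene_id))

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.loci), max(g.end for g in self.loci))

    def gene_ids(self) -> list:
        return [g.gene_id for g in self.loci]


def build_blocks(
    gene_tables: Sequence[GeneLocus] | Sequence[Sequence[GeneLocus]],
    anchor_family: str,
    neighbor_family_names: Iterable[str],
    max_gap_bp: int = DEFAULT_WINDOW_BP,
) -> list[SyntenyBlock]:
    """Cluster anchor + neighbor-family loci into synteny blocks.

    *gene_tables* may be a flat locus list or a list of per-species
    tables.  Per species/chromosome, relevant loci are single-linkage
    clustered with gap threshold *max_gap_bp*; clusters containing no
    anchor gene are dropped.
    """
    loci: list[GeneLocus] = []
    for item in gene_tables:
        if isinstance(item, GeneLocus):
            loci.append(item)
        else:
            loci.extend(item)
    families = set(neighbor_family_names)
    if not families:
        logger.warning("empty neighbor family list: blocks will contain anchors only")
    families.add(anchor_family)
    relevant = [g for g in loci if g.family in families]
    by_chrom: dict = {}
    for g in relevant:
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)
    blocks: list[SyntenyBlock] = []
    for (species, chromosome) in sorted(by_chrom):
        genes = sorted(by_chrom[(species, chromosome)], key=lambda g: (g.start, g.end))
        cluster: list[GeneLocus] = []
        reach = None  # max end seen in the current cluster
        clusters = []
        for g in genes:
            if cluster and g.start - reach >= max_gap_bp:
                clusters.append(cluster)
                cluster = []
                reach = None
            cluster.append(g)
            reach = g.end if reach is None else max(reach, g.end)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            if any(g.family == anchor_family for g in cl):
                blocks.append(SyntenyBlock(species, chromosome, cl))
    return blocks


class ReadthroughCall(NamedTuple):
    """A transcript spanning two distinct genes (putative fusion)."""

    transcript_id: str
    upstream_gene: str
    downstream_gene: str
    same_strand: bool


def _overlaps_gene(t: TranscriptAlignment, g: GeneLocus) -> bool:
    return any(s < g.end and g.start < e for s, e in t.blocks)


def detect_readthrough(
    transcripts: Sequence[TranscriptAlignment],
    gene_table: Sequence[GeneLocus],
) -> list[ReadthroughCall]:
    """Find transcripts overlapping two distinct genes on their chromosome.

    Upstream/downstream follow gene start order for a ``+`` transcript
    and are reversed for ``-``; the transcript's strand must equal the
    upstream gene's strand.  ``same_strand`` records whether the two
    genes agree in orientation.  With more than two genes hit, one call
    is emitted per adjacent pair in genomic order.
    """
    calls: list[ReadthroughCall] = []
    for t in transcripts:
        hit = [
            g
            for g in gene_table
            if g.species == t.species
            and g.chromosome == t.chromosome
            and _overlaps_gene(t, g)
        ]
        hit.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for left, right in zip(hit, hit[1:]):
            if t.strand == "+":
                upstream, downstream = left, right
            else:
                upstream, downstream = right, left
            if t.strand != upstream.strand:
                continue
            calls.append(
                ReadthroughCall(
                    transcript_id=t.transcript_id,
                    upstream_gene=upstream.gene_id,
                    downstream_gene=downstream.gene_id,
                    same_strand=(left.strand == right.strand),
                )
            )
    return calls


class OrientationCall(NamedTuple):
    gene_a: str
    gene_b: str
    same_strand: bool
    gap_bp: int


def pair_orientation(
    gene_table: Sequence[GeneLocus],
    family_a: str,
    family_b: str,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[OrientationCall]:
    """Nearest same-chromosome b-family gene for every a-family gene.

    Only pairs with gap strictly below *window_bp* are reported; a tie
    between an up- and a downstream candidate at equal gaps resolves to
    the downstream one (larger start).
    """
    a_genes = [g for g in gene_table if g.family == family_a]
    b_genes = [g for g in gene_table if g.family == family_b]
    if not a_genes:
        raise ValueError(f"family {family_a!r} absent from gene table")
    if not b_genes:
        raise ValueError(f"family {family_b!r} absent from gene table")
    out: list[OrientationCall] = []
    for a in sorted(a_genes, key=lambda g: (g.species, g.chromosome, g.start)):
        best = None
        for b in b_genes:
            dist = locus_distance(a, b)
            if dist is None or dist >= window_bp:
                continue
            key = (dist, -b.start, b.gene_id)  # ties -> larger start wins
            if best is None or key < best[0]:
                best = (key, b, dist)
        if best is not None:
            _, b, dist = best
            out.append(
                OrientationCall(
                    gene_a=a.gene_id,
                    gene_b=b.gene_id,
                    same_strand=(a.strand == b.strand),
                    gap_bp=dist,
                )
            )
    return out
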