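# Methods

This note documents the models, conventions and default parameters the
package implements, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All genomic intervals are 0-based half-open base-pair coordinates,
everywhere: gene tables, transcript blocks, block spans. Megabase
presentation values must be converted on input (the gene-table reader
rejects decimal coordinates outright rather than guessing a unit).
Chromosome names are opaque strings, so chromosome numbers, scaffold
(`s_…`) and ultracontig (`u_…`) identifiers coexist without
normalization. Newick trees are read in both common bootstrap dialects
(internal-node labels and `[&support=…]` comments) and always written
in the node-label dialect with branch lengths at six decimals; species
trees additionally carry `[&wgd=NAME]` branch annotations. Protein
sequences use the 20 amino-acid letters plus `X` for an unknown
residue; `-` is the alignment gap.

## Motif model

A degenerate pattern is an ordered list of positions: literal residue,
residue class, or wildcard. Scanning slides the pattern along a
sequence; a window is reported when at least `min_literal` literal and
`min_class` class positions match. Wildcards carry no threshold slack:
they accept any residue or an unknown `X` but never a gap, and a failed
wildcard disqualifies the window. An `X` in the sequence satisfies only
wildcard positions; at a literal or class position it simply fails to
match (consuming threshold slack), which is the conservative treatment
for curated predictions containing unknowns.

Pattern derivation classifies each alignment-window column: invariant
(exactly one residue, no gaps) → literal; all residues within one
substitution group (no gaps) → class recording the *observed* residue
set, not the whole group (so an E/D column yields `[DE]`, not `[DENQ]`);
anything else, including any column containing a gap or an `X`, →
wildcard. The default substitution groups are the Clustal-family
"strong" groups ({S,T,A}, {N,E,Q,K}, {N,H,Q,K}, {N,D,E,Q}, {Q,H,R,K},
{M,I,L,V}, {M,I,L,F}, {H,Y}, {F,Y,W}); the table is configurable. When
an observed set fits several groups the first in declared order is
recorded — a deterministic tie-break, not a biological claim. Window
selection is caller-specified; the package deliberately does not search
for maximal windows, since motif discovery is a different problem from
motif formalization.

## Distances, neighbor joining, bootstrap

The protein distance is the observed proportion of differing residues
over pairwise-deleted columns: a column counts for a pair only when
both rows carry a standard residue. Pairwise (not complete) deletion
matters for families with isoform-specific gaps, where complete
deletion would discard most columns. The optional Kimura correction
`d = −ln(1 − p − 0.2p²)` compensates multiple hits; when its argument
is ≤ 0 (saturation, p ≳ 0.854) the distance is capped at 10.0
substitutions/site with a warning rather than failing the whole run.
Pairs sharing fewer than `min_overlap` (default 20) columns are an
error naming the pair — too little signal to estimate anything.

Neighbor joining follows Saitou & Nei exactly: minimize
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, join, compute limb lengths by the
standard formulas, reduce the matrix, finish with the closed-form
three-taxon star. Determinism is part of the contract: ties on Q are
broken by the lexicographically smallest label pair, where an internal
cluster inherits the smallest leaf label it contains. Negative limb
lengths (possible on non-additive data) are clamped to zero without
redistribution; the raw value is kept on the node (`raw_limb`) for
diagnostics. On any exactly additive matrix the output topology and
branch lengths reproduce the generating tree to floating-point
accuracy (tested to 1e-9).

Bootstrapping resamples alignment columns with replacement, the same
number as the original; replicate *i* of a run seeded *s* uses its own
generator seeded `s + i`, so any replicate can be recomputed in
isolation. A replicate that breaks the `min_overlap` floor is redrawn
(up to 100 attempts). Supports are the percentage of replicates
containing each internal bipartition of the main (full-alignment) tree;
no consensus tree is built, matching how supports are usually drawn on
a single tree. The default replicate count in the pipeline is 1000,
reducible from the CLI.

## Synteny

The neighbor-family criterion: family F is accepted when members of F
lie closer than `window_bp` (default 5 Mb) to at least `min_anchors`
(default 3) *distinct anchor genes* in one reference genome. "Closer
than" is a strict inequality on the gap between nearest interval ends,
with overlap counting as distance zero; this convention is a documented
choice (start-to-start and midpoint conventions exist in the
literature), and a midpoint mode is provided behind a flag for
sensitivity analysis. One family member may support several anchors;
each anchor counts once per family.

Blocks are assembled per species/chromosome by single-linkage
clustering of anchor plus neighbor-family loci with the same 5 Mb gap
threshold; clusters without an anchor gene are discarded. Single
linkage is the simplest reproducible formalization of "a contiguous
neighborhood around the anchor".

Read-through detection calls a transcript when its aligned blocks
overlap (≥ 1 bp) two distinct genes on its chromosome. Upstream and
downstream follow gene start order for a `+` transcript and are
reversed for `-`, and the transcript's strand must equal the upstream
gene's strand — a fusion transcript initiates at the upstream promoter.
Gene intervals stand in for exon unions, which is the resolution of
block-level EST alignments. The call records whether the two genes
share strand, so an inverted downstream neighbor (the arrangement seen
for some teleost gene pairs) is distinguishable from a co-oriented one.

## Duplication timing

Gene-tree nodes are labeled by species overlap: a node is a duplication
when its child subtrees share at least one species. This is robust to
poorly resolved topologies and requires no reconciliation machinery;
the price is undercounting when differential losses leave the two child
clades with disjoint species sets (such nodes look like speciations).
Each duplication is mapped to the species-tree branch above the MRCA of
its combined species set; if that branch carries a WGD mark the
duplication is assigned that epoch, otherwise it is `lineage-specific`
(or `pre-root` above an unmarked root). 1R and 2R are one mark (`1R2R`)
by default because species sampling inside the vertebrate crown cannot
separate them; a two-mark species tree is accepted. The placement of
jawless-fish lineages relative to 1R/2R is left to the caller's species
tree — the package makes no default claim. Gene trees are rooted by an
explicit outgroup when given, else midpoint with a logged warning.
Calls at nodes with bootstrap support below `min_support` (default 50)
are flagged low-confidence but never suppressed.

Retention analysis censuses subtypes per species; a subtype is flagged
lost in a species when the species descends from the most tip-ward
WGD-marked branch ancestral to all carriers but lacks the subtype.
This scoping keeps teleost-specific duplicates from being flagged
"lost" in tetrapods, which never had them.

Paralogon concordance asks whether neighbor families duplicated in the
same epoch *and between the same block pair* as the focal family: a
neighbor agrees when at least one of its duplication calls at the focal
epoch has child clades occupying the same pair of synteny blocks as a
focal-family call. The block-pair requirement is deliberately strict —
it tests co-duplication of the chromosomal region, not merely
contemporaneous duplication — so under heavy differential loss
concordance degrades even when epochs agree.

## The simulator

The generator replays the quadruplication scenario as a forward walk
over a species tree. Defaults define the study conditions: seven gene
families on one ancestral chromosome (anchor `PALM` plus six
neighbors), 1 Mb intergene spacing, 10 kb genes, a six-species tree
(three tetrapods Hsa/Mmu/Gga, three teleosts Dre/Ola/Gac) with `1R2R`
on the root branch modeled as two back-to-back doublings and `3R` on
the teleost stem, per-copy post-WGD loss probability 0.3, per-branch
loss 0.05, translocation 0.05 per gene per branch, 300-residue
proteins, a planted 11-position motif at column 40, 25% invariant
sites, background substitution rate 1.0. With zero loss every tetrapod
genome carries exactly 4 copies per family and every teleost genome 8,
and gene order is conserved.

Two layout decisions are load-bearing. First, the anchor family is
centred in the ancestral gene order: with 7 families at 1 Mb spacing at
most three genes separate any neighbor from the anchor after
loss-compaction, so every surviving same-chromosome neighbor is within
the 5 Mb window and the synteny criterion's failures are attributable
to gene loss, not layout artefacts. Second, coordinates are re-laid at
uniform spacing after every event; the synteny criterion depends only
on distances relative to the window, so realistic intergenic length
distributions would add noise without adding signal.

Loss semantics: at each doubling only the new copies are exposed to
`p_loss` (the pre-existing copy is the continuing chromosome), and a
survival guard (on by default) refuses a loss that would extinguish a
family genome-wide — with `p_loss = 1` exactly one copy per family
survives. A smaller per-branch loss rate thereafter produces the
differential, species-specific losses that make epoch recovery
imperfect in interesting ways.

Sequences evolve by per-site Poisson replacement, uniform over the 19
other residues, giving the closed-form divergence
`P(differ) = (19/20)(1 − e^{−20rt/19})` used as the simulator's own
calibration check. Site rates are heterogeneous: motif literal/class
columns are frozen, a configured fraction of sites is invariant, the
rest evolve at the background rate. The optional indel mode is
deletion-only (Poisson deletion events of geometric length, inherited
by descendants); insertions are not simulated, so the true alignment
is obtained by stacking sequences and dropping columns deleted in every
extant row. Substitution is deliberately not an empirical-matrix model
(JTT/Gonnet): the tests need controllable divergence and conserved
columns, not biochemical realism, and maximum-likelihood inference is
out of the package's scope.

What the simulator does not emulate — and therefore what passing
recovery tests do not show about real data: alignment error (true
alignments are known), empirical amino-acid exchangeabilities and
among-site rate correlation, tandem duplication, realistic intergenic
distances and gene lengths, assembly artefacts (fragmented scaffolds,
missing sequence), and read-through transcription (read-through test
fixtures are hand-built toy tables by design).

## Problem sizes and numerics

The shipped tests and the acceptance script run at desk scale chosen to
make the statistics meaningful at interactive runtimes: 200 random
trees of 4–8 taxa for NJ consistency, 500 random pattern/sequence pairs
for scanner-oracle equivalence, 20 simulation replicates for synteny
and epoch recovery (about 480 duplication nodes), 100-replicate
bootstraps in examples. Branch lengths are compared at 1e-9 on additive
input; Newick round-trips preserve lengths to six decimals; all
stochastic components are reproducible from a single integer seed, with
replicate-level derivation (`seed + i`) where parallel recomputation
matters.

## Known limitations

Species-overlap duplication labeling undercounts duplications whose
child clades survive in disjoint species sets, and mis-times
duplications whose surviving species span less than the duplication's
true clade (both measured by the epoch-recovery statistic, ~99% at the
default loss rate rather than 100%). The NJ implementation is the
O(n³) textbook algorithm, appropriate for the tens-of-leaves trees of
gene-family work, not for thousands of taxa. The concordance score
requires block co-membership and is conservative under heavy loss.
Midpoint rooting of unrooted gene trees can misplace the root on
rate-heterogeneous families; provide an outgroup when one exists.
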