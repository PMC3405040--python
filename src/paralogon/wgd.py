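"""Duplication-epoch classification against a WGD-marked species tree.

Vertebrate gene families were shaped by two basal rounds of genome
tetraploidization (1R/2R, not separable and treated as one epoch mark
``1R2R`` by default) and a third, teleost-specific round (``3R``).
Given a rooted gene tree and a species tree whose branches may carry
WGD marks, every internal gene-tree node is labeled duplication or
speciation by the species-overlap rule (a node is a duplication when
its child subtrees share at least one species); each duplication is
mapped to the species-tree branch above the MRCA of its species set and
inherits that branch's WGD mark as its epoch, or is called
``lineage-specific`` (``pre-root`` when it maps above an unmarked
root).

Species-tree Newick dialect: branch annotations ``[&wgd=NAME]`` placed
after the subtree they subtend, e.g. ``((Dre,Ola),Gac)[&wgd=3R]:0.1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy

from .formats import FormatError, GeneLocus, read_newick

logger = logging.getLogger(__name__)

SPECIATION = "speciation"
LINEAGE_SPECIFIC = "lineage-specific"
PRE_ROOT = "pre-root"
DEFAULT_MIN_SUPPORT = 50.0


def species_of_label(label: str) -> str:
    """Default species-tag convention: the token before the first '_'."""
    return label.split("_", 1)[0]


def read_species_tree(source: str | Path, *, is_string: bool = False) -> dendropy.Tree:
    """Read a rooted species tree; ``[&wgd=...]`` marks land on ``node.wgd``."""
    tree = read_newick(source, is_string=is_string, rooted=True)
    tree.is_rooted = True
    for node in tree:
        mark = node.annotations.get_value("wgd")
        node.wgd = str(mark) if mark is not None else None
        if node.wgd is not None and node.is_leaf():
            raise FormatError("wgd marks belong on internal branches, not leaves")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("species tree has duplicate species tags")
    return tree


def write_species_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a species tree, re-emitting ``[&wgd=...]`` branch marks."""

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            text = node.taxon.label
        else:
            text = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        mark = getattr(node, "wgd", None)
        if mark:
            text += f"[&wgd={mark}]"
        if node.edge.length is not None:
            text += f":{node.edge.length:.6f}"
        return text

    out = render(tree.seed_node) + ";\n"
    if path is not None:
        Path(path).write_text(out)
    return out


@dataclass
class DuplicationCall:
    """Species-overlap verdict for one internal gene-tree node."""

    node_id: str
    is_duplication: bool
    child_species_sets: tuple
    child_leaf_sets: tuple
    mapped_branch: frozenset  # species below the mapped species-tree node
    epoch: str | None  # WGD mark, lineage-specific, pre-root; None if speciation
    support: float | None = None
    low_confidence: bool = False


def _root_gene_tree(
    gene_tree: dendropy.Tree, outgroup: str | None
) -> dendropy.Tree:
    tree = gene_tree.clone(depth=1)
    tree.is_rooted = True
    if outgroup is not None:
        matches = [
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == outgroup
        ]
        if not matches:
            raise ValueError(f"outgroup leaf {outgroup!r} not in gene tree")
        tree.to_outgroup_position(matches[0], update_bipartitions=False)
    elif len(tree.seed_node.child_nodes()) > 2:
        logger.warning("gene tree unrooted and no outgroup given: midpoint rooting")
        if any(nd.edge.length is None for nd in tree if nd is not tree.seed_node):
            for nd in tree:
                if nd is not tree.seed_node and nd.edge.length is None:
                    nd.edge.length = 1.0
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def classify_duplications(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    outgroup: str | None = None,
    species_of: Callable[[str], str] = species_of_label,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> list[DuplicationCall]:
    """Label every internal gene-tree node and time the duplications.

    The gene tree is rooted first (explicit *outgroup* if given, else
    midpoint with a warning if unrooted).  Calls with bootstrap support
    below *min_support* are flagged low-confidence but kept.  Raises on
    a leaf whose species tag is absent from the species tree.
    """
    tree = _root_gene_tree(gene_tree, outgroup)
    sp_leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    for lf in tree.leaf_node_iter():
        tag = species_of(lf.taxon.label)
        if tag not in sp_leaves:
            raise ValueError(
                f"species tag {tag!r} (leaf {lf.taxon.label!r}) "
                "is not in the species tree"
            )
    calls: list[DuplicationCall] = []
    counter = 0
    # postorder species sets
    species_below: dict = {}
    leaves_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            species_below[node] = frozenset({species_of(node.taxon.label)})
            leaves_below[node] = frozenset({node.taxon.label})
            continue
        kids = node.child_nodes()
        species_below[node] = frozenset().union(*(species_below[k] for k in kids))
        leaves_below[node] = frozenset().union(*(leaves_below[k] for k in kids))

    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        child_species = tuple(species_below[k] for k in kids)
        child_leaves = tuple(leaves_below[k] for k in kids)
        is_dup = any(
            child_species[i] & child_species[j]
            for i in range(len(kids))
            for j in range(i + 1, len(kids))
        )
        mapped_node = _mrca(species_tree, species_below[node])
        mapped = frozenset(
            lf.taxon.label for lf in mapped_node.leaf_iter()
        )
        epoch = None
        if is_dup:
            mark = getattr(mapped_node, "wgd", None)
            if mark is not None:
                epoch = mark
            elif mapped_node is species_tree.seed_node:
                epoch = PRE_ROOT
            else:
                epoch = LINEAGE_SPECIFIC
        support = getattr(node, "support", None)
        calls.append(
            DuplicationCall(
                node_id=f"n{counter}",
                is_duplication=is_dup,
                child_species_sets=child_species,
                child_leaf_sets=child_leaves,
                mapped_branch=mapped,
                epoch=epoch,
                support=support,
                low_confidence=(support is not None and support < min_support),
            )
        )
        counter += 1
    return calls


def _mrca(species_tree: dendropy.Tree, species: frozenset) -> dendropy.Node:
    if len(species) == 1:
        (tag,) = species
        for lf in species_tree.leaf_node_iter():
            if lf.taxon.label == tag:
                return lf
        raise ValueError(f"species {tag!r} not in species tree")
    node = species_tree.mrca(taxon_labels=list(species))
    if node is None:
        raise ValueError(f"no MRCA for species set {sorted(species)}")
    return node


# ---------------------------------------------------------------------------
# retained paralogs / losses
# ---------------------------------------------------------------------------


@dataclass
class ParalogRetention:
    """Per-species subtype census of one family, with loss flags."""

    family: str
    #: species -> sorted list of subtypes present
    present: dict
    #: species -> count of distinct subtypes
    counts: dict
    #: set of (species, subtype) pairs flagged as lost
    lost: set


def count_retained_paralogs(
    gene_table: Sequence[GeneLocus],
    family: str,
    species_tree: dendropy.Tree,
) -> ParalogRetention:
    """Census subtypes per species and flag inferred losses.

    A subtype is flagged lost in a species when at least one other
    species sharing the same side of the most tip-ward WGD mark above
    the subtype's carriers has it, but this species does not.  A
    species-tree species with no genes at all is warned about and picks
    up flags for every scoped subtype.
    """
    all_species = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    present: dict = {sp: set() for sp in all_species}
    for g in gene_table:
        if g.family != family:
            continue
        if g.species not in present:
            raise ValueError(f"species {g.species!r} not in species tree")
        present[g.species].add(g.subtype or g.gene_id)
    for sp in all_species:
        if not present[sp]:
            logger.warning("species %s carries no %s genes", sp, family)

    subtypes = sorted(set().union(*present.values())) if any(present.values()) else []
    lost: set = set()
    for subtype in subtypes:
        carriers = frozenset(sp for sp in all_species if subtype in present[sp])
        scope_node = _mrca(species_tree, carriers)
        # ascend to the nearest WGD-marked branch; its descendants are the
        # species expected to have had the chance to retain this subtype
        node = scope_node
        while node is not None and getattr(node, "wgd", None) is None:
            node = node.parent_node
        if node is not None:
            scope = [lf.taxon.label for lf in node.leaf_iter()]
        else:
            scope = all_species
        for sp in scope:
            if subtype not in present[sp]:
                lost.add((sp, subtype))
    return ParalogRetention(
        family=family,
        present={sp: sorted(present[sp]) for sp in all_species},
        counts={sp: len(present[sp]) for sp in all_species},
        lost=lost,
    )


# ---------------------------------------------------------------------------
# paralogon concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Cross-family agreement on the epoch of a shared block duplication."""

    focal_family: str
    epoch: str
    agreement: dict  # neighbor family -> bool
    concordance: float


def _call_block_pairs(
    calls: Sequence[DuplicationCall], epoch: str, block_of: Mapping
) -> set:
    pairs = set()
    for call in calls:
        if not call.is_duplication or call.epoch != epoch:
            continue
        sides = []
        for leaf_set in call.child_leaf_sets:
            blocks = frozenset(
                block_of[g] for g in leaf_set if g in block_of
            )
            if blocks:
                sides.append(blocks)
        if len(sides) >= 2:
            pairs.add(frozenset(sides[:2]) if len(sides) == 2 else frozenset(sides))
    return pairs


def paralogon_concordance(
    calls_by_family: Mapping,
    block_membership: Mapping,
    focal_family: str,
    epoch: str | None = None,
) -> ConcordanceReport:
    """Fraction of neighbor families whose duplication timing agrees.

    *calls_by_family* maps family name to its DuplicationCall list;
    *block_membership* maps gene_id to a synteny-block identifier.  A
    neighbor family agrees when it has at least one duplication at the
    focal epoch whose child clades occupy the same block pair as a
    focal-family duplication at that epoch.
    """
    if focal_family not in calls_by_family:
        raise ValueError(f"no duplication calls for focal family {focal_family!r}")
    focal_calls = calls_by_family[focal_family]
    if epoch is None:
        wgd_epochs = sorted(
            c.epoch
            for c in focal_calls
            if c.is_duplication and c.epoch not in (LINEAGE_SPECIFIC, PRE_ROOT, None)
        )
        if not wgd_epochs:
            raise ValueError(
                f"focal family {focal_family!r} has no WGD-epoch duplication call"
            )
        # most frequent epoch, alphabetical tie-break
        epoch = min(set(wgd_epochs), key=lambda e: (-wgd_epochs.count(e), e))
    neighbors = [f for f in sorted(calls_by_family) if f != focal_family]
    if not neighbors:
        raise ValueError("no neighbor families: concordance undefined")
    focal_pairs = _call_block_pairs(focal_calls, epoch, block_membership)
    agreement: dict = {}
    for fam in neighbors:
        fam_pairs = _call_block_pairs(calls_by_family[fam], epoch, block_membership)
        agreement[fam] = bool(fam_pairs & focal_pairs)
    concordance = sum(agreement.values()) / len(neighbors)
    return ConcordanceReport(
        focal_family=focal_family,
        epoch=epoch,
        agreement=agreement,
        concordance=concordance,
    )


def calls_to_json(calls: Sequence[DuplicationCall]) -> list:
    out = []
    for c in calls:
        out.append(
            {
                "node_id": c.node_id,
                "is_duplication": c.is_duplication,
                "child_species_sets": [sorted(s) for s in c.child_species_sets],
                "child_leaf_sets": [sorted(s) for s in c.child_leaf_sets],
                "mapped_branch": sorted(c.mapped_branch),
                "epoch": c.epoch,
                "support": c.support,
                "low_confidence": c.low_confidence,
            }
        )
    return out
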