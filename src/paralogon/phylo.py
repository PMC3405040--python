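"""Protein distances, neighbor joining, and column-bootstrap support.

The distance model is the observed proportion of differing residues
(p-distance) over pairwise-deleted columns — a column counts for a pair
only when **both** rows carry a standard amino-acid letter (gaps and the
unknown residue ``X`` are skipped per pair, not per column).  The
optional Kimura multiple-hit correction

    d = -ln(1 - p - 0.2 p^2)

is the standard companion of Clustal-style protein NJ.

Neighbor joining (Saitou & Nei) agglomerates by the Q-criterion

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with the standard limb-length formulas.  Ties on Q are broken by the
lexicographically smallest label pair (an internal cluster inherits the
smallest leaf label it contains), negative limb lengths are clamped to
zero with the raw value kept on the node (``raw_limb``), and the result
is an unrooted tree whose seed node is the final trifurcation.

Bootstrapping resamples alignment columns with replacement; replicate
``i`` of a run with seed ``s`` uses its own generator seeded ``s + i``,
so replicates are reproducible independently of execution order.
Supports are attached to the bipartitions of the main (full-alignment)
tree; no consensus tree is built.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .formats import AMINO_ACIDS, Alignment

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 20
KIMURA_CAP = 10.0


class DistanceError(ValueError):
    """Raised when a pair of rows has too few comparable columns."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair column counts."""

    taxa: tuple[str, ...]
    d: np.ndarray
    n_sites_used: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def as_dict(self) -> dict:
        return {
            (self.taxa[i], self.taxa[j]): float(self.d[i, j])
            for i in range(self.n)
            for j in range(self.n)
        }


def protein_distance(
    alignment: Alignment,
    correction: str = "none",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    cap_value: float = KIMURA_CAP,
) -> DistanceMatrix:
    """Pairwise p-distances (optionally Kimura-corrected) from an alignment.

    Raises :class:`DistanceError` naming the first pair with fewer than
    *min_overlap* comparable columns.  A Kimura log argument <= 0 is
    capped at *cap_value* with a warning.
    """
    if correction not in ("none", "kimura"):
        raise ValueError(f"unknown correction {correction!r}")
    if alignment.n_rows < 3:
        raise ValueError("distance matrix for tree building needs >= 3 rows")
    taxa = tuple(r.id for r in alignment.rows)
    # residues as a byte matrix; comparable = standard amino acid
    mat = np.frombuffer(
        "".join(r.residues for r in alignment.rows).encode("ascii"), dtype="S1"
    ).reshape(alignment.n_rows, alignment.n_columns)
    comparable = np.isin(mat, np.array(sorted(AMINO_ACIDS), dtype="S1"))
    n = alignment.n_rows
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    np.fill_diagonal(used, alignment.n_columns)
    for i in range(n):
        for j in range(i + 1, n):
            both = comparable[i] & comparable[j]
            n_used = int(both.sum())
            if n_used < min_overlap:
                raise DistanceError(
                    f"pair ({taxa[i]!r}, {taxa[j]!r}): only {n_used} comparable "
                    f"columns (< min_overlap={min_overlap})"
                )
            p = float((mat[i][both] != mat[j][both]).sum()) / n_used
            if correction == "kimura":
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0:
                    logger.warning(
                        "pair (%r, %r): Kimura argument %.4f <= 0; capping at %s",
                        taxa[i],
                        taxa[j],
                        arg,
                        cap_value,
                    )
                    dist = cap_value
                else:
                    dist = -math.log(arg)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
            used[i, j] = used[j, i] = n_used
    return DistanceMatrix(taxa=taxa, d=d, n_sites_used=used)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build the unrooted NJ tree for a distance matrix (n >= 3)."""
    n0 = dm.n
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        node = dendropy.Node(taxon=tns.new_taxon(label))
        node.support = None
        nodes.append(node)
    # cluster tie-break label = smallest leaf label inside the cluster
    labels: list[str] = list(dm.taxa)
    d: list[list[float]] = [[float(x) for x in row] for row in dm.d]

    def _join(i: int, j: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        parent.support = None
        for child, limb in ((nodes[i], li), (nodes[j], lj)):
            child.raw_limb = limb
            child.edge.length = max(0.0, limb)
            parent.add_child(child)
        # replace i with the merged cluster, drop j
        new_label = min(labels[i], labels[j])
        new_row = [
            0.5 * (d[i][k] + d[j][k] - d[i][j])
            for k in range(len(labels))
        ]
        for k in range(len(labels)):
            d[i][k] = d[k][i] = new_row[k]
        d[i][i] = 0.0
        nodes[i] = parent
        labels[i] = new_label
        for row in d:
            del row[j]
        del d[j]
        del nodes[j]
        del labels[j]

    while len(labels) > 3:
        n = len(labels)
        r = [sum(row) for row in d]
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i][j] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i][j] - li
        _join(i, j, li, lj)

    # final trifurcation: closed-form limbs
    la = 0.5 * (d[0][1] + d[0][2] - d[1][2])
    lb = 0.5 * (d[0][1] + d[1][2] - d[0][2])
    lc = 0.5 * (d[0][2] + d[1][2] - d[0][1])
    seed = dendropy.Node()
    seed.support = None
    for node, limb in zip(nodes, (la, lb, lc)):
        node.raw_limb = limb
        node.edge.length = max(0.0, limb)
        seed.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def tree_bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions of an unrooted tree as label-set pairs."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        above = all_leaves - below
        if len(below) >= 2 and len(above) >= 2:
            bips.add(frozenset((below, above)))
    return bips


@dataclass
class BootstrapResult:
    """Main NJ tree plus per-bipartition bootstrap percentages."""

    main_tree: dendropy.Tree
    support: dict
    n_replicates: int
    seed: int


def bootstrap_nj(
    alignment: Alignment,
    n_replicates: int,
    seed: int,
    correction: str = "none",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_redraws: int = 100,
) -> BootstrapResult:
    """NJ with column-bootstrap supports on the main tree.

    Each replicate resamples ``n_columns`` columns with replacement;
    a replicate whose resampled columns leave some pair below
    *min_overlap* is redrawn (up to *max_redraws* attempts, then the
    run fails).  ``n_replicates = 0`` returns the main tree with all
    supports absent.
    """
    dm = protein_distance(alignment, correction, min_overlap=min_overlap)
    main = neighbor_joining(dm)
    main_bips = tree_bipartitions(main)
    counts = {bip: 0 for bip in main_bips}
    n_cols = alignment.n_columns
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        for attempt in range(max_redraws):
            idx = rng.integers(0, n_cols, size=n_cols)
            sub = alignment.take_columns(list(idx))
            try:
                rep_dm = protein_distance(sub, correction, min_overlap=min_overlap)
            except DistanceError:
                continue
            break
        else:
            raise DistanceError(
                f"replicate {rep}: no resampling with sufficient overlap "
                f"after {max_redraws} attempts"
            )
        rep_bips = tree_bipartitions(neighbor_joining(rep_dm))
        for bip in main_bips & rep_bips:
            counts[bip] += 1

    support: dict = {}
    if n_replicates > 0:
        support = {
            bip: 100.0 * c / n_replicates for bip, c in counts.items()
        }
    _attach_supports(main, support if n_replicates > 0 else {})
    return BootstrapResult(
        main_tree=main, support=support, n_replicates=n_replicates, seed=seed
    )


def _attach_supports(tree: dendropy.Tree, support: dict) -> None:
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        bip = frozenset((below, all_leaves - below))
        node.support = support.get(bip)
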