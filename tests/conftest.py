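"""Shared fixtures: toy alignments, gene tables, and tree generators."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from paralogon.formats import Alignment, GeneLocus, ProteinSequence

PARALEMMIN_PATTERN = "KX[KR]XXR[ED]XWL[ML]"


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four rows forming two clearly separated pairs."""
    return Alignment(
        [
            ProteinSequence("a1", "ACDEFGHIKLMNPQRSTVWY" * 3, species="sp1"),
            ProteinSequence("a2", "ACDEFGHIKLMNPQRSTVWY" * 3, species="sp2"),
            ProteinSequence("b1", "MNPQRSTVWYACDEFGHIKL" * 3, species="sp1"),
            ProteinSequence("b2", "MNPQRSTVWYACDEFGHIKW" * 3, species="sp2"),
        ]
    )


def make_locus(
    gene_id: str,
    chromosome: str = "chr1",
    start: int = 0,
    end: int = 10_000,
    strand: str = "+",
    family: str = "PALM",
    subtype: str = "",
    species: str = "Hsa",
) -> GeneLocus:
    return GeneLocus(
        gene_id=gene_id,
        species=species,
        chromosome=chromosome,
        start=start,
        end=end,
        strand=strand,
        family=family,
        subtype=subtype,
    )


def random_binary_tree(n: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random unrooted binary tree with strictly positive branch lengths."""
    tns = dendropy.TaxonNamespace([f"t{i:02d}" for i in range(n)])
    nodes = [dendropy.Node(taxon=tns.get_taxon(f"t{i:02d}")) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (j, i):
            child = nodes.pop(k)
            child.edge.length = float(rng.uniform(0.1, 2.0))
            parent.add_child(child)
        nodes.append(parent)
    seed = dendropy.Node()
    for child in nodes:
        child.edge.length = float(rng.uniform(0.1, 2.0))
        seed.add_child(child)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree):
    """Exact leaf-to-leaf path lengths — the additive-matrix oracle."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                lookup[taxa[i]], lookup[taxa[j]]
            )
    return taxa, d
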