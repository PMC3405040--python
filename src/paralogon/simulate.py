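"""Forward simulation of gene-order and sequence evolution under WGDs.

The generator replays the study's scenario: a single ancestral
chromosome carrying one gene per family is quadrupled in the basal
vertebrate tetraploidizations (``1R2R``, modeled as two back-to-back
doublings) and doubled again on the teleost stem (``3R``), with
per-copy gene loss immediately after each doubling, a smaller
per-branch loss rate thereafter, and optional translocations.  The
anchor family sits at the centre of the ancestral gene order so that
at the default 1 Mb intergene spacing every surviving same-chromosome
neighbor stays within the 5 Mb synteny window.

Protein sequences evolve along each family's gene genealogy by
per-site Poisson replacement (uniform over the 19 other residues) with
site-heterogeneous rates: planted motif columns are frozen, a
configurable fraction of sites is invariant, and the rest evolve at a
background rate — emulating near-invariant motifs embedded in
otherwise poorly conserved sequence.  An optional deletion-only indel
mode produces a gapped true alignment.

Everything emitted (gene tables, FASTA, alignments, species tree,
truth JSON, manifest) is a deterministic function of the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import motif as motif_mod
from .formats import GeneLocus, ProteinSequence, Alignment, write_fasta, write_gene_table
from .wgd import read_species_tree, write_species_tree

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Six-species vertebrate scaffold: three tetrapods, three teleosts,
#: 1R2R on the root branch, 3R on the teleost stem.  Branch lengths in
#: substitutions/site.
DEFAULT_SPECIES_TREE = (
    "(((Hsa:0.10,Mmu:0.10):0.10,Gga:0.20):0.15,"
    "((Dre:0.22,Ola:0.22):0.05,Gac:0.27)[&wgd=3R]:0.10)[&wgd=1R2R]:0.10;"
)

#: Ancestral gene order; the anchor family (PALM) is centred (index 3 of 7)
#: so every same-chromosome neighbor stays within the 5 Mb window.
DEFAULT_FAMILIES = ("PDG", "S1PR", "PRG", "PALM", "ABCA", "CNN", "PTBP")
DEFAULT_ANCHOR = "PALM"
DEFAULT_MOTIF = "KX[KR]XXR[ED]XWL[ML]"


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    family_names: tuple = DEFAULT_FAMILIES
    anchor_family: str = DEFAULT_ANCHOR
    intergene_spacing_bp: int = 1_000_000
    gene_length_bp: int = 10_000
    species_tree_newick: str = DEFAULT_SPECIES_TREE
    #: WGD mark -> number of back-to-back doublings
    wgd_doublings: dict = field(default_factory=lambda: {"1R2R": 2, "3R": 1})
    p_loss: float = 0.3
    p_loss_branch: float = 0.05
    p_transloc: float = 0.05
    guard_survival: bool = True
    seq_length: int = 300
    #: list of (window_start, phi_pattern_text) ultra-conserved plants
    motif_spec: tuple = ((40, DEFAULT_MOTIF),)
    p_invariant: float = 0.25
    background_rate: float = 1.0
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_loss", "p_loss_branch", "p_transloc", "p_invariant"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.intergene_spacing_bp <= 0:
            raise ConfigError("intergene_spacing_bp must be positive")
        if self.gene_length_bp <= 0:
            raise ConfigError("gene_length_bp must be positive")
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        if self.anchor_family not in self.family_names:
            raise ConfigError(
                f"anchor family {self.anchor_family!r} not in family_names"
            )
        if len(set(self.family_names)) != len(self.family_names):
            raise ConfigError("family_names must be unique")
        for start, text in self.motif_spec:
            pat = motif_mod.parse_phi_pattern(text)
            if not (0 <= start and start + len(pat) <= self.seq_length):
                raise ConfigError(
                    f"motif window [{start}, {start + len(pat)}) outside "
                    f"seq_length {self.seq_length}"
                )

    @property
    def n_families(self) -> int:
        return len(self.family_names)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["family_names"] = list(self.family_names)
        d["motif_spec"] = [list(m) for m in self.motif_spec]
        return d

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_jsonable().items() if k != "seed"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


class GNode:
    """Gene-genealogy node: epoch-labeled internal nodes, gene-id leaves."""

    __slots__ = ("children", "length", "epoch", "label", "alive")

    def __init__(self, epoch: str | None = None, length: float = 0.0):
        self.children: list[GNode] = []
        self.length = length
        self.epoch = epoch  # WGD mark, "speciation", or None for leaves
        self.label: str | None = None  # gene id at extant leaves
        self.alive = True

    def leaves(self) -> list:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        epoch = f"[&epoch={self.epoch}]" if self.epoch else ""
        return f"({inner}){epoch}:{self.length:.6f}"


class _Copy:
    """A live gene copy during the forward walk."""

    __slots__ = ("family", "copy_label", "node")

    def __init__(self, family: str, copy_label: str, node: GNode):
        self.family = family
        self.copy_label = copy_label
        self.node = node


@dataclass
class SimulationTruth:
    """Planted history: tables, genealogies, groups, and the event log."""

    config: SimulationConfig
    species_tree_newick: str
    #: species -> list[GeneLocus]
    gene_tables: dict
    #: family -> rooted newick over extant gene ids (epochs as comments)
    gene_trees: dict
    #: family -> list of retained duplication dicts {epoch, left, right}
    duplications: dict
    #: "family:copy_label" -> sorted gene ids
    ortholog_groups: dict
    events: list
    #: family -> GNode root of the pruned genealogy (not serialized)
    family_roots: dict = field(repr=False, default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "config": self.config.to_jsonable(),
            "config_hash": self.config.config_hash(),
            "species_tree": self.species_tree_newick,
            "gene_tables": {
                sp: [asdict(g) for g in loci]
                for sp, loci in sorted(self.gene_tables.items())
            },
            "gene_trees": dict(sorted(self.gene_trees.items())),
            "duplications": dict(sorted(self.duplications.items())),
            "ortholog_groups": dict(sorted(self.ortholog_groups.items())),
            "events": self.events,
        }


def simulate_history(config: SimulationConfig) -> SimulationTruth:
    """Walk the species tree root-to-leaves, replaying WGDs and losses."""
    rng = np.random.default_rng([config.seed % (2**31), 101])
    species_tree = read_species_tree(config.species_tree_newick, is_string=True)
    events: list = []

    roots = {fam: GNode() for fam in config.family_names}
    # genome: list of (chromosome_label, list[_Copy])
    genome0 = [
        (
            "0",
            [
                _Copy(fam, "0", _child_of(roots[fam], None))
                for fam in config.family_names
            ],
        )
    ]
    gene_tables: dict = {}
    # label internal species-tree nodes for the event log
    for i, node in enumerate(species_tree.preorder_node_iter()):
        node.sim_label = (
            node.taxon.label if node.is_leaf() else f"anc{i}"
        )

    def alive_counts(genome) -> dict:
        counts: dict = {fam: 0 for fam in config.family_names}
        for _, genes in genome:
            for g in genes:
                counts[g.family] += 1
        return counts

    def try_lose(genome, chrom_label, copy: _Copy, kind: str, where: str) -> bool:
        if config.guard_survival and alive_counts(genome)[copy.family] <= 1:
            return False
        copy.node.alive = False
        events.append(
            {
                "type": kind,
                "branch": where,
                "family": copy.family,
                "copy": copy.copy_label,
                "chromosome": chrom_label,
            }
        )
        return True

    def walk(sp_node, genome) -> None:
        edge_len = sp_node.edge.length or 0.0
        mark = getattr(sp_node, "wgd", None)
        where = sp_node.sim_label
        n_doublings = config.wgd_doublings.get(mark, 1) if mark else 0
        seg = edge_len / (n_doublings + 1)
        _extend(genome, seg)
        for _ in range(n_doublings):
            events.append({"type": "wgd", "branch": where, "mark": mark})
            new_genome = []
            for chrom_label, genes in genome:
                old_genes, new_genes = [], []
                for g in genes:
                    g.node.epoch = mark
                    c_old = _child_of(g.node, None)
                    c_new = _child_of(g.node, None)
                    old_genes.append(_Copy(g.family, g.copy_label + "0", c_old))
                    new_genes.append(_Copy(g.family, g.copy_label + "1", c_new))
                new_genome.append((chrom_label + "0", old_genes))
                new_genome.append((chrom_label + "1", new_genes))
            genome[:] = new_genome
            # per-copy loss on the new copies only
            for chrom_label, genes in genome:
                if not chrom_label.endswith("1"):
                    continue
                survivors = []
                for g in genes:
                    if rng.random() < config.p_loss and try_lose(
                        genome, chrom_label, g, "wgd_loss", where
                    ):
                        continue
                    survivors.append(g)
                genes[:] = survivors
            _extend(genome, seg)
        # per-branch background loss
        if config.p_loss_branch > 0:
            for chrom_label, genes in genome:
                survivors = []
                for g in genes:
                    if rng.random() < config.p_loss_branch and try_lose(
                        genome, chrom_label, g, "branch_loss", where
                    ):
                        continue
                    survivors.append(g)
                genes[:] = survivors
        # translocation
        if config.p_transloc > 0 and len(genome) > 1:
            for ci, (chrom_label, genes) in enumerate(genome):
                movers = [g for g in genes if rng.random() < config.p_transloc]
                for g in movers:
                    genes.remove(g)
                    targets = [k for k in range(len(genome)) if k != ci]
                    ti = int(targets[rng.integers(0, len(targets))])
                    t_label, t_genes = genome[ti]
                    pos = int(rng.integers(0, len(t_genes) + 1))
                    t_genes.insert(pos, g)
                    events.append(
                        {
                            "type": "transloc",
                            "branch": where,
                            "family": g.family,
                            "copy": g.copy_label,
                            "from": chrom_label,
                            "to": t_label,
                        }
                    )
        if sp_node.is_leaf():
            gene_tables[sp_node.sim_label] = _lay_out(
                sp_node.sim_label, genome, config
            )
            for _, genes in genome:
                for g in genes:
                    g.node.label = _gene_id(sp_node.sim_label, g)
            return
        kids = sp_node.child_nodes()
        for kid in kids:
            child_genome = []
            for chrom_label, genes in genome:
                child_genes = []
                for g in genes:
                    g.node.epoch = "speciation"
                    child_genes.append(
                        _Copy(g.family, g.copy_label, _child_of(g.node, None))
                    )
                child_genome.append((chrom_label, child_genes))
            walk(kid, child_genome)

    walk(species_tree.seed_node, genome0)

    gene_trees: dict = {}
    duplications: dict = {}
    ortholog_groups: dict = {}
    family_roots: dict = {}
    for fam in config.family_names:
        pruned = _prune(roots[fam])
        if pruned is None:
            raise RuntimeError(f"family {fam} went extinct (guard off?)")
        family_roots[fam] = pruned
        gene_trees[fam] = pruned.newick()
        duplications[fam] = _retained_duplications(pruned)
    for sp, loci in gene_tables.items():
        for g in loci:
            fam, copy_label = g.family, g.subtype.split("-", 1)[1]
            ortholog_groups.setdefault(f"{fam}:{copy_label}", []).append(g.gene_id)
    for key in ortholog_groups:
        ortholog_groups[key].sort()

    return SimulationTruth(
        config=config,
        species_tree_newick=write_species_tree(read_species_tree(config.species_tree_newick, is_string=True)).strip(),
        gene_tables=gene_tables,
        gene_trees=gene_trees,
        duplications=duplications,
        ortholog_groups=ortholog_groups,
        events=events,
        family_roots=family_roots,
    )


def _child_of(parent: GNode, epoch) -> GNode:
    child = GNode(epoch=epoch)
    parent.children.append(child)
    return child


def _extend(genome, dt: float) -> None:
    for _, genes in genome:
        for g in genes:
            g.node.length += dt


def _gene_id(species: str, copy: _Copy) -> str:
    return f"{species}_{copy.family}_{copy.copy_label}"


def _lay_out(species: str, genome, config: SimulationConfig) -> list:
    loci = []
    for chrom_label, genes in genome:
        for i, g in enumerate(genes):
            start = i * config.intergene_spacing_bp
            loci.append(
                GeneLocus(
                    gene_id=_gene_id(species, g),
                    species=species,
                    chromosome=f"chr{chrom_label}",
                    start=start,
                    end=start + config.gene_length_bp,
                    strand="+",
                    family=g.family,
                    subtype=f"{g.family}-{g.copy_label}",
                )
            )
    return loci


def _prune(node: GNode) -> GNode | None:
    """Drop dead lineages and suppress unifurcations; keep edge lengths."""
    if not node.children:
        return node if (node.alive and node.label is not None) else None
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    node.children = kept
    return node


def _retained_duplications(root: GNode) -> list:
    out = []

    def visit(node: GNode):
        if not node.children:
            return
        if node.epoch not in (None, "speciation") and len(node.children) >= 2:
            sides = [sorted(lf.label for lf in c.leaves()) for c in node.children]
            out.append(
                {"epoch": node.epoch, "left": sides[0], "right": sides[1]}
            )
        for c in node.children:
            visit(c)

    visit(root)
    return out


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _site_rates(config: SimulationConfig, rng) -> np.ndarray:
    rates = np.full(config.seq_length, config.background_rate)
    n_inv = int(round(config.p_invariant * config.seq_length))
    if n_inv:
        inv_idx = rng.choice(config.seq_length, size=n_inv, replace=False)
        rates[inv_idx] = 0.0
    for start, text in config.motif_spec:
        pat = motif_mod.parse_phi_pattern(text)
        for k, pos in enumerate(pat.positions):
            if not isinstance(pos, motif_mod.Wildcard):
                rates[start + k] = 0.0
    return rates


def _root_sequence(config: SimulationConfig, rng) -> np.ndarray:
    seq = rng.integers(0, 20, size=config.seq_length)
    for start, text in config.motif_spec:
        pat = motif_mod.parse_phi_pattern(text)
        for k, pos in enumerate(pat.positions):
            if isinstance(pos, motif_mod.Literal):
                seq[start + k] = AA20.index(pos.residue)
            elif isinstance(pos, motif_mod.Class):
                seq[start + k] = AA20.index(sorted(pos.residues)[0])
    return seq


def simulate_sequences(
    truth: SimulationTruth, config: SimulationConfig | None = None
) -> dict:
    """Evolve protein sequences along each family's genealogy.

    Returns ``{family: {"sequences": {gene_id: str}, "alignment": Alignment}}``.
    Without indels the true alignment is simply the stacked sequences;
    in deletion-only indel mode deleted stretches appear as gaps.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed % (2**31), 202])
    rates = _site_rates(config, rng)
    out: dict = {}
    for fam in config.family_names:
        root = truth.family_roots.get(fam)
        if root is None:
            raise ValueError(
                "truth lacks genealogy objects; regenerate via simulate_history"
            )
        root_seq = _root_sequence(config, rng)
        gapped: dict = {}

        def evolve(node: GNode, seq: np.ndarray) -> None:
            seq = seq.copy()
            t = node.length
            if t > 0:
                lam = rates * t
                hits = rng.poisson(lam)
                for site in np.nonzero(hits)[0]:
                    if seq[site] < 0:  # deleted
                        continue
                    for _ in range(int(hits[site])):
                        shift = int(rng.integers(1, 20))
                        seq[site] = (seq[site] + shift) % 20
                if config.indel_rate > 0:
                    n_del = rng.poisson(config.indel_rate * t)
                    for _ in range(int(n_del)):
                        length = int(rng.geometric(1.0 / config.indel_mean_len))
                        start = int(rng.integers(0, config.seq_length))
                        seq[start : start + length] = -1
            if not node.children:
                gapped[node.label] = seq
                return
            for c in node.children:
                evolve(c, seq)

        evolve(root, root_seq)
        # columns deleted in every extant row carry no signal; drop them so
        # the emitted true alignment satisfies the no-all-gap invariant
        arrs = dict(sorted(gapped.items()))
        stacked = np.stack(list(arrs.values()))
        keep = ~(stacked < 0).all(axis=0)
        seqs = {
            gid: "".join(AA20[v] if v >= 0 else "-" for v in arr[keep])
            for gid, arr in arrs.items()
        }
        rows = [
            ProteinSequence(
                id=gid,
                residues=s,
                species=gid.split("_", 1)[0],
            )
            for gid, s in seqs.items()
        ]
        alignment = Alignment(rows) if len(rows) >= 2 else None
        out[fam] = {
            "sequences": {gid: s.replace("-", "") for gid, s in seqs.items()},
            "alignment": alignment,
        }
    return out


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def emit_dataset(
    truth: SimulationTruth,
    sequences: dict,
    out_dir: str | Path,
    force: bool = False,
) -> dict:
    """Write every pipeline input format plus truth and manifest files.

    Refuses a non-empty output directory unless *force* is set.
    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    files: list = []

    for sp, loci in sorted(truth.gene_tables.items()):
        p = out / f"genes_{sp}.tsv"
        write_gene_table(loci, p)
        files.append(p.name)
    for fam, data in sorted(sequences.items()):
        p = out / f"seqs_{fam}.fasta"
        write_fasta(
            [
                ProteinSequence(id=gid, residues=s, species=gid.split("_", 1)[0])
                for gid, s in sorted(data["sequences"].items())
            ],
            p,
        )
        files.append(p.name)
        if data["alignment"] is not None:
            p = out / f"aln_{fam}.fasta"
            write_fasta(data["alignment"].rows, p)
            files.append(p.name)
    for fam, nwk in sorted(truth.gene_trees.items()):
        p = out / f"genetree_{fam}.nwk"
        p.write_text(nwk + "\n")
        files.append(p.name)
    p = out / "species_tree.nwk"
    p.write_text(truth.species_tree_newick + "\n")
    files.append(p.name)
    p = out / "truth.json"
    p.write_text(json.dumps(truth.to_jsonable(), indent=1, sort_keys=True) + "\n")
    files.append(p.name)
    manifest = {
        "seed": truth.config.seed,
        "config_hash": truth.config.config_hash(),
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def simulate_dataset(config: SimulationConfig, out_dir: str | Path | None = None, force: bool = False):
    """Convenience wrapper: history + sequences (+ optional emission)."""
    truth = simulate_history(config)
    seqs = simulate_sequences(truth, config)
    if out_dir is not None:
        emit_dataset(truth, seqs, out_dir, force=force)
    return truth, seqs
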