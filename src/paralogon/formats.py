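"""Domain types and file formats shared by the whole pipeline.

Every interval in this package is 0-based half-open, measured in base
pairs; megabase presentation values must be converted before they enter
a :class:`GeneLocus`.  Protein sequences use the 20 standard amino-acid
letters plus ``X`` for an unknown residue; ``-`` is the gap character
and may appear only in alignment rows.

Formats handled here:

* FASTA (sequences and aligned FASTA) — via Biopython
* Clustal alignments — read-only, via Biopython
* Newick trees — via dendropy; bootstrap supports are read from either
  internal-node labels (``(a,b)90:1``) or ``[&support=90]`` comments and
  always written back in the node-label dialect
* gene tables — TSV with header
  ``gene_id species chromosome start end strand family subtype``
* transcript tables — TSV with header
  ``transcript_id species chromosome strand blocks`` where *blocks* is
  ``start-end,start-end,...``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}
GAP = "-"

GENE_TABLE_COLUMNS = (
    "gene_id",
    "species",
    "chromosome",
    "start",
    "end",
    "strand",
    "family",
    "subtype",
)
TRANSCRIPT_TABLE_COLUMNS = (
    "transcript_id",
    "species",
    "chromosome",
    "strand",
    "blocks",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------


@dataclass
class ProteinSequence:
    """A protein sequence with a species tag.

    ``residues`` is restricted to the 20 amino-acid letters plus ``X``;
    alignment rows may additionally contain ``-``.
    """

    id: str
    residues: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: empty residues")
        allowed = EXTENDED_ALPHABET | {GAP}
        bad = set(self.residues) - allowed
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: illegal residue character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """A multiple protein alignment: equal-length gapped rows."""

    rows: list[ProteinSequence]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("alignment row ids are not unique")
        for j in range(self.n_columns):
            if all(r.residues[j] == GAP for r in self.rows):
                raise FormatError(f"alignment column {j} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        """Alignment restricted to (possibly repeated) column indices.

        Used by the bootstrap; all-gap columns cannot arise because the
        source columns each carry at least one residue.
        """
        rows = [
            ProteinSequence(
                id=r.id,
                residues="".join(r.residues[j] for j in indices),
                species=r.species,
                description=r.description,
            )
            for r in self.rows
        ]
        return Alignment(rows)


def _species_from_description(rec_id: str, description: str) -> str:
    # convention: "id species=Hsa ..." in the description, else blank
    for token in description.split():
        if token.startswith("species="):
            return token.split("=", 1)[1]
    return ""


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein FASTA; ids are the first whitespace token of the header.

    Raises :class:`FormatError` on duplicate ids (naming the id) or on an
    illegal residue character (naming the line).
    """
    path = Path(path)
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - EXTENDED_ALPHABET
        if bad:
            line = _find_offending_line(path, rec.id, bad)
            raise FormatError(
                f"{path}:{line}: illegal residue character(s) "
                f"{''.join(sorted(bad))!r} in sequence {rec.id!r}"
            )
        seqs.append(
            ProteinSequence(
                id=rec.id,
                residues=residues,
                species=_species_from_description(rec.id, rec.description),
                description=rec.description,
            )
        )
    return seqs


def _find_offending_line(path: Path, seq_id: str, bad: set[str]) -> int:
    in_record = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == seq_id if line[1:].split() else False
            continue
        if in_record and (set(line.strip().upper()) & bad):
            return lineno
    return 0


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id
            if s.species and "species=" not in s.description:
                header += f" species={s.species}"
            elif s.description:
                header += f" {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an alignment from aligned FASTA or Clustal (``fmt='clustal'``)."""
    msa = AlignIO.read(str(path), fmt)
    rows = []
    for rec in msa:
        rows.append(
            ProteinSequence(
                id=rec.id,
                residues=str(rec.seq).upper(),
                species=_species_from_description(rec.id, rec.description),
                description=rec.description if rec.description != rec.id else "",
            )
        )
    return Alignment(rows)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    write_fasta(alignment.rows, path)


# ---------------------------------------------------------------------------
# gene and transcript tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    """One gene on a chromosome/scaffold, 0-based half-open coordinates."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    family: str
    subtype: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


GeneTable = list  # list[GeneLocus]; alias for readability in signatures


def _parse_coord(text: str, what: str, row: int) -> int:
    if "." in text:
        raise FormatError(
            f"row {row}: {what} {text!r} looks like a megabase decimal; "
            "coordinates must be integer base pairs"
        )
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"row {row}: cannot parse {what} {text!r}") from exc


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read the 8-column TSV gene-table dialect.

    Errors carry the 1-based data-row number.  A header-only file yields
    an empty table with a logged warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (missing header)")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != GENE_TABLE_COLUMNS:
        raise FormatError(
            f"{path}: bad header {header!r}; expected {GENE_TABLE_COLUMNS!r}"
        )
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    for row, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(GENE_TABLE_COLUMNS):
            raise FormatError(
                f"{path} row {row}: expected {len(GENE_TABLE_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        gene_id, species, chromosome, start, end, strand, family, subtype = fields
        if gene_id in seen:
            raise FormatError(f"{path} row {row}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            locus = GeneLocus(
                gene_id=gene_id,
                species=species,
                chromosome=chromosome,
                start=_parse_coord(start, "start", row),
                end=_parse_coord(end, "end", row),
                strand=strand,
                family=family,
                subtype=subtype,
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {row}: {exc}") from exc
        loci.append(locus)
    if not loci:
        logger.warning("%s: header-only gene table (no loci)", path)
    return loci


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in loci:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.species,
                        g.chromosome,
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.family,
                        g.subtype,
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class TranscriptAlignment:
    """An EST/transcript aligned to the genome as sorted, disjoint blocks."""

    transcript_id: str
    species: str
    chromosome: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"transcript {self.transcript_id!r}: unknown strand {self.strand!r}"
            )
        if not self.blocks:
            raise FormatError(f"transcript {self.transcript_id!r}: no blocks")
        prev_end = -1
        for s, e in self.blocks:
            if not (0 <= s < e):
                raise FormatError(
                    f"transcript {self.transcript_id!r}: invalid block [{s}, {e})"
                )
            if s < prev_end:
                raise FormatError(
                    f"transcript {self.transcript_id!r}: blocks overlap or unsorted"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])


def read_transcript_table(path: str | Path) -> list[TranscriptAlignment]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (missing header)")
    header = tuple(lines[0].split("\t"))
    if header != TRANSCRIPT_TABLE_COLUMNS:
        raise FormatError(
            f"{path}: bad header {header!r}; expected {TRANSCRIPT_TABLE_COLUMNS!r}"
        )
    out: list[TranscriptAlignment] = []
    for row, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(TRANSCRIPT_TABLE_COLUMNS):
            raise FormatError(
                f"{path} row {row}: expected {len(TRANSCRIPT_TABLE_COLUMNS)} fields"
            )
        tid, species, chromosome, strand, blocks_text = fields
        blocks = []
        for part in blocks_text.split(","):
            try:
                s, e = part.split("-")
                blocks.append((_parse_coord(s, "block start", row), _parse_coord(e, "block end", row)))
            except ValueError as exc:
                raise FormatError(
                    f"{path} row {row}: cannot parse block {part!r}"
                ) from exc
        try:
            out.append(
                TranscriptAlignment(
                    transcript_id=tid,
                    species=species,
                    chromosome=chromosome,
                    strand=strand,
                    blocks=tuple(blocks),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {row}: {exc}") from exc
    return out


def write_transcript_table(
    transcripts: Iterable[TranscriptAlignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRANSCRIPT_TABLE_COLUMNS) + "\n")
        for t in transcripts:
            blocks = ",".join(f"{s}-{e}" for s, e in t.blocks)
            fh.write(
                "\t".join([t.transcript_id, t.species, t.chromosome, t.strand, blocks])
                + "\n"
            )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _extract_support(node: dendropy.Node) -> float | None:
    """Support from a node label or a [&support=..] comment, if any."""
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    val = node.annotations.get_value("support")
    if val is not None:
        return float(val)
    for comment in list(node.comments) + list(node.edge.comments):
        try:
            return float(comment)
        except (TypeError, ValueError):
            continue
    return None


def read_newick(
    source: str | Path, *, is_string: bool = False, rooted: bool | None = None
) -> dendropy.Tree:
    """Parse a Newick tree.

    Bootstrap supports are accepted either as internal-node labels or as
    ``[&support=...]`` / bare-number comments; they are normalized onto
    ``node.support`` (float in [0, 100] or None).  Other ``[&key=value]``
    comments (e.g. ``wgd``) survive as dendropy annotations.
    """
    text = source if is_string else Path(source).read_text()
    _check_balanced(text)
    kwargs = {}
    if rooted is True:
        kwargs["rooting"] = "force-rooted"
    elif rooted is False:
        kwargs["rooting"] = "force-unrooted"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            **kwargs,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("newick tree has duplicate leaf labels")
    for node in tree:
        support = None
        if not node.is_leaf():
            support = _extract_support(node)
            if support is not None and not (0.0 <= support <= 100.0):
                raise FormatError(f"support {support} outside [0, 100]")
        node.support = support
        if node.edge.length is not None and node.edge.length < -1e-12:
            raise FormatError(
                f"negative branch length {node.edge.length} in newick input"
            )
    return tree


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced parentheses at character {offset}")
    if depth != 0:
        raise FormatError(
            f"unbalanced parentheses: {depth} unclosed at end of input"
        )


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize in the node-label support dialect, lengths to 6 decimals.

    Returns the Newick string; writes it to *path* when given.
    """
    clone = tree.clone(depth=1)
    for node in clone:
        if not node.is_leaf():
            support = getattr(node, "support", None)
            node.label = (
                format_number(support) if support is not None else None
            )
        node.annotations.clear()
        node.edge.annotations.clear()
        node.comments.clear() if isinstance(node.comments, list) else None
        if node.edge.length is not None:
            node.edge.length = round(float(node.edge.length), 6)
    text = clone.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def format_number(x: float) -> str:
    """Render 90.0 as '90' but keep genuine decimals."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted symmetric (Robinson–Foulds) distance between two trees.

    The trees are re-read onto a shared taxon namespace so callers may
    pass trees from independent sources.
    """
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)
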