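"""Domain types and file IO shared by every pipeline stage.

The screen works on four kinds of on-disk artifacts, all plain text:

* FASTA            — gene sequences (nucleotide or amino acid),
* gene-table TSV   — one row per annotated gene (coordinates, strand, COG),
* taxonomy TSV     — one row per genome, ranked lineage plus a focal flag,
* Newick           — species and per-gene trees, with integer bootstrap
                     percentages carried as internal-node labels.

Loading is all-or-nothing: a file either satisfies the type invariants or
raises, so no stage ever sees a partially valid dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger("hgtscreen")

#: Single-letter functional classes of the Clusters of Orthologous Groups scheme.
COG_CATEGORIES = frozenset("BCDEFGHIJKLMNOPQRSTUV")

#: Sentinel for genes whose COG class is absent or unrecognized.
COG_UNKNOWN = "unknown"

NUCLEOTIDE_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class ParseError(ValueError):
    """A text input violated its format or a type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One annotated gene of one genome.

    Coordinates are 1-based and inclusive at both ends (GFF convention).
    ``sequence`` may be empty until sequences are attached from FASTA.
    """

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    cog_category: str = COG_UNKNOWN
    product: str = ""
    sequence: str = ""

    def validate(self, require_sequence: bool = False) -> "GeneRecord":
        if not self.gene_id:
            raise ParseError("gene_id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise ParseError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.cog_category != COG_UNKNOWN and self.cog_category not in COG_CATEGORIES:
            raise ParseError(f"gene {self.gene_id!r}: bad COG category {self.cog_category!r}")
        if require_sequence and not self.sequence:
            raise ParseError(f"gene {self.gene_id!r}: sequence missing")
        return self


@dataclass(frozen=True)
class TaxonLineage:
    """Ranked taxonomy of one genome; the reference frame for "interphylum"."""

    genome_id: str
    phylum: str
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    is_focal: bool = False

    def validate(self) -> "TaxonLineage":
        if not self.genome_id:
            raise ParseError("genome_id must be non-empty")
        if not self.phylum:
            raise ParseError(f"genome {self.genome_id!r}: phylum must be non-empty")
        return self

    def rank(self, name: str) -> str:
        return getattr(self, "class_" if name == "class" else name)


class GeneTree:
    """Leaf-labeled phylogeny with branch lengths and optional bootstrap supports.

    Thin wrapper around a :class:`dendropy.Tree`.  Supports are integer
    percentages in [0, 100] attached to *edges* (``edge.support``) so they
    survive rerooting; on writing they appear as internal-node labels, the
    convention used for bootstrap percentages throughout phylogenetics.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool | None = None):
        self.tree = tree
        if rooted is not None:
            tree.is_rooted = rooted
        self.uninformative = False  # set when built from a signal-free alignment

    # -- basic accessors ----------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def is_rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def validate(self) -> "GeneTree":
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ParseError("duplicate leaf labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ParseError(f"negative branch length {edge.length} in tree")
            sup = getattr(edge, "support", None)
            if sup is not None and not (0 <= sup <= 100):
                raise ParseError(f"support {sup} outside [0, 100]")
        return self

    def clone(self) -> "GeneTree":
        out = GeneTree(parse_newick(write_newick(self)).tree, rooted=self.is_rooted)
        out.uninformative = self.uninformative
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneTree({write_newick(self)})"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    Sequences are uppercased; record order is preserved.  Malformed headers,
    empty sequences and duplicate ids raise :class:`ParseError` naming the
    offending line.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for {header!r} (header at line {header_line})")
        if header in seen:
            raise ParseError(f"{path}: duplicate sequence id {header!r} (line {line_no})")
        seen.add(header)
        records.append((header, seq))
        header, chunks = None, []

    line_no = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}: malformed FASTA header at line {line_no}")
                header, header_line = name, line_no
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence data before any header at line {line_no}")
                chunks.append(line.upper())
        flush(line_no)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed line wrapping."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene-table TSV
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "genome_id", "contig", "start", "end", "strand", "cog_category", "product"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the simplified gene-table TSV (sequences come separately from FASTA).

    Rows failing the GeneRecord invariants are rejected with their row number.
    An unrecognized COG letter is demoted to ``unknown`` with a logged warning
    rather than rejected, since annotations routinely carry nonstandard codes.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _GENE_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: gene table missing columns {missing}")
        idx = {c: header.index(c) for c in _GENE_COLUMNS}
        for row_no, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise ParseError(f"{path}: row {row_no}: expected {len(header)} fields, got {len(parts)}")
            try:
                cog = parts[idx["cog_category"]]
                if cog not in COG_CATEGORIES:
                    if cog not in ("", "-", COG_UNKNOWN):
                        logger.warning("%s row %d: unknown COG category %r treated as unknown", path, row_no, cog)
                    cog = COG_UNKNOWN
                rec = GeneRecord(
                    gene_id=parts[idx["gene_id"]],
                    genome_id=parts[idx["genome_id"]],
                    contig=parts[idx["contig"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    strand=parts[idx["strand"]],
                    cog_category=cog,
                    product=parts[idx["product"]],
                ).validate()
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path}: row {row_no}: {exc}") from exc
            if rec.gene_id in seen:
                raise ParseError(f"{path}: row {row_no}: duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            records.append(rec)
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.gene_id, r.genome_id, r.contig, str(r.start), str(r.end), r.strand, r.cog_category, r.product]
                )
                + "\n"
            )


def attach_sequences(records: Sequence[GeneRecord], fasta: Iterable[tuple[str, str]]) -> list[GeneRecord]:
    """Join gene records with their sequences (FASTA keyed by gene_id)."""
    seqs = dict(fasta)
    out = []
    for r in records:
        if r.gene_id not in seqs:
            raise ParseError(f"no sequence for gene {r.gene_id!r}")
        out.append(replace(r, sequence=seqs[r.gene_id]).validate(require_sequence=True))
    return out


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------

_TAX_COLUMNS = ["genome_id", "phylum", "class", "order", "family", "genus", "species", "is_focal"]


def read_taxonomy(path: str | Path, require_focal: bool = True) -> dict[str, TaxonLineage]:
    """Read the taxonomy TSV into a ``genome_id -> TaxonLineage`` map.

    Exactly one genome must be flagged focal unless ``require_focal=False``.
    """
    lineages: dict[str, TaxonLineage] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TAX_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: taxonomy missing columns {missing}")
        idx = {c: header.index(c) for c in _TAX_COLUMNS}
        for row_no, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            lin = TaxonLineage(
                genome_id=parts[idx["genome_id"]],
                phylum=parts[idx["phylum"]],
                class_=parts[idx["class"]],
                order=parts[idx["order"]],
                family=parts[idx["family"]],
                genus=parts[idx["genus"]],
                species=parts[idx["species"]],
                is_focal=parts[idx["is_focal"]].strip().lower() in ("1", "true", "yes"),
            ).validate()
            if lin.genome_id in lineages:
                raise ParseError(f"{path}: row {row_no}: duplicate genome_id {lin.genome_id!r}")
            lineages[lin.genome_id] = lin
    n_focal = sum(l.is_focal for l in lineages.values())
    if require_focal and n_focal != 1:
        raise ParseError(f"{path}: expected exactly one focal genome, found {n_focal}")
    return lineages


def write_taxonomy(lineages: Iterable[TaxonLineage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TAX_COLUMNS) + "\n")
        for l in lineages:
            fh.write(
                "\t".join(
                    [l.genome_id, l.phylum, l.class_, l.order, l.family, l.genus, l.species,
                     "true" if l.is_focal else "false"]
                )
                + "\n"
            )


def check_taxonomy_covers(genes: Sequence[GeneRecord], taxonomy: Mapping[str, TaxonLineage]) -> None:
    """Every genome seen in a gene table must have a lineage."""
    missing = sorted({g.genome_id for g in genes} - set(taxonomy))
    if missing:
        raise ParseError(f"genomes missing from taxonomy: {missing}")


def focal_genome(taxonomy: Mapping[str, TaxonLineage]) -> TaxonLineage:
    focal = [l for l in taxonomy.values() if l.is_focal]
    if len(focal) != 1:
        raise ParseError(f"expected exactly one focal genome, found {len(focal)}")
    return focal[0]


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def parse_newick(text: str, rooted: bool | None = None) -> GeneTree:
    """Parse a Newick string; integer internal-node labels become edge supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is not None:
            try:
                node.edge.support = int(node.label)
            except ValueError:
                pass  # non-numeric internal label; keep as plain label
            else:
                node.label = None
    gt = GeneTree(tree, rooted=rooted)
    return gt.validate()


def _format_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _newick_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        part = node.taxon.label
    else:
        children = ",".join(_newick_node(c) for c in node.child_nodes())
        sup = getattr(node.edge, "support", None)
        label = str(int(sup)) if sup is not None else (node.label or "")
        part = f"({children}){label}"
    if node.edge.length is not None:
        part += f":{_format_length(node.edge.length)}"
    return part


def write_newick(tree: GeneTree) -> str:
    """Serialize with stable float formatting (round-trips lengths to 1e-9)."""
    return _newick_node(tree.tree.seed_node) + ";"


def write_newick_file(tree: GeneTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(write_newick(tree) + "\n")


def read_newick_file(path: str | Path, rooted: bool | None = None) -> GeneTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read(), rooted=rooted)
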