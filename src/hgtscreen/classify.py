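"""Sister-clade HGT calling and donor attribution.

For each rooted gene tree the focal gene's nearest neighbor is its sister
clade: the other daughter of the node where the focal tips attach.  The
sister's taxonomy decides the verdict:

* any focal-phylum genome in the sister    -> ``vertical``
* one foreign phylum, adequate support     -> ``interphylum_transfer``
* mixed foreign phyla or weak support      -> ``ambiguous`` (the "Other"
  class of the source breakdown)
* no usable tree or no sister              -> ``no_tree``

Donor attribution refines phylum -> class -> genus, each rank filled only
when every sister leaf agrees (unanimity, not majority).  Aggregation then
produces the per-source counts and the COG-category-by-source-phylum
crosstab that summarize a genome-wide screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import COG_UNKNOWN, GeneRecord, GeneTree, TaxonLineage

STATUSES = ("vertical", "interphylum_transfer", "ambiguous", "no_tree")


@dataclass
class HGTCall:
    """Per-gene verdict of the transfer screen."""

    gene_id: str
    status: str
    donor_phylum: str | None = None
    donor_class: str | None = None
    donor_genus: str | None = None
    sister_leaf_count: int = 0
    support: int | None = None
    n_focal_tips: int = 1

    def validate(self) -> "HGTCall":
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.status != "interphylum_transfer" and self.donor_phylum is not None:
            raise ValueError("donor fields only allowed on interphylum_transfer calls")
        if self.status == "no_tree" and self.sister_leaf_count != 0:
            raise ValueError("no_tree calls cannot have sister leaves")
        return self


@dataclass
class SourceAttributionTable:
    """Counts of interphylum calls by donor taxon, plus the ambiguous tally."""

    phylum_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[tuple[str, str], int] = field(default_factory=dict)  # (phylum, class) -> n
    genus_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    status_totals: dict[str, int] = field(default_factory=dict)
    n_other: int = 0  # ambiguous donors ("Other" in the source breakdown)

    def to_json_dict(self) -> dict:
        return {
            "phylum": dict(sorted(self.phylum_counts.items())),
            "class": {f"{p}/{c}": n for (p, c), n in sorted(self.class_counts.items())},
            "genus": {f"{p}/{c}/{g}": n for (p, c, g), n in sorted(self.genus_counts.items())},
            "status_totals": dict(sorted(self.status_totals.items())),
            "other": self.n_other,
        }


# ---------------------------------------------------------------------------
# Sister clade
# ---------------------------------------------------------------------------


def _edge_support(node) -> int | None:
    sup = getattr(node.edge, "support", None)
    return int(sup) if sup is not None else None


def sister_clade(tree: GeneTree, focal_leaves: set[str]) -> tuple[set[str], int | None]:
    """The focal tips' nearest-neighbor leaves in the rooted gene tree.

    Let M be the smallest clade containing every focal leaf.  If M is
    exactly the focal set, the sister is the other daughter(s) of M's
    parent; if M also contains foreign leaves (focal copies are not
    monophyletic), those intermingled foreign leaves are returned instead.
    The support is the bootstrap percentage of the node certifying the
    relationship, when bootstrap was run.
    """
    if not focal_leaves:
        raise ValueError("focal_leaves must be non-empty")
    # an unrooted tree is interpreted with its seed node as root; leaving the
    # flag unset would let dendropy collapse the basal bifurcation during
    # MRCA lookup and silently drop the node carrying the sister support
    tree.tree.is_rooted = True
    labels = set(tree.leaf_labels())
    missing = focal_leaves - labels
    if missing:
        raise ValueError(f"focal leaves absent from tree: {sorted(missing)}")

    if len(focal_leaves) == 1:
        (label,) = focal_leaves
        mrca = next(lf for lf in tree.tree.leaf_node_iter() if lf.taxon.label == label)
    else:
        mrca = tree.tree.mrca(taxon_labels=sorted(focal_leaves))
    under = {lf.taxon.label for lf in mrca.leaf_iter()}

    if under == focal_leaves:
        parent = mrca.parent_node
        if parent is None:
            return set(), None  # focal tips are the whole tree
        sister = {
            lf.taxon.label
            for child in parent.child_nodes()
            if child is not mrca
            for lf in child.leaf_iter()
        }
        if parent.parent_node is not None:
            support = _edge_support(parent)
        else:
            support = _edge_support(mrca)  # at the root both child edges carry the same split
        return sister, support
    # focal copies non-monophyletic: the foreign leaves sharing their clade
    return under - focal_leaves, _edge_support(mrca)


# ---------------------------------------------------------------------------
# Per-gene and per-genome classification
# ---------------------------------------------------------------------------


def _unanimous(values: Sequence[str]) -> str | None:
    vals = {v for v in values}
    if len(vals) == 1 and "" not in vals:
        return next(iter(vals))
    return None


def classify_gene(
    tree: GeneTree | None,
    focal_leaves: set[str],
    taxonomy: Mapping[str, TaxonLineage],
    genome_of: Mapping[str, str],
    focal_phylum: str,
    min_support: int = 0,
    gene_id: str | None = None,
) -> HGTCall:
    """Apply the sister-clade decision rule to one gene tree."""
    gid = gene_id or (min(focal_leaves) if focal_leaves else "?")
    if tree is None:
        return HGTCall(gene_id=gid, status="no_tree", n_focal_tips=max(1, len(focal_leaves))).validate()

    sister, support = sister_clade(tree, focal_leaves)
    n_focal = len(focal_leaves)
    if not sister:
        return HGTCall(gene_id=gid, status="no_tree", n_focal_tips=n_focal).validate()

    lineages = []
    for leaf in sorted(sister):
        genome = genome_of.get(leaf)
        if genome is None or genome not in taxonomy:
            raise KeyError(f"no taxonomy for sister leaf {leaf!r}")
        lineages.append(taxonomy[genome])

    common = dict(
        sister_leaf_count=len(sister),
        support=support,
        n_focal_tips=n_focal,
        gene_id=gid,
    )
    phyla = {l.phylum for l in lineages}
    if focal_phylum in phyla:
        return HGTCall(status="vertical", **common).validate()
    if len(phyla) > 1:
        return HGTCall(status="ambiguous", **common).validate()
    if support is not None and support < min_support:
        return HGTCall(status="ambiguous", **common).validate()
    donor_phylum = next(iter(phyla))
    donor_class = _unanimous([l.class_ for l in lineages])
    donor_genus = _unanimous([l.genus for l in lineages]) if donor_class is not None else None
    return HGTCall(
        status="interphylum_transfer",
        donor_phylum=donor_phylum,
        donor_class=donor_class,
        donor_genus=donor_genus,
        **common,
    ).validate()


def classify_genome(
    gene_trees: Sequence[tuple[str, GeneTree | None, set[str]]],
    taxonomy: Mapping[str, TaxonLineage],
    genome_of: Mapping[str, str],
    focal_phylum: str,
    min_support: int = 0,
) -> tuple[list[HGTCall], dict[str, float]]:
    """Classify every gene; returns calls plus the interphylum fractions.

    ``fraction_of_trees`` divides by genes with a usable tree (the primary
    denominator); ``fraction_of_genes`` divides by all genes screened.
    """
    if not gene_trees:
        raise ValueError("no genes to classify")
    calls = [
        classify_gene(tree, focal, taxonomy, genome_of, focal_phylum, min_support, gene_id=gid)
        for gid, tree, focal in gene_trees
    ]
    n_total = len(calls)
    n_with_tree = sum(1 for c in calls if c.status != "no_tree")
    n_inter = sum(1 for c in calls if c.status == "interphylum_transfer")
    fractions = {
        "fraction_of_trees": n_inter / n_with_tree if n_with_tree else 0.0,
        "fraction_of_genes": n_inter / n_total,
    }
    return calls, fractions


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def attribute_sources(calls: Sequence[HGTCall]) -> SourceAttributionTable:
    """Tally interphylum calls by donor phylum / class / genus; ambiguous
    calls go to the "Other" bucket."""
    table = SourceAttributionTable()
    for status in STATUSES:
        table.status_totals[status] = 0
    for call in calls:
        table.status_totals[call.status] += 1
        if call.status == "ambiguous":
            table.n_other += 1
        if call.status != "interphylum_transfer":
            continue
        p = call.donor_phylum
        table.phylum_counts[p] = table.phylum_counts.get(p, 0) + 1
        if call.donor_class is not None:
            key = (p, call.donor_class)
            table.class_counts[key] = table.class_counts.get(key, 0) + 1
            if call.donor_genus is not None:
                gkey = (p, call.donor_class, call.donor_genus)
                table.genus_counts[gkey] = table.genus_counts.get(gkey, 0) + 1
    return table


def cog_crosstab(
    calls: Sequence[HGTCall],
    gene_table: Sequence[GeneRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """COG category x source phylum matrix over interphylum calls.

    Returns raw counts and per-category relative abundances (each nonzero
    row sums to 1).  Genes without a recognized COG letter are tallied under
    ``unknown``.
    """
    cog_of = {g.gene_id: g.cog_category for g in gene_table}
    cells: dict[tuple[str, str], int] = {}
    for call in calls:
        if call.status != "interphylum_transfer":
            continue
        if call.gene_id not in cog_of:
            raise KeyError(f"gene {call.gene_id!r} missing from gene table")
        cat = cog_of[call.gene_id] or COG_UNKNOWN
        key = (cat, call.donor_phylum)
        cells[key] = cells.get(key, 0) + 1
    if not cells:
        empty = pd.DataFrame(dtype=float)
        return empty, empty.copy()
    cats = sorted({k[0] for k in cells})
    phyla = sorted({k[1] for k in cells})
    counts = pd.DataFrame(0, index=cats, columns=phyla, dtype=int)
    for (cat, phy), n in cells.items():
        counts.loc[cat, phy] = n
    row_sums = counts.sum(axis=1)
    rel = counts.div(row_sums.where(row_sums > 0, 1), axis=0).astype(float)
    counts.index.name = rel.index.name = "cog_category"
    counts.columns.name = rel.columns.name = "source_phylum"
    return counts, rel
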