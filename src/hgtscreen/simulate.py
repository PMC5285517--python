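"""Gene-family evolution simulator with known interphylum transfer events.

The screen's inference — "this gene's nearest neighbor in its tree sits in a
foreign phylum, so it was probably acquired horizontally" — can only be
validated against data where the transfers are known.  This module generates
such data:

* a labeled, ultrametric birth–death species tree spanning several phyla,
  with the focal organism in a small, deep-branching phylum of its own
  (mirroring the isolation of a Deferribacteres-like lineage among gut
  bacteria);
* per-family gene trees that follow the species tree except that, with a
  stated probability, the focal tip is pruned and regrafted inside a foreign
  phylum (replacing transfer), with the event recorded as ground truth;
* gapless sequences evolved site-independently along each gene tree under
  JC69 or K2P with exact transition probabilities.

Every output is a pure function of the :class:`SimConfig`, so reruns are
byte-identical.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .core import (
    COG_CATEGORIES,
    GeneRecord,
    GeneTree,
    TaxonLineage,
    parse_newick,
    write_fasta,
    write_gene_table,
    write_newick,
    write_newick_file,
    write_taxonomy,
)

#: Relative depths (fractions of total tree height) at which the species tree
#: is cut to assign each sub-phylum rank.  Deeper cut => finer rank.
RANK_CUT_FRACTIONS = {"class": 0.45, "order": 0.60, "family": 0.72, "genus": 0.84}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    ``tree_depth`` is the root-to-tip height of the species tree in expected
    substitutions per site; 0.5 gives moderately diverged families whose
    trees are comfortably reconstructable at a few hundred sites.
    ``focal_clade_size`` is the number of genomes in the focal phylum
    (focal organism plus its relatives); 1 makes the focal tip the sole
    member of its phylum.
    """

    n_taxa: int = 40
    n_phyla: int = 4
    n_families: int = 200
    p_transfer: float = 0.25
    seq_length: int = 400
    subst_model: str = "JC69"
    kappa: float = 2.0
    seed: int = 0
    tree_depth: float = 0.5
    focal_clade_size: int = 3
    rate_sigma: float = 0.25

    def validate(self) -> "SimConfig":
        if self.n_taxa < 8:
            raise ValueError("n_taxa must be >= 8")
        if self.n_phyla < 2:
            raise ValueError("n_phyla must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.p_transfer <= 1.0:
            raise ValueError("p_transfer must be in [0, 1]")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50 (shorter alignments give unstable trees)")
        if self.subst_model not in ("JC69", "K2P"):
            raise ValueError(f"subst_model must be JC69 or K2P, got {self.subst_model!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.focal_clade_size < 1:
            raise ValueError("focal_clade_size must be >= 1")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be > 0")
        if self.rate_sigma < 0:
            raise ValueError("rate_sigma must be >= 0")
        n_backbone = self.n_taxa - self.focal_clade_size
        if n_backbone < max(2, self.n_phyla - 1):
            raise ValueError(
                f"n_phyla={self.n_phyla} unattainable: only {n_backbone} non-focal taxa "
                f"for {self.n_phyla - 1} non-focal phyla"
            )
        return self


@dataclass(frozen=True)
class TruthEvent:
    """Ground truth for one transferred family: who donated the gene."""

    family_id: str
    donor_genome: str
    donor_phylum: str
    donor_class: str
    donor_genus: str


@dataclass
class FamilySim:
    family_id: str
    tree: GeneTree  # true gene tree, leaves labeled with gene ids
    sequences: list[tuple[str, str]]  # (gene_id, sequence)
    cog_category: str
    event: TruthEvent | None = None


@dataclass
class SimResult:
    config: SimConfig
    species_tree: GeneTree  # leaves labeled with genome ids
    taxonomy: dict[str, TaxonLineage]
    families: list[FamilySim]
    gene_table: list[GeneRecord] = field(default_factory=list)

    @property
    def truth_events(self) -> list[TruthEvent]:
        return [f.event for f in self.families if f.event is not None]

    @property
    def focal_genome(self) -> str:
        return next(l.genome_id for l in self.taxonomy.values() if l.is_focal)


# ---------------------------------------------------------------------------
# Species tree and taxonomy
# ---------------------------------------------------------------------------


def _yule_tree(n_tips: int, rng: random.Random) -> dendropy.Tree:
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    return tree


def _tree_height(tree: dendropy.Tree) -> float:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return max(lf.root_distance for lf in tree.leaf_node_iter())


def _scale_tree(tree: dendropy.Tree, factor: float) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def simulate_species_tree(config: SimConfig) -> tuple[GeneTree, dict[str, TaxonLineage]]:
    """Ultrametric species tree plus hierarchical taxonomy by depth cuts.

    The focal clade (``focal_clade_size`` genomes, the first of which is the
    focal organism) attaches at the root as a deep-branching phylum of its
    own; the remaining taxa form a birth–death backbone cut into
    ``n_phyla - 1`` monophyletic phyla at the earliest divergences.  Ranks
    below phylum come from progressively deeper cuts, so every rank is
    monophyletic by construction.
    """
    config.validate()
    rng = random.Random(config.seed)
    n_backbone = config.n_taxa - config.focal_clade_size

    backbone = _yule_tree(n_backbone, rng)
    hb = _tree_height(backbone)
    _scale_tree(backbone, 1.0 / hb)  # backbone height -> 1.0

    root = dendropy.Node()
    stem = 0.25
    focal_height = 0.5
    if config.focal_clade_size == 1:
        focal_root = dendropy.Node()
        focal_root.edge.length = stem + 1.0  # tip at the same depth as backbone tips
    else:
        focal_tree = _yule_tree(config.focal_clade_size, rng)
        hf = _tree_height(focal_tree)
        _scale_tree(focal_tree, focal_height / hf)
        focal_root = focal_tree.seed_node
        focal_root.edge.length = stem + 1.0 - focal_height
    backbone_root = backbone.seed_node
    backbone_root.edge.length = stem
    root.add_child(focal_root)
    root.add_child(backbone_root)

    tree = dendropy.Tree(seed_node=root)
    # keep every terminal branch strictly positive (the birth-death stop
    # condition can leave zero-length twin tips) while staying ultrametric
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + 0.10
    height = _tree_height(tree)
    _scale_tree(tree, config.tree_depth / height)

    # name genomes: focal clade first (leaf order), then backbone
    width = max(3, len(str(config.n_taxa)))
    focal_leaves = [lf for lf in focal_root.leaf_iter()]
    backbone_leaves = [lf for lf in backbone_root.leaf_iter()]
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for k, lf in enumerate(focal_leaves + backbone_leaves, start=1):
        lf.taxon = ns.new_taxon(f"G{k:0{width}d}")

    taxonomy = _assign_taxonomy(tree, focal_root, backbone_root, config)
    gt = GeneTree(tree, rooted=True).validate()
    return gt, taxonomy


def _cut_groups(leaves: Sequence[dendropy.Node], depth: float) -> list[list[dendropy.Node]]:
    """Group leaves by their shallowest ancestor deeper than ``depth``."""
    groups: dict[int, list[dendropy.Node]] = {}
    order: list[int] = []
    for lf in leaves:
        anc = lf
        while anc.parent_node is not None and anc.parent_node.root_distance > depth:
            anc = anc.parent_node
        if id(anc) not in groups:
            groups[id(anc)] = []
            order.append(id(anc))
        groups[id(anc)].append(lf)
    return [groups[k] for k in order]


def _assign_taxonomy(
    tree: dendropy.Tree,
    focal_root: dendropy.Node,
    backbone_root: dendropy.Node,
    config: SimConfig,
) -> dict[str, TaxonLineage]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(lf.root_distance for lf in tree.leaf_node_iter())

    # phylum partition: focal clade + the n_phyla-1 earliest backbone clades
    phyla: list[list[dendropy.Node]] = [list(focal_root.leaf_iter())]
    m = config.n_phyla - 1
    if m == 1:
        phyla.append(list(backbone_root.leaf_iter()))
    else:
        div_depths = sorted(
            nd.root_distance
            for nd in backbone_root.preorder_iter()
            if not nd.is_leaf()
        )
        # cutting just below the (m-1)-th divergence yields exactly m lineages
        cut = div_depths[m - 1] - 1e-9 if m - 1 < len(div_depths) else height
        phyla.extend(_cut_groups(list(backbone_root.leaf_iter()), cut))

    lineages: dict[str, TaxonLineage] = {}
    rank_fields = list(RANK_CUT_FRACTIONS)
    counters = {r: 0 for r in rank_fields}
    focal_label = min(lf.taxon.label for lf in focal_root.leaf_iter())
    for p_idx, phylum_leaves in enumerate(phyla, start=1):
        phylum = f"P{p_idx:02d}"
        rank_of_leaf: dict[str, dict[str, str]] = {lf.taxon.label: {} for lf in phylum_leaves}
        for rank in rank_fields:
            depth = RANK_CUT_FRACTIONS[rank] * height
            for group in _cut_groups(phylum_leaves, depth):
                counters[rank] += 1
                name = f"{rank[0]}{counters[rank]:03d}"
                for lf in group:
                    rank_of_leaf[lf.taxon.label][rank] = name
        for lf in phylum_leaves:
            label = lf.taxon.label
            ranks = rank_of_leaf[label]
            lineages[label] = TaxonLineage(
                genome_id=label,
                phylum=phylum,
                class_=ranks["class"],
                order=ranks["order"],
                family=ranks["family"],
                genus=ranks["genus"],
                species=f"s_{label}",
                is_focal=(label == focal_label),
            ).validate()
    # deterministic ordering by genome id
    return {k: lineages[k] for k in sorted(lineages)}


# ---------------------------------------------------------------------------
# Gene families with transfers
# ---------------------------------------------------------------------------


def _clone_species_tree(gt: GeneTree) -> dendropy.Tree:
    return parse_newick(write_newick(gt), rooted=True).tree


def _prune_and_regraft(tree: dendropy.Tree, focal_label: str, donor_label: str) -> None:
    """Move the focal tip to sister position of the donor tip, grafting at
    half the donor's terminal branch."""
    focal = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == focal_label)
    parent = focal.parent_node
    parent.remove_child(focal)
    # dissolve the resulting unifurcation (or a degenerate root)
    if parent.num_child_nodes() == 1:
        child = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            child.edge.length = None
            child.parent_node = None
            tree.seed_node = child
        else:
            length = (parent.edge.length or 0.0) + (child.edge.length or 0.0)
            grand.remove_child(parent)
            grand.add_child(child)
            child.edge.length = length

    donor = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == donor_label)
    b = donor.edge.length or 0.0
    dparent = donor.parent_node
    dparent.remove_child(donor)
    joint = dendropy.Node()
    joint.edge.length = b / 2.0
    dparent.add_child(joint)
    donor.edge.length = b / 2.0
    joint.add_child(donor)
    focal.edge.length = b / 2.0
    joint.add_child(focal)


def simulate_gene_families(
    species_tree: GeneTree,
    taxonomy: dict[str, TaxonLineage],
    config: SimConfig,
) -> tuple[list[tuple[str, GeneTree]], list[TruthEvent]]:
    """Per-family true gene trees plus the transfer ground truth.

    Each family starts as the species tree with branch lengths rescaled by a
    lognormal family rate (mean 1).  With probability ``p_transfer`` the
    focal tip is pruned and regrafted as sister to a uniformly chosen leaf
    from a foreign phylum.  Leaves are relabeled ``<genome>_<family>``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    focal_lineage = next(l for l in taxonomy.values() if l.is_focal)
    focal_genome = focal_lineage.genome_id
    donor_pool = sorted(
        g for g, lin in taxonomy.items() if lin.phylum != focal_lineage.phylum
    )
    width = max(4, len(str(config.n_families)))

    out: list[tuple[str, GeneTree]] = []
    events: list[TruthEvent] = []
    for k in range(1, config.n_families + 1):
        fam = f"fam{k:0{width}d}"
        tree = _clone_species_tree(species_tree)
        if config.rate_sigma > 0:
            rate = rng.lognormal(mean=-0.5 * config.rate_sigma**2, sigma=config.rate_sigma)
        else:
            rate = 1.0
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rate
        transferred = rng.random() < config.p_transfer
        if transferred:
            donor = donor_pool[int(rng.integers(0, len(donor_pool)))]
            _prune_and_regraft(tree, focal_genome, donor)
            dl = taxonomy[donor]
            events.append(
                TruthEvent(
                    family_id=fam,
                    donor_genome=donor,
                    donor_phylum=dl.phylum,
                    donor_class=dl.class_,
                    donor_genus=dl.genus,
                )
            )
        for lf in tree.leaf_node_iter():
            lf.taxon = dendropy.Taxon(label=f"{lf.taxon.label}_{fam}")
        tree.update_taxon_namespace()
        out.append((fam, GeneTree(tree, rooted=True).validate()))
    return out, events


# ---------------------------------------------------------------------------
# Sequence evolution (JC69 / K2P, exact transition probabilities)
# ---------------------------------------------------------------------------

# base encoding: A=0, G=1, C=2, T=3; transitions flip the low bit within
# purines (A<->G) and pyrimidines (C<->T): partner = base ^ 1
_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)


def _evolve_along(parent: np.ndarray, d: float, model: str, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if d <= 0:
        return parent.copy()
    L = parent.size
    if model == "JC69":
        # with prob e^{-4d/3} no substitution event hit the site; otherwise
        # the state is uniform over the four bases
        keep = rng.random(L) < math.exp(-4.0 * d / 3.0)
        fresh = rng.integers(0, 4, size=L).astype(np.int8)
        return np.where(keep, parent, fresh).astype(np.int8)
    # K2P: transition rate alpha, transversion rate beta (two targets),
    # kappa = alpha/beta, d = (alpha + 2 beta) t
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)          # transversion decay
    e2 = math.exp(-2.0 * (at + bt))   # transition decay
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1           # each of the two transversion targets
    u = rng.random(L)
    child = parent.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    child[ts_mask] ^= 1
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    # transversions swap purine <-> pyrimidine: +2 maps A,G -> C,T and back
    child[tv1] = (parent[tv1] + 2) % 4
    child[tv2] = ((parent[tv2] ^ 1) + 2) % 4
    return child.astype(np.int8)


def evolve_sequences(
    gene_tree: GeneTree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Evolve one gapless sequence per leaf along the gene tree.

    The root sequence is uniform i.i.d.; each site evolves independently
    along every branch with the exact substitution-model transition
    probabilities, so outputs are pre-aligned (no indels).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    tree = gene_tree.tree
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=config.seq_length).astype(np.int8)
    out: list[tuple[str, str]] = []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            parent_seq = _evolve_along(
                seqs[id(node.parent_node)],
                node.edge.length or 0.0,
                config.subst_model,
                config.kappa,
                rng,
            )
            seqs[id(node)] = parent_seq
        if node.is_leaf():
            out.append((node.taxon.label, bytes(_BASES[seqs[id(node)]]).decode("ascii")))
    out.sort(key=lambda item: item[0])
    return out


# ---------------------------------------------------------------------------
# Whole-dataset orchestration and fixture writing
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full simulation: species tree, families, sequences, gene table."""
    config.validate()
    species, taxonomy = simulate_species_tree(config)
    fam_trees, events = simulate_gene_families(species, taxonomy, config)
    event_by_family = {e.family_id: e for e in events}
    cog_rng = np.random.default_rng([config.seed, 3])
    seq_rng = np.random.default_rng([config.seed, 2])
    cog_letters = sorted(COG_CATEGORIES)

    families: list[FamilySim] = []
    gene_table: list[GeneRecord] = []
    spacing = 100
    for k, (fam, tree) in enumerate(fam_trees):
        seqs = evolve_sequences(tree, config, rng=seq_rng)
        cog = cog_letters[int(cog_rng.integers(0, len(cog_letters)))]
        families.append(
            FamilySim(family_id=fam, tree=tree, sequences=seqs, cog_category=cog, event=event_by_family.get(fam))
        )
        start = k * (config.seq_length + spacing) + 1
        for gene_id, seq in seqs:
            genome = gene_id.rsplit("_", 1)[0]
            gene_table.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome,
                    contig=f"{genome}_c1",
                    start=start,
                    end=start + config.seq_length - 1,
                    strand="+",
                    cog_category=cog,
                    product=f"simulated gene family {fam}",
                    sequence=seq,
                ).validate(require_sequence=True)
            )
    return SimResult(config=config, species_tree=species, taxonomy=taxonomy, families=families, gene_table=gene_table)


TRUTH_COLUMNS = ["family_id", "donor_genome", "donor_phylum", "donor_class", "donor_genus"]


def write_truth_table(events: Sequence[TruthEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for e in events:
            fh.write("\t".join([e.family_id, e.donor_genome, e.donor_phylum, e.donor_class, e.donor_genus]) + "\n")


def read_truth_table(path: str | Path) -> list[TruthEvent]:
    events = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in TRUTH_COLUMNS}
        for raw in fh:
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            events.append(TruthEvent(*[parts[idx[c]] for c in TRUTH_COLUMNS]))
    return events


def write_fixture(outdir: str | Path, result: SimResult) -> dict[str, Path]:
    """Write every simulation artifact as plain text under ``outdir``.

    Layout: ``species_tree.nwk``, ``taxonomy.tsv``, ``genes.tsv``,
    ``genes.fasta`` (all genes), ``truth.tsv``, plus per-family FASTA and
    true-tree Newick under ``families/``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    famdir = outdir / "families"
    famdir.mkdir(exist_ok=True)

    paths = {
        "species_tree": outdir / "species_tree.nwk",
        "taxonomy": outdir / "taxonomy.tsv",
        "gene_table": outdir / "genes.tsv",
        "fasta": outdir / "genes.fasta",
        "truth": outdir / "truth.tsv",
        "families_dir": famdir,
        "config": outdir / "sim_config.json",
    }
    write_newick_file(result.species_tree, paths["species_tree"])
    write_taxonomy(result.taxonomy.values(), paths["taxonomy"])
    write_gene_table(result.gene_table, paths["gene_table"])
    write_fasta([(g.gene_id, g.sequence) for g in result.gene_table], paths["fasta"])
    write_truth_table(result.truth_events, paths["truth"])
    for fam in result.families:
        write_fasta(fam.sequences, famdir / f"{fam.family_id}.fasta")
        write_newick_file(fam.tree, famdir / f"{fam.family_id}.nwk")
    import json

    with open(paths["config"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(asdict(result.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
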