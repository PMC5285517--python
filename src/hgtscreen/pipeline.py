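"""End-to-end orchestration: simulate -> homologs -> trees -> classify -> evaluate.

One JSON config drives the whole screen.  In synthetic mode the simulator
provides the inputs and a truth table, so the report carries precision,
recall and donor accuracy; in real mode the user supplies a gene table,
FASTA and taxonomy, and the truth metrics are absent.

Everything is seeded: the same config and seed give byte-identical stage
outputs and report.  Progress and stage timers go to stderr via logging;
results only ever go to files or stdout.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import classify as _classify
from . import simulate as _simulate
from . import trees as _trees
from .core import (
    GeneRecord,
    GeneTree,
    TaxonLineage,
    attach_sequences,
    check_taxonomy_covers,
    focal_genome,
    read_fasta,
    read_gene_table,
    read_taxonomy,
    write_newick_file,
)
from .homology import HomologSet, Scoring, find_homologs
from .simulate import SimConfig, TruthEvent, read_truth_table

logger = logging.getLogger("hgtscreen")


@dataclass
class EvaluationReport:
    n_genes: int
    n_trees: int
    n_interphylum: int
    fraction_of_trees: float
    fraction_of_genes: float
    precision: float | None = None
    recall: float | None = None
    donor_phylum_accuracy: float | None = None
    status_totals: dict = field(default_factory=dict)
    source_attribution: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def evaluate_against_truth(
    calls: Sequence[_classify.HGTCall],
    truth: Sequence[TruthEvent],
    family_of_gene: Mapping[str, str] | None = None,
) -> tuple[float | None, float | None, float | None]:
    """Precision / recall / donor-phylum accuracy of the interphylum calls.

    Calls are matched to truth events by gene family; by default the family
    is the part of the gene id after the genome prefix (``<genome>_<family>``).
    Precision is None when there are no positive calls; donor accuracy is
    None when there are no true positives.
    """
    def fam(gene_id: str) -> str:
        if family_of_gene is not None:
            if gene_id not in family_of_gene:
                raise KeyError(f"gene {gene_id!r} has no family mapping")
            return family_of_gene[gene_id]
        return gene_id.rsplit("_", 1)[-1]

    truth_by_family = {e.family_id: e for e in truth}
    called = {fam(c.gene_id): c for c in calls if c.status == "interphylum_transfer"}
    tp = [f for f in called if f in truth_by_family]
    precision = len(tp) / len(called) if called else None
    recall = (len(tp) / len(truth_by_family)) if truth_by_family else None
    if tp:
        donor_ok = sum(1 for f in tp if called[f].donor_phylum == truth_by_family[f].donor_phylum)
        donor_acc = donor_ok / len(tp)
    else:
        donor_acc = None
    return precision, recall, donor_acc


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "alphabet": "nt",  # 'nt' or 'aa'; which sequence type the dataset carries
    "simulate": None,  # SimConfig fields, or None for real-mode inputs
    "input": None,  # {"gene_table":..., "fasta":..., "taxonomy":...}
    "homology": {"min_identity": 0.30, "min_coverage": 0.80},
    "trees": {"bootstrap_replicates": 0, "model": "jc"},
    "classify": {"min_support": 0},
}


def resolve_config(raw: Mapping) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in raw.items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(cfg.get(key), dict) and isinstance(val, Mapping):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["simulate"] is None and cfg["input"] is None:
        raise ValueError("config needs either a 'simulate' block or an 'input' block")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return resolve_config(json.load(fh))


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


class StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
        return False


def build_family_tree(
    family_genes: Sequence[GeneRecord],
    query: GeneRecord,
    homology_cfg: Mapping,
    trees_cfg: Mapping,
    alphabet: str,
    seed: int,
    scoring: Scoring = Scoring(),
) -> tuple[GeneTree | None, HomologSet]:
    """Homolog gathering + MSA + NJ (+ optional bootstrap) + midpoint rooting
    for one query gene and its candidate set."""
    homs = find_homologs(
        query,
        family_genes,
        min_identity=homology_cfg["min_identity"],
        min_coverage=homology_cfg["min_coverage"],
        scoring=scoring,
    )
    if len(homs.members) < 2:
        return None, homs  # a tree needs the query plus at least two homologs
    by_id = {g.gene_id: g for g in family_genes}
    seqs = [(query.gene_id, query.sequence)] + [
        (gid, by_id[gid].sequence) for gid, *_ in homs.members
    ]
    seqs.sort(key=lambda item: item[0])
    alpha = _trees.NUCLEOTIDE_ALPHABET if alphabet == "nt" else _trees.PROTEIN_ALPHABET
    msa = _trees.progressive_msa(seqs, scoring, alpha)
    model = trees_cfg.get("model", "jc" if alphabet == "nt" else "poisson")
    replicates = int(trees_cfg.get("bootstrap_replicates", 0))
    if replicates > 0 and len(msa) >= 4:
        unrooted = _trees.bootstrap_support(msa, replicates, seed=seed, alphabet=alpha, model=model)
    else:
        dm = _trees.distance_matrix_from_msa(msa, alpha, model)
        unrooted = _trees.neighbor_joining(dm)
    return _trees.midpoint_root(unrooted), homs


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> EvaluationReport:
    """Run every stage in order, writing all intermediates under ``outdir``."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    alphabet = cfg["alphabet"]
    scoring = Scoring()

    truth: list[TruthEvent] = []
    if cfg["simulate"] is not None:
        with StageTimer("simulate"):
            sim_cfg = SimConfig(**{**cfg["simulate"], "seed": cfg["simulate"].get("seed", seed)}).validate()
            sim = _simulate.simulate_dataset(sim_cfg)
            _simulate.write_fixture(outdir / "simulated", sim)
            genes = sim.gene_table
            taxonomy = sim.taxonomy
            truth = sim.truth_events
    else:
        with StageTimer("load"):
            paths = cfg["input"]
            for key in ("gene_table", "fasta", "taxonomy"):
                if key not in paths:
                    raise ValueError(f"input block missing {key!r}")
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(f"input file not found: {paths[key]}")
            genes = attach_sequences(read_gene_table(paths["gene_table"]), read_fasta(paths["fasta"]))
            taxonomy = read_taxonomy(paths["taxonomy"])
            check_taxonomy_covers(genes, taxonomy)
            if "truth" in paths and paths["truth"]:
                truth = read_truth_table(paths["truth"])

    focal = focal_genome(taxonomy)
    genome_of = {g.gene_id: g.genome_id for g in genes}

    # group candidate homolog sets: one family per focal gene.  Synthetic
    # gene ids encode the family (<genome>_<family>); real-mode queries are
    # searched against every non-focal gene.
    focal_genes = [g for g in genes if g.genome_id == focal.genome_id]
    if not focal_genes:
        raise ValueError(f"no genes for focal genome {focal.genome_id!r}")
    if cfg["simulate"] is not None:
        by_family: dict[str, list[GeneRecord]] = {}
        for g in genes:
            by_family.setdefault(g.gene_id.rsplit("_", 1)[-1], []).append(g)
        candidate_sets = {
            q.gene_id: by_family[q.gene_id.rsplit("_", 1)[-1]] for q in focal_genes
        }
    else:
        candidate_sets = {q.gene_id: list(genes) for q in focal_genes}

    trees_dir = outdir / "gene_trees"
    trees_dir.mkdir(exist_ok=True)
    gene_trees: list[tuple[str, GeneTree | None, set[str]]] = []
    with StageTimer("homologs+trees"):
        for q in focal_genes:
            tree, homs = build_family_tree(
                candidate_sets[q.gene_id], q, cfg["homology"], cfg["trees"], alphabet, seed, scoring
            )
            if tree is not None:
                write_newick_file(tree, trees_dir / f"{q.gene_id}.nwk")
            focal_leaves = {q.gene_id}
            gene_trees.append((q.gene_id, tree, focal_leaves))

    with StageTimer("classify"):
        calls, fractions = _classify.classify_genome(
            gene_trees, taxonomy, genome_of, focal.phylum, min_support=int(cfg["classify"]["min_support"])
        )
        attribution = _classify.attribute_sources(calls)
        counts, rel = _classify.cog_crosstab(calls, genes)
        _write_calls(calls, outdir / "calls.tsv")
        if not counts.empty:
            counts.to_csv(outdir / "cog_crosstab_counts.tsv", sep="\t")
            rel.to_csv(outdir / "cog_crosstab_relative.tsv", sep="\t", float_format="%.6f")

    precision = recall = donor_acc = None
    if truth or cfg["simulate"] is not None:
        precision, recall, donor_acc = evaluate_against_truth(calls, truth)

    n_trees = sum(1 for c in calls if c.status != "no_tree")
    n_inter = sum(1 for c in calls if c.status == "interphylum_transfer")
    report = EvaluationReport(
        n_genes=len(calls),
        n_trees=n_trees,
        n_interphylum=n_inter,
        fraction_of_trees=round(fractions["fraction_of_trees"], 10),
        fraction_of_genes=round(fractions["fraction_of_genes"], 10),
        precision=_round(precision),
        recall=_round(recall),
        donor_phylum_accuracy=_round(donor_acc),
        status_totals=attribution.status_totals,
        source_attribution=attribution.to_json_dict(),
        config_echo=cfg,
        seed=seed,
    )
    with open(outdir / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(report.to_json())
    return report


def _round(x: float | None) -> float | None:
    return None if x is None else round(x, 10)


CALL_COLUMNS = [
    "gene_id", "status", "donor_phylum", "donor_class", "donor_genus",
    "sister_leaf_count", "support", "n_focal_tips",
]


def _write_calls(calls: Sequence[_classify.HGTCall], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.gene_id,
                        c.status,
                        c.donor_phylum or "",
                        c.donor_class or "",
                        c.donor_genus or "",
                        str(c.sister_leaf_count),
                        "" if c.support is None else str(c.support),
                        str(c.n_focal_tips),
                    ]
                )
                + "\n"
            )


def read_calls(path: str | Path) -> list[_classify.HGTCall]:
    calls = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in CALL_COLUMNS}
        for raw in fh:
            if not raw.strip():
                continue
            p = raw.rstrip("\n").split("\t")
            calls.append(
                _classify.HGTCall(
                    gene_id=p[idx["gene_id"]],
                    status=p[idx["status"]],
                    donor_phylum=p[idx["donor_phylum"]] or None,
                    donor_class=p[idx["donor_class"]] or None,
                    donor_genus=p[idx["donor_genus"]] or None,
                    sister_leaf_count=int(p[idx["sister_leaf_count"]]),
                    support=int(p[idx["support"]]) if p[idx["support"]] else None,
                    n_focal_tips=int(p[idx["n_focal_tips"]]),
                ).validate()
            )
    return calls
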