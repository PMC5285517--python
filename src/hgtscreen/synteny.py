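"""Operon / neighborhood synteny between two genomes.

Shared genes are identified by reciprocal best hits (RBH) at the same
identity/coverage thresholds the screen uses elsewhere (30% identity over
at least 80% of the gene by default), then gene-order conservation is
quantified two ways:

* order conservation — longest common subsequence of the paired genes'
  orders in the two genomes, evaluated in both orientations of the second
  genome and divided by the number of pairs;
* adjacency conservation — the fraction of neighboring paired genes in the
  first genome whose partners are also neighbors in the second.

Both scores are orientation-agnostic (an operon read off the complementary
strand is the same operon) and equal 1 exactly when the paired orders are
identical up to reversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .core import GeneRecord
from .homology import Scoring, global_align

logger = logging.getLogger("hgtscreen")


@dataclass
class SyntenyResult:
    pairs: list[tuple[str, str, float, float]]  # (gene_a, gene_b, identity, coverage_a)
    order_conservation: float
    adjacency_conservation: float
    blocks: list[dict] = field(default_factory=list)
    thresholds: tuple[float, float] = (0.30, 0.80)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------


def _best_hits(
    queries: Sequence[GeneRecord],
    subjects: Sequence[GeneRecord],
    min_identity: float,
    min_coverage: float,
    scoring: Scoring,
) -> dict[str, tuple[str, float, float]]:
    """query gene_id -> (best subject id, identity, query coverage).

    Best = highest identity, ties broken by higher coverage then by
    lexicographic subject id.
    """
    out: dict[str, tuple[str, float, float]] = {}
    for q in queries:
        best = None
        for s in subjects:
            aln = global_align(q.sequence, s.sequence, scoring)
            if aln.identity < min_identity or aln.coverage_query < min_coverage:
                continue
            key = (-aln.identity, -aln.coverage_query, s.gene_id)
            if best is None or key < best[0]:
                best = (key, s.gene_id, aln.identity, aln.coverage_query)
        if best is not None:
            out[q.gene_id] = (best[1], best[2], best[3])
    return out


def reciprocal_best_hits(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    min_identity: float = 0.30,
    min_coverage: float = 0.80,
    scoring: Scoring = Scoring(),
) -> list[tuple[str, str, float, float]]:
    """Gene pairs that are each other's best hit, both meeting thresholds."""
    if not genes_a or not genes_b:
        raise ValueError("both gene lists must be non-empty")
    fwd = _best_hits(genes_a, genes_b, min_identity, min_coverage, scoring)
    rev = _best_hits(genes_b, genes_a, min_identity, min_coverage, scoring)
    pairs = []
    for a_id, (b_id, ident, cov) in sorted(fwd.items()):
        if rev.get(b_id, (None,))[0] == a_id:
            pairs.append((a_id, b_id, ident, cov))
    return pairs


# ---------------------------------------------------------------------------
# Order statistics
# ---------------------------------------------------------------------------


def lcs_length(x: Sequence, y: Sequence) -> int:
    """Classic O(len(x)*len(y)) longest-common-subsequence DP."""
    n, m = len(x), len(y)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if x[i - 1] == y[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def _paired_orders(
    pairs: Sequence[tuple[str, str, float, float]],
    order_a: Sequence[str],
    order_b: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Paired genes of A in A-order, and their partners' order in B,
    both expressed as gene_a ids."""
    a_of_b = {b: a for a, b, *_ in pairs}
    paired_a = {a for a, *_ in pairs}
    seq_a = [g for g in order_a if g in paired_a]
    seq_b = [a_of_b[g] for g in order_b if g in a_of_b]
    return seq_a, seq_b


def order_conservation(
    pairs: Sequence[tuple[str, str, float, float]],
    order_a: Sequence[str],
    order_b: Sequence[str],
) -> float:
    """LCS of the paired gene orders (best of the two B orientations) / #pairs."""
    if not pairs:
        logger.warning("order_conservation: no shared gene pairs")
        return 0.0
    seq_a, seq_b = _paired_orders(pairs, order_a, order_b)
    best = max(lcs_length(seq_a, seq_b), lcs_length(seq_a, seq_b[::-1]))
    return best / len(pairs)


def adjacency_conservation(
    pairs: Sequence[tuple[str, str, float, float]],
    order_a: Sequence[str],
    order_b: Sequence[str],
) -> float:
    """Fraction of neighboring paired genes in A whose partners neighbor in B."""
    if not pairs:
        logger.warning("adjacency_conservation: no shared gene pairs")
        return 0.0
    seq_a, seq_b = _paired_orders(pairs, order_a, order_b)
    if len(seq_a) < 2:
        return 1.0  # a single pair has no adjacencies to break
    pos_b = {g: k for k, g in enumerate(seq_b)}
    kept = sum(
        1
        for g1, g2 in zip(seq_a, seq_a[1:])
        if abs(pos_b[g1] - pos_b[g2]) == 1
    )
    return kept / (len(seq_a) - 1)


def colinear_blocks(
    pairs: Sequence[tuple[str, str, float, float]],
    order_a: Sequence[str],
    order_b: Sequence[str],
) -> list[dict]:
    """Maximal runs of pairs consecutive in A whose B positions step by a
    constant +1 or -1 (forward or reverted block)."""
    if not pairs:
        return []
    seq_a, seq_b = _paired_orders(pairs, order_a, order_b)
    pos_b = {g: k for k, g in enumerate(seq_b)}
    blocks: list[dict] = []
    run: list[str] = [seq_a[0]] if seq_a else []
    direction = 0
    for g1, g2 in zip(seq_a, seq_a[1:]):
        step = pos_b[g2] - pos_b[g1]
        if step in (1, -1) and (direction in (0, step)):
            run.append(g2)
            direction = step
        else:
            blocks.append({"genes_a": run, "orientation": "+" if direction >= 0 else "-"})
            run = [g2]
            direction = 0
    if run:
        blocks.append({"genes_a": run, "orientation": "+" if direction >= 0 else "-"})
    return blocks


def compare_regions(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    min_identity: float = 0.30,
    min_coverage: float = 0.80,
    scoring: Scoring = Scoring(),
) -> SyntenyResult:
    """Full two-genome synteny comparison: RBH pairing plus order scores.

    Gene order within each genome comes from coordinates (contig, then
    start), i.e., the order the genes appear on the replicon.
    """
    pairs = reciprocal_best_hits(genes_a, genes_b, min_identity, min_coverage, scoring)
    order_a = [g.gene_id for g in sorted(genes_a, key=lambda g: (g.contig, g.start))]
    order_b = [g.gene_id for g in sorted(genes_b, key=lambda g: (g.contig, g.start))]
    return SyntenyResult(
        pairs=pairs,
        order_conservation=order_conservation(pairs, order_a, order_b),
        adjacency_conservation=adjacency_conservation(pairs, order_a, order_b),
        blocks=colinear_blocks(pairs, order_a, order_b),
        thresholds=(min_identity, min_coverage),
    )
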