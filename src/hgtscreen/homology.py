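"""Pairwise global alignment, percent identity, query coverage, homolog sets.

Homolog gathering for the transfer screen uses exact Needleman–Wunsch/Gotoh
alignment with affine gap costs against every candidate gene — no heuristic
seeding.  Inputs are desk-scale (simulated families or a handful of genomes),
so exhaustive alignment is affordable and keeps the identity/coverage numbers
free of seeding artifacts.

The screen's default retention thresholds are 30% identity over at least 80%
of the query — the same cutoffs used for calling shared operon genes in the
synteny comparison.

A gap run of length L costs ``gap_open + (L - 1) * gap_extend``; all gaps,
including terminal ones, are penalized (true global alignment).  Percent
identity excludes terminal-gap columns from its denominator so that a short
gene aligned inside a long one is not punished twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GeneRecord, NUCLEOTIDE_ALPHABET, PROTEIN_ALPHABET

NEG = -1e30  # effectively -infinity, safe to add penalties to


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring: first gap residue costs ``gap_open``, each further one ``gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def gap_cost(self, length: int) -> float:
        return 0.0 if length == 0 else self.gap_open + (length - 1) * self.gap_extend


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage_query: float


@dataclass
class HomologSet:
    """Genes retained as homologs of one query, sorted by descending identity."""

    query_gene_id: str
    members: list[tuple[str, str, float, float]] = field(default_factory=list)  # (gene_id, genome_id, identity, coverage)
    thresholds: tuple[float, float] = (0.30, 0.80)

    def member_ids(self) -> list[str]:
        return [m[0] for m in self.members]


def check_alphabet(seq: str, alphabet: str) -> None:
    extra = set(seq) - set(alphabet)
    if extra:
        raise ValueError(f"sequence contains symbols {sorted(extra)} outside alphabet {alphabet!r}")


def alphabet_for(kind: str) -> str:
    if kind in ("nt", "nucleotide", "dna"):
        return NUCLEOTIDE_ALPHABET
    if kind in ("aa", "protein"):
        return PROTEIN_ALPHABET
    raise ValueError(f"unknown alphabet kind {kind!r}")


# ---------------------------------------------------------------------------
# Gotoh global alignment (three-state affine DP, vectorized across columns)
# ---------------------------------------------------------------------------


def affine_dp(sub: np.ndarray, gap_open: float, gap_extend: float) -> tuple[float, list[str]]:
    """Affine-gap global DP over an arbitrary column-scoring matrix.

    ``sub[i, j]`` is the score of pairing row item ``i`` with column item
    ``j`` (characters for sequence alignment, columns for profile merging).
    Returns the optimal score and the operation string: ``'M'`` consumes one
    of each, ``'X'`` consumes a row item against a gap, ``'Y'`` a column item
    against a gap.  Traceback ties are broken deterministically, preferring
    diagonal over up over left.
    """
    n, m = sub.shape
    go, ge = gap_open, gap_extend
    # M: items paired; X: row item vs gap ("up"); Y: column item vs gap ("left").
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    jj = np.arange(1, m + 1)
    Y[0, 1:] = go + (jj - 1) * ge
    ii = np.arange(1, n + 1)
    X[1:, 0] = go + (ii - 1) * ge

    kk = np.arange(m + 1)
    for r in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[r - 1, :-1], X[r - 1, :-1]), Y[r - 1, :-1])
        M[r, 1:] = best_prev + sub[r - 1]
        X[r, 1:] = np.maximum(np.maximum(M[r - 1, 1:] + go, X[r - 1, 1:] + ge), Y[r - 1, 1:] + go)
        # Y within the row: a gap opened at some column k < j from M or X.
        z = np.maximum(M[r], X[r]) - ge * kk
        Y[r, 1:] = go + ge * (jj - 1) + np.maximum.accumulate(z[:-1])

    score = float(max(M[n, m], X[n, m], Y[n, m]))
    tol = 1e-6
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i, j], s == "M", s == "X"))
    ops: list[str] = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - prev) <= tol:
                    state = s
                    break
        elif state == "X":
            cur = X[i, j]
            i -= 1
            if abs(cur - (M[i, j] + go)) <= tol:
                state = "M"
            elif abs(cur - (X[i, j] + ge)) <= tol:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            cur = Y[i, j]
            j -= 1
            if abs(cur - (M[i, j] + go)) <= tol:
                state = "M"
            elif abs(cur - (Y[i, j] + ge)) <= tol:
                state = "Y"
            else:
                state = "X"
    ops.reverse()
    return score, ops


def global_align(a: str, b: str, scoring: Scoring = Scoring(), alphabet: str | None = None) -> AlignmentResult:
    """Optimal global alignment of ``a`` (query) vs ``b`` (subject).

    Exact affine-gap DP; traceback ties are broken deterministically,
    preferring a substitution column over a gap in the subject over a gap in
    the query (diagonal > up > left).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if alphabet is not None:
        check_alphabet(a, alphabet)
        check_alphabet(b, alphabet)

    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], scoring.match, scoring.mismatch)
    score, ops = affine_dp(sub, scoring.gap_open, scoring.gap_extend)

    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for op in ops:
        if op == "M":
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif op == "X":
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    aligned_a, aligned_b = "".join(out_a), "".join(out_b)
    identity = percent_identity_cols(aligned_a, aligned_b)
    coverage = coverage_query_cols(aligned_a, aligned_b)
    return AlignmentResult(aligned_a, aligned_b, score, identity, coverage)


# ---------------------------------------------------------------------------
# Identity and coverage
# ---------------------------------------------------------------------------


def _internal_span(row_a: str, row_b: str) -> tuple[int, int]:
    """Column range once terminal-gap columns of either row are trimmed."""
    lo = 0
    hi = len(row_a)
    for row in (row_a, row_b):
        lo = max(lo, len(row) - len(row.lstrip("-")))
        hi = min(hi, len(row.rstrip("-")))
    return lo, max(lo, hi)


def percent_identity_cols(aligned_a: str, aligned_b: str) -> float:
    """Identical columns / alignment columns, excluding terminal-gap columns."""
    lo, hi = _internal_span(aligned_a, aligned_b)
    if hi <= lo:
        return 0.0
    same = sum(
        1 for x, y in zip(aligned_a[lo:hi], aligned_b[lo:hi]) if x == y and x != "-"
    )
    return same / (hi - lo)


def percent_identity(aln: AlignmentResult) -> float:
    return percent_identity_cols(aln.aligned_a, aln.aligned_b)


def coverage_query_cols(aligned_a: str, aligned_b: str) -> float:
    """Fraction of query residues aligned opposite subject residues.

    Asymmetric by design: coverage of a short query inside a long subject is
    high, the reverse is low.
    """
    qlen = sum(1 for x in aligned_a if x != "-")
    if qlen == 0:
        return 0.0
    paired = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    return paired / qlen


def coverage_query(aln: AlignmentResult, query_length: int | None = None) -> float:
    qlen = sum(1 for x in aln.aligned_a if x != "-")
    if query_length is not None and query_length != qlen:
        raise ValueError(f"query_length {query_length} does not match ungapped query length {qlen}")
    return coverage_query_cols(aln.aligned_a, aln.aligned_b)


# ---------------------------------------------------------------------------
# Homolog-set construction
# ---------------------------------------------------------------------------


def find_homologs(
    query: GeneRecord,
    db: Sequence[GeneRecord],
    min_identity: float = 0.30,
    min_coverage: float = 0.80,
    scoring: Scoring = Scoring(),
) -> HomologSet:
    """All db genes meeting both thresholds against the query; self-hits removed."""
    if not db:
        raise ValueError("homolog database is empty")
    members = []
    for gene in db:
        if gene.gene_id == query.gene_id:
            continue
        aln = global_align(query.sequence, gene.sequence, scoring)
        if aln.identity >= min_identity and aln.coverage_query >= min_coverage:
            members.append((gene.gene_id, gene.genome_id, aln.identity, aln.coverage_query))
    members.sort(key=lambda m: (-m[2], m[0]))
    return HomologSet(query_gene_id=query.gene_id, members=members, thresholds=(min_identity, min_coverage))
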