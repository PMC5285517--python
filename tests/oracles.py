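"""Independent brute-force oracles for validating the package's algorithms.

These deliberately avoid the implementation's code paths:

* exhaustive enumeration of every global alignment (for the affine-gap DP),
* exhaustive unrooted-topology search scored by least squares (for NJ),
* exhaustive subsequence enumeration and patience-sorting longest increasing
  subsequence (for the LCS order-conservation score).
"""

from __future__ import annotations

import bisect
import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Alignment: enumerate every monotone alignment, score gap runs directly
# ---------------------------------------------------------------------------


def score_alignment(row_a: str, row_b: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Score a finished alignment: column-wise substitutions plus
    open+extend costs per maximal gap run (terminal gaps included)."""
    total = 0.0
    run_a = run_b = 0  # current gap-run lengths in each row
    for x, y in zip(row_a, row_b):
        if x == "-":
            run_a += 1
            total += gap_open if run_a == 1 else gap_extend
        else:
            run_a = 0
        if y == "-":
            run_b += 1
            total += gap_open if run_b == 1 else gap_extend
        else:
            run_b = 0
        if x != "-" and y != "-":
            total += match if x == y else mismatch
    return total


def best_alignment_score_bruteforce(a: str, b: str, match: float, mismatch: float,
                                    gap_open: float, gap_extend: float) -> float:
    """Max score over every possible global alignment (lengths <= ~7)."""
    best = -np.inf

    def rec(i: int, j: int, col_a: list[str], col_b: list[str]) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            s = score_alignment("".join(col_a), "".join(col_b), match, mismatch, gap_open, gap_extend)
            if s > best:
                best = s
            return
        if i < len(a) and j < len(b):
            col_a.append(a[i]); col_b.append(b[j])
            rec(i + 1, j + 1, col_a, col_b)
            col_a.pop(); col_b.pop()
        if i < len(a):
            col_a.append(a[i]); col_b.append("-")
            rec(i + 1, j, col_a, col_b)
            col_a.pop(); col_b.pop()
        if j < len(b):
            col_a.append("-"); col_b.append(b[j])
            rec(i, j + 1, col_a, col_b)
            col_a.pop(); col_b.pop()

    rec(0, 0, [], [])
    return float(best)


# ---------------------------------------------------------------------------
# Unrooted topologies: enumeration + least-squares branch-length fit
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Built by stepwise insertion: each new leaf subdivides an existing edge.
    Nodes >= n are internal.  Yields (edges, n_nodes).
    """
    base_edges = [(0, n), (1, n), (2, n)]  # star on first three leaves

    def insert(edges, next_internal, leaf):
        for k in range(len(edges)):
            u, v = edges[k]
            new = []
            new.extend(edges[:k])
            new.extend(edges[k + 1:])
            new.append((u, next_internal))
            new.append((v, next_internal))
            new.append((leaf, next_internal))
            yield new

    def rec(edges, next_internal, leaf):
        if leaf == n:
            yield edges, next_internal
            return
        for e2 in insert(edges, next_internal, leaf):
            yield from rec(e2, next_internal + 1, leaf + 1)

    yield from rec(base_edges, n + 1, 3)


def _leaf_paths(edges, n_nodes, n_leaves):
    """0/1 incidence matrix: leaf pair x edge (is the edge on the path?)."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))

    def path_edges(src, dst):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, path = stack.pop()
            if node == dst:
                return path
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, path + [eidx]))
        raise RuntimeError("disconnected topology")

    for r, (i, j) in enumerate(pairs):
        for eidx in path_edges(i, j):
            A[r, eidx] = 1.0
    return pairs, A


def topology_splits(edges, n_leaves) -> set[frozenset[int]]:
    """Nontrivial bipartitions (as the side without leaf 0) of a topology."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue  # terminal edge -> trivial split
        # leaves on v's side when the edge u-v is removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(frozenset(side) if 0 not in side else frozenset(set(range(n_leaves)) - side))
    return splits


def least_squares_best_topology(D: np.ndarray) -> set[frozenset[int]]:
    """Splits of the topology minimizing the OLS fit to the distance matrix."""
    n = D.shape[0]
    best = None
    for edges, n_nodes in enumerate_unrooted_topologies(n):
        pairs, A = _leaf_paths(edges, n_nodes, n)
        d = np.array([D[i, j] for i, j in pairs])
        x, residuals, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(np.sum((A @ x - d) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, topology_splits(edges, n))
    return best[1]


def random_additive_matrix(n: int, rng: np.random.Generator) -> tuple[np.ndarray, set[frozenset[int]]]:
    """Distances realized exactly on a random binary tree with random
    branch lengths; returns the matrix and the true nontrivial splits."""
    topos = list(enumerate_unrooted_topologies(n))
    edges, n_nodes = topos[int(rng.integers(0, len(topos)))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    pairs, A = _leaf_paths(edges, n_nodes, n)
    D = np.zeros((n, n))
    d = A @ lengths
    for (i, j), dist in zip(pairs, d):
        D[i, j] = D[j, i] = dist
    return D, topology_splits(edges, n)


# ---------------------------------------------------------------------------
# LCS oracles
# ---------------------------------------------------------------------------


def lcs_exhaustive(x, y) -> int:
    """Longest common subsequence by enumerating all subsequences of x."""
    best = 0
    for r in range(len(x), 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(x, r):
            it = iter(y)
            if all(c in it for c in combo):
                best = r
                break
    return best


def lcs_of_permutations_lis(x, y) -> int:
    """LCS of two sequences of distinct items = longest increasing
    subsequence of y's items ranked by their position in x (patience sorting)."""
    pos = {v: k for k, v in enumerate(x)}
    ranks = [pos[v] for v in y if v in pos]
    piles: list[int] = []
    for r in ranks:
        k = bisect.bisect_left(piles, r)
        if k == len(piles):
            piles.append(r)
        else:
            piles[k] = r
    return len(piles)
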