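"""Per-gene phylogenies: progressive MSA, corrected distances, NJ, bootstrap, rooting.

One tree per homolog set, built the deterministic desk-scale way:

1. progressive multiple alignment guided by single-linkage clustering of
   pairwise p-distances, profiles merged by affine-gap DP;
2. pairwise p-distances from the alignment, corrected to substitutions per
   site (Jukes–Cantor for nucleotides, Poisson for proteins), saturated
   pairs flagged and capped;
3. neighbor joining (Q-matrix minimization with Studier–Keppler updates);
4. optional nonparametric bootstrap: alignment columns resampled with
   replacement, each replicate re-run through distances + NJ, support =
   percentage of replicates containing each original bipartition;
5. midpoint rooting on the longest leaf-to-leaf path.

Every stochastic step takes an explicit seed; identical inputs and seeds
give identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from .core import GeneTree, NUCLEOTIDE_ALPHABET, PROTEIN_ALPHABET
from .homology import Scoring, affine_dp, global_align

#: Distance assigned to pairs whose correction diverged (saturated signal).
MAX_DISTANCE = 5.0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances in substitutions per site."""

    labels: list[str]
    values: np.ndarray
    saturated_pairs: set[tuple[str, str]] = field(default_factory=set)

    def validate(self) -> "DistanceMatrix":
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        return self


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _encode_rows(rows: Sequence[str], alphabet: str) -> np.ndarray:
    """Rows -> int matrix; alphabet indices, gap/other = -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for k, ch in enumerate(alphabet):
        lut[ord(ch)] = k
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(len(rows), -1)
    return lut[mat]


def _profile(rows: list[str], alphabet: str) -> np.ndarray:
    """Column residue frequencies (gaps contribute nothing), L x |alphabet|."""
    enc = _encode_rows(rows, alphabet)
    L = enc.shape[1]
    prof = np.zeros((L, len(alphabet)))
    for k in range(len(alphabet)):
        prof[:, k] = (enc == k).sum(axis=0)
    return prof / len(rows)


def _merge_alignments(
    group_a: list[tuple[str, str]],
    group_b: list[tuple[str, str]],
    scoring: Scoring,
    alphabet: str,
) -> list[tuple[str, str]]:
    """Align two sub-alignments by profile-profile affine DP; gap columns inserted as needed."""
    rows_a = [r for _, r in group_a]
    rows_b = [r for _, r in group_b]
    pa = _profile(rows_a, alphabet)
    pb = _profile(rows_b, alphabet)
    W = np.full((len(alphabet), len(alphabet)), scoring.mismatch)
    np.fill_diagonal(W, scoring.match)
    sub = pa @ W @ pb.T
    _, ops = affine_dp(sub, scoring.gap_open, scoring.gap_extend)

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        take_a = op in ("M", "X")
        take_b = op in ("M", "Y")
        for r, row in enumerate(rows_a):
            out_a[r].append(row[i] if take_a else "-")
        for r, row in enumerate(rows_b):
            out_b[r].append(row[j] if take_b else "-")
        i += take_a
        j += take_b
    merged = [(name, "".join(chars)) for (name, _), chars in zip(group_a, out_a)]
    merged += [(name, "".join(chars)) for (name, _), chars in zip(group_b, out_b)]
    return merged


def _guide_distances(seqs: Sequence[tuple[str, str]], scoring: Scoring) -> np.ndarray:
    """Condensed pairwise p-distances for the guide tree.

    Equal-length inputs are compared column-wise directly (the common case
    for simulator output); unequal lengths fall back to pairwise alignment.
    """
    n = len(seqs)
    lengths = {len(s) for _, s in seqs}
    out = []
    if len(lengths) == 1:
        mat = np.frombuffer("".join(s for _, s in seqs).encode("ascii"), dtype=np.uint8).reshape(n, -1)
        for i in range(n):
            diff = (mat[i + 1 :] != mat[i]).mean(axis=1)
            out.extend(diff.tolist())
    else:
        for i in range(n):
            for j in range(i + 1, n):
                aln = global_align(seqs[i][1], seqs[j][1], scoring)
                out.append(1.0 - aln.identity)
    return np.asarray(out)


def progressive_msa(
    seqs: Sequence[tuple[str, str]],
    scoring: Scoring = Scoring(),
    alphabet: str = NUCLEOTIDE_ALPHABET,
) -> list[tuple[str, str]]:
    """Progressive multiple alignment; returns gapped rows in input order.

    Guide order comes from single-linkage clustering of pairwise p-distances;
    sub-alignments are merged pairwise by profile DP, so ungapping any output
    row recovers the corresponding input exactly.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    if len(seqs) == 2:
        aln = global_align(seqs[0][1], seqs[1][1], scoring)
        merged = [(seqs[0][0], aln.aligned_a), (seqs[1][0], aln.aligned_b)]
    else:
        cond = _guide_distances(seqs, scoring)
        Z = linkage(cond, method="single")
        clusters: dict[int, list[tuple[str, str]]] = {i: [list(seqs)[i]] for i in range(len(seqs))}
        nxt = len(seqs)
        for a, b, _, _ in Z:
            clusters[nxt] = _merge_alignments(clusters.pop(int(a)), clusters.pop(int(b)), scoring, alphabet)
            nxt += 1
        merged = clusters[nxt - 1]
    order = {name: k for k, (name, _) in enumerate(seqs)}
    merged.sort(key=lambda item: order[item[0]])
    return merged


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def jc_distance(p: float, ceiling: float = MAX_DISTANCE) -> tuple[float, bool]:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) for nucleotides.

    Returns ``(distance, saturated)``; p >= 3/4 is beyond what the model can
    explain, so those pairs get the ceiling and a saturation flag.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion of differing sites must be in [0,1], got {p}")
    if p >= 0.75:
        return ceiling, True
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return min(float(d), ceiling), False


def poisson_distance(p: float, ceiling: float = MAX_DISTANCE) -> tuple[float, bool]:
    """Poisson correction d = -ln(1 - p) for protein sequences."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion of differing sites must be in [0,1], got {p}")
    if p >= 1.0 - 1e-12:
        return ceiling, True
    d = -np.log1p(-p)
    return min(float(d), ceiling), False


def p_distance_matrix(msa: Sequence[tuple[str, str]], alphabet: str = NUCLEOTIDE_ALPHABET) -> tuple[list[str], np.ndarray]:
    """Pairwise mismatch fractions over columns where both rows have residues."""
    labels = [name for name, _ in msa]
    enc = _encode_rows([row for _, row in msa], alphabet)
    n = len(labels)
    P = np.zeros((n, n))
    valid = enc >= 0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diffs = (enc[i] != enc[i + 1 :]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(denom > 0, diffs.sum(axis=1) / np.maximum(denom, 1), 1.0)
        P[i, i + 1 :] = p
        P[i + 1 :, i] = p
    return labels, P


def distance_matrix_from_msa(
    msa: Sequence[tuple[str, str]],
    alphabet: str = NUCLEOTIDE_ALPHABET,
    model: str = "jc",
    ceiling: float = MAX_DISTANCE,
) -> DistanceMatrix:
    """Corrected distance matrix from an alignment; saturated pairs capped and flagged."""
    labels, P = p_distance_matrix(msa, alphabet)
    correct = jc_distance if model == "jc" else poisson_distance
    n = len(labels)
    D = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            d, sat = correct(float(P[i, j]), ceiling)
            D[i, j] = D[j, i] = d
            if sat:
                saturated.add((min(labels[i], labels[j]), max(labels[i], labels[j])))
    return DistanceMatrix(labels, D, saturated).validate()


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> GeneTree:
    """Classic NJ; returns an unrooted tree (trifurcation at the storage root).

    Ties in the Q matrix are broken by the lexicographically smallest pair of
    cluster representative labels; negative branch-length estimates are
    clamped to zero with the deficit moved to the sibling branch.
    """
    dm.validate()
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        taxon = ns.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    reps = list(dm.labels)  # representative (min leaf) label per active cluster
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def pick_pair() -> tuple[int, int]:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        return best[1], best[2]

    while len(active) > 3:
        k = len(active)
        ai, aj = pick_pair()
        i, j = active[ai], active[aj]
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        # Studier–Keppler update: distance from the new node to every other.
        others = [x for x in active if x not in (i, j)]
        newd = 0.5 * (D[i, others] + D[j, others] - dij)
        newd = np.maximum(newd, 0.0)
        u = i  # reuse slot i for the merged cluster
        D[u, others] = newd
        D[np.asarray(others), u] = newd
        D[u, u] = 0.0
        nodes[u] = parent
        reps[u] = min(reps[i], reps[j])
        active.remove(j)

    # resolve the final three clusters on a central (storage-root) node
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(float(ln), 0.0)

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    return GeneTree(tree, rooted=False).validate()


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(gt: GeneTree) -> dict[int, frozenset[str]]:
    """Map id(edge) -> canonical split (the side not containing the min leaf)."""
    all_leaves = frozenset(gt.leaf_labels())
    ref = min(all_leaves)
    out: dict[int, frozenset[str]] = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial split
        out[id(node.edge)] = side if ref not in side else all_leaves - side
    return out


def bipartition_set(gt: GeneTree) -> set[frozenset[str]]:
    return set(_bipartitions(gt).values())


def bootstrap_support(
    msa: Sequence[tuple[str, str]],
    n_replicates: int = 500,
    seed: int | None = None,
    alphabet: str = NUCLEOTIDE_ALPHABET,
    model: str = "jc",
    ceiling: float = MAX_DISTANCE,
) -> GeneTree:
    """NJ tree from the alignment with bootstrap percentages on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate is re-run through distance correction + NJ, and each original
    internal bipartition's support is the percentage of replicates containing
    it.  A signal-free alignment (all rows identical) yields an arbitrary
    resolution flagged ``uninformative`` with all supports zero.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(msa) < 4:
        raise ValueError("bootstrap needs an alignment with >= 4 rows")
    dm = distance_matrix_from_msa(msa, alphabet, model, ceiling)
    tree = neighbor_joining(dm)
    splits = _bipartitions(tree)
    if not np.any(dm.values > 0):
        tree.uninformative = True
        for node in tree.tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                node.edge.support = 0
        return tree

    labels = [name for name, _ in msa]
    rows = [row for _, row in msa]
    L = len(rows[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in splits.values()}
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(len(rows), L)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_rows = mat[:, cols]
        rep_msa = [(lab, bytes(r).decode("ascii")) for lab, r in zip(labels, rep_rows)]
        rep_dm = distance_matrix_from_msa(rep_msa, alphabet, model, ceiling)
        rep_splits = bipartition_set(neighbor_joining(rep_dm))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        split = splits.get(id(node.edge))
        if split is not None:
            node.edge.support = int(round(100.0 * counts[split] / n_replicates))
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------


def midpoint_root(gt: GeneTree) -> GeneTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (sorted) leaf pair; the midpoint is measured from the smaller
    label of the winning pair.  An all-zero-length tree is rooted on the
    first edge and flagged ``arbitrary_root``.
    """
    work = gt.clone()
    tree = work.tree
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")

    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0

    # all pairwise leaf distances via root-distance + MRCA (desk-scale trees)
    pdm = tree.phylogenetic_distance_matrix()
    best = None
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            pair = tuple(sorted((leaves[i].taxon.label, leaves[j].taxon.label)))
            key = (-d, pair)
            if best is None or key < best[0]:
                best = (key, d, leaves[i], leaves[j])
    _, maxd, la, lb = best
    if la.taxon.label > lb.taxon.label:
        la, lb = lb, la

    if maxd <= 0:
        edge = tree.seed_node.child_nodes()[0].edge
        tree.reroot_at_edge(edge, length1=0.0, length2=edge.length, update_bipartitions=False)
        tree.seed_node.edge.length = None
        out = GeneTree(tree, rooted=True)
        out.uninformative = work.uninformative
        out.arbitrary_root = True
        return out

    # walk the a->b path; the midpoint sits maxd/2 from leaf a
    path = _path_edges(la, lb)
    target = maxd / 2.0
    walked = 0.0
    root_edge = None
    offset = 0.0
    for node, edge in path:
        length = edge.length or 0.0
        if walked + length >= target - 1e-12:
            root_edge = edge
            # distance from the child end of the edge (the end nearer leaf a side)
            offset = target - walked
            root_child_end = node
            break
        walked += length
    if root_edge is None:  # numeric fallback: root on last path edge
        root_child_end, root_edge = path[-1]
        offset = root_edge.length or 0.0

    # dendropy's reroot_at_edge: length1 is assigned to the side of edge.tail_node.
    length = root_edge.length or 0.0
    if root_child_end is root_edge.head_node:
        l_head = offset
    else:
        l_head = length - offset
    l_head = min(max(l_head, 0.0), length)
    tree.reroot_at_edge(root_edge, length1=length - l_head, length2=l_head, update_bipartitions=False)
    tree.seed_node.edge.length = None
    out = GeneTree(tree, rooted=True)
    out.uninformative = work.uninformative
    out.arbitrary_root = False
    return out.validate()


def _path_edges(leaf_a: dendropy.Node, leaf_b: dendropy.Node) -> list[tuple[dendropy.Node, dendropy.Edge]]:
    """Edges along the path from leaf_a to leaf_b, each tagged with the node
    at its end nearer leaf_a (its 'entry' point when walking from a)."""
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_b = []
    node = leaf_b
    while node is not None:
        anc_b.append(node)
        node = node.parent_node
    set_a = {id(n) for n in anc_a}
    mrca = next(n for n in anc_b if id(n) in set_a)
    up = []
    for n in anc_a:
        if n is mrca:
            break
        up.append((n, n.edge))  # walking up: enter edge at its head (child) end
    down = []
    for n in anc_b:
        if n is mrca:
            break
        down.append((n.parent_node, n.edge))  # walking down: enter at tail (parent) end
    down.reverse()
    return up + down
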