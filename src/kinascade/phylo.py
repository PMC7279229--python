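"""Alignment and distance-based phylogenetics.

Pairwise global alignment (affine gaps, BLOSUM62 by default) backs percent
identity; a guide-tree progressive aligner produces family MSAs; evolutionary
distances use the Poisson correction d = -ln(1 - p) for the proportion p of
differing aligned sites; trees come from neighbor joining, with support from
majority-rule bootstrap consensus over column-resampled replicates.

Identity is computed over columns with no gap in either row. NJ is exact on
additive matrices (topology and branch lengths); negative branch lengths from
non-additive input are clamped to zero, as is conventional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix, TreeNode

AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX-"


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring: a named substitution matrix or match/mismatch, with
    affine gap penalties (a gap of length L costs open + (L-1) * extend)."""

    matrix: Optional[str] = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


def _aligner(scoring: Scoring) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    if scoring.matrix:
        al.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        al.match_score = scoring.match
        al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def percent_identity(row_a: str, row_b: str) -> float:
    """100 x identical pairs / columns with no gap in either row."""
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


def global_align(a, b, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences."""
    seq_a = getattr(a, "sequence", a)
    seq_b = getattr(b, "sequence", b)
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _aligner(scoring).align(seq_a, seq_b)[0]
    row_a, row_b = aln[0], aln[1]
    return AlignmentResult(row_a, row_b, float(aln.score), percent_identity(row_a, row_b))


# --- progressive MSA ------------------------------------------------------

def _substitution_array(scoring: Scoring) -> np.ndarray:
    """Residue-by-residue score table over AA_ORDER; gap and X rows are 0."""
    k = len(AA_ORDER)
    S = np.zeros((k, k))
    if scoring.matrix:
        mat = substitution_matrices.load(scoring.matrix)
        for i, x in enumerate(AA_ORDER[:20]):
            for j, y in enumerate(AA_ORDER[:20]):
                S[i, j] = mat[x, y]
    else:
        S[:20, :20] = scoring.mismatch
        np.fill_diagonal(S[:20, :20], scoring.match)
    return S


def _profile_counts(rows: list[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(AA_ORDER)}
    counts = np.zeros((len(rows[0]), len(AA_ORDER)))
    for row in rows:
        for j, c in enumerate(row):
            counts[j, idx.get(c, idx["X"])] += 1
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], S: np.ndarray, scoring: Scoring
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles (sum-of-pairs, averaged)."""
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    col = (ca @ S @ cb.T) / (len(rows_a) * len(rows_b))
    n, m = col.shape
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = -1e30

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consumes A column)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        ci = col[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + ci[j - 1]
            Xi[j] = max(Mi1[j] + go, Xi1[j] + ge, Yi1[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Yi[j - 1] + ge, Xi[j - 1] + go)

    # traceback (prefer diagonal, then gap-in-B, then gap-in-A)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
            nstate = int(np.argmax(prev))
            out_a.append(i - 1)
            out_b.append(j - 1)
            i, j, state = i - 1, j - 1, nstate
        elif state == 1 and i > 0:
            cands = [M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go]
            nstate = int(np.argmax(cands))
            out_a.append(i - 1)
            out_b.append(None)
            i, state = i - 1, nstate
        elif state == 2 and j > 0:
            cands = [M[i][j - 1] + go, Y[i][j - 1] + ge, X[i][j - 1] + go]
            nstate = [0, 2, 1][int(np.argmax(cands))]
            out_a.append(None)
            out_b.append(j - 1)
            j, state = j - 1, nstate
        else:  # boundary: forced gap
            if i > 0:
                out_a.append(i - 1)
                out_b.append(None)
                i -= 1
            else:
                out_a.append(None)
                out_b.append(j - 1)
                j -= 1
    out_a.reverse()
    out_b.reverse()

    def expand(rows: list[str], cols: list) -> list[str]:
        return ["".join(row[c] if c is not None else "-" for c in cols) for row in rows]

    return expand(rows_a, out_a), expand(rows_b, out_b)


def progressive_msa(seqs: Sequence, scoring: Scoring = DEFAULT_SCORING) -> list[str]:
    """Guide-tree progressive multiple alignment.

    The guide tree is UPGMA on pairwise p-distances from global alignments;
    merges align profiles with averaged sum-of-pairs scores. Rows are returned
    in input order and de-gap to their inputs. Deterministic given input order.
    Quadratic DP per merge: intended for family-sized inputs (tens of
    sequences), not whole proteomes.
    """
    sequences = [getattr(s, "sequence", s) for s in seqs]
    if len(sequences) < 2:
        raise ValueError("progressive_msa needs >= 2 sequences")
    if len(sequences) == 2:
        res = global_align(sequences[0], sequences[1], scoring)
        return [res.aligned_a, res.aligned_b]

    n = len(sequences)
    pdist = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(sequences[i], sequences[j], scoring).identity_pct
            pdist[k] = 1.0 - ident / 100.0
            k += 1
    Z = linkage(pdist, method="average")

    S = _substitution_array(scoring)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b, S, scoring)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)

    order, rows = clusters.popitem()[1]
    result = [None] * n
    for pos, row in zip(order, rows):
        result[pos] = row
    return result


# --- Poisson distances ----------------------------------------------------

def poisson_distance(msa: Sequence[str], i: int, j: int) -> float:
    """Poisson-corrected distance between aligned rows i and j.

    p = differing sites / sites where neither row is gapped; d = -ln(1 - p).
    """
    diffs = 0
    comparable = 0
    for x, y in zip(msa[i], msa[j]):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError("distance undefined: no comparable sites")
    p = diffs / comparable
    if p >= 1.0:
        raise ValueError("distance undefined: p >= 1")
    return -np.log(1.0 - p)


def poisson_distance_matrix(msa: Sequence[str], ids: Sequence[str]) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(msa, i, j)
    return DistanceMatrix(d, list(ids))


# --- neighbor joining -----------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; exact on additive matrices.

    Ties in the Q criterion break toward the lowest index pair. Negative limb
    lengths (non-additive input only) are clamped to zero. The returned tree
    is unrooted (trifurcating root).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("nj_tree needs >= 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=name) for name in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent.append(child_i)
        parent.append(child_j)

        new_d = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            nd = 0.5 * (d[i, ka] + d[j, ka] - d[i, j])
            new_d[a, m - 2] = new_d[m - 2, a] = nd
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # final three taxa: three-point formulas
    root = TreeNode()
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(length, 0.0)
        root.append(node)
    return root


# --- bootstrap consensus --------------------------------------------------

def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the smaller side
    (lexicographic tie-break on equal halves)."""
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (
            len(side) == len(other) and sorted(side) < sorted(other)
        ):
            parts.add(side)
        else:
            parts.add(other)
    return parts


def _saturation_capped_poisson(sub: np.ndarray, gap_code: int) -> np.ndarray:
    """Pairwise Poisson distances on a column-resampled alignment, with
    saturated pairs (p >= 1 or no comparable sites) capped instead of raised:
    bootstrap replicates must always yield a distance."""
    n, L = sub.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (sub[i] != gap_code) & (sub[j] != gap_code)
            comparable = int(ok.sum())
            if comparable == 0:
                p = 1.0 - 1.0 / (2 * (L + 1))
            else:
                p = (sub[i][ok] != sub[j][ok]).sum() / comparable
                p = min(p, 1.0 - 1.0 / (2 * comparable))
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return d


def bootstrap_consensus(
    msa: Sequence[str],
    ids: Sequence[str],
    replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Majority-rule (>50%) consensus of NJ trees over column-resampled
    replicates; internal nodes carry integer percent support.

    Replicate r draws from an independent RNG stream (seed, r), so results do
    not depend on evaluation order. Deterministic given the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    import warnings

    L = len(msa[0])
    if L < 4:
        warnings.warn("alignment has < 4 columns; bootstrap support is unreliable")
    idx = {c: i for i, c in enumerate(AA_ORDER)}
    gap_code = idx["-"]
    arr = np.array(
        [[idx.get(c, idx["X"]) for c in row] for row in msa], dtype=np.int8
    )
    all_tips = frozenset(ids)

    counts: dict[frozenset[str], int] = {}
    for r in range(replicates):
        rng = np.random.default_rng([int(seed), r])
        cols = rng.integers(0, L, size=L)
        d = _saturation_capped_poisson(arr[:, cols], gap_code)
        tree = nj_tree(DistanceMatrix(d, list(ids)))
        for part in _bipartitions(tree, all_tips):
            counts[part] = counts.get(part, 0) + 1

    majority = {
        part: 100.0 * c / replicates
        for part, c in counts.items()
        if c / replicates > 0.5
    }
    return _build_consensus(majority, list(ids))


def _build_consensus(
    supported: dict[frozenset[str], float], ids: list[str]
) -> TreeNode:
    """Build a tree from a laminar family of >50% bipartitions.

    Each bipartition is realized on the side not containing the first taxon
    (a fixed arbitrary rooting); majority bipartitions are mutually
    compatible, so insertion order by decreasing size is always realizable.
    """
    anchor = ids[0]
    groups = []
    for part, support in supported.items():
        side = part if anchor not in part else frozenset(ids) - part
        if 2 <= len(side) <= len(ids) - 2:
            groups.append((side, support))
    groups.sort(key=lambda g: (-len(g[0]), sorted(g[0])))

    root = TreeNode()
    tipsets: dict[int, frozenset[str]] = {}
    for name in ids:
        tip = TreeNode(name=name)
        root.append(tip)
        tipsets[id(tip)] = frozenset([name])
    tipsets[id(root)] = frozenset(ids)

    for side, support in groups:
        host = root
        while True:
            child_host = None
            for ch in host.children:
                if not ch.is_tip() and side <= tipsets[id(ch)]:
                    child_host = ch
                    break
            if child_host is None:
                break
            host = child_host
        members = [ch for ch in host.children if tipsets[id(ch)] <= side]
        if not members or frozenset().union(*(tipsets[id(m)] for m in members)) != side:
            continue  # incompatible remainder; cannot happen for >50% cutoffs
        new = TreeNode()
        new.support = int(round(support))
        for m in members:
            host.remove(m)
            new.append(m)
        host.append(new)
        tipsets[id(new)] = side
    return root


def to_newick(tree: TreeNode) -> str:
    """Newick string; skbio renders integer ``support`` attributes as
    internal node labels."""
    return str(tree).strip()


def read_newick(source: str) -> TreeNode:
    return TreeNode.read([source])
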