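"""Pairwise alignment, Jukes-Cantor distances, relative-rate tests, and
small exhaustive minimum-evolution trees.

The scientific target is the rate contrast between a degenerate tRNA
paralog (a pseudogene) and its functional counterpart, measured against a
shared outgroup: under equal rates the two lineages' distances to the
outgroup are equal in expectation, and the test statistic
z = (rate1 - rate2) / SD is asymptotically standard normal.  Distances use
the Jukes-Cantor model, d = -(3/4) ln(1 - 4p/3), whose sampling variance is
p(1-p) / (L (1 - 4p/3)^2) for L compared sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm

GAP = "-"


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    match: float
    mismatch: float
    gap: float

    @property
    def identity(self) -> float:
        """Percent identical columns over all alignment columns (gap columns
        count in the denominator)."""
        same = sum(a == b and a != GAP for a, b in zip(self.aligned_a, self.aligned_b))
        return 100.0 * same / len(self.aligned_a)

    @property
    def identity_gap_excluded(self) -> float:
        pairs = [(a, b) for a, b in zip(self.aligned_a, self.aligned_b)
                 if GAP not in (a, b)]
        return 100.0 * sum(a == b for a, b in pairs) / len(pairs)


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap: float = -2.0) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with linear gap penalty.

    Tie-break on traceback is diagonal > up (gap in ``b``) > left (gap in
    ``a``), which makes the reported alignment deterministic.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    bvec = np.frombuffer(b.encode(), dtype=np.uint8)
    avec = np.frombuffer(a.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(bvec == avec[i - 1], match, mismatch)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] + gap
        prev = score[i, 0]
        row = score[i]
        prow = ptr[i]
        for j in range(1, m + 1):
            left = prev + gap
            best, which = diag[j - 1], 0
            if up[j - 1] > best:
                best, which = up[j - 1], 1
            if left > best:
                best, which = left, 2
            row[j] = best
            prow[j] = which
            prev = best
    out_a, out_b = [], []
    i, j = n, m
    while i or j:
        which = ptr[i, j]
        if which == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif which == 1:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(score[n, m]), match, mismatch, gap)


def strip_gap_columns(rows: list[str]) -> tuple[list[str], int, int]:
    """Remove every column containing a gap from an equal-length alignment.

    Returns (stripped rows, surviving sites, parsimony-informative sites).
    """
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    cols = [c for c in zip(*rows) if GAP not in c]
    if not cols:
        raise ValueError("no gap-free columns survive")
    stripped = ["".join(r) for r in zip(*cols)]
    informative = 0
    for c in cols:
        counts = {}
        for ch in c:
            counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return stripped, len(cols), informative


@dataclass
class DistanceEntry:
    taxon_a: str
    taxon_b: str
    p: float       # proportion of differing sites
    d: float       # Jukes-Cantor distance
    var_d: float   # sampling variance of d
    L: int         # compared sites


def jc_distance(p: float, L: int) -> tuple[float, float]:
    """Jukes-Cantor distance and its variance from a p-distance over L sites."""
    if not 0 <= p < 0.75:
        raise ValueError(f"JC distance saturates at p >= 0.75 (got p={p})")
    d = -0.75 * math.log1p(-4.0 * p / 3.0)
    var = p * (1 - p) / (L * (1 - 4.0 * p / 3.0) ** 2) if L > 0 else float("nan")
    return d, var


def p_distance(a: str, b: str) -> tuple[float, int]:
    """p and L over gap-free columns of two aligned rows."""
    pairs = [(x, y) for x, y in zip(a, b) if GAP not in (x, y)]
    L = len(pairs)
    diffs = sum(x != y for x, y in pairs)
    return diffs / L, L


def distance_matrix(aligned: dict[str, str]) -> list[DistanceEntry]:
    """All pairwise JC distances from a pre-aligned, gap-stripped set."""
    entries = []
    for ta, tb in combinations(aligned, 2):
        p, L = p_distance(aligned[ta], aligned[tb])
        d, var = jc_distance(p, L)
        entries.append(DistanceEntry(ta, tb, p, d, var, L))
    return entries


def _lookup(entries: list[DistanceEntry]) -> dict[frozenset, DistanceEntry]:
    return {frozenset((e.taxon_a, e.taxon_b)): e for e in entries}


def to_square_matrix(entries: list[DistanceEntry],
                     taxa: list[str] | None = None):
    """(taxa, ndarray) square distance matrix from pairwise entries."""
    look = _lookup(entries)
    if taxa is None:
        taxa = sorted({t for e in entries for t in (e.taxon_a, e.taxon_b)})
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                D[i, j] = D[j, i] = look[frozenset((a, b))].d
    return taxa, D


def write_phylip_matrix(entries: list[DistanceEntry], path) -> None:
    """PHYLIP-style square distance matrix (lower+upper, full)."""
    taxa, D = to_square_matrix(entries)
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for t, row in zip(taxa, D):
            fh.write(f"{t:<10s} " + " ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class RelativeRateResult:
    rate1: float
    rate2: float
    sd: float
    z: float
    p_value: float


def _jc_var_at(d: float, L: float) -> float:
    """Variance of a JC estimate whose true distance is d (delta method)."""
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    return p * (1 - p) / (L * (1 - 4.0 * p / 3.0) ** 2)


def _p_mismatch(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _joint_mismatch(b1: float, b2: float, c: float) -> float:
    """P(leaf1 != outgroup and leaf2 != outgroup) under JC on the 3-taxon
    star (branches b1, b2 to the lineages, c to the outgroup), by direct
    4-state enumeration."""

    def trans(t: float) -> list[list[float]]:
        e = math.exp(-4.0 * t / 3.0)
        same, diff = 0.25 + 0.75 * e, 0.25 * (1.0 - e)
        return [[same if i == j else diff for j in range(4)] for i in range(4)]

    t1, t2, tc = trans(b1), trans(b2), trans(c)
    total = 0.0
    for x in range(4):
        for o in range(4):
            po = 0.25 * tc[x][o]
            p1_diff = sum(t1[x][s] for s in range(4) if s != o)
            p2_diff = sum(t2[x][s] for s in range(4) if s != o)
            total += po * p1_diff * p2_diff
    return total


def _jc_cov(d1o: float, d2o: float, d12: float, L: float) -> float:
    """Covariance of the two lineage-to-outgroup JC estimates, from the
    branch lengths implied by the three mean distances (delta method on the
    exact joint mismatch probability)."""
    a = max(0.0, (d1o + d2o - d12) / 2.0)   # outgroup -> ancestor
    b1 = max(0.0, d1o - a)
    b2 = max(0.0, d2o - a)
    p1, p2 = _p_mismatch(d1o), _p_mismatch(d2o)
    cov_p = (_joint_mismatch(b1, b2, a) - p1 * p2) / L
    return cov_p / ((1.0 - 4.0 * p1 / 3.0) * (1.0 - 4.0 * p2 / 3.0))


def relative_rate_test(distances: list[DistanceEntry], lineage1: list[str],
                       lineage2: list[str], outgroup: list[str]) -> RelativeRateResult:
    """Two-lineage relative-rate test against a shared outgroup.

    Lineage rates are mean distances to the common ancestor of the two
    lineages, rate_i = (d12 + d_iO - d_jO)/2 with equal weight per taxon.
    The variance of rate1 - rate2 = d1O - d2O subtracts twice the shared-
    path covariance, approximated by the JC sampling variance of the
    outgroup-to-ancestor path — the topology-based covariance treatment of
    standard relative-rate software.
    """
    look = _lookup(distances)

    def mean_d(xs: list[str], ys: list[str]) -> tuple[float, float, float]:
        ds, vars_, Ls = [], [], []
        for x in xs:
            for y in ys:
                key = frozenset((x, y))
                if key not in look:
                    raise KeyError(f"missing distance for pair {x}-{y}")
                e = look[key]
                ds.append(e.d); vars_.append(e.var_d); Ls.append(e.L)
        return float(np.mean(ds)), float(np.mean(vars_)), float(np.mean(Ls))

    d1o, v1, L1 = mean_d(lineage1, outgroup)
    d2o, v2, L2 = mean_d(lineage2, outgroup)
    d12, _, _ = mean_d(lineage1, lineage2)
    rate1 = (d12 + d1o - d2o) / 2.0
    rate2 = (d12 + d2o - d1o) / 2.0
    cov = _jc_cov(d1o, d2o, d12, (L1 + L2) / 2.0)
    var = v1 + v2 - 2.0 * cov
    sd = math.sqrt(max(var, 1e-300))
    z = (rate1 - rate2) / sd
    p_value = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return RelativeRateResult(rate1, rate2, sd, z, p_value)


# ---------------------------------------------------------------------------
# Minimum-evolution trees by exhaustive topology enumeration (<= 8 taxa)


@dataclass
class METree:
    newick: str
    branch_lengths: dict[frozenset, float]  # edge (as frozenset of node ids)
    total_length: float
    edges: list[tuple[int, int]]
    leaves: dict[int, str]


def _enumerate_topologies(n: int):
    """All unrooted binary topologies on n labelled leaves (leaf ids 0..n-1,
    internal ids n, n+1, ...), as edge lists, by stepwise insertion."""
    if n == 3:
        yield [(3, 0), (3, 1), (3, 2)]
        return
    trees = [[(n, 0), (n, 1), (n, 2)]]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                nid = next_internal
                e2 = edges[:k] + edges[k + 1:] + [(u, nid), (nid, v), (nid, leaf)]
                new_trees.append(e2)
        trees = new_trees
        next_internal += 1
    yield from trees


def _path_matrix(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    """Indicator matrix: rows = leaf pairs (in combinations order), cols =
    edges, 1 where the edge lies on the pair's path."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    pairs = list(combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))

    def path_edges(src: int, dst: int) -> list[int]:
        stack = [(src, -1, [])]
        while stack:
            node, parent, used = stack.pop()
            if node == dst:
                return used
            for nxt, k in adj[node]:
                if nxt != parent:
                    stack.append((nxt, node, used + [k]))
        raise RuntimeError("disconnected tree")

    for r, (i, j) in enumerate(pairs):
        for k in path_edges(i, j):
            A[r, k] = 1.0
    return A


def _newick(edges: list[tuple[int, int]], leaves: dict[int, str],
            lengths: np.ndarray | None = None) -> str:
    adj: dict[int, list[tuple[int, int]]] = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    root = max(adj)  # an internal node (internal ids exceed leaf ids)

    def sub(node: int, parent: int) -> str:
        children = [(c, k) for c, k in adj[node] if c != parent]
        if not children:
            return leaves[node]
        parts = []
        for c, k in children:
            s = sub(c, node)
            if lengths is not None:
                s += f":{lengths[k]:.6f}"
            parts.append(s)
        parts.sort()
        return "(" + ",".join(parts) + ")"

    return sub(root, -1) + ";"


def me_tree_small(dist: np.ndarray, taxa: list[str]) -> METree:
    """Minimum-evolution tree by exhaustive search: OLS branch lengths on
    every unrooted topology, minimal total length wins (ties broken by
    canonical newick encoding)."""
    n = len(taxa)
    if n > 8:
        raise ValueError("exhaustive ME search is capped at 8 taxa")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) \
            or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    dvec = np.array([dist[i, j] for i, j in combinations(range(n), 2)])
    leaves = dict(enumerate(taxa))
    best = None
    for edges in _enumerate_topologies(n):
        A = _path_matrix(edges, n)
        b, *_ = np.linalg.lstsq(A, dvec, rcond=None)
        total = float(b.sum())
        key = (round(total, 12), _newick(edges, leaves))
        if best is None or key < best[0]:
            blens = {frozenset(e): float(x) for e, x in zip(edges, b)}
            best = (key, METree(_newick(edges, leaves, b), blens, total,
                                edges, leaves))
    return best[1]
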