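"""Independent reference implementations used only as test oracles.

Each oracle is written as a direct, unoptimised transcription of the
definition it checks — exhaustive enumeration or dense linear algebra —
and shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# local alignment by exhaustive enumeration
# ---------------------------------------------------------------------------

_B62 = substitution_matrices.load("BLOSUM62")


def _global_enumerate(a: str, b: str, go: float, ge: float) -> float:
    """Best global affine-gap alignment score by recursive enumeration.

    Gap of length L costs go + L*ge (first gap residue go + ge, then ge).
    """

    def rec(i: int, j: int, last: str | None) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = ge if last == "A" else go + ge
            best = max(best, -cost + rec(i + 1, j, "A"))
        if j < len(b):
            cost = ge if last == "B" else go + ge
            best = max(best, -cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, None)


def local_align_bruteforce(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score: max over all substring pairs of the
    exhaustively enumerated global score, floored at 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best,
                        _global_enumerate(a[i1:i2], b[j1:j2], gap_open, gap_extend),
                    )
    return best


# ---------------------------------------------------------------------------
# dense Markov clustering
# ---------------------------------------------------------------------------


def mcl_dense(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    inflation: float = 1.5,
    max_iter: int = 100,
    prune_eps: float = 1e-5,
) -> set[frozenset[str]]:
    """Markov clustering with dense numpy matrices; returns the partition."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, w in edges:
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)

    def norm(A):
        s = A.sum(axis=0)
        s[s == 0] = 1.0
        return A / s

    M = norm(M)
    for _ in range(max_iter):
        prev = M.copy()
        M = norm(M @ M) ** inflation
        M = norm(M)
        M[M < prune_eps] = 0.0
        M = norm(M)
        if np.abs(M - prev).max() < 1e-8:
            break

    # connected components of the symmetrised support
    B = (M + M.T) > 0
    unseen = set(range(n))
    clusters = set()
    while unseen:
        start = unseen.pop()
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in np.nonzero(B[x])[0]:
                if y in unseen:
                    unseen.remove(y)
                    comp.add(int(y))
                    stack.append(int(y))
        clusters.add(frozenset(nodes[i] for i in comp))
    return clusters


# ---------------------------------------------------------------------------
# category rule table
# ---------------------------------------------------------------------------


def classify_ruletable(
    copies: dict[str, int], species: list[str], lineage: set[str]
) -> str:
    """Category by literal precedence-ordered rule evaluation."""
    S = len(species)
    present = {s for s in species if copies.get(s, 0) >= 1}
    deviating = sum(1 for s in species if copies.get(s, 0) != 1)
    absent = sum(1 for s in species if copies.get(s, 0) == 0)
    if len(present) == 1:
        return "species-specific"
    if deviating <= 1:
        return "universal-single"
    if absent <= 1:
        return "universal-multi"
    if lineage and present <= lineage and len(present) >= 3:
        return "lineage-only"
    if len(present) >= math.ceil(S / 2):
        return "present-at-half"
    return "patchy"


# ---------------------------------------------------------------------------
# random additive trees
# ---------------------------------------------------------------------------


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], set[frozenset[str]]]:
    """Random unrooted binary tree: returns its additive distance matrix,
    taxon labels, and the set of canonical internal bipartitions."""
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    # grow by attaching each new taxon to a random existing edge
    # adjacency: node -> {neighbor: length}
    adj: dict[int, dict[int, float]] = {}
    leaf_of: dict[int, str] = {}

    def new_node(name=None):
        nid = len(adj) + 1000
        adj[nid] = {}
        if name is not None:
            leaf_of[nid] = name
        return nid

    def link(u, v, w):
        adj[u][v] = w
        adj[v][u] = w

    def unlink(u, v):
        del adj[u][v]
        del adj[v][u]

    def blen():
        return float(rng.uniform(0.05, 0.3))

    a = new_node(labels[0])
    b = new_node(labels[1])
    link(a, b, blen())
    c = new_node(labels[2])
    mid = new_node()
    w = adj[a][b]
    unlink(a, b)
    link(a, mid, w / 2)
    link(mid, b, w / 2)
    link(mid, c, blen())
    for name in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        unlink(u, v)
        mid = new_node()
        link(u, mid, w / 2)
        link(mid, v, w / 2)
        link(mid, new_node(name), blen())

    # path distances by BFS from each leaf
    leaves = {nid: nm for nid, nm in leaf_of.items()}
    order = sorted(leaves, key=lambda nid: leaves[nid])
    D = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(order):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, dst in enumerate(order):
            D[i, j] = dist[dst]

    all_set = frozenset(labels)
    ref = min(labels)
    biparts = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                seen = {u, v}
                stack = [v]
                side = set()
                while stack:
                    x = stack.pop()
                    if x in leaf_of:
                        side.add(leaf_of[x])
                    for y in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                fs = frozenset(side)
                if ref in fs:
                    fs = all_set - fs
                if 2 <= len(fs) <= n_taxa - 2:
                    biparts.add(fs)
    return D, labels, biparts


# ---------------------------------------------------------------------------
# exhaustive three-sequence alignment
# ---------------------------------------------------------------------------


def threeway_align_optimum(a: str, b: str, c: str, g: float) -> float:
    """Optimal sum-of-pairs score for three sequences by 3D dynamic
    programming with linear gap cost ``g`` per gap symbol in each pairwise
    projection (gap-gap pairs cost 0)."""

    def pair(x: str | None, y: str | None) -> float:
        if x is None and y is None:
            return 0.0
        if x is None or y is None:
            return -g
        return float(_B62[x, y])

    LA, LB, LC = len(a), len(b), len(c)
    NEG = -math.inf
    dp = np.full((LA + 1, LB + 1, LC + 1), NEG)
    dp[0, 0, 0] = 0.0
    moves = [(1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for i in range(LA + 1):
        for j in range(LB + 1):
            for k in range(LC + 1):
                if dp[i, j, k] == NEG:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > LA or nj > LB or nk > LC:
                        continue
                    ca = a[i] if di else None
                    cb = b[j] if dj else None
                    cc = c[k] if dk else None
                    sc = pair(ca, cb) + pair(ca, cc) + pair(cb, cc)
                    val = dp[i, j, k] + sc
                    if val > dp[ni, nj, nk]:
                        dp[ni, nj, nk] = val
    return float(dp[LA, LB, LC])
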