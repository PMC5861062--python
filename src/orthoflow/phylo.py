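"""Distance-based species-tree inference from the single-copy supermatrix.

p-distances (1 - fraction identical over columns where both species are
non-gap) feed neighbor joining (Q-criterion agglomeration with the
standard branch-length formulas); internal-edge support comes from
bootstrap resampling of supermatrix columns.  The method is deterministic:
agglomeration ties break on the lexicographically smallest pair of cluster
labels, and the bootstrap is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .blocks import Supermatrix
from .seqio import GAP


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


class UnrootedTree:
    """Unrooted tree as an adjacency map; leaves carry species labels."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_name: dict[int, str] = {}
        self._next = 0

    def new_node(self, name: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if name is not None:
            self.leaf_name[nid] = name
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_name.values())

    def _side(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in self.leaf_name:
                out.append(self.leaf_name[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical internal-edge bipartitions (side not containing the
        lexicographically smallest leaf)."""
        all_leaves = frozenset(self.leaf_name.values())
        ref = min(all_leaves)
        out = set()
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    side = self._side(u, v)
                    if ref in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        out.add(side)
        return out

    def to_newick(
        self,
        supports: Mapping[frozenset[str], float] | None = None,
        outgroup: str | None = None,
    ) -> str:
        all_leaves = frozenset(self.leaf_name.values())
        ref = min(all_leaves)
        name_to_id = {n: i for i, n in self.leaf_name.items()}
        if outgroup is not None:
            if outgroup not in name_to_id:
                raise ValueError(f"outgroup {outgroup!r} is not a leaf")
            root = next(iter(self.adj[name_to_id[outgroup]]))
        else:
            root = next(iter(self.adj[name_to_id[ref]]))

        def fmt(node: int, parent: int | None) -> str:
            if node in self.leaf_name:
                return self.leaf_name[node]
            parts = [
                fmt(ch, node) + f":{self.adj[node][ch]:.6g}"
                for ch in sorted(
                    self.adj[node],
                    key=lambda c: min(self._side(node, c)),
                )
                if ch != parent
            ]
            label = ""
            if supports is not None and parent is not None:
                side = self._side(parent, node)
                if ref in side:
                    side = all_leaves - side
                if side in supports:
                    label = f"{supports[side]:.0f}"
            return "(" + ",".join(parts) + ")" + label

        return fmt(root, None) + ";"


@dataclass
class SupportedTree:
    tree: UnrootedTree
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    negative_branches_clamped: bool = False

    def to_newick(self, outgroup: str | None = None) -> str:
        return self.tree.to_newick(self.supports or None, outgroup)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _encode(sm: Supermatrix) -> np.ndarray:
    return np.frombuffer("".join(sm.rows).encode(), dtype=np.uint8).reshape(
        len(sm.rows), -1
    )


def _pdist_from_encoded(enc: np.ndarray) -> np.ndarray:
    gap = ord(GAP)
    n = enc.shape[0]
    D = np.zeros((n, n))
    nogap = enc != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = nogap[i] & nogap[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(f"species pair ({i}, {j}) has no comparable columns")
            matches = int(((enc[i] == enc[j]) & both).sum())
            D[i, j] = D[j, i] = 1.0 - matches / comp
    return D


def p_distances(sm: Supermatrix) -> DistanceMatrix:
    """Pairwise p-distances over comparable (both non-gap) columns."""
    if len(sm.species) < 3:
        raise ValueError("need >= 3 species")
    return DistanceMatrix(list(sm.species), _pdist_from_encoded(_encode(sm)))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dist: DistanceMatrix) -> SupportedTree:
    """Standard neighbor joining with deterministic tie-breaking.

    Joins minimise the Q criterion; exact ties choose the lexicographically
    smallest (label, label) pair, where a cluster is labelled by its
    smallest leaf.  Negative branch lengths are clamped to zero and
    flagged.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tree = UnrootedTree()
    nodes = [tree.new_node(lab) for lab in dist.labels]
    labels = list(dist.labels)  # cluster label = smallest member leaf
    D = dist.matrix.astype(float).copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li_raw = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        li = clamp(li_raw)
        lj = clamp(D[i, j] - li_raw)
        new = tree.new_node()
        tree.add_edge(new, nodes[i], li)
        tree.add_edge(new, nodes[j], lj)
        # grow bookkeeping arrays for the new cluster
        Dn = np.zeros((D.shape[0] + 1, D.shape[0] + 1))
        Dn[: D.shape[0], : D.shape[0]] = D
        k_new = D.shape[0]
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            Dn[k_new, k] = Dn[k, k_new] = dk
        D = Dn
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [k_new]

    # final three-point join
    i, j, k = active
    center = tree.new_node()
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    tree.add_edge(center, nodes[i], li)
    tree.add_edge(center, nodes[j], lj)
    tree.add_edge(center, nodes[k], lk)
    return SupportedTree(tree, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap(sm: Supermatrix, n_reps: int = 100, seed: int = 0) -> SupportedTree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate's NJ tree contributes to the percentage of replicates
    containing each internal bipartition of the tree built on the original
    supermatrix.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = _encode(sm)
    labels = list(sm.species)
    original = neighbor_joining(DistanceMatrix(labels, _pdist_from_encoded(enc)))
    target = original.tree.bipartitions()
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    L = enc.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = neighbor_joining(
            DistanceMatrix(labels, _pdist_from_encoded(enc[:, cols]))
        )
        found = rep.tree.bipartitions()
        for bp in target:
            if bp in found:
                hits[bp] += 1
    original.supports = {bp: 100.0 * h / n_reps for bp, h in hits.items()}
    return original
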