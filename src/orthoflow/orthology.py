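"""Ortholog clustering and gene-family categorisation.

Reciprocal hits become an undirected similarity graph (edge weight = mean
of the two -log10 E-values, capped), the graph is partitioned by Markov
clustering (MCL), and every cluster receives one category label:

* universal-single  — present in all species, tolerating absence *or*
  duplication in at most one genome;
* universal-multi   — present in all species (absence in at most one
  genome tolerated) but failing the single-copy tolerance;
* lineage-only      — present only within a designated lineage, in at
  least three of its genomes;
* species-specific  — all members from a single species;
* present-at-half   — present in at least half (ceil(S/2)) of the genomes;
* patchy            — any remaining scattered presence;
* homology-only     — unclustered genes that nevertheless have a retained
  similarity hit;
* none              — unclustered genes without any hit.

Precedence when rules overlap: species-specific, universal-single,
universal-multi, lineage-only, present-at-half, patchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .search import HitTable

WEIGHT_CAP = 200.0

GROUP_CATEGORIES = (
    "species-specific",
    "universal-single",
    "universal-multi",
    "lineage-only",
    "present-at-half",
    "patchy",
)


@dataclass
class OrthologGroup:
    group_id: str
    members: list[str]
    species_of: dict[str, str] = field(repr=False)

    def copy_counts(self, all_species: Sequence[str]) -> dict[str, int]:
        counts = {s: 0 for s in all_species}
        for m in self.members:
            counts[self.species_of[m]] += 1
        return counts

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MclResult:
    groups: list[OrthologGroup]
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------


def build_graph(
    hits: HitTable,
    species_of: Mapping[str, str],
    genes: Iterable[str] | None = None,
) -> nx.Graph:
    """Undirected reciprocal-hit graph.

    An edge (u, v) exists only if both directed hits passed the E-value
    threshold; its weight is the mean of the two -log10 E-values, capped at
    200 (E-values are floored upstream).  Nodes carry a ``species``
    attribute.  When the full gene universe is passed via ``genes``, genes
    without any hit become isolated nodes, so the clustering partitions
    every gene and hit-less genes end up as singleton groups.
    """
    g = nx.Graph()
    universe = set(genes) if genes is not None else set()
    for gene in sorted(hits.queries_and_subjects() | universe):
        g.add_node(gene, species=species_of[gene])
    for h in hits:
        if h.query >= h.subject:
            continue
        back = hits.get(h.subject, h.query)
        if back is None:
            continue
        w = 0.5 * (-math.log10(h.evalue) - math.log10(back.evalue))
        g.add_edge(h.query, h.subject, weight=min(w, WEIGHT_CAP))
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def _mcl_matrix(
    M: sp.csr_matrix, inflation: float, max_iter: int, prune_eps: float
) -> tuple[sp.csr_matrix, bool, int]:
    """Iterate expansion/inflation on a column-stochastic sparse matrix."""

    def normalize(A: sp.csr_matrix) -> sp.csr_matrix:
        colsum = np.asarray(A.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return (A @ sp.diags(1.0 / colsum)).tocsr()

    M = normalize(M)
    for it in range(1, max_iter + 1):
        prev = M.copy()
        M = (M @ M).tocsr()  # expansion
        M.data = M.data**inflation  # inflation
        M = normalize(M)
        M.data[M.data < prune_eps] = 0.0  # pruning
        M.eliminate_zeros()
        M = normalize(M)
        change = abs(M - prev).max() if (M - prev).nnz else 0.0
        if change < 1e-8:
            return M, True, it
    return M, False, max_iter


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    prune_eps: float = 1e-5,
) -> MclResult:
    """Markov clustering of the similarity graph into ortholog groups.

    Self-loops are added with the node's maximum incident edge weight
    (1.0 for isolated nodes), columns are normalised to a stochastic
    matrix, and expansion (squaring) alternates with inflation
    (elementwise power then renormalisation) until the matrix change drops
    below 1e-8 or ``max_iter`` is reached.  Clusters are read off the
    attractor structure of the limit matrix and always partition the node
    set.  Deterministic: node order is the sorted gene id order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return MclResult([], True, 0)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    loop = np.ones(n)
    for u, v, w in graph.edges(data="weight"):
        i, j = idx[u], idx[v]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    rows += list(range(n))
    cols += list(range(n))
    data += list(loop)
    M = sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    M, converged, iters = _mcl_matrix(M, inflation, max_iter, prune_eps)

    # connected components of the attractor relation give the partition
    B = (M + M.T).astype(bool)
    n_comp, labels = sp.csgraph.connected_components(B, directed=False)
    species_of = {m: graph.nodes[m]["species"] for m in nodes}
    clusters: dict[int, list[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), []).append(node)
    members_sorted = sorted(clusters.values(), key=lambda ms: ms[0])
    width = max(4, len(str(len(members_sorted))))
    groups = [
        OrthologGroup(f"OG{i + 1:0{width}d}", ms,
                      {m: species_of[m] for m in ms})
        for i, ms in enumerate(members_sorted)
    ]
    return MclResult(groups, converged, iters)


# ---------------------------------------------------------------------------
# categorisation
# ---------------------------------------------------------------------------


def classify_counts(
    copies: Mapping[str, int],
    all_species: Sequence[str],
    lineage_species: Iterable[str] = (),
) -> str:
    """Category label for a per-species copy-count vector.

    Rules are applied in precedence order (see module docstring); exactly
    one label is returned for any vector with at least one copy.
    """
    lineage = set(lineage_species)
    if not lineage <= set(all_species):
        raise ValueError("lineage species must be a subset of the species universe")
    S = len(all_species)
    c = [int(copies.get(s, 0)) for s in all_species]
    present = [s for s, k in zip(all_species, c) if k >= 1]
    if not present:
        raise ValueError("copy-count vector has no present species")

    if len(present) == 1:
        return "species-specific"
    if sum(1 for k in c if k != 1) <= 1:
        return "universal-single"
    if sum(1 for k in c if k == 0) <= 1:
        return "universal-multi"
    if lineage and set(present) <= lineage and len(present) >= 3:
        return "lineage-only"
    if len(present) >= math.ceil(S / 2):
        return "present-at-half"
    return "patchy"


def classify_group(
    group: OrthologGroup,
    all_species: Sequence[str],
    lineage_species: Iterable[str] = (),
) -> str:
    return classify_counts(group.copy_counts(all_species), all_species, lineage_species)


def flag_homology_only(
    genes: Iterable[str], hits: HitTable, groups: Sequence[OrthologGroup]
) -> set[str]:
    """Genes outside every multi-gene group that still have a retained hit."""
    grouped = {m for g in groups if len(g) > 1 for m in g.members}
    with_hits = hits.queries_and_subjects()
    return {g for g in genes if g not in grouped and g in with_hits}


def category_counts(
    groups: Sequence[OrthologGroup],
    labels: Mapping[str, str],
    all_species: Sequence[str],
    all_genes: Mapping[str, str] | None = None,
    hits: HitTable | None = None,
) -> pd.DataFrame:
    """Species x category table of gene counts.

    ``labels`` maps group id to category.  When the full gene universe
    (gene id -> species) and the hit table are supplied, unclustered genes
    are tallied under homology-only / none so each species row sums to its
    proteome size.
    """
    cats = list(GROUP_CATEGORIES) + ["homology-only", "none"]
    table = pd.DataFrame(0, index=list(all_species), columns=cats, dtype=int)
    clustered: set[str] = set()
    for g in groups:
        if g.group_id not in labels:
            raise ValueError(f"group {g.group_id} has no category label")
        if len(g) == 1:
            continue  # singletons are handled as unclustered genes below
        for m in g.members:
            table.loc[g.species_of[m], labels[g.group_id]] += 1
            clustered.add(m)
    if all_genes is not None:
        with_hits = hits.queries_and_subjects() if hits is not None else set()
        for gene, sp_label in all_genes.items():
            if gene in clustered:
                continue
            col = "homology-only" if gene in with_hits else "none"
            table.loc[sp_label, col] += 1
    return table


def select_single_copy(
    groups: Sequence[OrthologGroup],
    species_subset: Sequence[str],
    strict: bool = True,
) -> list[OrthologGroup]:
    """Single-copy groups over a species subset.

    Copy counts are projected onto the subset.  ``strict`` keeps only
    groups with exactly one copy in *every* subset species (the
    concatenation-ready set); tolerant mode applies the universal
    single-copy rule, allowing absence or duplication in one genome.
    """
    subset = list(species_subset)
    if not subset:
        raise ValueError("species subset must be non-empty")
    out = []
    for g in groups:
        counts = g.copy_counts(subset)
        vals = [counts[s] for s in subset]
        if strict:
            ok = all(v == 1 for v in vals)
        else:
            ok = sum(1 for v in vals if v != 1) <= 1 and sum(vals) >= 1
        if ok:
            out.append(g)
    return out


def write_groups(
    groups: Sequence[OrthologGroup], labels: Mapping[str, str], path
) -> None:
    """Groups as tab-separated ``group_id  species  gene_id  category``."""
    with open(path, "w") as fh:
        fh.write("#group\tspecies\tgene\tcategory\n")
        for g in groups:
            for m in sorted(g.members):
                fh.write(f"{g.group_id}\t{g.species_of[m]}\t{m}\t{labels.get(g.group_id, '')}\n")
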