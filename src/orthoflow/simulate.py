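"""Ground-truthed synthetic proteome evolution.

Generates per-species protein FASTA files whose gene-family structure
(universal single-copy, universal multi-copy, lineage-restricted,
species-specific, patchy) and sequence divergence are known exactly, so the
clustering, identity and phylogeny stages can be tested against truth.

Replacement model
-----------------
Sequences evolve along a species tree under a Poisson replacement process:
along a branch of length ``d`` (expected replacements per site) each site is
hit by at least one event with probability ``1 - exp(-d)``; on an event the
residue is redrawn from the stationary frequency vector ``pi`` (possibly
redrawing the same residue).  Because every redraw is an independent draw
from ``pi``, the expected fraction of identical sites between two leaves at
path distance ``D`` has the closed form::

    E[identity] = exp(-D) + (1 - exp(-D)) * sum(pi**2)

which the test suite uses as an exact oracle.  There are no indels: family
alignments are gap-free by construction.  Gene duplications copy the current
sequence at the midpoint of the terminal branch of the duplicated lineage
and evolve independently thereafter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .seqio import AMINO_ACIDS, FastaRecord, Proteome, write_fasta

CATEGORIES = (
    "universal-single",
    "universal-multi",
    "lineage-only",
    "species-specific",
    "present-at-half",
    "patchy",
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTree:
    """Rooted binary species tree with branch lengths in expected
    replacements per site."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(leaves) < 3:
            raise ValueError(f"species tree needs >= 3 leaves, got {len(leaves)}")
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            d = node.edge.length
            where = node.taxon.label if node.taxon else "internal node"
            if d is None:
                raise ValueError(f"missing branch length above {where}")
            if d < 0:
                raise ValueError(f"negative branch length {d} above {where}")

    @property
    def species(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def path_distance(self, a: str, b: str) -> float:
        """Patristic distance (sum of branch lengths) between two leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        return pdm.patristic_distance(
            tns.get_taxon(a), tns.get_taxon(b)
        )

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def parse_newick(text: str) -> SpeciesTree:
    """Parse a newick string with mandatory branch lengths.

    Malformed input, duplicate leaf labels and negative branch lengths are
    rejected; parse errors carry the offending position, semantic errors
    name the offending taxon.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    return SpeciesTree(tree)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# family specifications
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    """One gene family: its category and per-species copy counts."""

    family_id: str
    category: str
    copies: dict[str, int]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not any(c >= 1 for c in self.copies.values()):
            raise ValueError(f"family {self.family_id}: no species has a copy")
        if any(c < 0 for c in self.copies.values()):
            raise ValueError(f"family {self.family_id}: negative copy count")

    @property
    def present(self) -> list[str]:
        return sorted(s for s, c in self.copies.items() if c >= 1)


@dataclass
class CopyParams:
    """Tunables for copy-count sampling.

    max_copies:     largest per-species copy number for duplicated lineages.
    extra_dup_rate: Poisson mean of duplicated species beyond the minimum
                    two that universal multi-copy families require.
    """

    max_copies: int = 3
    extra_dup_rate: float = 0.5


@dataclass
class GeneRecord:
    gene_id: str
    species: str
    family_id: str
    seq: str


@dataclass
class TruthSet:
    """Everything the simulator knows: specs, genes, and parameters."""

    families: list[FamilySpec]
    genes: list[GeneRecord]
    params: dict
    tree: SpeciesTree | None = None

    def family_of(self) -> dict[str, str]:
        return {g.gene_id: g.family_id for g in self.genes}

    def category_of(self) -> dict[str, str]:
        cat = {f.family_id: f.category for f in self.families}
        return {g.gene_id: cat[g.family_id] for g in self.genes}

    def proteomes(self) -> list[Proteome]:
        by_sp: dict[str, list[FastaRecord]] = {}
        for g in self.genes:
            by_sp.setdefault(g.species, []).append(FastaRecord(g.gene_id, g.seq))
        return [Proteome(sp, recs) for sp, recs in sorted(by_sp.items())]


def _substream(seed: int, family_id: str) -> np.random.Generator:
    """Per-family RNG substream, stable under family reordering."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(family_id.encode())])


def expected_identity(distance: float, pi: Sequence[float] | None = None) -> float:
    """Closed-form expected per-site identity at path distance ``distance``."""
    p = np.full(20, 0.05) if pi is None else np.asarray(pi, dtype=float)
    return float(np.exp(-distance) + (1.0 - np.exp(-distance)) * np.sum(p**2))


def _check_pi(pi: Sequence[float] | None) -> np.ndarray:
    if pi is None:
        return np.full(20, 0.05)
    p = np.asarray(pi, dtype=float)
    if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be a 20-vector of non-negative frequencies summing to 1")
    return p


# ---------------------------------------------------------------------------
# sampling family specs
# ---------------------------------------------------------------------------


def _sample_one_family(
    fid: str,
    category: str,
    species: list[str],
    lineage: set[str],
    params: CopyParams,
    rng: np.random.Generator,
) -> FamilySpec:
    from .orthology import classify_counts  # deferred: avoid import cycle

    S = len(species)
    for _ in range(1000):
        copies = {s: 0 for s in species}
        if category == "universal-single":
            copies = {s: 1 for s in species}
        elif category == "universal-multi":
            copies = {s: 1 for s in species}
            m = min(S, 2 + rng.poisson(params.extra_dup_rate))
            dup = rng.choice(S, size=m, replace=False)
            for i in dup:
                copies[species[i]] = int(rng.integers(2, params.max_copies + 1))
        elif category == "lineage-only":
            lin = sorted(lineage)
            if len(lin) < 3:
                raise ValueError("lineage-only families need a lineage of >= 3 species")
            k = int(rng.integers(3, len(lin) + 1))
            for i in rng.choice(len(lin), size=k, replace=False):
                copies[lin[i]] = 1
        elif category == "species-specific":
            s = species[int(rng.integers(S))]
            copies[s] = int(rng.integers(1, params.max_copies + 1))
        elif category == "present-at-half":
            half = -(-S // 2)  # ceil(S/2)
            if half > S - 2:
                raise ValueError(f"present-at-half unattainable with {S} species")
            k = int(rng.integers(half, S - 1))
            for i in rng.choice(S, size=k, replace=False):
                copies[species[i]] = 1
        elif category == "patchy":
            half = -(-S // 2)
            if half <= 2:
                raise ValueError(f"patchy unattainable with {S} species")
            k = int(rng.integers(2, half))
            for i in rng.choice(S, size=k, replace=False):
                copies[species[i]] = 1
        spec_try = FamilySpec(fid, category, copies)
        if classify_counts(copies, species, lineage) == category:
            return spec_try
    raise ValueError(
        f"could not sample a {category!r} family over {S} species "
        f"(lineage size {len(lineage)}) in 1000 attempts"
    )


def sample_families(
    tree: SpeciesTree,
    category_proportions: Mapping[str, float],
    n_families: int,
    copy_params: CopyParams | None = None,
    seed: int = 0,
    lineage: Iterable[str] | None = None,
) -> list[FamilySpec]:
    """Sample family specifications with the requested category mixture.

    Each family's copy-count vector is guaranteed to classify to its
    declared category under the group classifier.  Deterministic given
    ``seed``; per-family substreams are derived by stable hashing of the
    family id so the set is reproducible under reordering.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    cats = list(category_proportions)
    props = np.array([category_proportions[c] for c in cats], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"category proportions sum to {props.sum()}, not 1")
    for c in cats:
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r}")
    lineage_set = set(lineage) if lineage is not None else set()
    if "lineage-only" in cats and category_proportions["lineage-only"] > 0 and not lineage_set:
        raise ValueError("lineage-only requested but no lineage species given")
    species = tree.species
    params = copy_params or CopyParams()

    master = np.random.default_rng(seed & 0x7FFFFFFF)
    drawn = master.choice(len(cats), size=n_families, p=props)
    out = []
    width = max(4, len(str(n_families)))
    for i, ci in enumerate(drawn):
        fid = f"F{i + 1:0{width}d}"
        out.append(
            _sample_one_family(
                fid, cats[ci], species, lineage_set, params, _substream(seed, fid)
            )
        )
    return out


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, d: float, pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve one sequence along a branch of length ``d``."""
    out = seq.copy()
    if d <= 0:
        return out
    hit = rng.random(seq.size) < -np.expm1(-d)
    k = int(hit.sum())
    if k:
        out[hit] = rng.choice(20, size=k, p=pi)
    return out


def _decode(seq: np.ndarray) -> str:
    return _AA[seq].tobytes().decode()


def evolve_family(
    tree: SpeciesTree,
    family: FamilySpec,
    pi: Sequence[float] | None = None,
    seed: int = 0,
    root_length: int = 300,
) -> dict[str, list[str]]:
    """Evolve one family down the tree; returns per-species sequence copies.

    Duplications (copy count >= 2) branch at the midpoint of the terminal
    branch of the duplicated lineage and evolve independently to the leaf.
    """
    if root_length < 1:
        raise ValueError("root sequence length must be >= 1")
    p = _check_pi(pi)
    rng = _substream(seed, family.family_id)
    root = rng.choice(20, size=root_length, p=p)

    state: dict[int, np.ndarray] = {id(tree.tree.seed_node): root}
    out: dict[str, list[str]] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = state[id(node.parent_node)]
        d = float(node.edge.length)
        if node.is_leaf():
            sp = node.taxon.label
            c = family.copies.get(sp, 0)
            if c == 0:
                continue
            if c == 1:
                out[sp] = [_decode(_mutate(parent_seq, d, p, rng))]
            else:
                mid = _mutate(parent_seq, d / 2.0, p, rng)
                out[sp] = [_decode(_mutate(mid, d / 2.0, p, rng)) for _ in range(c)]
        else:
            state[id(node)] = _mutate(parent_seq, d, p, rng)
    return out


def simulate_truth(
    tree: SpeciesTree,
    n_families: int,
    category_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    root_length: int = 300,
    pi: Sequence[float] | None = None,
    lineage: Iterable[str] | None = None,
    copy_params: CopyParams | None = None,
) -> TruthSet:
    """Sample families and evolve them: the one-call simulator entry point."""
    props = dict(category_proportions or {"universal-single": 1.0})
    fams = sample_families(
        tree, props, n_families, copy_params=copy_params, seed=seed, lineage=lineage
    )
    p = _check_pi(pi)
    genes: list[GeneRecord] = []
    for fam in fams:
        seqs = evolve_family(tree, fam, pi=p, seed=seed, root_length=root_length)
        for sp in sorted(seqs):
            for k, s in enumerate(seqs[sp], start=1):
                genes.append(GeneRecord(f"{sp}|{fam.family_id}|g{k}", sp, fam.family_id, s))
    params = {
        "seed": int(seed),
        "root_length": int(root_length),
        "pi": [float(x) for x in p],
        "n_families": int(n_families),
        "category_proportions": {k: float(v) for k, v in props.items()},
    }
    return TruthSet(fams, genes, params, tree=tree)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_truth(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write per-species FASTA files plus the ground-truth table.

    Returns the mapping of artifact name to path.  The truth table is
    tab-separated with a '#'-prefixed header; FASTA headers carry
    ``<species>|<family>|g<k>`` ids.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for prot in truth.proteomes():
        fp = outdir / f"{prot.species}.faa"
        write_fasta(prot.records, fp)
        written[prot.species] = fp

    cat = {f.family_id: f.category for f in truth.families}
    tbl = outdir / "truth.tsv"
    with open(tbl, "w") as fh:
        fh.write("#gene\tspecies\tfamily\tcategory\n")
        for g in sorted(truth.genes, key=lambda g: (g.species, g.gene_id)):
            fh.write(f"{g.gene_id}\t{g.species}\t{g.family_id}\t{cat[g.family_id]}\n")
    written["truth"] = tbl

    if truth.tree is not None:
        nwk = outdir / "species_tree.nwk"
        write_newick(truth.tree, nwk)
        written["tree"] = nwk
    return written


def read_truth_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read a truth table back as (gene, species, family, category) rows."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
        rows.append(tuple(parts))
    return rows
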