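"""Pipeline configuration and the end-to-end driver.

Stages run in a fixed order — isoform filter, all-against-all search,
reciprocal-hit graph, Markov clustering, categorisation, single-copy
selection, alignment, conserved blocks, per-ortholog identity, three-way
comparison with lowess, supermatrix concatenation, NJ tree with bootstrap
— and every artifact lands in a run directory together with a manifest
recording parameters, seeds and input checksums.  A single master seed in
the config drives every stochastic stage through named substreams, so any
stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import MSA, progressive_msa, read_alignment, write_alignment
from .blocks import common_blocks, concatenate, write_supermatrix
from .identity import (
    attach_smoother,
    compute_identities,
    summarize_distribution,
    three_way,
    write_identities,
)
from .orthology import (
    build_graph,
    category_counts,
    classify_group,
    mcl,
    select_single_copy,
    write_groups,
)
from .phylo import bootstrap, p_distances
from .search import all_against_all, filter_longest_isoform, read_hits, write_hits
from .seqio import read_proteome, species_map, write_fasta

logger = logging.getLogger(__name__)


def derive_seed(master: int, stream: str) -> int:
    """Named substream seed below 2**31, stable across runs."""
    return (master ^ zlib.crc32(stream.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Everything a run needs; serialised verbatim into the manifest."""

    input_dir: str
    species: list[str]
    focal: str
    comp_a: str
    comp_b: str
    lineage: list[str] = field(default_factory=list)
    evalue_threshold: float = 1e-5
    search_engine: str = "builtin"  # or "blast"
    hits_path: str | None = None  # precomputed 12-column hits, takes precedence
    alignments_dir: str | None = None  # precomputed aligned FASTA per group
    inflation: float = 1.5
    max_iter: int = 100
    prune_eps: float = 1e-5
    b1: int | None = None
    b2: int | None = None
    b3: int = 8
    b4: int = 10
    gap_policy: str = "none"
    strict_single_copy: bool = True
    tie_eps: float = 0.0
    lowess_frac: float = 2.0 / 3.0
    lowess_iters: int = 3
    bootstrap_reps: int = 100
    outgroup: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate(self) -> None:
        sset = set(self.species)
        if len(self.species) < 3:
            raise ValueError("need >= 3 species")
        if len(sset) != len(self.species):
            raise ValueError("duplicate species labels")
        for sp in (self.focal, self.comp_a, self.comp_b):
            if sp not in sset:
                raise ValueError(f"species {sp!r} not in the species universe")
        if not set(self.lineage) <= sset:
            raise ValueError("lineage species must be a subset of the species universe")
        if self.outgroup is not None and self.outgroup not in sset:
            raise ValueError(f"outgroup {self.outgroup!r} not in the species universe")
        for sp in self.species:
            fp = Path(self.input_dir) / f"{sp}.faa"
            if not fp.is_file():
                raise FileNotFoundError(f"missing proteome FASTA for {sp!r}: {fp}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure writes ``status.json`` naming the stage and
    re-raises.  Identical config and inputs give byte-identical tabular
    outputs.
    """
    config.validate()  # pre-flight: nothing is written on config errors
    run = Path(outdir)
    run.mkdir(parents=True, exist_ok=True)
    status = {"status": "running", "stage": None}
    counts: dict[str, int] = {}
    stage = "preflight"
    try:
        # -- stage 01: proteomes + isoform filter ---------------------------
        stage = "01_isoform_filter"
        raw = [
            read_proteome(Path(config.input_dir) / f"{sp}.faa", sp)
            for sp in config.species
        ]
        proteomes = [filter_longest_isoform(p) for p in raw]
        pdir = run / "01_proteomes"
        pdir.mkdir(exist_ok=True)
        for p in proteomes:
            write_fasta(p.records, pdir / f"{p.species}.faa")
        counts["genes_in"] = sum(len(p) for p in raw)
        counts["genes_after_isoform_filter"] = sum(len(p) for p in proteomes)
        sp_of = species_map(proteomes)

        # -- stage 02: all-against-all hits ---------------------------------
        stage = "02_search"
        if config.hits_path:
            hits = read_hits(config.hits_path, config.evalue_threshold)
        else:
            hits = all_against_all(
                proteomes,
                evalue_threshold=config.evalue_threshold,
                engine=config.search_engine,
            )
        write_hits(hits, run / "02_hits.tsv")
        counts["hits"] = len(hits)

        # -- stage 03: similarity graph -------------------------------------
        stage = "03_graph"
        graph = build_graph(hits, sp_of, genes=sp_of)
        with open(run / "03_graph.tsv", "w") as fh:
            fh.write("#gene_a\tgene_b\tweight\n")
            for u, v, w in sorted(graph.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{w:.4f}\n")
        counts["graph_edges"] = graph.number_of_edges()

        # -- stage 04: Markov clustering + categories -----------------------
        stage = "04_mcl"
        res = mcl(graph, config.inflation, config.max_iter, config.prune_eps)
        if not res.converged:
            logger.warning("MCL did not converge in %d iterations", config.max_iter)
        labels = {
            g.group_id: classify_group(g, config.species, config.lineage)
            for g in res.groups
        }
        write_groups(res.groups, labels, run / "04_groups.tsv")
        counts["groups"] = len(res.groups)

        # -- stage 05: category count table ---------------------------------
        stage = "05_categories"
        all_genes = {r.id: p.species for p in proteomes for r in p.records}
        tab = category_counts(res.groups, labels, config.species, all_genes, hits)
        tab.to_csv(run / "05_categories.tsv", sep="\t", index_label="#species")

        # -- stage 06: single-copy selection --------------------------------
        stage = "06_single_copy"
        sc = select_single_copy(res.groups, config.species, config.strict_single_copy)
        (run / "06_single_copy.txt").write_text(
            "".join(g.group_id + "\n" for g in sc)
        )
        counts["single_copy_groups"] = len(sc)

        # -- stage 07: alignments -------------------------------------------
        stage = "07_align"
        adir = run / "07_alignments"
        adir.mkdir(exist_ok=True)
        alignments: dict[str, MSA] = {}
        gene_seq = {r.id: r.seq for p in proteomes for r in p.records}
        for g in sc:
            if config.alignments_dir:
                ext = Path(config.alignments_dir) / f"{g.group_id}.fasta"
                msa = read_alignment(ext)
            else:
                from .seqio import FastaRecord

                recs = [FastaRecord(m, gene_seq[m]) for m in sorted(g.members)]
                msa = progressive_msa(recs)
            alignments[g.group_id] = msa
            write_alignment(msa, adir / f"{g.group_id}.fasta")

        # -- stage 08: conserved blocks -------------------------------------
        stage = "08_blocks"
        blocked = common_blocks(
            alignments, config.species, config.b1, config.b2, config.b3,
            config.b4, config.gap_policy,
        )
        with open(run / "08_blocks.tsv", "w") as fh:
            fh.write("#group\tn_retained\tblocks\n")
            for gid in sorted(blocked):
                ba = blocked[gid]
                spans = ",".join(f"{a}-{b}" for a, b in ba.blocks)
                fh.write(f"{gid}\t{len(ba.retained)}\t{spans}\n")
        counts["blocked_groups"] = len(blocked)

        # -- stage 09: identities -------------------------------------------
        stage = "09_identity"
        records = compute_identities(blocked, config.species)
        write_identities(records, run / "09_identity.tsv")
        counts["identity_records"] = len(records)

        # -- stage 10: distribution summaries + three-way + lowess ----------
        stage = "10_compare"
        summaries = {}
        pairs = {r.pair for r in records}
        for pair in sorted(pairs):
            s = summarize_distribution(records, pair)
            summaries["|".join(pair)] = {
                "n": s.n, "q1": s.q1, "median": s.median, "q3": s.q3, "notch": s.notch,
            }
        (run / "10_summary.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))
        cmp_table = three_way(records, config.focal, config.comp_a, config.comp_b, config.tie_eps)
        if len(cmp_table.table) >= 3:
            attach_smoother(cmp_table, config.lowess_frac, config.lowess_iters)
        cmp_table.table.sort_values("group").to_csv(
            run / "10_comparison.tsv", sep="\t", index=False
        )
        if cmp_table.smoother is not None:
            with open(run / "10_lowess.tsv", "w") as fh:
                fh.write("#x\tfitted\n")
                for xv, fv in zip(cmp_table.smoother.x, cmp_table.smoother.fitted):
                    fh.write(f"{xv:.6f}\t{fv:.6f}\n")
        counts["three_way_groups"] = len(cmp_table.table)

        # -- stage 11: supermatrix ------------------------------------------
        stage = "11_supermatrix"
        sm = concatenate(blocked, config.species)
        write_supermatrix(sm, run / "11_supermatrix.fasta", run / "11_partitions.tsv")
        counts["supermatrix_columns"] = sm.length

        # -- stage 12: distances + NJ + bootstrap ---------------------------
        stage = "12_tree"
        dm = p_distances(sm)
        dm.write_phylip(run / "12_distances.phy")
        tree = bootstrap(sm, config.bootstrap_reps, derive_seed(config.seed, "bootstrap"))
        (run / "12_tree.nwk").write_text(tree.to_newick(config.outgroup) + "\n")

        # -- manifest --------------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "counts": counts,
            "derived_seeds": {"bootstrap": derive_seed(config.seed, "bootstrap")},
            "input_checksums": {
                sp: _sha256(Path(config.input_dir) / f"{sp}.faa")
                for sp in config.species
            },
            "comparison": {
                "counts": cmp_table.counts,
                "fractions": cmp_table.fractions,
                "lowess_r_squared": (
                    cmp_table.smoother.r_squared if cmp_table.smoother else None
                ),
            },
        }
        (run / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        status = {"status": "ok", "stage": None}
        return run
    except Exception as exc:
        status = {"status": "error", "stage": stage, "error": str(exc)}
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    finally:
        (run / "status.json").write_text(json.dumps(status, indent=2))
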