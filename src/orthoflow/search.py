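"""All-against-all protein similarity search.

Produces the E-value-thresholded hit table (default E < 1e-5) that feeds
ortholog clustering.  Three routes are supported:

* a built-in optimal local aligner (Smith-Waterman with affine gaps, via
  Biopython's pairwise aligner) with Karlin-Altschul E-values — exact and
  dependency-free, suitable for small gene sets;
* the ``blastp`` command-line tool when installed, for larger sets;
* import of externally computed hits in the standard 12-column tabular
  format.

Gap penalties follow the search-tool convention: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import FastaRecord, Proteome, write_fasta

#: E-values of 0 in imported tables are floored here before log transforms
EVALUE_FLOOR = 1e-200
DEFAULT_EVALUE = 1e-5

#: standard gapped Karlin-Altschul constants for BLOSUM62 with open 11 / extend 1
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267


@dataclass(frozen=True)
class Hit:
    """One directed similarity hit (query -> subject)."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    identity: float  # aligned identity fraction in [0, 1]
    raw_score: float | None = None
    qlen: int | None = None
    slen: int | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be > 0 (floor zeros before constructing)")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


class HitTable:
    """Best-per-ordered-pair hit collection under an E-value threshold.

    At most one hit is stored per ordered (query, subject) pair: the best by
    E-value, ties broken by higher bit score.  Self-hits are never stored.
    """

    def __init__(self, threshold: float = DEFAULT_EVALUE) -> None:
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        self.threshold = threshold
        self._hits: dict[tuple[str, str], Hit] = {}

    def add(self, hit: Hit) -> bool:
        """Add a hit if it passes the threshold and beats any stored hit."""
        if hit.query == hit.subject or hit.evalue >= self.threshold:
            return False
        key = (hit.query, hit.subject)
        prev = self._hits.get(key)
        if prev is None or (hit.evalue, -hit.bitscore) < (prev.evalue, -prev.bitscore):
            self._hits[key] = hit
            return True
        return False

    def get(self, query: str, subject: str) -> Hit | None:
        return self._hits.get((query, subject))

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self._hits[k] for k in sorted(self._hits))

    def queries_and_subjects(self) -> set[str]:
        out: set[str] = set()
        for q, s in self._hits:
            out.add(q)
            out.add(s)
        return out


# ---------------------------------------------------------------------------
# isoform filtering
# ---------------------------------------------------------------------------


def filter_longest_isoform(proteome: Proteome) -> Proteome:
    """Keep one sequence per gene: the longest isoform.

    Isoforms share a gene identifier (the id before any ``.<isoform>``
    suffix).  Equal lengths are broken toward the lexicographically smaller
    isoform id, so the result is deterministic.
    """
    best: dict[str, FastaRecord] = {}
    order: list[str] = []
    for rec in proteome.records:
        g = rec.gene_id
        cur = best.get(g)
        if cur is None:
            best[g] = rec
            order.append(g)
        elif (-len(rec.seq), rec.id) < (-len(cur.seq), cur.id):
            best[g] = rec
    return Proteome(proteome.species, [best[g] for g in order])


# ---------------------------------------------------------------------------
# built-in local alignment and E-values
# ---------------------------------------------------------------------------


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be > 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # first gap residue costs open + extend under the search-tool convention
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str, on_unknown: str) -> str:
    unknown = set(seq) - set(alphabet)
    if not unknown:
        return seq
    if on_unknown == "reject":
        raise ValueError(f"unknown residue letters {sorted(unknown)}")
    # '*' carries the minimum substitution value in the standard matrices
    return "".join(c if c in alphabet else "*" for c in seq)


def align_local(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    on_unknown: str = "reject",
) -> tuple[float, float, int]:
    """Optimal local alignment score, identity fraction and aligned length.

    Returns ``(score, identity, aligned_length)``; score is 0 with an empty
    alignment when no positive-scoring residue pair exists.  ``on_unknown``
    is ``"reject"`` (raise on letters outside the matrix alphabet) or
    ``"min"`` (score them at the matrix minimum).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    a = _sanitize(a, alphabet, on_unknown)
    b = _sanitize(b, alphabet, on_unknown)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0.0, 0
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    length = aln.length
    ident = counts.identities / length if length else 0.0
    return float(score), float(ident), int(length)


def evalue(
    score: float, m: int, n: int, K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA
) -> float:
    """Karlin-Altschul expected hit count: ``E = K * m * n * exp(-lambda*S)``."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be > 0")
    return K * m * n * math.exp(-lam * score)


def all_against_all(
    proteomes: Sequence[Proteome],
    evalue_threshold: float = DEFAULT_EVALUE,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
    engine: str = "builtin",
) -> HitTable:
    """Evaluate every ordered gene pair (within and across species).

    ``engine="builtin"`` uses the exact local aligner; ``engine="blast"``
    shells out to an installed ``blastp``.  Self-pairs are skipped; only
    hits with E below the threshold are stored.
    """
    if len(proteomes) < 2:
        raise ValueError("need >= 2 proteomes")
    for p in proteomes:
        if len(p) == 0:
            raise ValueError(f"empty proteome for species {p.species!r}")
    if engine == "blast":
        return _all_against_all_blast(proteomes, evalue_threshold)
    if engine != "builtin":
        raise ValueError(f"unknown engine {engine!r}")

    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    seqs = [
        (rec.id, _sanitize(rec.seq, alphabet, "min"))
        for p in proteomes
        for rec in p.records
    ]
    table = HitTable(evalue_threshold)
    for i in range(len(seqs)):
        qid, qseq = seqs[i]
        for j in range(i + 1, len(seqs)):
            sid, sseq = seqs[j]
            if qid == sid:
                continue
            score = aligner.score(qseq, sseq)
            if score <= 0:
                continue
            e = evalue(score, len(qseq), len(sseq), K, lam)
            if e >= evalue_threshold:
                continue
            aln = next(iter(aligner.align(qseq, sseq)))
            counts = aln.counts()
            ident = counts.identities / aln.length if aln.length else 0.0
            bits = (lam * score - math.log(K)) / math.log(2.0)
            for q, s, ql, sl in ((qid, sid, len(qseq), len(sseq)),
                                 (sid, qid, len(sseq), len(qseq))):
                table.add(
                    Hit(q, s, evalue=max(e, EVALUE_FLOOR), bitscore=bits,
                        identity=float(ident), raw_score=float(score),
                        qlen=ql, slen=sl)
                )
    return table


def _all_against_all_blast(
    proteomes: Sequence[Proteome], evalue_threshold: float
) -> HitTable:
    """All-against-all via an installed ``blastp`` (tabular output).

    Ids are mapped to safe tokens before the run so pipe-delimited gene ids
    survive the tool's id parsing, and mapped back afterwards.
    """
    for tool in ("makeblastdb", "blastp"):
        if shutil.which(tool) is None:
            raise RuntimeError(f"{tool} not found on PATH; use engine='builtin'")
    recs = [rec for p in proteomes for rec in p.records]
    fwd = {rec.id: f"s{i:07d}" for i, rec in enumerate(recs)}
    rev = {v: k for k, v in fwd.items()}
    with tempfile.TemporaryDirectory() as td:
        faa = Path(td) / "all.faa"
        write_fasta([FastaRecord(fwd[r.id], r.seq) for r in recs], faa)
        subprocess.run(
            ["makeblastdb", "-in", str(faa), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        out = Path(td) / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(faa), "-db", str(faa), "-outfmt", "6",
             "-evalue", str(evalue_threshold), "-out", str(out)],
            check=True, capture_output=True,
        )
        table = read_hits(out, evalue_threshold)
    mapped = HitTable(evalue_threshold)
    for h in table:
        mapped.add(
            Hit(rev[h.query], rev[h.subject], evalue=h.evalue, bitscore=h.bitscore,
                identity=h.identity, raw_score=h.raw_score, qlen=h.qlen, slen=h.slen)
        )
    return mapped


# ---------------------------------------------------------------------------
# 12-column tabular import/export
# ---------------------------------------------------------------------------


def read_hits(path: str | Path, evalue_threshold: float = DEFAULT_EVALUE) -> HitTable:
    """Read 12-column tabular hits (query, subject, %identity, alignment
    length, mismatches, gap opens, qstart, qend, sstart, send, E-value,
    bit score); duplicates collapse to the best hit by E-value."""
    table = HitTable(evalue_threshold)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                ev = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: unparsable numeric field: {exc}") from exc
            if ev <= 0:
                ev = EVALUE_FLOOR
            table.add(
                Hit(parts[0], parts[1], evalue=ev, bitscore=bits,
                    identity=min(max(pident / 100.0, 0.0), 1.0))
            )
    return table


def write_hits(table: HitTable, path: str | Path) -> None:
    """Write a hit table in the 12-column tabular format (positional fields
    not tracked by this pipeline are written as 0)."""
    with open(path, "w") as fh:
        for h in table:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity * 100.0:.2f}\t0\t0\t0"
                f"\t0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )
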