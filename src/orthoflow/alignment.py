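"""Protein multiple sequence alignment.

A built-in progressive aligner keeps the pipeline free of external
binaries: pairwise global alignments give a distance matrix, an
average-linkage guide tree orders the merges, and profiles are aligned by
global affine-gap dynamic programming on profile-to-profile sum-of-pairs
column scores.  Externally computed alignments (aligned FASTA) can be
imported instead and always take precedence in the pipeline.

Column scores between profiles are expectation-of-pairs values
``f_a' S f_b`` over residue frequencies, with gap characters inside a
matched column scoring 0 (their cost was paid when the gap was opened).
Gap penalties follow the same convention as the search stage: a gap of
length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy

from .seqio import GAP, FastaRecord, read_fasta, write_fasta

NEG = -1e30  # effectively -inf for the DP


@dataclass
class MSA:
    """A protein multiple alignment: parallel ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, expected {L}"
                )
            if set(row) == {GAP}:
                raise ValueError(f"row {rid!r} is all gaps")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def species(self) -> list[str | None]:
        """Species labels from the ``<species>|...`` id dialect, else None."""
        return [i.split("|", 1)[0] if "|" in i else None for i in self.ids]

    def row_by_species(self, sp: str) -> str:
        for s, row in zip(self.species, self.rows):
            if s == sp:
                return row
        raise KeyError(f"no row for species {sp!r}")


def read_alignment(path: str | Path) -> MSA:
    """Read an aligned FASTA file; ragged rows are rejected by record id."""
    recs = read_fasta(path, strict=False)
    return MSA([r.id for r in recs], [r.seq for r in recs])


def write_alignment(msa: MSA, path: str | Path) -> None:
    write_fasta(
        [FastaRecord(i, r) for i, r in zip(msa.ids, msa.rows)], path
    )


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------


class _Scorer:
    """Substitution matrix extended with a zero-scoring gap symbol."""

    def __init__(self, matrix: str):
        m = substitution_matrices.load(matrix)
        self.alphabet = str(m.alphabet)
        k = len(self.alphabet)
        self.gap_index = k
        S = np.zeros((k + 1, k + 1))
        S[:k, :k] = np.asarray(m)
        self.S = S
        self.index = {c: i for i, c in enumerate(self.alphabet)}
        self.star = self.index.get("*", k - 1)

    def encode(self, row: str) -> np.ndarray:
        return np.array(
            [self.gap_index if c == GAP else self.index.get(c, self.star) for c in row],
            dtype=np.int64,
        )

    def profile(self, rows: Sequence[str]) -> np.ndarray:
        """Column frequency matrix of shape (L, alphabet+gap)."""
        enc = np.stack([self.encode(r) for r in rows])
        L = enc.shape[1]
        F = np.zeros((L, self.S.shape[0]))
        for j in range(L):
            vals, counts = np.unique(enc[:, j], return_counts=True)
            F[j, vals] = counts / enc.shape[0]
        return F


def _profile_dp(
    S_col: np.ndarray, go: float, ge: float
) -> tuple[float, list[str]]:
    """Global affine-gap DP over a precomputed column-score matrix.

    Returns the score and the edit path as a list of ops ('M' = aligned
    column, 'A' = column from the first profile vs gap, 'B' = gap vs column
    from the second profile).  Ties prefer M, then A, then B.
    """
    L1, L2 = S_col.shape
    M = np.full((L1 + 1, L2 + 1), NEG)
    X = np.full((L1 + 1, L2 + 1), NEG)  # ends with first-profile column vs gap
    Y = np.full((L1 + 1, L2 + 1), NEG)  # ends with gap vs second-profile column
    M[0, 0] = 0.0
    j = np.arange(1, L2 + 1)
    Y[0, 1:] = -(go + (j - 1) * ge)
    steps = ge * np.arange(L2 + 1)
    for i in range(1, L1 + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + S_col[i - 1]
        X[i] = np.maximum(
            np.maximum(M[i - 1] - go, Y[i - 1] - go), X[i - 1] - ge
        )
        V = np.maximum(M[i], X[i]) + steps
        acc = np.maximum.accumulate(V[:-1])
        Y[i, 1:] = acc - go - steps[1:] + ge
    score = max(M[L1, L2], X[L1, L2], Y[L1, L2])

    # traceback by recomputing which predecessor attains each stored value
    ops: list[str] = []
    i_, j_ = L1, L2
    state = max(
        (("M", M[i_, j_]), ("A", X[i_, j_]), ("B", Y[i_, j_])),
        key=lambda t: t[1],
    )[0]
    tol = 1e-9
    while i_ > 0 or j_ > 0:
        if state == "M":
            ops.append("M")
            val = M[i_, j_] - S_col[i_ - 1, j_ - 1]
            i_, j_ = i_ - 1, j_ - 1
            for s, v in (("M", M[i_, j_]), ("A", X[i_, j_]), ("B", Y[i_, j_])):
                if abs(v - val) <= tol:
                    state = s
                    break
        elif state == "A":
            ops.append("A")
            here = X[i_, j_]
            i_ -= 1
            if abs(M[i_, j_] - go - here) <= tol:
                state = "M"
            elif abs(X[i_, j_] - ge - here) <= tol:
                state = "A"
            else:
                state = "B"
        else:
            ops.append("B")
            here = Y[i_, j_]
            j_ -= 1
            if abs(M[i_, j_] - go - here) <= tol:
                state = "M"
            elif abs(X[i_, j_] - go - here) <= tol:
                state = "A"
            else:
                state = "B"
        if i_ == 0 and j_ > 0:
            ops.extend("B" * j_)
            break
        if j_ == 0 and i_ > 0:
            ops.extend("A" * i_)
            break
    ops.reverse()
    return float(score), ops


def _merge(rows_a: list[str], rows_b: list[str], ops: list[str]) -> list[str]:
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "A"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("M", "B"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a + out_b


def _pairwise_identity_distance(
    seqs: Sequence[str], matrix: str, go: float, ge: float
) -> np.ndarray:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(go + ge)
    aligner.extend_gap_score = -ge
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = next(iter(aligner.align(seqs[i], seqs[j])))
            ident = aln.counts().identities / aln.length if aln.length else 0.0
            D[i, j] = D[j, i] = 1.0 - ident
    return D


def sop_score(msa: MSA, matrix: str = "BLOSUM62",
              gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Sum-of-pairs score of an alignment: substitution values over aligned
    residue pairs minus affine gap costs per pairwise projection."""
    m = substitution_matrices.load(matrix)
    total = 0.0
    for i in range(msa.n):
        for j in range(i + 1, msa.n):
            a, b = msa.rows[i], msa.rows[j]
            in_gap = None
            for ca, cb in zip(a, b):
                if ca == GAP and cb == GAP:
                    continue
                if ca == GAP or cb == GAP:
                    side = "a" if ca == GAP else "b"
                    if in_gap != side:
                        total -= gap_open + gap_extend
                    else:
                        total -= gap_extend
                    in_gap = side
                else:
                    total += m[ca, cb]
                    in_gap = None
    return total


def progressive_msa(
    records: Sequence[FastaRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MSA:
    """Progressive multiple alignment.

    Guide tree: average-linkage clustering of (1 - pairwise identity)
    distances from global pairwise alignments.  Profiles are merged in
    guide-tree order; columns are never reordered.  A single input is
    returned unchanged; two inputs reduce to the pairwise global alignment.
    """
    if not records:
        raise ValueError("no sequences to align")
    ids = [r.id for r in records]
    seqs = [r.seq for r in records]
    if len(records) == 1:
        return MSA(ids, [seqs[0]])
    scorer = _Scorer(matrix)
    go = gap_open + gap_extend  # cost of the first residue of a gap
    ge = gap_extend

    if len(records) == 2:
        order = [(0, 1)]
    else:
        D = _pairwise_identity_distance(seqs, matrix, gap_open, gap_extend)
        condensed = D[np.triu_indices(len(seqs), k=1)]
        Z = hierarchy.linkage(condensed, method="average")
        order = [(int(a), int(b)) for a, b, *_ in Z]

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s]) for i, s in enumerate(seqs)
    }
    nxt = len(seqs)
    for a, b in order:
        idx_a, rows_a = clusters.pop(a)
        idx_b, rows_b = clusters.pop(b)
        Fa = scorer.profile(rows_a)
        Fb = scorer.profile(rows_b)
        S_col = Fa @ scorer.S @ Fb.T
        _, ops = _profile_dp(S_col, go, ge)
        merged = _merge(rows_a, rows_b, ops)
        clusters[nxt] = (idx_a + idx_b, merged)
        nxt += 1
    (final_idx, final_rows), = clusters.values()
    # restore input order
    by_orig = {orig: row for orig, row in zip(final_idx, final_rows)}
    return MSA(ids, [by_orig[i] for i in range(len(seqs))])
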