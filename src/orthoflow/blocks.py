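"""Conserved-block extraction from protein alignments and supermatrix
concatenation.

Poorly aligned alignment regions are excluded by per-column conservation
rules in the tradition of classic block-selection tools:

1. each column is classified by the count of rows sharing its majority
   (most frequent non-gap) residue: *nonconserved* below ``b1``,
   *conserved* at >= ``b1`` but below ``b2``, *highly conserved* at
   >= ``b2``;
2. under the default gap policy any column containing a gap is
   nonconserved and can never be retained;
3. runs of more than ``b3`` contiguous nonconserved columns are rejected
   outright;
4. the remaining candidate blocks are trimmed from both ends until they
   are flanked by highly conserved columns;
5. blocks shorter than ``b4`` columns are rejected.

Retained column indices are 0-based; block boundaries are half-open
``[start, end)`` spans.  Defaults for ``n`` rows: ``b1 = n//2 + 1``,
``b2 = max(b1, ceil(0.85 n))``, ``b3 = 8``, ``b4 = 10``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .alignment import MSA
from .seqio import GAP

logger = logging.getLogger(__name__)


@dataclass
class BlockedAlignment:
    """An MSA plus its retained conserved-block columns."""

    msa: MSA
    retained: list[int]
    blocks: list[tuple[int, int]]  # half-open [start, end) spans

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.retained, self.retained[1:])):
            raise ValueError("retained indices must be strictly increasing")
        if self.retained and not (
            0 <= self.retained[0] and self.retained[-1] < self.msa.length
        ):
            raise ValueError("retained indices out of range")

    def retained_rows(self) -> list[str]:
        return ["".join(row[i] for i in self.retained) for row in self.msa.rows]


@dataclass
class Supermatrix:
    """Species-indexed concatenation of retained blocks across groups."""

    species: list[str]
    rows: list[str]
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.rows[0]) if self.rows else 0
        if any(len(r) != L for r in self.rows):
            raise ValueError("supermatrix rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def default_params(n: int) -> tuple[int, int, int, int]:
    b1 = n // 2 + 1
    b2 = max(b1, math.ceil(0.85 * n))
    return b1, b2, 8, 10


def column_status(msa: MSA, b1: int, b2: int, gap_policy: str = "none") -> list[str]:
    """Per-column status: 'N' (nonconserved), 'C' (conserved), 'H' (highly
    conserved), or 'G' (gap-containing under gap_policy='none': treated as
    nonconserved and never retainable)."""
    status = []
    for j in range(msa.length):
        col = [row[j] for row in msa.rows]
        if gap_policy == "none" and GAP in col:
            status.append("G")
            continue
        residues = [c for c in col if c != GAP]
        if not residues:
            status.append("G")
            continue
        # majority residue: most frequent non-gap residue, ties alphabetical
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))[1]
        if top >= b2:
            status.append("H")
        elif top >= b1:
            status.append("C")
        else:
            status.append("N")
    return status


def extract_blocks(
    msa: MSA,
    b1: int | None = None,
    b2: int | None = None,
    b3: int = 8,
    b4: int = 10,
    gap_policy: str = "none",
) -> BlockedAlignment:
    """Apply the conserved-block rules to one alignment.

    Preconditions: ``b1 > n/2``, ``b2 >= b1``, ``b3 >= 1``, ``b4 >= 2``.
    Gap-containing columns (``gap_policy='none'``) count as nonconserved
    for the flanking/stretch rules and are excluded from the retained set
    even inside surviving blocks.
    """
    n = msa.n
    if n < 2:
        raise ValueError("block extraction needs >= 2 rows")
    d1, d2, _, _ = default_params(n)
    b1 = d1 if b1 is None else b1
    b2 = max(b1, d2) if b2 is None else b2
    if not b1 > n / 2:
        raise ValueError(f"b1 must exceed n/2 (= {n / 2}); got {b1}")
    if b2 < b1:
        raise ValueError("b2 must be >= b1")
    if b3 < 1 or b4 < 2:
        raise ValueError("b3 must be >= 1 and b4 >= 2")
    if gap_policy not in ("none", "all"):
        raise ValueError("gap_policy must be 'none' or 'all'")

    status = column_status(msa, b1, b2, gap_policy)
    L = msa.length
    noncons = [s in ("N", "G") for s in status]

    # rule 3: reject long nonconserved stretches
    rejected = [False] * L
    j = 0
    while j < L:
        if noncons[j]:
            k = j
            while k < L and noncons[k]:
                k += 1
            if k - j > b3:
                for t in range(j, k):
                    rejected[t] = True
            j = k
        else:
            j += 1

    # candidate blocks between rejected stretches
    blocks: list[tuple[int, int]] = []
    retained: list[int] = []
    j = 0
    while j < L:
        if rejected[j]:
            j += 1
            continue
        k = j
        while k < L and not rejected[k]:
            k += 1
        # rule 4: trim to highly conserved flanks
        start, end = j, k
        while start < end and status[start] != "H":
            start += 1
        while end > start and status[end - 1] != "H":
            end -= 1
        # rule 5: minimum block length
        if end - start >= b4:
            blocks.append((start, end))
            retained.extend(
                t for t in range(start, end) if status[t] != "G"
            )
        j = k

    return BlockedAlignment(msa, retained, blocks)


def common_blocks(
    alignments: Mapping[str, MSA],
    species: Sequence[str],
    b1: int | None = None,
    b2: int | None = None,
    b3: int = 8,
    b4: int = 10,
    gap_policy: str = "none",
) -> dict[str, BlockedAlignment]:
    """Block extraction on alignments containing every analysed species.

    Each group's retained set is computed once, on the alignment holding
    all species, so every species pair is compared over the same columns.
    Groups missing a species are dropped with a logged reason.
    """
    want = set(species)
    out: dict[str, BlockedAlignment] = {}
    n_dropped = 0
    for gid in sorted(alignments):
        msa = alignments[gid]
        have = {s for s in msa.species if s is not None}
        if not want <= have:
            missing = sorted(want - have)
            logger.info("group %s dropped: missing species %s", gid, missing)
            n_dropped += 1
            continue
        out[gid] = extract_blocks(msa, b1, b2, b3, b4, gap_policy)
    if n_dropped:
        logger.info("common_blocks: %d group(s) dropped for missing species", n_dropped)
    return out


def concatenate(
    blocked: Mapping[str, BlockedAlignment], species: Sequence[str]
) -> Supermatrix:
    """Concatenate retained columns into a species-by-columns supermatrix.

    Groups are concatenated in lexicographic group-id order, so the result
    is independent of input order.  Every group must have exactly one row
    per species.
    """
    species = list(species)
    parts: dict[str, list[str]] = {s: [] for s in species}
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for gid in sorted(blocked):
        ba = blocked[gid]
        sub_rows = {}
        for sp in species:
            try:
                row = ba.msa.row_by_species(sp)
            except KeyError as exc:
                raise ValueError(f"group {gid} lacks a row for species {sp!r}") from exc
            sub_rows[sp] = "".join(row[i] for i in ba.retained)
        width = len(ba.retained)
        offsets[gid] = (pos, pos + width)
        pos += width
        for sp in species:
            parts[sp].append(sub_rows[sp])
    return Supermatrix(species, ["".join(parts[s]) for s in species], offsets)


def write_supermatrix(sm: Supermatrix, fasta_path: str | Path, partition_path: str | Path) -> None:
    from .seqio import FastaRecord, write_fasta

    write_fasta([FastaRecord(s, r) for s, r in zip(sm.species, sm.rows)], fasta_path)
    with open(partition_path, "w") as fh:
        fh.write("#group\tstart\tend\n")
        for gid, (a, b) in sorted(sm.offsets.items()):
            fh.write(f"{gid}\t{a}\t{b}\n")
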