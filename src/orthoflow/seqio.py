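"""FASTA input/output and the sequence-record conventions shared by the pipeline.

Header dialect
--------------
Sequence identifiers are plain tokens or pipe-delimited compounds.  The
simulator emits ``<species>|<family>|g<k>``; external proteomes may use any
id.  Splice isoforms of one gene share a gene identifier and are
distinguished by a trailing ``.<isoform>`` suffix (``G12.1``, ``G12.2``);
ids without a dot are their own gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 canonical amino-acid letters
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: accepted in input proteomes but flagged: ambiguity / rare letters
EXTENDED_LETTERS = set(AMINO_ACIDS) | {"X", "B", "Z", "U", "O", "*"}

GAP = "-"


@dataclass(frozen=True)
class FastaRecord:
    """One protein sequence with its identifier."""

    id: str
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)

    @property
    def gene_id(self) -> str:
        """Gene identifier: the id with any ``.<isoform>`` suffix removed."""
        return self.id.split(".", 1)[0]


@dataclass
class Proteome:
    """All protein sequences of one species."""

    species: str
    records: list[FastaRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FastaRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | Path, *, strict: bool = True) -> list[FastaRecord]:
    """Read a protein FASTA file.

    Parameters
    ----------
    path:
        Text FASTA (LF or CRLF line endings).
    strict:
        If True, duplicate ids and letters outside the extended protein
        alphabet raise ``ValueError``.  If False, duplicate ids are
        deduplicated by appending ``_dupN`` and odd letters pass through.
    """
    records: list[FastaRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        rid = rec.id
        if not seq:
            raise ValueError(f"empty sequence for record {rid!r} in {path}")
        if strict:
            bad = set(seq) - EXTENDED_LETTERS
            if bad:
                raise ValueError(
                    f"illegal residue letters {sorted(bad)} in record {rid!r} of {path}"
                )
        if rid in seen:
            if strict:
                raise ValueError(f"duplicate sequence id {rid!r} in {path}")
            seen[rid] += 1
            rid = f"{rid}_dup{seen[rid]}"
        else:
            seen[rid] = 0
        records.append(FastaRecord(rid, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, *, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    path = Path(path)
    with io.open(path, "w", newline="\n") as fh:
        SeqIO.write(
            (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
            fh,
            "fasta",
        )


def read_proteome(path: str | Path, species: str, *, strict: bool = True) -> Proteome:
    """Read one species' proteome from FASTA."""
    return Proteome(species, read_fasta(path, strict=strict))


def species_map(proteomes: Iterable[Proteome]) -> dict[str, str]:
    """Map every gene id to its species label."""
    out: dict[str, str] = {}
    for p in proteomes:
        for r in p.records:
            if r.id in out:
                raise ValueError(f"gene id {r.id!r} occurs in more than one proteome")
            out[r.id] = p.species
    return out
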