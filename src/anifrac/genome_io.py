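"""Sequence records, FASTA I/O and genome fragmentation.

Genomes are compared either whole (after being chopped into
non-overlapping fragments), as sets of nucleotide coding sequences, or as
sets of proteins.  This module holds the three record types used by the
rest of the package and the FASTA plumbing around them.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "CdsSet",
    "Fragment",
    "read_fasta",
    "write_fasta",
    "fragment_genome",
    "fragments_to_records",
]

# IUPAC nucleotide codes (ambiguity codes are accepted on input; anything
# other than A/C/G/T is treated as N downstream and never counts as a match).
_NT_ALPHABET = set("ACGTRYSWKMBDHVN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


@dataclass(frozen=True)
class GenomeRecord:
    """A single sequence: one genome, one CDS or one protein."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class CdsSet:
    """Ordered coding sequences of one genome, optionally with proteins.

    ``cds`` preserves gene order along the genome; ``proteins`` (if given)
    is parallel to ``cds``.
    """

    genome_id: str
    cds: list[tuple[str, str]] = field(default_factory=list)
    proteins: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.cds]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate CDS ids in genome {self.genome_id!r}")
        if self.proteins is not None and len(self.proteins) != len(self.cds):
            raise ValueError("proteins must parallel the CDS list")

    @property
    def total_nt(self) -> int:
        return sum(len(s) for _, s in self.cds)

    @property
    def total_aa(self) -> int:
        if self.proteins is None:
            raise ValueError("no proteins attached")
        return sum(len(p) for p in self.proteins)

    def translated(self) -> "CdsSet":
        """Return a copy with proteins obtained by translating each CDS.

        Uses the standard code; internal stops are kept as ``*`` and score
        as mismatches downstream.  A trailing stop is stripped.
        """
        prots = []
        for _, nt in self.cds:
            aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
            prots.append(aa if aa else "X")
        return CdsSet(self.genome_id, list(self.cds), prots)


@dataclass(frozen=True)
class Fragment:
    """One non-overlapping genome fragment (query unit in fragment mode)."""

    genome_id: str
    index: int
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("fragment coordinates inconsistent with sequence")

    @property
    def id(self) -> str:
        return f"{self.genome_id}|frag{self.index}|{self.start}-{self.end}"


def read_fasta(path: str | Path, alphabet: Literal["nt", "aa"] = "nt") -> list[GenomeRecord]:
    """Read a FASTA file into records.

    Sequences are uppercased; for nucleotides U is mapped to T.  Duplicate
    ids, empty files and characters outside the IUPAC alphabet are
    rejected.
    """
    allowed = _NT_ALPHABET if alphabet == "nt" else _AA_ALPHABET
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if alphabet == "nt":
            seq = seq.replace("U", "T")
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {entry.id!r} in {path} contains illegal characters: "
                f"{''.join(sorted(bad))}"
            )
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(GenomeRecord(entry.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def fragment_genome(genome: GenomeRecord, fl: int) -> list[Fragment]:
    """Chop a genome into non-overlapping fragments of length ``fl``.

    Fragment ``i`` covers ``[i*fl, min((i+1)*fl, L))``.  The terminal
    fragment is kept even when shorter than ``fl``; its coverage filter is
    later applied relative to its own length, so small genomes still
    contribute alignable queries.
    """
    if fl <= 0:
        raise ValueError(f"fragment length must be positive, got {fl}")
    frags = []
    for i, start in enumerate(range(0, genome.length, fl)):
        end = min(start + fl, genome.length)
        frags.append(Fragment(genome.id, i, start, end, genome.seq[start:end]))
    return frags


def fragments_to_records(fragments: Iterable[Fragment]) -> list[GenomeRecord]:
    """Fragments as plain records, e.g. for FASTA export."""
    return [GenomeRecord(f.id, f.seq) for f in fragments]


_FRAG_ID = re.compile(r"^(?P<genome>.+)\|frag(?P<index>\d+)\|(?P<start>\d+)-(?P<end>\d+)$")


def parse_fragment_id(frag_id: str) -> tuple[str, int, int, int]:
    """Split a ``<genome>|frag<i>|<start>-<end>`` header back into fields."""
    m = _FRAG_ID.match(frag_id)
    if m is None:
        raise ValueError(f"not a fragment id: {frag_id!r}")
    return m["genome"], int(m["index"]), int(m["start"]), int(m["end"])
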