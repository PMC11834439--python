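"""Scoring schemes, search parameters and sequence encoding.

Three nucleotide match/mismatch schemes are supported, each tuned for a
different divergence range: BLASTN (+3/-2, ~90% identity), UNIT (+1/-1,
~75%) and WU (+5/-4, ~65%).  Protein search uses BLOSUM62.  Gap penalties
are not part of the named schemes; the defaults (open 5, extend 2) are the
common nucleotide-search values and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "SearchParams",
    "ACCURATE",
    "FAST",
    "ANIB",
    "PROTEIN_DEFAULTS",
    "encode_nt",
    "encode_aa",
    "revcomp",
    "NT_CODES",
    "AA_CODES",
]

# --- alphabets -------------------------------------------------------------

# A,C,G,T -> 0..3; everything else (incl. N and ambiguity codes) -> 4.
NT_CODES = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    NT_CODES[ord(_b)] = _i
NT_N = 4

_AA_LETTERS = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_CODES = np.full(128, _AA_LETTERS.index("X"), dtype=np.int8)
for _i, _a in enumerate(_AA_LETTERS):
    AA_CODES[ord(_a)] = _i
AA_X = _AA_LETTERS.index("X")

_COMP = np.arange(5, dtype=np.int8)
_COMP[:4] = [3, 2, 1, 0]  # A<->T, C<->G; N stays N


def encode_nt(seq: str) -> np.ndarray:
    return NT_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return AA_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int16)
    np.fill_diagonal(m, match)
    # anything aligned against N (or N against N) is a mismatch
    m[NT_N, :] = mismatch
    m[:, NT_N] = mismatch
    return m


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_AA_LETTERS)
    m = np.full((n, n), -4, dtype=np.int16)
    for i, a in enumerate(_AA_LETTERS):
        for j, b in enumerate(_AA_LETTERS):
            try:
                m[i, j] = int(blosum[a, b])
            except (KeyError, IndexError):
                pass
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scoring plus affine gap penalties."""

    name: str
    match: int = 1
    mismatch: int = -1
    gap_open: int = 5
    gap_extend: int = 2
    alphabet: str = "nt"  # "nt" or "aa"

    def __post_init__(self) -> None:
        if self.alphabet == "nt" and not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def matrix(self) -> np.ndarray:
        """Substitution matrix indexed by encoded symbols."""
        if self.alphabet == "aa":
            return _blosum62_matrix()
        return _nt_matrix(self.match, self.mismatch)

    @staticmethod
    def preset(name: str) -> "ScoringScheme":
        try:
            return _SCHEMES[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown scoring scheme {name!r}; choose from {sorted(_SCHEMES)}"
            ) from None


_SCHEMES = {
    "BLASTN": ScoringScheme("BLASTN", 3, -2),
    "UNIT": ScoringScheme("UNIT", 1, -1),
    "WU": ScoringScheme("WU", 5, -4),
    "BLOSUM62": ScoringScheme("BLOSUM62", 1, -1, alphabet="aa"),
}


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the fragment/CDS/protein homology search.

    ``fi`` is the minimum identity computed over the *full* query length
    and ``fc`` the minimum query coverage; hits failing either are
    discarded before any ANI/AF accounting.  ``sensitivity`` mirrors the
    prefilter sensitivity flag of k-mer search tools; with exact k-mer
    seeding it has no effect and is recorded for provenance only.
    """

    k: int = 11
    zdrop: int = 40
    fl: int = 500
    band: int = 64  # half-width of the extension band around the seed diagonal
    max_targets_per_query: int = 20_000
    max_seq_len: int = 65_000
    sensitivity: float = 7.5  # recorded, inert with exact seeding
    fi: float = 0.30
    fc: float = 0.70
    min_aln_nt: int = 500
    min_aln_aa: int = 150

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k-mer length below 4 gives degenerate seeding")
        if not (0 < self.fi <= 1 and 0 < self.fc <= 1):
            raise ValueError("FI and FC must lie in (0, 1]")
        if self.zdrop < 0:
            raise ValueError("zdrop must be non-negative")

    def with_(self, **kw) -> "SearchParams":
        return replace(self, **kw)


# Named parameter sets.  Accurate favours sensitivity (short k-mers, short
# fragments); Fast favours speed; ANIB mirrors the classic BLAST-based
# fragment recipe (1,020 bp fragments, BLASTN scoring, larger z-drop).
ACCURATE = SearchParams(k=11, fl=500, zdrop=40)
FAST = SearchParams(k=15, fl=1020, zdrop=40)
ANIB = SearchParams(k=11, fl=1020, zdrop=150, max_seq_len=100_000)

# Protein mode: shorter seeds (exact amino-acid k-mers are rare) and the
# 150 aa minimum total alignment.
PROTEIN_DEFAULTS = SearchParams(k=5, fl=500, zdrop=40)

PRESETS = {"accurate": ACCURATE, "fast": FAST, "anib": ANIB}

SCHEME_FOR_PRESET = {"accurate": "UNIT", "fast": "UNIT", "anib": "BLASTN"}
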