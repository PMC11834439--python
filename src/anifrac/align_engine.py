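"""k-mer seeded, z-drop terminated local alignment and best-hit selection.

The search mirrors the classic seed-and-extend design: exact k-mer seeds
are located through a precomputed index of the target sequences, grouped
per target and diagonal, and extended in both directions by banded
affine-gap dynamic programming that terminates an arm once the running
score drops ``zdrop`` below its running maximum.  Nucleotide queries are
searched on both strands; proteins forward only.

Scores are not meant to be bit-compatible with any particular external
search tool; correctness is checked against a full Smith-Waterman oracle
in the test-suite.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kernels import banded_global_stats, seed_score, xdrop_extend
from .genome_io import GenomeRecord
from .scoring import AA_X, NT_N, ScoringScheme, SearchParams, encode_aa, encode_nt, revcomp

__all__ = [
    "KmerIndex",
    "LocalAlignment",
    "build_index",
    "seed_and_extend",
    "best_hit",
    "best_bidirectional_hits",
    "hits_to_tsv",
]

HIT_COLUMNS = [
    "query",
    "target",
    "strand",
    "qstart",
    "qend",
    "tstart",
    "tend",
    "matches",
    "columns",
    "score",
    "identity_aln",
    "identity_full",
    "qcov",
]


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query against a target.

    ``identity_full`` divides matches by the *full* query length (the FI
    filter of fragment-based ANI), ``identity_aln`` by aligned columns.
    Query coordinates are always on the forward query; ``strand == '-'``
    means the reverse complement of the query aligned to the target.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    columns: int
    score: int
    q_len: int

    @property
    def identity_aln(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def identity_full(self) -> float:
        return self.matches / self.q_len

    @property
    def q_cov(self) -> float:
        return (self.q_end - self.q_start) / self.q_len


def _encode(seq: str, alphabet: str) -> np.ndarray:
    return encode_nt(seq) if alphabet == "nt" else encode_aa(seq)


def _kmer_codes(codes: np.ndarray, k: int, n_symbols: int, bad: int):
    """Integer codes of all k-mers plus a validity mask (no bad symbol)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = n_symbols ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win.astype(np.int64) @ powers
    valid = (win != bad).all(axis=1)
    return vals, valid


class KmerIndex:
    """Exact k-mer postings over a set of target sequences.

    k-mers containing N (nucleotide) or X (protein) are omitted.
    """

    def __init__(self, targets: Sequence[GenomeRecord], k: int, alphabet: str = "nt"):
        if k < 4:
            raise ValueError("k-mer length below 4 gives degenerate seeding")
        self.k = k
        self.alphabet = alphabet
        self.n_symbols = 5 if alphabet == "nt" else 24
        self.bad = NT_N if alphabet == "nt" else AA_X
        if 64 <= k * np.log2(self.n_symbols):
            raise ValueError(f"k={k} too large for integer k-mer packing")
        self.targets = {t.id: _encode(t.seq, alphabet) for t in targets}
        self.target_lengths = {t.id: t.length for t in targets}
        # per target: sorted kmer codes + positions for binary-search lookup
        self._codes: dict[str, np.ndarray] = {}
        self._positions: dict[str, np.ndarray] = {}
        for tid, enc in self.targets.items():
            vals, valid = _kmer_codes(enc, k, self.n_symbols, self.bad)
            pos = np.nonzero(valid)[0]
            vals = vals[pos]
            order = np.argsort(vals, kind="stable")
            self._codes[tid] = vals[order]
            self._positions[tid] = pos[order].astype(np.int64)

    def lookup(self, tid: str, query_codes: np.ndarray, query_valid: np.ndarray):
        """Seed list (q_pos, t_pos) for one target."""
        codes = self._codes[tid]
        if codes.size == 0 or query_codes.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos_all = np.nonzero(query_valid)[0]
        qvals = query_codes[qpos_all]
        left = np.searchsorted(codes, qvals, side="left")
        right = np.searchsorted(codes, qvals, side="right")
        counts = right - left
        hits = counts > 0
        if not hits.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos_rep = np.repeat(qpos_all[hits], counts[hits])
        idx = np.concatenate([np.arange(l, r) for l, r in zip(left[hits], right[hits])])
        return qpos_rep, self._positions[tid][idx]

    def postings(self, kmer: str) -> list[tuple[str, int]]:
        """All (target_id, position) postings of one k-mer string."""
        enc = _encode(kmer, self.alphabet)
        if len(enc) != self.k or (enc == self.bad).any():
            return []
        powers = self.n_symbols ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        code = int(enc.astype(np.int64) @ powers)
        out = []
        for tid, codes in self._codes.items():
            l = np.searchsorted(codes, code, side="left")
            r = np.searchsorted(codes, code, side="right")
            out.extend((tid, int(p)) for p in self._positions[tid][l:r])
        return out


def build_index(targets: Sequence[GenomeRecord], k: int, alphabet: str = "nt") -> KmerIndex:
    if targets and k > min(t.length for t in targets):
        # an index is still valid, just empty for the short targets
        pass
    return KmerIndex(targets, k, alphabet)


def _extend_seed(q, t, qp, tp, k, subst, scoring: ScoringScheme, params: SearchParams, ncode):
    """Extend one seed both ways; return score, coords and column stats."""
    go, ge = scoring.gap_open, scoring.gap_extend
    s_seed = seed_score(q, t, qp, tp, k, subst)
    # right arm
    sr, qr, tr = xdrop_extend(q[qp + k:], t[tp + k:], subst, go, ge, params.band, params.zdrop)
    # left arm on reversed prefixes
    sl, ql, tl = xdrop_extend(q[:qp][::-1].copy(), t[:tp][::-1].copy(), subst, go, ge,
                              params.band, params.zdrop)
    qs, qe = qp - ql, qp + k + qr
    ts, te = tp - tl, tp + k + tr
    matches = k
    columns = k
    score = int(s_seed)
    if qr or tr:
        s2, m2, c2 = banded_global_stats(q[qp + k:qe], t[tp + k:te], subst, go, ge,
                                         params.band, ncode)
        score += int(s2)
        matches += int(m2)
        columns += int(c2)
    if ql or tl:
        s2, m2, c2 = banded_global_stats(q[qs:qp][::-1].copy(), t[ts:tp][::-1].copy(),
                                         subst, go, ge, params.band, ncode)
        score += int(s2)
        matches += int(m2)
        columns += int(c2)
    return score, qs, qe, ts, te, matches, columns


def seed_and_extend(
    query: GenomeRecord,
    index: KmerIndex,
    scoring: ScoringScheme,
    params: SearchParams,
) -> list[LocalAlignment]:
    """Align one query against every indexed target.

    Returns the non-redundant hits per (target, strand), capped at
    ``max_targets_per_query`` targets ranked by their best score.
    """
    if not query.seq:
        raise ValueError("empty query")
    alphabet = index.alphabet
    if len(query.seq) < index.k:
        return []
    subst = scoring.matrix()
    ncode = NT_N if alphabet == "nt" else AA_X
    k = index.k
    qlen = query.length

    enc_fwd = _encode(query.seq, alphabet)
    strands = [("+", enc_fwd)]
    if alphabet == "nt":
        strands.append(("-", revcomp(enc_fwd)))

    for tid, tlen in index.target_lengths.items():
        if tlen > params.max_seq_len:
            print(
                f"warning: target {tid} length {tlen} exceeds max_seq_len="
                f"{params.max_seq_len}; processing whole",
                file=sys.stderr,
            )

    hits: list[LocalAlignment] = []
    for strand, q in strands:
        qvals, qvalid = _kmer_codes(q, k, index.n_symbols, index.bad)
        for tid, t in index.targets.items():
            qpos, tpos = index.lookup(tid, qvals, qvalid)
            if qpos.size == 0:
                continue
            # visit seeds sorted by diagonal then query position so that
            # seeds inside an already-extended alignment are skipped fast
            diag = tpos - qpos
            order = np.lexsort((qpos, diag))
            accepted: list[tuple[int, int, int, int, int, int, int]] = []
            accepted_diag: list[int] = []
            for s_i in order:
                qp = int(qpos[s_i])
                tp = int(tpos[s_i])
                d = tp - qp
                covered = False
                for (sc, qs, qe, ts, te, mm, cc), ad in zip(accepted, accepted_diag):
                    # skip only seeds on the diagonal an accepted extension
                    # was anchored on AND inside its span; an off-diagonal
                    # covering alignment must not mask a better-anchored seed
                    if (
                        d == ad
                        and qs <= qp and qp + k <= qe
                        and ts <= tp and tp + k <= te
                    ):
                        covered = True
                        break
                if covered:
                    continue
                accepted.append(
                    _extend_seed(q, t, qp, tp, k, subst, scoring, params, ncode)
                )
                accepted_diag.append(d)
            # non-redundant set: drop alignments whose query interval is
            # mostly covered by a higher-scoring one
            accepted.sort(key=lambda a: (-a[0], -(a[6]), a[3]))
            kept: list[tuple[int, int, int, int, int, int, int]] = []
            for cand in accepted:
                _, qs, qe, ts, te, _, _ = cand
                redundant = False
                for _, kqs, kqe, kts, kte, _, _ in kept:
                    ov = min(qe, kqe) - max(qs, kqs)
                    if ov > 0 and ov >= 0.5 * (qe - qs):
                        redundant = True
                        break
                if not redundant:
                    kept.append(cand)
            for score, qs, qe, ts, te, matches, columns in kept:
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(
                    LocalAlignment(
                        query_id=query.id,
                        target_id=tid,
                        q_start=qs,
                        q_end=qe,
                        t_start=ts,
                        t_end=te,
                        strand=strand,
                        matches=matches,
                        columns=columns,
                        score=score,
                        q_len=qlen,
                    )
                )

    # cap number of targets by their best hit score
    if params.max_targets_per_query and hits:
        best_per_target: dict[str, int] = {}
        for h in hits:
            best_per_target[h.target_id] = max(best_per_target.get(h.target_id, -(10**9)), h.score)
        keep_targets = set(
            sorted(best_per_target, key=lambda t: -best_per_target[t])[: params.max_targets_per_query]
        )
        hits = [h for h in hits if h.target_id in keep_targets]
    return hits


def _hit_rank(h: LocalAlignment) -> tuple:
    # deterministic: best score, then most columns, then leftmost target start
    return (-h.score, -h.columns, h.t_start)


def best_hit(alignments: Iterable[LocalAlignment]) -> list[LocalAlignment]:
    """Single best alignment per (query, target); deterministic tie-breaks."""
    best: dict[tuple[str, str], LocalAlignment] = {}
    for h in alignments:
        key = (h.query_id, h.target_id)
        cur = best.get(key)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[key] = h
    return list(best.values())


@dataclass(frozen=True)
class BidirectionalPair:
    """A mutual-best-hit pair with stats averaged over the two directions."""

    id_a: str
    id_b: str
    matches: float
    columns: float
    columns_ab: int
    columns_ba: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def best_bidirectional_hits(
    hits_ab: Iterable[LocalAlignment], hits_ba: Iterable[LocalAlignment]
) -> list[BidirectionalPair]:
    """Mutual best hits between two gene sets (orthology approximation).

    ``hits_ab`` are alignments of A's sequences against B's, ``hits_ba``
    the reverse; both are expected to be pre-filtered (FI/FC).  A pair
    (a, b) is reported iff b is a's best hit and a is b's best hit; its
    identity and length are means of the two directional alignments.
    """
    def best_target(hits: Iterable[LocalAlignment]) -> dict[str, LocalAlignment]:
        out: dict[str, LocalAlignment] = {}
        for h in hits:
            cur = out.get(h.query_id)
            if cur is None or _hit_rank(h) < _hit_rank(cur):
                out[h.query_id] = h
        return out

    fwd = best_target(hits_ab)
    rev = best_target(hits_ba)
    pairs = []
    for a, hab in sorted(fwd.items()):
        b = hab.target_id
        hba = rev.get(b)
        if hba is not None and hba.target_id == a:
            pairs.append(
                BidirectionalPair(
                    id_a=a,
                    id_b=b,
                    matches=(hab.matches + hba.matches) / 2.0,
                    columns=(hab.columns + hba.columns) / 2.0,
                    columns_ab=hab.columns,
                    columns_ba=hba.columns,
                )
            )
    return pairs


def hits_to_tsv(hits: Iterable[LocalAlignment], path) -> None:
    """Write hits as a BLAST-outfmt-6-like TSV (see HIT_COLUMNS)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            h.query_id, h.target_id, h.strand,
                            h.q_start, h.q_end, h.t_start, h.t_end,
                            h.matches, h.columns, h.score,
                            f"{h.identity_aln:.6f}",
                            f"{h.identity_full:.6f}",
                            f"{h.q_cov:.6f}",
                        ],
                    )
                )
                + "\n"
            )
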