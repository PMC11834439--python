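"""Pairwise genome relatedness: ANI/AAI and alignment fraction.

Fragment mode follows the classic fragment-based recipe: the query genome
is chopped into non-overlapping fragments, each fragment's best hit in
the target genome is kept if it shows at least ``fi`` identity over the
full fragment length and at least ``fc`` fragment coverage, and the
directional ANI is the length-weighted mean identity over the surviving
hits.  The pair's ANI averages the two directions and the alignment
length conservatively takes the directional minimum; pairs whose total
alignment falls below the minimum (500 bp nucleotide, 150 aa protein)
keep their ANI but have AF zeroed.

CDS and protein modes replace fragments with user-supplied genes and
approximate orthology with best-bidirectional hits before applying the
same identity accounting (AAI in protein space).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import pandas as pd

from .align_engine import (
    KmerIndex,
    LocalAlignment,
    best_bidirectional_hits,
    best_hit,
    seed_and_extend,
)
from .genome_io import CdsSet, GenomeRecord, fragment_genome
from .scoring import ACCURATE, PROTEIN_DEFAULTS, ScoringScheme, SearchParams

__all__ = [
    "RelatednessResult",
    "directional_ani",
    "pair_relatedness",
    "pair_relatedness_cds",
    "pair_relatedness_protein",
    "merge_modes",
    "results_to_frame",
]

Mode = Literal["fragment", "cds", "protein"]

RESULT_COLUMNS = [
    "id_a", "id_b", "mode", "ani", "aln_len",
    "af_a", "af_b", "af_mean", "af_min", "af_max", "wgani", "filtered",
]


@dataclass(frozen=True)
class RelatednessResult:
    """ANI (or AAI) and AF summary for one genome pair in one mode."""

    id_a: str
    id_b: str
    mode: Mode
    ani: float
    aln_len: float
    af_a: float
    af_b: float
    af_mean: float
    af_min: float
    af_max: float
    wgani: float
    filtered: bool = False

    def swapped(self) -> "RelatednessResult":
        return replace(self, id_a=self.id_b, id_b=self.id_a, af_a=self.af_b, af_b=self.af_a)


def _filter_hits(hits: Iterable[LocalAlignment], params: SearchParams) -> list[LocalAlignment]:
    return [h for h in hits if h.identity_full >= params.fi and h.q_cov >= params.fc]


def directional_ani(
    query_genome: GenomeRecord,
    target_genome: GenomeRecord,
    params: SearchParams = ACCURATE,
    scoring: ScoringScheme | None = None,
    index: KmerIndex | None = None,
) -> tuple[float, int]:
    """One-directional fragment-mode ANI and total alignment length.

    Returns ``(ani, aln_len)``; ``(0.0, 0)`` when no fragment survives the
    FI/FC filters — absence of homology is a value, not an error.
    """
    scoring = scoring or ScoringScheme.preset("UNIT")
    if index is None:
        index = KmerIndex([target_genome], params.k, "nt")
    total_matches = 0
    total_columns = 0
    for frag in fragment_genome(query_genome, params.fl):
        hits = seed_and_extend(GenomeRecord(frag.id, frag.seq), index, scoring, params)
        kept = _filter_hits(best_hit(hits), params)
        if not kept:
            continue
        # a fragment contributes its single best surviving placement
        top = min(kept, key=lambda h: (-h.score, -h.columns, h.t_start))
        total_matches += top.matches
        total_columns += top.columns
    if total_columns == 0:
        return 0.0, 0
    return total_matches / total_columns, total_columns


def _summarize(
    id_a: str,
    id_b: str,
    mode: Mode,
    ani_ab: float,
    ani_ba: float,
    aln_ab: float,
    aln_ba: float,
    len_a: int,
    len_b: int,
    min_aln: int,
    wgani_af: str = "mean",
) -> RelatednessResult:
    # average directions that produced an alignment; a single live
    # direction degrades gracefully to that direction's value
    live = [(a, l) for a, l in ((ani_ab, aln_ab), (ani_ba, aln_ba)) if l > 0]
    if not live:
        ani = 0.0
        aln_len = 0.0
    else:
        ani = sum(a for a, _ in live) / len(live)
        aln_len = min(l for _, l in live) if len(live) == 2 else live[0][1]
    filtered = aln_len < min_aln
    if filtered:
        af_a = af_b = af_mean = af_min = af_max = 0.0
    else:
        af_a = min(aln_len / len_a, 1.0)
        af_b = min(aln_len / len_b, 1.0)
        af_mean = (af_a + af_b) / 2.0
        af_min = min(af_a, af_b)
        af_max = max(af_a, af_b)
    af_for_wg = {"mean": af_mean, "min": af_min, "max": af_max}[wgani_af]
    return RelatednessResult(
        id_a=id_a, id_b=id_b, mode=mode, ani=ani, aln_len=aln_len,
        af_a=af_a, af_b=af_b, af_mean=af_mean, af_min=af_min, af_max=af_max,
        wgani=ani * af_for_wg, filtered=filtered,
    )


def pair_relatedness(
    a: GenomeRecord,
    b: GenomeRecord,
    params: SearchParams = ACCURATE,
    scoring: ScoringScheme | None = None,
    wgani_af: str = "mean",
) -> RelatednessResult:
    """Fragment-mode ANI and AF for one genome pair (both directions)."""
    scoring = scoring or ScoringScheme.preset("UNIT")
    ani_ab, aln_ab = directional_ani(a, b, params, scoring)
    ani_ba, aln_ba = directional_ani(b, a, params, scoring)
    return _summarize(
        a.id, b.id, "fragment", ani_ab, ani_ba, aln_ab, aln_ba,
        a.length, b.length, params.min_aln_nt, wgani_af,
    )


def _bbh_relatedness(
    a: CdsSet,
    b: CdsSet,
    seqs_a: list[GenomeRecord],
    seqs_b: list[GenomeRecord],
    len_a: int,
    len_b: int,
    mode: Mode,
    params: SearchParams,
    scoring: ScoringScheme,
    alphabet: str,
    min_aln: int,
    wgani_af: str,
) -> RelatednessResult | None:
    if not seqs_a or not seqs_b:
        return None
    idx_b = KmerIndex(seqs_b, params.k, alphabet)
    idx_a = KmerIndex(seqs_a, params.k, alphabet)
    hits_ab: list[LocalAlignment] = []
    for s in seqs_a:
        hits_ab.extend(seed_and_extend(s, idx_b, scoring, params))
    hits_ba: list[LocalAlignment] = []
    for s in seqs_b:
        hits_ba.extend(seed_and_extend(s, idx_a, scoring, params))
    hits_ab = _filter_hits(best_hit(hits_ab), params)
    hits_ba = _filter_hits(best_hit(hits_ba), params)
    pairs = best_bidirectional_hits(hits_ab, hits_ba)
    total_matches = sum(p.matches for p in pairs)
    total_columns = sum(p.columns for p in pairs)
    aln_ab = sum(p.columns_ab for p in pairs)
    aln_ba = sum(p.columns_ba for p in pairs)
    ani = total_matches / total_columns if total_columns else 0.0
    return _summarize(
        a.genome_id, b.genome_id, mode, ani, ani, aln_ab, aln_ba,
        len_a, len_b, min_aln, wgani_af,
    )


def pair_relatedness_cds(
    a: CdsSet,
    b: CdsSet,
    params: SearchParams = ACCURATE,
    scoring: ScoringScheme | None = None,
    wgani_af: str = "mean",
) -> RelatednessResult | None:
    """CDS-mode ANI over best-bidirectional-hit gene pairs.

    AF denominators are the summed CDS lengths of each genome.  Returns
    None when either gene set is empty (excluded pair).
    """
    scoring = scoring or ScoringScheme.preset("UNIT")
    seqs_a = [GenomeRecord(cid, s) for cid, s in a.cds]
    seqs_b = [GenomeRecord(cid, s) for cid, s in b.cds]
    return _bbh_relatedness(
        a, b, seqs_a, seqs_b, a.total_nt, b.total_nt, "cds",
        params, scoring, "nt", params.min_aln_nt, wgani_af,
    )


def pair_relatedness_protein(
    a: CdsSet,
    b: CdsSet,
    params: SearchParams = PROTEIN_DEFAULTS,
    wgani_af: str = "mean",
) -> RelatednessResult | None:
    """Protein-mode AAI over best-bidirectional-hit protein pairs.

    Proteins are translated from the CDSs when not already attached.
    AF denominators are summed protein lengths; the minimum total
    alignment is 150 aa.
    """
    if a.proteins is None:
        a = a.translated()
    if b.proteins is None:
        b = b.translated()
    seqs_a = [
        GenomeRecord(cid, p) for (cid, _), p in zip(a.cds, a.proteins) if p
    ]
    seqs_b = [
        GenomeRecord(cid, p) for (cid, _), p in zip(b.cds, b.proteins) if p
    ]
    scoring = ScoringScheme.preset("BLOSUM62")
    return _bbh_relatedness(
        a, b, seqs_a, seqs_b, a.total_aa, b.total_aa, "protein",
        params, scoring, "aa", params.min_aln_aa, wgani_af,
    )


def results_to_frame(results: Iterable[RelatednessResult]) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in RESULT_COLUMNS}
        for r in results
        if r is not None
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def merge_modes(results_by_mode: dict[str, Iterable[RelatednessResult]]) -> pd.DataFrame:
    """Union of pairs over modes, zero-filling modes where a pair is absent.

    Pairs aligned in no mode do not appear at all.  The output is wide:
    one row per unordered pair, per-mode ani/af columns.
    """
    frames = {}
    for mode, results in results_by_mode.items():
        df = results_to_frame(results)
        if df.empty:
            continue
        key = ["\x1f".join(sorted((a, b))) for a, b in zip(df.id_a, df.id_b)]
        frames[mode] = df.assign(pair=key).set_index("pair")
    if not frames:
        return pd.DataFrame()
    all_pairs = sorted(set().union(*(set(df.index) for df in frames.values())))
    out = pd.DataFrame(index=pd.Index(all_pairs, name="pair"))
    out["id_a"] = [p.split("\x1f")[0] for p in all_pairs]
    out["id_b"] = [p.split("\x1f")[1] for p in all_pairs]
    for mode, df in frames.items():
        for col in ("ani", "aln_len", "af_mean", "af_min", "af_max", "wgani"):
            out[f"{col}_{mode}"] = df[col].reindex(out.index).fillna(0.0)
    return out.reset_index(drop=True)
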