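"""Ground-truth genome-pair simulator.

Generates pairs of genome-like sequences with a predefined evolutionary
distance ``d`` (HKY substitution model, expected substitutions per site)
and coverage ``c`` (fraction of genes that are orthologous between the
two genomes), together with exact truth values of ANI and AF:

* each genome carries ``N`` genes (default 75) whose lengths are drawn
  from a log-normal distribution (mean 2.22, sd 0.34 in base-10 logs, in
  codons) and multiplied by 3 to give nucleotide lengths;
* the ``NO = round(c * N)`` orthologous genes are random DNA in genome A
  and HKY-evolved copies at distance ``d`` in genome B, concatenated in
  the same order in both genomes;
* the ``NU = N - NO`` unrelated genes are generated independently per
  genome, grouped into blocks of mean size 8 (multinomial), and the
  blocks are inserted at random positions between orthologs, yielding a
  mosaic structure;
* optionally a proportion ``s`` of orthologs in genome B is relocated to
  random positions, breaking synteny without changing site identity.

True ANI is the realized proportion of identical sites over orthologous
genes; true AF of each genome is total ortholog length over genome
length.  Both are therefore exact for every simulated pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genome_io import CdsSet, GenomeRecord, write_fasta

__all__ = [
    "SimulationParams",
    "SimulatedPair",
    "sample_gene_lengths",
    "hky_rate_matrix",
    "hky_transition_matrix",
    "hky_expected_identity",
    "evolve_hky",
    "partition_blocks",
    "simulate_pair",
    "simulate_grid",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated genome pair."""

    d: float = 0.1              # expected substitutions per site
    c: float = 1.0              # coverage: orthologous genes / all genes
    n_genes: int = 75           # genes per genome
    mu_log10: float = 2.22      # mean of log10 gene length (codons)
    sigma_log10: float = 0.34   # sd of log10 gene length (codons)
    codon_multiplier: int = 3
    block_mean: float = 8.0     # mean unrelated-block size (genes)
    s: float = 0.0              # shuffled ortholog proportion
    kappa: float = 2.0          # HKY transition/transversion rate ratio
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("evolutionary distance d must be non-negative")
        if not 0 <= self.c <= 1:
            raise ValueError("coverage c must lie in [0, 1]")
        if not 0 <= self.s <= 1:
            raise ValueError("shuffle proportion s must lie in [0, 1]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    @property
    def n_ortholog(self) -> int:
        return int(round(self.c * self.n_genes))

    @property
    def n_unrelated(self) -> int:
        return self.n_genes - self.n_ortholog


@dataclass(frozen=True)
class SimulatedPair:
    """Two mosaic genomes plus their exact relatedness truth."""

    genome_a: GenomeRecord
    genome_b: GenomeRecord
    cds_a: CdsSet
    cds_b: CdsSet
    true_ani: float
    true_af_a: float
    true_af_b: float
    params: SimulationParams


def sample_gene_lengths(
    n: int, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw nucleotide gene lengths: round(10^Normal(mu, sigma)) codons x 3."""
    x = rng.normal(params.mu_log10, params.sigma_log10, size=n)
    codons = np.maximum(1, np.rint(10.0**x)).astype(np.int64)
    return codons * params.codon_multiplier


def random_dna(length: int, rng: np.random.Generator,
               freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(freqs, dtype=float))
    return _BASES[codes].tobytes().decode("ascii")


def hky_rate_matrix(kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """HKY rate matrix scaled to one expected substitution per site per unit time.

    Transitions (A<->G, C<->T) occur at ``kappa`` times the transversion
    rate; row i, column j holds the rate i -> j.
    """
    pi = np.asarray(freqs, dtype=float)
    q = np.empty((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    return q / rate


def hky_transition_matrix(d: float, kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """P(d) = expm(Q d): substitution probabilities at distance d."""
    if d < 0:
        raise ValueError("d must be non-negative")
    return expm(hky_rate_matrix(kappa, freqs) * d)


def hky_expected_identity(d: float, kappa: float = 2.0,
                          freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> float:
    """Expected per-site identity between the two ends of a branch of length d."""
    p = hky_transition_matrix(d, kappa, freqs)
    pi = np.asarray(freqs, dtype=float)
    return float((pi * np.diag(p)).sum())


def evolve_hky(gene: str, d: float, kappa: float, freqs: Sequence[float],
               rng: np.random.Generator) -> str:
    """Substitute each site independently via the HKY transition matrix.

    No indels: the output has the same length as the input.  N (or any
    non-ACGT symbol) is left untouched.
    """
    p = hky_transition_matrix(d, kappa, freqs)
    raw = np.frombuffer(gene.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    out = raw.copy()
    for i in range(4):
        mask = codes == i
        n = int(mask.sum())
        if n:
            out[mask] = _BASES[rng.choice(4, size=n, p=p[i])]
    return out.tobytes().decode("ascii")


def partition_blocks(nu: int, block_mean: float, rng: np.random.Generator) -> list[int]:
    """Split ``nu`` unrelated genes into blocks of mean size ``block_mean``.

    The number of blocks is max(1, round(nu / block_mean)); sizes follow a
    multinomial over equally likely blocks, empty blocks are dropped.
    """
    if nu < 0:
        raise ValueError("gene count must be non-negative")
    if nu == 0:
        return []
    n_blocks = max(1, int(round(nu / block_mean)))
    sizes = rng.multinomial(nu, np.full(n_blocks, 1.0 / n_blocks))
    return [int(s) for s in sizes if s > 0]


def _insert_blocks(
    ortholog_order: list[int],
    blocks: list[list[int]],
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Gene order as (kind, index) given blocks of unrelated genes.

    Each block occupies one slot among the ``NO + 1`` gaps between
    orthologs (sampled without replacement while slots remain).
    """
    n_slots = len(ortholog_order) + 1
    if len(blocks) <= n_slots:
        slots = rng.choice(n_slots, size=len(blocks), replace=False)
    else:
        slots = rng.choice(n_slots, size=len(blocks), replace=True)
    per_slot: dict[int, list[list[int]]] = {}
    for slot, block in zip(slots, blocks):
        per_slot.setdefault(int(slot), []).append(block)
    order: list[tuple[str, int]] = []
    for pos in range(n_slots):
        for block in per_slot.get(pos, []):
            order.extend(("unrelated", g) for g in block)
        if pos < len(ortholog_order):
            order.append(("ortholog", ortholog_order[pos]))
    return order


def simulate_pair(params: SimulationParams, rng: np.random.Generator) -> SimulatedPair:
    """Generate one genome pair with its exact ANI/AF truth."""
    no, nu = params.n_ortholog, params.n_unrelated

    orth_lengths = sample_gene_lengths(no, params, rng)
    orth_a = [random_dna(int(l), rng, params.base_freqs) for l in orth_lengths]
    orth_b = [
        evolve_hky(g, params.d, params.kappa, params.base_freqs, rng) for g in orth_a
    ]

    genomes: dict[str, list[tuple[str, int]]] = {}
    unrelated: dict[str, list[str]] = {}
    for which in ("a", "b"):
        lengths = sample_gene_lengths(nu, params, rng)
        unrelated[which] = [random_dna(int(l), rng, params.base_freqs) for l in lengths]
        blocks = partition_blocks(nu, params.block_mean, rng)
        gene_ids: list[list[int]] = []
        start = 0
        for size in blocks:
            gene_ids.append(list(range(start, start + size)))
            start += size
        genomes[which] = _insert_blocks(list(range(no)), gene_ids, rng)

    # break synteny in genome B: relocate a proportion s of orthologs
    n_shuffle = int(round(params.s * no))
    if n_shuffle:
        order_b = genomes["b"]
        orth_positions = [i for i, (kind, _) in enumerate(order_b) if kind == "ortholog"]
        moved_idx = rng.choice(len(orth_positions), size=n_shuffle, replace=False)
        moved = [order_b[orth_positions[i]] for i in moved_idx]
        remaining = [
            g for i, g in enumerate(order_b)
            if i not in {orth_positions[j] for j in moved_idx}
        ]
        for gene in moved:
            remaining.insert(int(rng.integers(0, len(remaining) + 1)), gene)
        genomes["b"] = remaining

    def build(which: str, orth_seqs: list[str]) -> tuple[GenomeRecord, CdsSet]:
        parts = []
        cds = []
        for kind, idx in genomes[which]:
            seq = orth_seqs[idx] if kind == "ortholog" else unrelated[which][idx]
            tag = f"orth{idx}" if kind == "ortholog" else f"unrel{which}{idx}"
            cds.append((f"{which}|{tag}", seq))
            parts.append(seq)
        gid = f"genome_{which}"
        return GenomeRecord(gid, "".join(parts)), CdsSet(gid, cds)

    genome_a, cds_a = build("a", orth_a)
    genome_b, cds_b = build("b", orth_b)

    orth_total = int(orth_lengths.sum()) if no else 0
    if orth_total:
        identical = sum(
            sum(x == y for x, y in zip(ga, gb)) for ga, gb in zip(orth_a, orth_b)
        )
        true_ani = identical / orth_total
    else:
        true_ani = 0.0
    return SimulatedPair(
        genome_a=genome_a,
        genome_b=genome_b,
        cds_a=cds_a,
        cds_b=cds_b,
        true_ani=true_ani,
        true_af_a=orth_total / genome_a.length,
        true_af_b=orth_total / genome_b.length,
        params=params,
    )


def simulate_grid(
    d_values: Sequence[float],
    c_values: Sequence[float],
    reps: int = 20,
    seed: int = 0,
    base_params: SimulationParams = SimulationParams(),
    out_dir: str | Path | None = None,
) -> tuple[list[SimulatedPair], pd.DataFrame]:
    """Simulate ``reps`` pairs per (d, c) combination with a truth table.

    When ``out_dir`` is given, per-pair genome FASTA, per-gene CDS FASTA
    (ortholog labels in headers) and ``truth.tsv`` are written there.
    """
    rng = np.random.default_rng(seed)
    pairs: list[SimulatedPair] = []
    rows = []
    for d in d_values:
        for c in c_values:
            for rep in range(reps):
                params = replace(base_params, d=float(d), c=float(c))
                pair = simulate_pair(params, rng)
                pair_id = f"d{d:g}_c{c:g}_r{rep}"
                pairs.append(pair)
                rows.append(
                    {
                        "pair_id": pair_id,
                        "d": float(d),
                        "c": float(c),
                        "s": params.s,
                        "kappa": params.kappa,
                        "true_ani": pair.true_ani,
                        "true_af_a": pair.true_af_a,
                        "true_af_b": pair.true_af_b,
                    }
                )
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, pair in zip(rows, pairs):
            pid = row["pair_id"]
            write_fasta(
                [
                    GenomeRecord(f"{pid}|A", pair.genome_a.seq),
                    GenomeRecord(f"{pid}|B", pair.genome_b.seq),
                ],
                out / f"{pid}.fasta",
            )
            cds_records = [
                GenomeRecord(f"{pid}|A|{cid}", seq) for cid, seq in pair.cds_a.cds
            ] + [GenomeRecord(f"{pid}|B|{cid}", seq) for cid, seq in pair.cds_b.cds]
            write_fasta(cds_records, out / f"{pid}.cds.fasta")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return pairs, truth
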