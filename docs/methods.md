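# Methods note

## Estimation model

### Fragment mode

The query genome is tiled into non-overlapping fragments of length
`FL` (500 bp in the `ACCURATE` preset, 1020 bp in `FAST` and `ANIB`);
a short terminal fragment is kept. Each fragment is searched against
the target genome on both strands:

- **Seeding.** Exact k-mer matches (k=11 sensitive, k=15 fast) from a
  sorted-array index; k-mers containing ambiguous bases are excluded.
  Seeds are processed in diagonal-major order, and a seed is skipped
  only when a previously accepted alignment was anchored on the *same*
  diagonal and spans it — an off-diagonal alignment is never allowed
  to mask a seed, which protects against repetitive spurious anchors.
- **Extension.** Two banded (half-width 64) affine-gap
  (open 5, extend 2) dynamic-programming arms extend the seed left and
  right; extension stops when the best score in the band drops more
  than `zdrop` (40 unit-scoring, 150 BLASTN-scoring) below the running
  maximum. A second banded pass over the decided interval recovers
  exact match and column counts by traceback. The kernels are
  numba-compiled; their scores are verified against a pure-Python
  full-matrix Smith–Waterman oracle in the test suite.
- **Redundancy and choice.** Per target and strand, alignments
  overlapping a better one by more than half are discarded; the
  fragment's best hit is chosen by score, then columns, then smallest
  target start (fully deterministic).

A hit survives only with identity ≥ `FI` = 0.30 computed over the
*full fragment length* (unaligned fragment tails count as mismatches)
and fragment coverage ≥ `FC` = 0.70. Directional ANI is
Σ matches / Σ columns over surviving fragments; the pair's ANI is the
mean of the two directions, and the conservative alignment length is
the directional minimum. AF is that length divided by each genome
length (reported per genome, mean, min, max), capped at 1. Pairs with
total alignment < 500 bp keep their ANI but get AF = 0 and a
`filtered` flag. `wgANI = ANI × AF` (mean AF by default).

### CDS and protein modes

Genes replace fragments; orthology is approximated by
best-bidirectional hits after the same FI/FC filtering; per-ortholog
statistics average the two directional alignments. Protein mode
translates CDSs (standard code, trailing stop stripped), seeds with
exact 5-mers, scores with BLOSUM62, and requires ≥ 150 aa total
alignment. AF denominators are summed CDS (or protein) lengths.

## Scoring presets

| preset  | k  | FL   | scheme        | zdrop |
|---------|----|------|---------------|-------|
| ACCURATE| 11 | 500  | unit +1/−1    | 40    |
| FAST    | 15 | 1020 | unit +1/−1    | 40    |
| ANIB    | 11 | 1020 | BLASTN +3/−2  | 150   |

A WU-style +5/−4 scheme is also available. `SearchParams` records a
sensitivity value (7.5) for interface completeness, but it is inert:
exact k-mer seeding enumerates all seeds, so there is no subsampling
sensitivity to tune. Caps: 20 000 targets per query, and sequences
longer than 65 000 (nt) / 100 000 are flagged with a warning.

## Simulator

`simulate_pair` emulates a pair of mosaic viral genomes:

- `round(c·N)` orthologous genes (N = 75 by default) shared by both
  genomes, evolved to total distance `d` under HKY85 with κ = 2 and
  uniform base frequencies (both configurable; the rate matrix is
  scaled to one expected substitution per site per unit distance, and
  transition probabilities come from the exact matrix exponential).
- Gene lengths are `round(10^Normal(2.22, 0.34))` codons × 3 nt.
- The remaining genes of each genome are unrelated random sequence,
  inserted in blocks whose sizes are multinomial with mean 8, at
  random positions between orthologs.
- A shuffle proportion `s` relocates orthologs in the second genome
  only, changing order but not content.

Truth is *realized*, not expected: true ANI is the observed site
identity over ortholog pairs, true AF the ortholog length over genome
length, so estimator error is measured against the actual sample path.

What the simulator does **not** model: insertions/deletions within
orthologs, recombination breakpoints inside genes, intergenic
sequence, codon structure or selection (see Limitations), and
compositional bias.

## Benchmark and taxonomy evaluation

Accuracy is summarized by RMSE (optionally binned by distance) and by
ordinary-least-squares regression of estimates on truth with a
1000-replicate nonparametric bootstrap (percentile median and 95% CI
for slope, intercept and R²). Genus predictiveness is evaluated by an
unpenalized logistic regression of same-genus membership on (ANI, AF):
genera are split 65/35 with a seed search so the pair-level ratio also
lands near 65/35 (cross-side pairs are dropped); cross-validation
folds are grouped by genus pair so no genus pair spans folds;
precision–recall AUC is integrated by the trapezoid rule with a
bootstrap CI, alongside F1, FDR and a joint (ANI, AF) threshold scan.

## Numerical choices

- Band half-width 64 and gap penalties 5/2 are package defaults chosen
  to be conventional for unit-type scoring; they are not fitted to any
  dataset.
- All stochastic components take explicit `numpy.random.Generator`
  seeds; every reported statistic is reproducible bit-for-bit under a
  fixed seed.
- The HKY identity used as an oracle has the closed form
  `0.25 + 0.25·e^{−4βd} + 0.5·e^{−2(α+β)d}` with `β = 1/(κ+2)`,
  `α = κ/(κ+2)` under uniform frequencies; at d = 0.8, κ = 2 this is
  0.513, i.e. distance 0.8 corresponds to ANI ≈ 0.5.

## Limitations

- **AF is biased low at high divergence and high mosaicism.**
  Fragments straddling an ortholog/unrelated junction fail the 70%
  coverage filter, and at high `d` marginal fragments fall below 30%
  identity; ANI, computed only over surviving alignments, remains
  nearly unbiased while AF loses the junction-adjacent sequence.
- **No indels within orthologs.** The simulator diverges sequences by
  substitution only, so alignment-length truth is exact but the
  aligner's gap handling is exercised only by the oracle-based tests,
  not by the simulation benchmark.
- **No selection.** Because substitutions are neutral, amino-acid
  identity of simulated orthologs falls *below* nucleotide identity —
  the opposite of real protein-coding genes under purifying selection.
  Protein mode's advantage (reading through synonymous divergence) is
  therefore demonstrated with explicit synonymous-substitution
  constructions rather than with the neutral simulator.
- Fragment boundaries quantize the alignment length: aligned length is
  resolved per fragment, so AF has granularity ~FL/genome length.
- The banded extension can miss optimal alignments whose paths deviate
  more than 64 columns from the seed diagonal (extremely gappy
  alignments); this mirrors the behaviour of production mappers.
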