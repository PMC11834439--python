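"""Independent reference implementations used as test oracles.

These are deliberately naive (full-matrix dynamic programming, closed
forms) and share no code with the package's aligner or simulator.
"""

from __future__ import annotations

import math

import numpy as np


def smith_waterman_affine(
    q: str, t: str, match: int = 1, mismatch: int = -1, gap_open: int = 5, gap_extend: int = 2
) -> int:
    """Best local alignment score, full O(nm) affine-gap Smith-Waterman."""
    n, m = len(q), len(t)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - gap_open - gap_extend, Ei[j - 1] - gap_extend)
            Fi[j] = max(Hi1[j] - gap_open - gap_extend, Fi1[j] - gap_extend)
            s = match if qi == t[j - 1] else mismatch
            h = max(0, Hi1[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def k80_identity(d: float, kappa: float) -> float:
    """Closed-form expected site identity under K80 (uniform frequencies).

    With the rate matrix scaled to one expected substitution per site,
    the transition rate is kappa/(kappa+2) and each transversion rate is
    1/(kappa+2); the probability that the two ends of a branch of length
    d carry the same base is 1/4 + 1/4 e^{-4 beta d} + 1/2 e^{-2(alpha+beta) d}.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa / (kappa + 2.0)
    return 0.25 + 0.25 * math.exp(-4 * beta * d) + 0.5 * math.exp(-2 * (alpha + beta) * d)


def mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Apply exactly n_sub random substitutions at distinct positions."""
    bases = "ACGT"
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        old = out[pos]
        out[pos] = rng.choice([b for b in bases if b != old])
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
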