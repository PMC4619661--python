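"""Mutation-clock dating of a shared allele from sequence divergence.

Ten accessions carry the same LINE insertion with nearly identical
sequence; under a neutral clock the age of their common ancestor follows
from the mean pairwise divergence. With k mean pairwise differences over L
compared sites, mutation rate μ per site per generation and two diverging
lineages, T = k / (2·μ·L) generations. Interval-valued μ and
generations-per-year g propagate conservatively to the widest bracket:

    gen_lo = k / (2·μ_hi·L),  gen_hi = k / (2·μ_lo·L)
    years_lo = gen_lo / g_hi, years_hi = gen_hi / g_lo

No multiple-hit correction is applied (k ≪ L in this regime).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = ["ClockInput", "AgeEstimate", "pairwise_differences", "estimate_allele_age"]

_VALID = frozenset(b"ACGT")


@dataclass(frozen=True)
class ClockInput:
    """Observed divergence and interval-valued clock parameters.

    k: mean pairwise nucleotide differences; L: mean pairwise compared sites;
    mu: per-site per-generation mutation rate interval; g: seed generations
    per year interval.
    """

    k: float
    L: float
    mu_lo: float
    mu_hi: float
    g_lo: float
    g_hi: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not 0 < self.mu_lo <= self.mu_hi:
            raise ValueError("need 0 < mu_lo <= mu_hi")
        if not 0 < self.g_lo <= self.g_hi:
            raise ValueError("need 0 < g_lo <= g_hi")


@dataclass(frozen=True)
class AgeEstimate:
    gen_lo: float
    gen_hi: float
    years_lo: float
    years_hi: float
    resolved: bool = True  # False when k = 0 (no divergence observed)


def pairwise_differences(sequences: Sequence[str]) -> tuple[float, float]:
    """Mean pairwise differences k and compared sites L over an alignment.

    Only positions where *both* sequences of a pair carry an unambiguous
    base (A/C/G/T, case-insensitive) are compared; gaps and ambiguity codes
    are excluded from both k and L. All sequences must share the alignment
    length.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 aligned sequences")
    arrs = [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in sequences]
    length = arrs[0].size
    if any(a.size != length for a in arrs):
        raise ValueError("aligned sequences must have equal length")
    valid = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrs]
    ks, ls = [], []
    for i, j in combinations(range(len(arrs)), 2):
        both = valid[i] & valid[j]
        ls.append(int(both.sum()))
        ks.append(int(((arrs[i] != arrs[j]) & both).sum()))
    return float(np.mean(ks)), float(np.mean(ls))


def estimate_allele_age(inp: ClockInput) -> AgeEstimate:
    """Generation and calendar-year brackets for the allele's common ancestor."""
    if inp.k == 0:
        return AgeEstimate(gen_lo=0.0, gen_hi=0.0, years_lo=0.0, years_hi=0.0, resolved=False)
    gen_lo = inp.k / (2.0 * inp.mu_hi * inp.L)
    gen_hi = inp.k / (2.0 * inp.mu_lo * inp.L)
    return AgeEstimate(
        gen_lo=gen_lo,
        gen_hi=gen_hi,
        years_lo=gen_lo / inp.g_hi,
        years_hi=gen_hi / inp.g_lo,
        resolved=True,
    )
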