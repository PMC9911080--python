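"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive double loops and exact arithmetic
so they share no code path with the vectorized implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from pirnahd import ReferenceSet, generate_references

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def naive_hamming(a: str, b: str) -> int:
    """N in the read never matches (the reference is N-free)."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def oracle_align(seq: str, entries, max_mm: int):
    """Best ungapped placement by exhaustive double loop.

    Returns (family, strand, start, mismatches) or None.  Tie-break:
    family lexicographic, then + before -, then smallest start.
    """
    best = None
    for entry in sorted(entries, key=lambda e: e.name):
        ref = entry.sequence
        for strand, q in (("+", seq), ("-", naive_revcomp(seq))):
            if len(q) > len(ref) or not q:
                continue
            for start in range(len(ref) - len(q) + 1):
                mm = naive_hamming(q, ref[start:start + len(q)])
                if mm <= max_mm and (best is None or mm < best[3]):
                    best = (entry.name, strand, start, mm)
    return best


def oracle_trim(read: str, adapter: str, min_overlap: int,
                max_error_rate: float) -> str:
    """Enumerate every suffix/adapter-prefix alignment; longest match wins."""
    candidates = []
    for length in range(min_overlap, min(len(adapter), len(read)) + 1):
        p = len(read) - length
        mm = sum(1 for a, b in zip(read[p:], adapter[:length]) if a != b)
        if mm <= math.floor(max_error_rate * length):
            candidates.append((length, p))
    if not candidates:
        return read
    length, p = max(candidates)
    return read[:p]


def oracle_fisher(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(min(total, Fraction(1)))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_refs() -> ReferenceSet:
    """3 TEs + 5 miRNAs, fixed seed, reused across read-level tests."""
    return generate_references(n_te=3, te_length=(500, 1000), n_mirna=5,
                               mirna_length=(21, 23), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
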