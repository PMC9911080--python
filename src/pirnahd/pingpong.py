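"""Ping-pong signature detection.

The ping-pong amplification cycle leaves a diagnostic footprint in piRNA
libraries: sense/antisense read pairs whose 5' ends overlap by exactly
10 nt, a uridine bias at piRNA position 1 (1U, antisense reads) and an
adenine at position 10 (10A, sense reads).  This module computes the 5'
overlap histogram per TE family, a z-score for the 10-nt bin against the
other overlap bins, and the 1U/10A base fractions from the sequenced reads.

5'-end convention (0-based, half-open alignments): a plus-strand read's 5'
end is ``start``; a minus-strand read's 5' end is ``end - 1``.  The overlap
between a plus read with 5' end s and a minus read with 5' end e is
o = e - s + 1.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .readproc import AlignmentRecord

DEFAULT_OMAX = 20
DEFAULT_FOCAL = 10


@dataclass
class OverlapHistogram:
    family: str
    counts: dict[int, float]  # overlap o in [1, o_max] -> pair weight
    o_max: int
    pair_weighting: str  # "read-pairs" or "position-pairs"

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[o] for o in range(1, self.o_max + 1)])

    @property
    def total_weight(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class PingPongSignature:
    family: str
    library: str | None
    z10: float | None  # None when the background sd is zero
    u1_fraction: float | None
    a10_fraction: float | None
    n_pairs: float
    low_coverage: bool = False


def overlap_histogram(alignments: Sequence[AlignmentRecord],
                      o_max: int = DEFAULT_OMAX,
                      weighting: str = "read-pairs") -> OverlapHistogram:
    """5' sense/antisense overlap histogram for a single family.

    Under ``read-pairs`` weighting every (plus read, minus read) pair with
    overlap in [1, o_max] contributes weight 1 (duplicated reads count with
    multiplicity); under ``position-pairs`` each distinct (s, e) coordinate
    pair contributes 1.
    """
    if weighting not in ("read-pairs", "position-pairs"):
        raise ValueError(f"unknown weighting {weighting!r}")
    families = {a.family for a in alignments}
    if len(families) > 1:
        raise ValueError(f"mixed families in input: {sorted(families)}")
    family = families.pop() if families else ""
    plus = Counter(a.five_prime for a in alignments if a.strand == "+")
    minus = Counter(a.five_prime for a in alignments if a.strand == "-")
    counts = {o: 0.0 for o in range(1, o_max + 1)}
    for s, ns in plus.items():
        for o in range(1, o_max + 1):
            nm = minus.get(s + o - 1, 0)
            if nm:
                counts[o] += (ns * nm if weighting == "read-pairs" else 1.0)
    return OverlapHistogram(family, counts, o_max, weighting)


def pingpong_zscore(hist: OverlapHistogram,
                    focal: int = DEFAULT_FOCAL) -> float | None:
    """z = (c_focal - mean(background)) / sd(background).

    The background is every bin in [1, o_max] except the focal bin; sd is
    the sample standard deviation (ddof=1).  Returns None (undefined) when
    the background sd is zero.
    """
    if hist.o_max < focal:
        raise ValueError("o_max must cover the focal overlap")
    if hist.o_max < 3:
        raise ValueError("o_max must be >= 3")
    background = np.array([hist.counts[o] for o in range(1, hist.o_max + 1)
                           if o != focal], dtype=float)
    sd = float(background.std(ddof=1))
    if sd == 0.0:
        return None
    return float((hist.counts[focal] - background.mean()) / sd)


def nucleotide_bias(sense_seqs: Iterable[str],
                    antisense_seqs: Iterable[str]
                    ) -> tuple[float | None, float | None]:
    """(u1_fraction, a10_fraction) from sequenced read bases.

    u1 = fraction of antisense-aligned reads whose first sequenced base is
    T (U in the RNA); a10 = fraction of sense-aligned reads with A at
    position 10.  Sequenced bases are used deliberately — the biogenesis
    biases act on the piRNA molecule, not on the reference.  A fraction
    with a zero denominator is None.
    """
    anti = [s for s in antisense_seqs if s]
    sense = [s for s in sense_seqs if len(s) >= 10]
    u1 = (sum(1 for s in anti if s[0] == "T") / len(anti)) if anti else None
    a10 = (sum(1 for s in sense if s[9] == "A") / len(sense)) if sense else None
    return u1, a10


def pingpong_signature(alignments: Sequence[AlignmentRecord],
                       o_max: int = DEFAULT_OMAX,
                       weighting: str = "read-pairs",
                       min_pairs: float = 20.0,
                       library: str | None = None) -> PingPongSignature:
    """Full signature (z10, 1U, 10A, pair weight) for one family's alignments."""
    hist = overlap_histogram(alignments, o_max=o_max, weighting=weighting)
    z = pingpong_zscore(hist)
    sense = [a.sequence for a in alignments
             if a.strand == "+" and a.sequence is not None]
    anti = [a.sequence for a in alignments
            if a.strand == "-" and a.sequence is not None]
    u1, a10 = nucleotide_bias(sense, anti)
    n_pairs = hist.total_weight
    return PingPongSignature(hist.family, library, z, u1, a10, n_pairs,
                             low_coverage=n_pairs < min_pairs)


def pingpong_report(alignments: Mapping[str, Sequence[AlignmentRecord]],
                    length_window: tuple[int, int] = (23, 31),
                    o_max: int = DEFAULT_OMAX,
                    weighting: str = "read-pairs",
                    min_pairs: float = 20.0) -> pd.DataFrame:
    """Signature table, one row per (library, family).

    ``alignments`` maps library id -> records (any families mixed); reads
    are filtered to the piRNA length window first.  Rows whose total pair
    weight falls below ``min_pairs`` carry a low-coverage flag.
    Deterministic: no randomness anywhere in the computation.
    """
    lo, hi = length_window
    rows = []
    for lib, recs in alignments.items():
        by_family: dict[str, list[AlignmentRecord]] = {}
        for rec in recs:
            if lo <= rec.read_length <= hi:
                by_family.setdefault(rec.family, []).append(rec)
        for fam in sorted(by_family):
            sig = pingpong_signature(by_family[fam], o_max=o_max,
                                     weighting=weighting,
                                     min_pairs=min_pairs, library=lib)
            rows.append({
                "library": lib, "family": fam, "n_pairs": sig.n_pairs,
                "z10": math.nan if sig.z10 is None else sig.z10,
                "u1": math.nan if sig.u1_fraction is None else sig.u1_fraction,
                "a10": (math.nan if sig.a10_fraction is None
                        else sig.a10_fraction),
                "low_coverage": sig.low_coverage,
            })
    return pd.DataFrame(rows, columns=["library", "family", "n_pairs", "z10",
                                       "u1", "a10", "low_coverage"])
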