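"""Read processing: adapter trimming, length filtering, ungapped TE mapping
at tiered mismatch thresholds, and miRNA subtraction.

The mapper considers every ungapped placement of a read (and of its reverse
complement) at every offset of every reference and reports the single
minimum-Hamming-distance placement within the mismatch budget, with a
deterministic tie-break: family name lexicographic, then + strand before -,
then smallest start.  Gapped alignment is deliberately out of scope — reads
that would need indels to map are simply unreported, mirroring a pipeline
that discards indel alignments.

Coordinates are 0-based half-open [start, end); a minus-strand read stores
its leftmost reference coordinate in ``start`` and has its 5' end at
``end - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequtils import revcomp
from .simulate import Read, ReadSet, ReferenceSet

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class AlignmentRecord:
    """Ungapped placement of a read on a reference."""

    read_id: str
    family: str
    strand: str  # "+" or "-"
    start: int  # 0-based leftmost reference coordinate
    end: int  # exclusive; end - start == read_length
    mismatches: int
    read_length: int
    sequence: str | None = None  # sequenced bases, as read (not reference)
    library: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.read_length:
            raise ValueError("ungapped alignment requires end - start == length")

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class MappingPolicy:
    """Mapping stringency: the study design uses tiers of 3 and 6 mismatches."""

    max_mismatches: int = 3
    best_hit_only: bool = True  # ties resolved deterministically, never sampled

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------


def trim_adapter(read: str, adapter: str, min_overlap: int = 3,
                 max_error_rate: float = 0.1) -> str:
    """Remove a 3' adapter occurrence from a read.

    An occurrence at read position p matches a length-L adapter *prefix*
    (L >= min_overlap) extending to the read's 3' end, with at most
    floor(max_error_rate * L) mismatches.  The longest such match (smallest
    p) wins; without one the read is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(read)
    longest = min(len(adapter), n)
    for length in range(longest, min_overlap - 1, -1):
        p = n - length
        allowed = math.floor(max_error_rate * length)
        mism = sum(1 for a, b in zip(read[p:], adapter[:length]) if a != b)
        if mism <= allowed:
            return read[:p]
    return read


def trim_reads(reads: ReadSet, adapter: str, min_overlap: int = 3,
               max_error_rate: float = 0.1) -> ReadSet:
    """Apply :func:`trim_adapter` to every read, preserving ids and truth."""
    return ReadSet([
        Read(r.read_id,
             trim_adapter(r.sequence, adapter, min_overlap, max_error_rate),
             r.truth)
        for r in reads
    ])


def filter_by_length(reads: ReadSet, min_len: int = 5) -> ReadSet:
    """Keep reads of length >= min_len, preserving order."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return ReadSet([r for r in reads if len(r.sequence) >= min_len])


# ---------------------------------------------------------------------------
# ungapped best-hit mapping
# ---------------------------------------------------------------------------


def _onehot(seq: str) -> np.ndarray:
    """(len, 4) one-hot; N rows are all-zero so N can never match."""
    idx = np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8,
                      count=len(seq))
    out = np.zeros((len(seq), 4), dtype=np.float32)
    valid = idx < 4
    out[np.nonzero(valid)[0], idx[valid]] = 1.0
    return out


def _window_matrix(ref_onehot: np.ndarray, k: int) -> np.ndarray:
    """All length-k windows of a one-hot reference, shape (m, 4k)."""
    w = np.lib.stride_tricks.sliding_window_view(ref_onehot, k, axis=0)
    # w: (m, 4, k) -> (m, k, 4) -> (m, 4k)
    m = w.shape[0]
    return np.ascontiguousarray(w.transpose(0, 2, 1)).reshape(m, 4 * k)


def align_reads(reads: ReadSet, refs: ReferenceSet,
                policy: MappingPolicy | None = None,
                role: str = "TE",
                stats: dict | None = None) -> list[AlignmentRecord]:
    """Map every read, ungapped, to the best placement on any reference.

    Returns at most one :class:`AlignmentRecord` per read (input order
    preserved); reads with no placement within ``policy.max_mismatches`` are
    unreported.  Reads longer than every reference cannot be placed and are
    tallied in ``stats['n_too_long']`` when a stats dict is supplied.
    """
    if policy is None:
        policy = MappingPolicy()
    entries = sorted((e for e in refs.entries if e.role == role),
                     key=lambda e: e.name)
    if not entries:
        raise ValueError(f"reference set contains no {role} entries")

    read_list = list(reads)
    n = len(read_list)
    best_mm = np.full(n, policy.max_mismatches + 1, dtype=np.int32)
    best_rec: list[AlignmentRecord | None] = [None] * n

    # group read indices by length; each (family, strand) pass is one matmul
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(read_list):
        if len(r.sequence) > 0:
            by_len.setdefault(len(r.sequence), []).append(i)

    max_ref_len = max(len(e.sequence) for e in entries)
    fwd_onehot = {k: np.stack([_onehot(read_list[i].sequence) for i in idx])
                  .reshape(len(idx), -1)
                  for k, idx in by_len.items() if k <= max_ref_len}
    rev_onehot = {k: np.stack([_onehot(revcomp(read_list[i].sequence))
                               for i in idx]).reshape(len(idx), -1)
                  for k, idx in by_len.items() if k <= max_ref_len}

    for entry in entries:  # lexicographic family order = tie-break priority
        ref_oh = _onehot(entry.sequence)
        ref_len = len(entry.sequence)
        for strand in ("+", "-"):  # + before - = tie-break priority
            mats = fwd_onehot if strand == "+" else rev_onehot
            for k, read_oh in mats.items():
                if k > ref_len:
                    continue
                windows = _window_matrix(ref_oh, k)
                matches = read_oh @ windows.T  # (n_k, m)
                mism = k - np.rint(matches).astype(np.int32)
                starts = np.argmin(mism, axis=1)  # first min = smallest start
                mins = mism[np.arange(len(starts)), starts]
                idx = by_len[k]
                for j, (mm, st) in enumerate(zip(mins, starts)):
                    i = idx[j]
                    if mm < best_mm[i]:  # strict: earlier passes win ties
                        best_mm[i] = mm
                        r = read_list[i]
                        best_rec[i] = AlignmentRecord(
                            r.read_id, entry.name, strand, int(st),
                            int(st) + k, int(mm), k, sequence=r.sequence)

    records = [rec for rec in best_rec if rec is not None]
    if stats is not None:
        n_too_long = sum(1 for r in read_list
                         if len(r.sequence) > max_ref_len)
        stats.update({
            "n_reads": n,
            "n_mapped": len(records),
            "n_unmapped": n - len(records),
            "n_too_long": n_too_long,
        })
    return records


def filter_mirna(reads: ReadSet, mirna_refs: ReferenceSet,
                 max_mismatches: int = 1) -> ReadSet:
    """Drop reads with any ungapped miRNA placement within the budget.

    A read matches a miRNA if it has an ungapped placement, on either
    strand of any miRNA reference, with Hamming distance <= max_mismatches;
    matching reads are removed and the complement returned in input order.
    """
    mirna_only = mirna_refs.subset("miRNA")
    if not mirna_only.entries:
        return ReadSet(list(reads))
    hits = align_reads(reads, mirna_only,
                       MappingPolicy(max_mismatches=max_mismatches),
                       role="miRNA")
    hit_ids = {h.read_id for h in hits}
    return ReadSet([r for r in reads if r.read_id not in hit_ids])
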