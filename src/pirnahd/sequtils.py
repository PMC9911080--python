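"""Tiny DNA-string helpers shared across modules."""

_COMP = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")
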