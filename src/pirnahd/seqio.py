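"""Standard-format readers and writers.

FASTA/FASTQ go through Biopython's SeqIO; alignments are serialized both as
a TSV (0-based half-open coordinates) and as a minimal SAM dialect (FLAG
0/16, 1-based POS, CIGAR "<L>M", NM:i tag) readable by samtools/pysam.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readproc import AlignmentRecord
from .sequtils import revcomp
from .simulate import Read, ReadSet, ReferenceEntry, ReferenceSet


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path, role: str = "TE") -> ReferenceSet:
    """Read a FASTA file into a ReferenceSet with a single role."""
    entries = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            entries.append(ReferenceEntry(rec.id, str(rec.seq).upper(), role))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceSet(entries)


def write_fasta(path, refs: ReferenceSet | Iterable[ReferenceEntry],
                width: int = 60) -> None:
    entries = refs.entries if isinstance(refs, ReferenceSet) else list(refs)
    records = [SeqRecord(Seq(e.sequence), id=e.name, description="")
               for e in entries]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fastq(path) -> ReadSet:
    """Read FASTQ into a ReadSet (qualities are ignored by the pipeline)."""
    reads = []
    with open(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                reads.append(Read(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ {path}: {exc}") from exc
    return ReadSet(reads)


def write_fastq(path, reads: ReadSet) -> None:
    """Write FASTQ with constant qualities ('I'), per the no-quality model."""
    with open(path, "w") as handle:
        for r in reads:
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# alignments: TSV and minimal SAM
# ---------------------------------------------------------------------------

_ALN_COLUMNS = ["read_id", "family", "strand", "start", "end", "mismatches",
                "read_length"]


def write_alignments_tsv(path, records: Sequence[AlignmentRecord]) -> None:
    rows = [{c: getattr(r, c) for c in _ALN_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=_ALN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    return [AlignmentRecord(row.read_id, row.family, row.strand,
                            int(row.start), int(row.end), int(row.mismatches),
                            int(row.read_length))
            for row in df.itertuples()]


def write_alignments_sam(path, records: Sequence[AlignmentRecord],
                         refs: ReferenceSet) -> None:
    """Minimal SAM: FLAG 0/16, POS 1-based, CIGAR '<L>M', NM tag.

    Minus-strand records store the reverse complement of the read in SEQ,
    per the SAM convention that SEQ is given on the reference strand.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for e in sorted(refs.entries, key=lambda e: e.name):
            fh.write(f"@SQ\tSN:{e.name}\tLN:{len(e.sequence)}\n")
        for r in records:
            flag = 0 if r.strand == "+" else 16
            seq = r.sequence or "*"
            if r.strand == "-" and seq != "*":
                seq = revcomp(seq)
            fh.write(f"{r.read_id}\t{flag}\t{r.family}\t{r.start + 1}\t255\t"
                     f"{r.read_length}M\t*\t0\t0\t{seq}\t*\tNM:i:{r.mismatches}\n")


def read_alignments_sam(path) -> list[AlignmentRecord]:
    """Read the minimal SAM dialect back via pysam."""
    import pysam

    records = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            strand = "-" if seg.is_reverse else "+"
            seq = seg.query_sequence
            if seq is not None and strand == "-":
                seq = revcomp(seq)
            length = seg.query_length or len(seq or "")
            records.append(AlignmentRecord(
                seg.query_name, seg.reference_name, strand,
                seg.reference_start, seg.reference_start + length,
                int(seg.get_tag("NM")), length, sequence=seq))
    return records


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(path, df: pd.DataFrame, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_cross_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"maternal_line", "paternal_line", "tester_subline",
                "direction", "temperature", "n_dysgenic", "n_normal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cross table missing columns: {sorted(missing)}")
    if "line" not in df.columns:
        df["line"] = df.apply(
            lambda r: (r["maternal_line"] if r["direction"] == "dysgenic"
                       else r["paternal_line"]), axis=1)
    return df


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"line", "direction", "temperature", "replicate", "target", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df
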