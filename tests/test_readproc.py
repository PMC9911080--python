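"""Adapter trimming, length filtering, and the ungapped best-hit mapper,
checked against independent brute-force oracles."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_align, oracle_trim, random_dna
from pirnahd import (LibraryConfig, MappingPolicy, Read, ReadSet,
                     ReferenceEntry, ReferenceSet, align_reads,
                     filter_by_length, filter_mirna,
                     simulate_small_rna_library, trim_adapter)
from pirnahd.sequtils import revcomp

ADAPTER = "TGGAATTCTCGG"

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


class TestTrimAdapter:
    @pytest.mark.parametrize("read,expected", [
        ("ACGTACGT" + "TGGAATTC", "ACGTACGT"),  # exact adapter-prefix suffix
        ("ACGTACGT", "ACGTACGT"),  # no occurrence
        ("TGGAATTCTCGG", ""),  # read is pure adapter
        ("", ""),  # empty read returned unchanged
    ])
    def test_examples(self, read, expected):
        assert trim_adapter(read, ADAPTER, min_overlap=3,
                            max_error_rate=0.1) == expected

    def test_one_mismatch_within_rate(self):
        # 10-nt adapter prefix with one error: floor(0.1 * 10) = 1 allowed
        read = "AAAACCCC" + "TGGAATTCTG"  # last base G vs C in adapter[9]
        assert trim_adapter(read, ADAPTER, 3, 0.1) == "AAAACCCC"
        # but 2 errors in 10 nt must not trim
        read2 = "AAAACCCC" + "TGGAATTGAG"
        assert trim_adapter(read2, ADAPTER, 3, 0.1) == read2

    @settings(max_examples=300, deadline=None)
    @given(insert=dna, adapter_len=st.integers(0, 12),
           junk=st.text(alphabet="ACGT", min_size=0, max_size=6))
    def test_matches_brute_force_enumeration(self, insert, adapter_len, junk):
        read = insert + ADAPTER[:adapter_len] + junk
        assert trim_adapter(read, ADAPTER, 3, 0.1) == \
            oracle_trim(read, ADAPTER, 3, 0.1)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", "")
        with pytest.raises(ValueError):
            trim_adapter("ACGT", ADAPTER, min_overlap=0)


class TestFilterByLength:
    def test_min_len_boundary(self):
        reads = ReadSet([Read(f"r{i}", "A" * n)
                         for i, n in enumerate([3, 4, 5, 6])])
        kept = filter_by_length(reads, 5)
        assert [len(r.sequence) for r in kept] == [5, 6]

    def test_zero_is_identity_and_all_short_empties(self):
        reads = ReadSet([Read("a", "ACGT"), Read("b", "AC")])
        assert len(filter_by_length(reads, 0)) == 2
        assert len(filter_by_length(reads, 5)) == 0


def _te(name, seq):
    return ReferenceEntry(name, seq, "TE")


class TestAlignReads:
    def test_exact_substring_and_revcomp(self, small_refs):
        te1 = small_refs.get("TE1").sequence
        reads = ReadSet([
            Read("fwd", te1[100:125]),
            Read("rev", revcomp(te1[40:65])),
        ])
        recs = {r.read_id: r for r in align_reads(reads, small_refs)}
        assert (recs["fwd"].family, recs["fwd"].strand, recs["fwd"].start,
                recs["fwd"].mismatches) == ("TE1", "+", 100, 0)
        assert (recs["rev"].family, recs["rev"].strand, recs["rev"].start,
                recs["rev"].mismatches) == ("TE1", "-", 40, 0)

    def test_mismatch_tiers(self, small_refs, rng):
        te1 = small_refs.get("TE1").sequence
        seq = list(te1[200:228])
        for pos in (2, 9, 15, 21):  # 4 substitutions
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        reads = ReadSet([Read("mut", "".join(seq))])
        assert align_reads(reads, small_refs, MappingPolicy(3)) == []
        rec = align_reads(reads, small_refs, MappingPolicy(6))[0]
        assert (rec.family, rec.start, rec.mismatches) == ("TE1", 200, 4)

    def test_read_longer_than_references_is_skipped(self):
        refs = ReferenceSet([_te("TE1", "ACGT" * 30)])
        reads = ReadSet([Read("long", "ACGT" * 40)])
        stats = {}
        assert align_reads(reads, refs, stats=stats) == []
        assert stats["n_too_long"] == 1

    def test_n_bases_count_as_mismatches(self):
        ref = "ACGTACGTACGTACGTACGTACGTACGT" + "A" * 100
        refs = ReferenceSet([_te("TE1", ref)])
        read = "NCGTACGTACGTACGTACGTACGT"
        rec = align_reads(ReadSet([Read("n1", read)]), refs,
                          MappingPolicy(1))[0]
        assert rec.mismatches == 1 and rec.start == 0
        # an all-N read can never match
        assert align_reads(ReadSet([Read("nn", "N" * 24)]), refs,
                           MappingPolicy(3)) == []

    def test_deterministic_tie_break_orders_family_strand_start(self):
        # identical 30-nt block planted in two families and both strands
        block = "ACGTTGCAACGTTGCAACGTTGCAACGTTG"
        pad = "C" * 80
        refs = ReferenceSet([
            _te("TEa", pad + block + pad),
            _te("TEb", block + pad + revcomp(block)),
        ])
        rec = align_reads(ReadSet([Read("r", block)]), refs)[0]
        assert (rec.family, rec.strand, rec.start) == ("TEa", "+", 80)
        # within one family, + placement preferred over - at equal distance
        refs2 = ReferenceSet([_te("TEc", pad + revcomp(block) + block + pad)])
        rec2 = align_reads(ReadSet([Read("r", block)]), refs2)[0]
        assert (rec2.strand, rec2.start) == ("+", 80 + 30)

    def test_oracle_equivalence_random_instances(self, rng):
        refs = ReferenceSet([
            _te("TE1", random_dna(rng, 700)),
            _te("TE2", random_dna(rng, 400)),
        ])
        blob = {e.name: e.sequence for e in refs.entries}
        for tier in (3, 6):
            policy = MappingPolicy(tier)
            for i in range(60):
                k = int(rng.integers(18, 32))
                if rng.random() < 0.5:  # planted read with substitutions
                    fam = "TE1" if rng.random() < 0.5 else "TE2"
                    start = int(rng.integers(0, len(blob[fam]) - k + 1))
                    seq = list(blob[fam][start:start + k])
                    for _ in range(int(rng.integers(0, 5))):
                        p = int(rng.integers(0, k))
                        seq[p] = "ACGT"[int(rng.integers(0, 4))]
                    seq = "".join(seq)
                    if rng.random() < 0.5:
                        seq = revcomp(seq)
                else:
                    seq = random_dna(rng, k)
                got = align_reads(ReadSet([Read("r", seq)]), refs, policy)
                want = oracle_align(seq, refs.entries, tier)
                if want is None:
                    assert got == []
                else:
                    rec = got[0]
                    assert (rec.family, rec.strand, rec.start,
                            rec.mismatches) == want

    def test_strand_involution(self, small_refs, rng):
        te2 = small_refs.get("TE2").sequence
        for _ in range(20):
            k = int(rng.integers(20, 30))
            start = int(rng.integers(0, len(te2) - k))
            seq = te2[start:start + k]
            a = align_reads(ReadSet([Read("f", seq)]), small_refs)[0]
            b = align_reads(ReadSet([Read("r", revcomp(seq))]), small_refs)[0]
            assert (a.family, a.start, a.mismatches) == \
                (b.family, b.start, b.mismatches)
            assert {a.strand, b.strand} == {"+", "-"}

    def test_tier3_subset_of_tier6(self, small_refs, rng):
        cfg = LibraryConfig(n_reads=300, error_rate=0.05, seed=21)
        reads = simulate_small_rna_library(small_refs, cfg)
        ids3 = {r.read_id for r in align_reads(reads, small_refs,
                                               MappingPolicy(3))}
        ids6 = {r.read_id for r in align_reads(reads, small_refs,
                                               MappingPolicy(6))}
        assert ids3 <= ids6

    def test_error_free_reads_recover_truth(self, small_refs):
        cfg = LibraryConfig(n_reads=400, class_mix={"piRNA": 0.7,
                                                    "siRNA": 0.3},
                            pingpong_fraction=0.5, error_rate=0.0, seed=22)
        reads = simulate_small_rna_library(small_refs, cfg)
        recs = {r.read_id: r for r in align_reads(reads, small_refs)}
        for r in reads:
            rec = recs[r.read_id]
            t = r.truth
            assert (rec.family, rec.strand, rec.start, rec.mismatches) == \
                (t.family, t.strand, t.start, 0)


class TestFilterMirna:
    def test_exact_and_near_matches_removed(self, small_refs):
        mir = small_refs.mirna_entries[0].sequence
        one_off = "A" + mir[1:] if mir[0] != "A" else "C" + mir[1:]
        two_off = list(mir)
        two_off[0] = "A" if mir[0] != "A" else "C"
        two_off[5] = "A" if mir[5] != "A" else "C"
        reads = ReadSet([Read("exact", mir), Read("one", one_off),
                         Read("two", "".join(two_off))])
        kept = filter_mirna(reads, small_refs, max_mismatches=1)
        assert [r.read_id for r in kept] == ["two"]

    def test_reverse_complement_matches_removed(self, small_refs):
        mir = small_refs.mirna_entries[1].sequence
        kept = filter_mirna(ReadSet([Read("rc", revcomp(mir))]), small_refs)
        assert len(kept) == 0

    def test_random_reads_kept_when_oracle_says_no_match(self, small_refs,
                                                         rng):
        for _ in range(30):
            seq = random_dna(rng, 25)
            kept = filter_mirna(ReadSet([Read("r", seq)]), small_refs)
            want = oracle_align(seq, small_refs.mirna_entries, 1)
            assert (len(kept) == 0) == (want is not None)
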