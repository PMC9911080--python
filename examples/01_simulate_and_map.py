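"""Simulate a small ovarian small-RNA library and map it to TE consensus
sequences at both mismatch tiers.

Builds random TE/miRNA references, draws 2,000 reads (miRNA + siRNA + piRNA
classes, 30% carrying a 3' adapter, 1% per-base error), then runs the read
chain: adapter trim -> drop reads < 5 nt -> subtract miRNA matches (<= 1
mismatch) -> ungapped best-hit TE mapping at <= 3 and <= 6 mismatches.
"""

from pirnahd import (LibraryConfig, MappingPolicy, align_reads,
                     filter_by_length, filter_mirna, generate_references,
                     simulate_small_rna_library, trim_reads)

refs = generate_references(n_te=4, te_length=(600, 1200), n_mirna=6,
                           mirna_length=(21, 23), seed=1)
cfg = LibraryConfig(n_reads=2000, pingpong_fraction=0.3, error_rate=0.01,
                    adapter_fraction=0.3, seed=2)
reads = simulate_small_rna_library(refs, cfg)
print(f"simulated reads:            {len(reads)}")

reads = trim_reads(reads, cfg.adapter)
reads = filter_by_length(reads, 5)
print(f"after trim + length filter: {len(reads)}")

reads = filter_mirna(reads, refs, max_mismatches=1)
print(f"after miRNA subtraction:    {len(reads)}")

for tier in (3, 6):
    recs = align_reads(reads, refs, MappingPolicy(max_mismatches=tier))
    print(f"mapped at <= {tier} mismatches:  {len(recs)}")

# The two tiers are nested: every read reported at <= 3 mismatches is also
# reported at <= 6; the difference is reads that only map loosely, which
# matters for piRNAs that tolerate imperfect complementarity to a target.
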