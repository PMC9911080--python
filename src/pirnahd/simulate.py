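"""Synthetic ovarian small-RNA study generator.

Everything the analysis pipeline consumes can be simulated here with full
ground-truth bookkeeping: TE-consensus and miRNA reference sets, small-RNA
libraries with a known ping-pong-paired read structure (10-nt 5' overlaps,
1U/10A biases), reciprocal-cross dysgenesis count tables from a binomial
model with logit-scale line effects, and qPCR Ct tables with
line/direction/temperature effects.

Reads are emitted in the DNA alphabet (T, not U); the 1U bias acts on the
first sequenced base of antisense piRNA reads. All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequtils import DNA_ALPHABET, revcomp

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    sequence: str
    role: str  # "TE" or "miRNA"


@dataclass
class ReferenceSet:
    """Named nucleotide sequences: TE consensus families and mature miRNAs."""

    entries: list[ReferenceEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("reference names must be unique")
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for {e.name}")
            if e.role not in ("TE", "miRNA"):
                raise ValueError(f"unknown role {e.role!r} for {e.name}")
            bad = set(e.sequence) - set("ACGT")
            if bad:
                raise ValueError(f"non-ACGT characters {bad} in {e.name}")
            if e.role == "TE" and len(e.sequence) < 100:
                raise ValueError(f"TE sequence {e.name} shorter than 100 nt")
            if e.role == "miRNA" and not 18 <= len(e.sequence) <= 30:
                raise ValueError(f"miRNA {e.name} outside 18-30 nt")

    @property
    def te_entries(self) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.role == "TE"]

    @property
    def mirna_entries(self) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.role == "miRNA"]

    def subset(self, role: str) -> "ReferenceSet":
        return ReferenceSet([e for e in self.entries if e.role == role])

    def get(self, name: str) -> ReferenceEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of a simulated read, for recovery tests."""

    family: str
    strand: str  # "+" or "-"
    start: int  # 0-based leftmost coordinate on the reference
    length: int  # insert length before adapter/errors
    read_class: str  # miRNA / siRNA / piRNA
    pingpong_partner_id: str | None = None


@dataclass
class Read:
    read_id: str
    sequence: str
    truth: ReadTruth | None = None


@dataclass
class ReadSet:
    reads: list[Read]

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids must be unique")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]


def _default_length_dist() -> dict[str, dict[int, float]]:
    # Conventional class length profiles: miRNAs 21-23 nt, siRNAs 21 nt,
    # piRNAs 23-31 nt with a broad mode near 26 nt.
    pirna = {23: 0.06, 24: 0.10, 25: 0.16, 26: 0.20, 27: 0.18,
             28: 0.12, 29: 0.08, 30: 0.06, 31: 0.04}
    return {
        "miRNA": {21: 0.25, 22: 0.50, 23: 0.25},
        "siRNA": {21: 1.0},
        "piRNA": pirna,
    }


@dataclass
class LibraryConfig:
    """Generative knobs for one simulated small-RNA library.

    ``pingpong_fraction`` is the fraction of piRNA reads emitted as
    sense/antisense pairs whose 5' ends overlap by exactly 10 nt.  The
    antisense partner's first sequenced base is uridine (T in DNA) with
    marginal probability ``u1_bias`` and the sense partner's 10th base is A
    with marginal probability ``a10_bias``; both biases also apply to
    unpaired piRNA reads of the corresponding strand so that the empirical
    base fraction matches the configured bias.  ``None`` (the default)
    disables the forcing entirely and leaves the genomic base, so that
    error-free reads map back to their truth placement with 0 mismatches.
    """

    n_reads: int = 10_000
    family_weights: Mapping[str, float] | None = None  # None = uniform over TEs
    pingpong_fraction: float = 0.0
    pingpong_families: frozenset[str] | None = None  # None = all families
    u1_bias: float | None = None
    a10_bias: float | None = None
    length_dist: Mapping[str, Mapping[int, float]] = field(
        default_factory=_default_length_dist)
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"miRNA": 0.3, "siRNA": 0.2, "piRNA": 0.5})
    error_rate: float = 0.0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_fraction: float = 0.0
    max_read_length: int | None = None  # None = never truncate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        for p in (self.pingpong_fraction, self.u1_bias, self.a10_bias,
                  self.error_rate, self.adapter_fraction):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        if self.family_weights is not None:
            w = sum(self.family_weights.values())
            if not math.isclose(w, 1.0, abs_tol=1e-9):
                raise ValueError("family_weights must sum to 1")
            if any(v < 0 for v in self.family_weights.values()):
                raise ValueError("family weights must be nonnegative")


@dataclass
class CrossDesign:
    """Reciprocal dysgenesis-cross design with logit-scale line effects."""

    lines: Mapping[str, float]  # line name -> logit of dysgenic proportion
    tester_sublines: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 0.0})
    n_f1_per_cross: int = 100
    directions: Sequence[str] = ("dysgenic", "reciprocal")
    reciprocal_logit: float = -4.0
    temperature: float = 29.0
    tester_line: str = "Cro18"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f1_per_cross < 1:
            raise ValueError("n_f1_per_cross must be >= 1")
        if not self.lines:
            raise ValueError("at least one line required")
        for d in self.directions:
            if d not in ("dysgenic", "reciprocal"):
                raise ValueError(f"unknown direction {d!r}")


@dataclass
class QpcrEffects:
    """Shifts on the Ct scale (a negative Ct shift doubles expression per cycle)."""

    direction: float = 0.0  # applied in the dysgenic direction
    temperature: float = 0.0  # applied at the higher temperature
    interaction: float = 0.0  # dysgenic x high-temperature
    line: Mapping[str, float] = field(default_factory=dict)


@dataclass
class QpcrDesign:
    lines: Sequence[str]
    directions: Sequence[str] = ("dysgenic", "reciprocal")
    temperatures: Sequence[float] = (25.0, 29.0)
    baseline_ct: float = 26.0
    reference_ct: float = 18.0
    spliced_effects: QpcrEffects = field(default_factory=QpcrEffects)
    total_effects: QpcrEffects = field(default_factory=QpcrEffects)
    replicate_sd: float = 0.3
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be > 0")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def generate_references(n_te: int,
                        te_length: tuple[int, int] = (500, 2000),
                        n_mirna: int = 10,
                        mirna_length: tuple[int, int] = (21, 23),
                        seed: int = 0) -> ReferenceSet:
    """Random TE-consensus and mature-miRNA reference sequences.

    Guarantees that no miRNA is a substring of any TE on either strand, so
    that miRNA subtraction cannot silently remove genuine TE-derived reads.
    """
    if n_te < 1:
        raise ValueError("n_te must be >= 1")
    if n_mirna < 0:
        raise ValueError("n_mirna must be >= 0")
    for lo, hi in (te_length, mirna_length):
        if lo > hi or lo < 1:
            raise ValueError("invalid length range")
    if te_length[0] < 100:
        raise ValueError("TE length must be >= 100")
    if not (18 <= mirna_length[0] and mirna_length[1] <= 30):
        raise ValueError("miRNA length range must lie within [18, 30]")
    rng = np.random.default_rng(seed)
    tes = []
    for i in range(n_te):
        length = int(rng.integers(te_length[0], te_length[1] + 1))
        tes.append(ReferenceEntry(f"TE{i + 1}", _random_seq(rng, length), "TE"))
    te_blob = " ".join(e.sequence for e in tes)
    te_blob_rc = revcomp(te_blob.replace(" ", " "))
    mirnas = []
    for i in range(n_mirna):
        for _ in range(100):
            length = int(rng.integers(mirna_length[0], mirna_length[1] + 1))
            seq = _random_seq(rng, length)
            if seq not in te_blob and seq not in te_blob_rc:
                break
        else:  # pragma: no cover - vanishingly unlikely for length >= 18
            raise RuntimeError("could not draw a miRNA disjoint from TEs")
        mirnas.append(ReferenceEntry(f"mir{i + 1}", seq, "miRNA"))
    return ReferenceSet(tes + mirnas)


# ---------------------------------------------------------------------------
# small-RNA library simulation
# ---------------------------------------------------------------------------


def _apportion(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to weighted bins."""
    keys = sorted(weights)
    raw = {k: n * weights[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    # hand leftovers to the largest fractional parts; ties by name
    order = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


class _LengthSampler:
    """Inverse-CDF sampler over a discrete length distribution (cached)."""

    def __init__(self, dist: Mapping[int, float]):
        self.lengths = sorted(dist)
        probs = np.array([dist[k] for k in self.lengths], dtype=float)
        self.cum = np.cumsum(probs / probs.sum())

    def draw(self, rng: np.random.Generator) -> int:
        return self.lengths[int(np.searchsorted(self.cum, rng.random()))]


def _biased_base(rng: np.random.Generator, bias: float | None,
                 genomic: str, base: str) -> str:
    """First-base forcing with an exact marginal.

    None keeps the genomic base; otherwise `base` with probability `bias`,
    a uniform non-`base` letter with probability 1 - bias, so the marginal
    frequency of `base` equals the configured bias exactly.
    """
    if bias is None:
        return genomic
    if rng.random() < bias:
        return base
    others = [b for b in DNA_ALPHABET if b != base]
    return others[int(rng.integers(0, 3))]


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alts = [b for b in DNA_ALPHABET if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_small_rna_library(refs: ReferenceSet,
                               config: LibraryConfig,
                               read_id_prefix: str = "r") -> ReadSet:
    """Simulate one small-RNA library with ground-truth provenance tags.

    piRNA and siRNA reads are drawn from TE consensus positions on either
    strand; miRNA-class reads are prefixes of the mature miRNA references.
    A fraction ``pingpong_fraction`` of piRNA reads is emitted as
    sense/antisense pairs whose 5' ends overlap by exactly 10 nt: the sense
    read's 5' start s is drawn uniformly and the antisense 5' end placed at
    s + 9, so truth overlaps are exactly 10 by construction.
    """
    te_names = [e.name for e in refs.te_entries]
    if not te_names:
        raise ValueError("reference set contains no TE entries")
    weights = config.family_weights
    if weights is None:
        weights = {n: 1.0 / len(te_names) for n in te_names}
    unknown = set(weights) - set(te_names)
    if unknown:
        raise ValueError(f"family weights for unknown families: {sorted(unknown)}")
    te_seq = {e.name: e.sequence for e in refs.te_entries}
    mirna_entries = refs.mirna_entries

    rng = np.random.default_rng(config.seed)
    class_counts = _apportion(config.n_reads, config.class_mix)
    samplers = {cls: _LengthSampler(dist)
                for cls, dist in config.length_dist.items()}
    reads: list[Read] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{read_id_prefix}{counter:06d}"

    # --- miRNA-class reads -------------------------------------------------
    for _ in range(class_counts.get("miRNA", 0)):
        if not mirna_entries:
            raise ValueError("class_mix requests miRNA reads but no miRNA refs")
        entry = mirna_entries[int(rng.integers(0, len(mirna_entries)))]
        length = min(samplers["miRNA"].draw(rng), len(entry.sequence))
        seq = entry.sequence[:length]
        reads.append(Read(next_id(), seq,
                          ReadTruth(entry.name, "+", 0, length, "miRNA")))

    # --- siRNA-class reads (TE-derived, ~21 nt) ---------------------------
    def te_single(read_class: str, dist_key: str, family: str) -> Read:
        ref = te_seq[family]
        length = min(samplers[dist_key].draw(rng), len(ref))
        start = int(rng.integers(0, len(ref) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        window = ref[start:start + length]
        seq = window if strand == "+" else revcomp(window)
        return Read(next_id(), seq,
                    ReadTruth(family, strand, start, length, read_class))

    si_fams = _apportion(class_counts.get("siRNA", 0), weights)
    for fam, k in si_fams.items():
        for _ in range(k):
            reads.append(te_single("siRNA", "siRNA", fam))

    # --- piRNA-class reads -------------------------------------------------
    pi_fams = _apportion(class_counts.get("piRNA", 0), weights)
    for fam in sorted(pi_fams):
        n_pi = pi_fams[fam]
        ref = te_seq[fam]
        pp_on = (config.pingpong_families is None
                 or fam in config.pingpong_families)
        frac = config.pingpong_fraction if pp_on else 0.0
        n_pairs = int(round(frac * n_pi / 2.0))
        n_single = n_pi - 2 * n_pairs
        for _ in range(n_pairs):
            len_s = samplers["piRNA"].draw(rng)
            len_a = samplers["piRNA"].draw(rng)
            lo = max(0, len_a - 10)
            hi = len(ref) - max(len_s, 10)
            if hi < lo:  # reference too short for this pair; emit singles
                reads.append(te_single("piRNA", "piRNA", fam))
                reads.append(te_single("piRNA", "piRNA", fam))
                continue
            s = int(rng.integers(lo, hi + 1))
            e = s + 9  # antisense 5' end: exactly 10-nt 5' overlap
            sense_seq = list(ref[s:s + len_s])
            sense_seq[9] = _biased_base(rng, config.a10_bias, sense_seq[9], "A")
            anti_start = e - len_a + 1
            anti_seq = list(revcomp(ref[anti_start:e + 1]))
            anti_seq[0] = _biased_base(rng, config.u1_bias, anti_seq[0], "T")
            sid, aid = next_id(), next_id()
            reads.append(Read(sid, "".join(sense_seq),
                              ReadTruth(fam, "+", s, len_s, "piRNA", aid)))
            reads.append(Read(aid, "".join(anti_seq),
                              ReadTruth(fam, "-", anti_start, len_a, "piRNA",
                                        sid)))
        for _ in range(n_single):
            read = te_single("piRNA", "piRNA", fam)
            if read.truth.strand == "-" and config.u1_bias is not None:
                seq = list(read.sequence)
                seq[0] = _biased_base(rng, config.u1_bias, seq[0], "T")
                read.sequence = "".join(seq)
            reads.append(read)

    # --- adapter read-through, then sequencing errors ---------------------
    for read in reads:
        if config.adapter and rng.random() < config.adapter_fraction:
            budget = config.max_read_length
            if budget is None:
                read.sequence = read.sequence + config.adapter
            elif len(read.sequence) < budget:
                room = budget - len(read.sequence)
                read.sequence = read.sequence + config.adapter[:room]
        read.sequence = _inject_errors(rng, read.sequence, config.error_rate)

    return ReadSet(reads)


# ---------------------------------------------------------------------------
# cross-count simulation
# ---------------------------------------------------------------------------


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_cross_counts(design: CrossDesign) -> pd.DataFrame:
    """Per-cross dysgenic/normal F1 female counts.

    One row per (line x tester subline x direction); the dysgenic count is
    Binomial(n_f1_per_cross, invlogit(line effect + subline offset)) in the
    dysgenic direction and invlogit(reciprocal_logit) in the reciprocal.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for line in sorted(design.lines):
        for sub in sorted(design.tester_sublines):
            for direction in design.directions:
                if direction == "dysgenic":
                    p = _invlogit(design.lines[line]
                                  + design.tester_sublines[sub])
                    maternal, paternal = line, design.tester_line
                else:
                    p = _invlogit(design.reciprocal_logit)
                    maternal, paternal = design.tester_line, line
                n_dys = int(rng.binomial(design.n_f1_per_cross, p))
                rows.append({
                    "maternal_line": maternal,
                    "paternal_line": paternal,
                    "tester_subline": sub,
                    "direction": direction,
                    "temperature": design.temperature,
                    "n_dysgenic": n_dys,
                    "n_normal": design.n_f1_per_cross - n_dys,
                    "line": line,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(design: QpcrDesign) -> pd.DataFrame:
    """Ct table for spliced/total P-element targets plus the reference gene.

    Ct = baseline - (sum of condition effects) + Normal(0, replicate_sd);
    the reference gene is unaffected by condition effects, so condition
    effects propagate one-for-one into delta-Ct.
    """
    rng = np.random.default_rng(design.seed)
    hi_temp = max(design.temperatures)
    effects = {"spliced": design.spliced_effects, "total": design.total_effects}
    rows = []
    for line in design.lines:
        for direction in design.directions:
            for temp in design.temperatures:
                for rep in range(1, design.n_replicates + 1):
                    for target in ("spliced", "total", "reference"):
                        if target == "reference":
                            mu = design.reference_ct
                        else:
                            eff = effects[target]
                            is_dys = direction == "dysgenic"
                            is_hot = temp == hi_temp
                            shift = (eff.direction * is_dys
                                     + eff.temperature * is_hot
                                     + eff.interaction * (is_dys and is_hot)
                                     + eff.line.get(line, 0.0))
                            mu = design.baseline_ct - shift
                        ct = mu + rng.normal(0.0, design.replicate_sd)
                        rows.append({
                            "line": line, "direction": direction,
                            "temperature": temp, "replicate": rep,
                            "target": target, "ct": ct,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-study simulation (references + libraries + metadata)
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """A small multi-line study: per-line libraries with planted signals.

    ``abundance_family`` gets a per-line weight scaled by
    2**(abundance_log2fc * resistance), planting a resistance-correlated
    piRNA abundance; ``pingpong_family`` gets ping-pong-paired piRNA reads.
    """

    line_resistance: Mapping[str, float]  # line -> resistance in [0, 1]
    n_replicates: int = 2
    n_reads: int = 2000
    n_te: int = 5
    n_mirna: int = 8
    te_length: tuple[int, int] = (600, 1200)
    abundance_family: str | None = None
    abundance_log2fc: float = 0.0
    pingpong_family: str | None = None
    pingpong_fraction: float = 0.0
    u1_bias: float | None = None
    a10_bias: float | None = None
    error_rate: float = 0.0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_fraction: float = 0.0
    seed: int = 0


@dataclass
class Study:
    refs: ReferenceSet
    libraries: dict[str, ReadSet]  # library id -> reads
    metadata: pd.DataFrame  # library, line, replicate, resistance
    design: StudyDesign


def simulate_study(design: StudyDesign) -> Study:
    """Generate references plus one library per (line, replicate)."""
    root = np.random.SeedSequence(design.seed)
    ref_seed, lib_root = root.spawn(2)
    refs = generate_references(design.n_te, design.te_length,
                               design.n_mirna, (21, 23),
                               seed=ref_seed.generate_state(1)[0] % (2**31))
    te_names = [e.name for e in refs.te_entries]
    meta_rows = []
    libraries: dict[str, ReadSet] = {}
    lib_seeds = lib_root.spawn(len(design.line_resistance) * design.n_replicates)
    i = 0
    for line in sorted(design.line_resistance):
        resistance = design.line_resistance[line]
        for rep in range(1, design.n_replicates + 1):
            lib_id = f"{line}_rep{rep}"
            base = {n: 1.0 for n in te_names}
            if design.abundance_family is not None:
                base[design.abundance_family] = 2.0 ** (
                    design.abundance_log2fc * resistance)
            total = sum(base.values())
            weights = {n: w / total for n, w in base.items()}
            cfg = LibraryConfig(
                n_reads=design.n_reads,
                family_weights=weights,
                pingpong_fraction=design.pingpong_fraction,
                pingpong_families=(None if design.pingpong_family is None
                                   else frozenset([design.pingpong_family])),
                u1_bias=design.u1_bias,
                a10_bias=design.a10_bias,
                error_rate=design.error_rate,
                adapter=design.adapter,
                adapter_fraction=design.adapter_fraction,
                seed=int(lib_seeds[i].generate_state(1)[0] % (2**31)),
            )
            libraries[lib_id] = simulate_small_rna_library(
                refs, cfg, read_id_prefix=f"{lib_id}:")
            meta_rows.append({"library": lib_id, "line": line,
                              "replicate": rep, "resistance": resistance})
            i += 1
    return Study(refs, libraries, pd.DataFrame(meta_rows), design)


def truth_table(reads: ReadSet) -> pd.DataFrame:
    """Ground-truth sidecar (read_id, family, strand, start, class, partner)."""
    rows = []
    for r in reads:
        t = r.truth
        if t is None:
            continue
        rows.append({"read_id": r.read_id, "family": t.family,
                     "strand": t.strand, "start": t.start,
                     "length": t.length, "read_class": t.read_class,
                     "partner_id": t.pingpong_partner_id or ""})
    return pd.DataFrame(rows)
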