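"""Simulation-based validation experiments.

Each function runs a seeded end-to-end experiment on synthetic data with
known ground truth and returns the measured operating characteristic:
false-positive rates under null generative models, detection rates under
planted signals, and recovery of planted parameters.  They are used by the
test suite and the reproduction script, and are convenient when re-tuning
the pipeline's defaults for other datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crosses import line_effect_glm
from .pingpong import nucleotide_bias, overlap_histogram, pingpong_zscore
from .quantify import CountMatrix, differential_abundance, voom_fit
from .readproc import AlignmentRecord
from .simulate import (CrossDesign, LibraryConfig, ReadSet, StudyDesign,
                       generate_references, simulate_cross_counts,
                       simulate_small_rna_library)


def alignments_from_truth(reads: ReadSet) -> list[AlignmentRecord]:
    """Error-free alignments straight from simulation provenance tags."""
    recs = []
    for r in reads:
        t = r.truth
        if t is None:
            continue
        recs.append(AlignmentRecord(r.read_id, t.family, t.strand, t.start,
                                    t.start + t.length, 0, t.length,
                                    sequence=r.sequence))
    return recs


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# ping-pong operating characteristics
# ---------------------------------------------------------------------------


def pingpong_z_simulation(n_sims: int, n_reads: int,
                          pingpong_fraction: float, seed: int,
                          te_length: tuple[int, int] = (1000, 1000),
                          z_threshold: float = 3.0) -> float:
    """Fraction of simulated single-family libraries with z10 > threshold.

    With ``pingpong_fraction=0`` reads are placed independently and
    uniformly, so this measures the false-positive rate of the z10 > 3
    call; with a positive fraction it measures detection power.
    """
    refs = generate_references(1, te_length, 0, (21, 23), seed=seed)
    hits = 0
    for lib_seed in _child_seeds(seed + 1, n_sims):
        cfg = LibraryConfig(n_reads=n_reads, class_mix={"piRNA": 1.0},
                            pingpong_fraction=pingpong_fraction,
                            error_rate=0.0, seed=lib_seed)
        reads = simulate_small_rna_library(refs, cfg)
        hist = overlap_histogram(alignments_from_truth(reads))
        z = pingpong_zscore(hist)
        if z is not None and z > z_threshold:
            hits += 1
    return hits / n_sims


def u1_bias_recovery(n_reads: int, u1_bias: float, seed: int
                     ) -> tuple[float, int]:
    """(measured antisense 1U fraction, number of antisense reads)."""
    refs = generate_references(1, (1000, 1000), 0, (21, 23), seed=seed)
    cfg = LibraryConfig(n_reads=n_reads, class_mix={"piRNA": 1.0},
                        pingpong_fraction=0.6, u1_bias=u1_bias,
                        error_rate=0.0, seed=seed + 1)
    reads = simulate_small_rna_library(refs, cfg)
    anti = [r.sequence for r in reads if r.truth.strand == "-"]
    u1, _ = nucleotide_bias([], anti)
    return float(u1), len(anti)


# ---------------------------------------------------------------------------
# differential-abundance operating characteristics
# ---------------------------------------------------------------------------


def _nb_count_matrix(rng: np.random.Generator, n_fam: int, n_lib: int,
                     planted_log2fc: float = 0.0,
                     covariate: np.ndarray | None = None,
                     lib_size: int = 100_000,
                     nb_size: float = 10.0) -> CountMatrix:
    """Negative-binomial family counts; family 0 optionally carries a
    covariate-linked fold change."""
    libs = [f"l{i}" for i in range(n_lib)]
    mu = np.exp(rng.normal(3.5, 1.0, size=n_fam))
    counts = np.empty((n_fam, n_lib), dtype=int)
    for g in range(n_fam):
        m = np.full(n_lib, mu[g])
        if g == 0 and planted_log2fc != 0.0 and covariate is not None:
            m = m * 2.0 ** (planted_log2fc * covariate)
        counts[g] = rng.negative_binomial(nb_size, nb_size / (nb_size + m))
    df = pd.DataFrame(counts, index=[f"TE{g}" for g in range(n_fam)],
                      columns=libs)
    sizes = pd.Series(lib_size, index=libs)
    return CountMatrix(df, sizes, pd.DataFrame(index=libs))


def da_null_type1(n_sims: int, seed: int, n_fam: int = 20,
                  n_lib: int = 12, alpha: float = 0.05) -> float:
    """Raw-p rejection rate under a permuted-covariate null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    total = 0
    base_cov = np.linspace(0.0, 1.0, n_lib)
    for _ in range(n_sims):
        cm = _nb_count_matrix(rng, n_fam, n_lib)
        cov = rng.permutation(base_cov)
        logcpm, w = voom_fit(cm, cov)
        res = differential_abundance(logcpm, w, cov).table
        rejections += int((res["p"] < alpha).sum())
        total += n_fam
    return rejections / total


def da_planted_power(n_sims: int, seed: int, log2fc: float = 2.0,
                     n_fam: int = 20, n_lib: int = 12,
                     alpha: float = 0.05) -> float:
    """BH-adjusted detection rate for one family with a planted effect.

    The covariate is a balanced two-group contrast (0/1); the planted
    family's mean shifts by ``log2fc`` log2 units between groups.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([0.0] * (n_lib // 2) + [1.0] * (n_lib - n_lib // 2))
    hits = 0
    for _ in range(n_sims):
        cm = _nb_count_matrix(rng, n_fam, n_lib, planted_log2fc=log2fc,
                              covariate=cov)
        logcpm, w = voom_fit(cm, cov)
        res = differential_abundance(logcpm, w, cov).table
        if res.loc["TE0", "p_adj"] < alpha:
            hits += 1
    return hits / n_sims


# ---------------------------------------------------------------------------
# GLM operating characteristics
# ---------------------------------------------------------------------------


def glm_lrt_type1(n_sims: int, seed: int, n_lines: int = 6,
                  n_per_cross: int = 100, alpha: float = 0.05) -> float:
    """LRT rejection rate when every line shares the same dysgenesis logit."""
    hits = 0
    for s in _child_seeds(seed, n_sims):
        design = CrossDesign(
            lines={f"L{i}": 0.0 for i in range(n_lines)},
            tester_sublines={"T1": 0.0, "T2": 0.3, "T3": -0.3},
            n_f1_per_cross=n_per_cross, directions=("dysgenic",), seed=s)
        res = line_effect_glm(simulate_cross_counts(design))
        if res.p_value < alpha:
            hits += 1
    return hits / n_sims


# ---------------------------------------------------------------------------
# end-to-end truth recovery
# ---------------------------------------------------------------------------


@dataclass
class EndToEndRecovery:
    abundance_rank: int  # 1 = planted family tops the differential report
    pingpong_rank: int  # 1 = planted family tops the mean-z10 ranking
    differential: pd.DataFrame
    pingpong_mean_z: pd.Series


def end_to_end_recovery(seed: int, n_lines: int = 12, n_replicates: int = 2,
                        n_reads: int = 2000) -> EndToEndRecovery:
    """Full-pipeline recovery of two planted signals.

    Simulates a study (``n_lines`` lines x ``n_replicates`` replicates)
    with one TE family whose piRNA abundance tracks line resistance and a
    second family carrying ping-pong-paired reads, processes it through
    trimming, filtering, miRNA subtraction, tier-6 mapping, voom-weighted
    differential abundance, and the ping-pong report, and returns the rank
    of each planted family in its respective report.
    """
    from .pipeline import PipelineConfig, run_pipeline

    resistance = {f"L{i + 1:02d}": v
                  for i, v in enumerate(np.linspace(0.05, 0.95, n_lines))}
    design = StudyDesign(
        line_resistance=resistance, n_replicates=n_replicates,
        n_reads=n_reads, n_te=5, n_mirna=8, te_length=(600, 1200),
        abundance_family="TE1", abundance_log2fc=2.0,
        pingpong_family="TE2", pingpong_fraction=0.4,
        u1_bias=0.85, a10_bias=0.85, error_rate=0.005,
        adapter_fraction=0.5, seed=seed)
    config = PipelineConfig(out_dir="unused", simulate=design, seed=seed,
                            write_outputs=False)
    result = run_pipeline(config)
    da = (result.differential.table
          .assign(abs_t=lambda d: d["t"].abs())
          .sort_values(["p", "abs_t"], ascending=[True, False])
          .drop(columns="abs_t"))
    abundance_rank = int(da.index.get_loc("TE1")) + 1
    pp = result.pingpong
    mean_z = pp.groupby("family")["z10"].mean().sort_values(ascending=False)
    pingpong_rank = int(mean_z.index.get_loc("TE2")) + 1
    return EndToEndRecovery(abundance_rank, pingpong_rank, da, mean_z)
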