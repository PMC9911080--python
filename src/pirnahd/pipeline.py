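"""End-to-end pipeline driver with run manifests.

Stages: (optional) simulate -> adapter trim -> length filter -> miRNA
subtraction -> TE mapping at two mismatch tiers (3 and 6) -> per-family
piRNA quantification (RPM + voom-weighted differential abundance against
resistance) -> ping-pong signature report.  Every run emits a JSON manifest
with per-stage read accounting and output checksums; identical seed and
config reproduce identical checksums.

One global seed fans out to per-stage child seeds through
numpy.random.SeedSequence(seed).spawn, so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantify, seqio
from .pingpong import pingpong_report
from .readproc import MappingPolicy, align_reads, filter_by_length, trim_reads, \
    filter_mirna
from .simulate import ReferenceSet, Study, StudyDesign, simulate_study, \
    truth_table

logger = logging.getLogger("pirnahd")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    out_dir: str = "pirnahd_out"
    # input paths (ignored when a simulated Study is supplied)
    te_fasta: str | None = None
    mirna_fasta: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)  # library -> path
    metadata_csv: str | None = None
    # simulation
    simulate: StudyDesign | None = None
    # stage parameters
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 5
    mismatch_tiers: tuple[int, ...] = (3, 6)
    mirna_max_mismatches: int = 1
    pirna_window: tuple[int, int] = quantify.PIRNA_WINDOW
    o_max: int = 20
    weighting: str = "read-pairs"
    test_covariate: str = "resistance"
    report_tier: int = 6  # tier used for quantification and ping-pong
    seed: int = 0
    write_outputs: bool = True


@dataclass
class PipelineResult:
    manifest: dict
    counts: quantify.CountMatrix | None
    rpm: pd.DataFrame | None
    differential: quantify.DifferentialResult | None
    pingpong: pd.DataFrame | None
    alignments: dict[int, dict[str, list]]  # tier -> library -> records


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    if config.simulate is not None:
        snap["simulate"]["line_resistance"] = dict(
            config.simulate.line_resistance)
    return snap


def run_pipeline(config: PipelineConfig,
                 study: Study | None = None) -> PipelineResult:
    """Execute the full analysis chain and return results plus a manifest."""
    out = Path(config.out_dir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "pirnahd",
        "version": __version__,
        "seed": config.seed,
        "config": _config_snapshot(config),
        "stages": {},
        "checksums": {},
    }
    marker = out / ".partial"
    if config.write_outputs:
        marker.write_text("run in progress\n")

    try:
        # --- stage: inputs / simulation ----------------------------------
        if study is None and config.simulate is not None:
            design = dataclasses.replace(config.simulate, seed=config.seed)
            logger.info("[simulate] generating study (seed=%d)", config.seed)
            study = simulate_study(design)
        if study is not None:
            refs = study.refs
            libraries = dict(study.libraries)
            metadata = study.metadata
            if config.write_outputs:
                seqio.write_fasta(out / "te.fasta", refs.subset("TE"))
                seqio.write_fasta(out / "mirna.fasta", refs.subset("miRNA"))
                for lib, reads in libraries.items():
                    seqio.write_fastq(out / f"{lib}.fastq", reads)
                    seqio.write_table(out / f"{lib}.truth.tsv",
                                      truth_table(reads), sep="\t")
                seqio.write_table(out / "metadata.csv", metadata)
        else:
            if config.te_fasta is None or not config.fastq:
                raise ValueError("need either a simulation design or "
                                 "te_fasta + fastq inputs")
            te = seqio.read_fasta(config.te_fasta, role="TE")
            mirna = (seqio.read_fasta(config.mirna_fasta, role="miRNA")
                     if config.mirna_fasta else ReferenceSet([]))
            refs = ReferenceSet(te.entries + mirna.entries)
            libraries = {lib: seqio.read_fastq(path)
                         for lib, path in config.fastq.items()}
            metadata = (pd.read_csv(config.metadata_csv)
                        if config.metadata_csv else
                        pd.DataFrame({"library": list(libraries)}))

        accounting: dict[str, dict[str, int]] = {}

        def record(stage: str, lib: str, n: int) -> None:
            accounting.setdefault(lib, {})[stage] = n

        # --- stages: trim -> length filter -> miRNA subtract -------------
        processed = {}
        for lib, reads in libraries.items():
            record("input", lib, len(reads))
            trimmed = trim_reads(reads, config.adapter)
            record("trimmed", lib, len(trimmed))
            kept = filter_by_length(trimmed, config.min_len)
            record("length_filtered", lib, len(kept))
            if refs.mirna_entries:
                kept = filter_mirna(kept, refs,
                                    config.mirna_max_mismatches)
            record("mirna_removed", lib, len(kept))
            processed[lib] = kept
        logger.info("[process] %d libraries trimmed and filtered",
                    len(processed))

        # --- stage: TE mapping at both tiers ------------------------------
        alignments: dict[int, dict[str, list]] = {}
        for tier in config.mismatch_tiers:
            policy = MappingPolicy(max_mismatches=tier)
            alignments[tier] = {}
            for lib, reads in processed.items():
                recs = align_reads(reads, refs, policy)
                for r in recs:
                    r.library = lib
                alignments[tier][lib] = recs
                record(f"te_mapped_mm{tier}", lib, len(recs))
            logger.info("[map] tier %d: done", tier)
            if config.write_outputs:
                flat = [r for lib in sorted(alignments[tier])
                        for r in alignments[tier][lib]]
                seqio.write_alignments_tsv(out / f"alignments_mm{tier}.tsv",
                                           flat)
                seqio.write_alignments_sam(out / f"alignments_mm{tier}.sam",
                                           flat, refs.subset("TE"))

        # --- stage: quantification ----------------------------------------
        tier = config.report_tier
        library_sizes = {lib: accounting[lib]["mirna_removed"]
                         for lib in processed}
        counts = quantify.count_by_family(
            alignments[tier], window=config.pirna_window,
            library_sizes=library_sizes, metadata=metadata,
            families=[e.name for e in refs.te_entries])
        rpm = quantify.normalize_rpm(counts)
        differential = None
        if (config.test_covariate in counts.metadata.columns
                and counts.metadata[config.test_covariate].nunique() > 1):
            covariate = counts.metadata.loc[counts.libraries,
                                            config.test_covariate]
            logcpm, weights = quantify.voom_fit(counts, covariate)
            differential = quantify.differential_abundance(
                logcpm, weights, covariate)
        if config.write_outputs:
            counts.counts.to_csv(out / "counts.tsv", sep="\t")
            rpm.to_csv(out / "rpm.tsv", sep="\t")
            if differential is not None:
                differential.table.to_csv(out / "differential.tsv", sep="\t")
        logger.info("[quantify] %d families x %d libraries",
                    len(counts.families), len(counts.libraries))

        # --- stage: ping-pong ---------------------------------------------
        pp = pingpong_report(alignments[tier],
                             length_window=config.pirna_window,
                             o_max=config.o_max, weighting=config.weighting)
        if config.write_outputs:
            pp.to_csv(out / "pingpong.tsv", sep="\t", index=False)
        logger.info("[pingpong] %d (library, family) rows", len(pp))

        # --- manifest ------------------------------------------------------
        manifest["stages"] = accounting
        for lib, acc in accounting.items():
            order = ["input", "trimmed", "length_filtered", "mirna_removed"]
            vals = [acc[s] for s in order if s in acc]
            if any(later > earlier for earlier, later in zip(vals, vals[1:])):
                raise RuntimeError(f"read accounting increased for {lib}")
        if config.write_outputs:
            for path in sorted(out.glob("*")):
                if path.name.startswith("."):
                    continue
                manifest["checksums"][path.name] = _checksum(path)
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True, default=str))
            marker.unlink(missing_ok=True)
        return PipelineResult(manifest, counts, rpm, differential, pp,
                              alignments)
    except Exception:
        logger.error("[pipeline] failed; partial outputs marked in %s", out)
        raise


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
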