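"""End-to-end orchestration: simulate → fragmap → phasemap → call → filter → qc.

``RunConfig`` gathers every stage's tunables (unknown YAML keys are
rejected), ``run_library`` executes the full pipeline for one library in
memory, and ``run_pipeline`` adds the on-disk outputs plus a checksummed
manifest so repeated runs are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import filters as filt
from . import fragmap, io, phasemap, qc, simulate, varcall

__all__ = ["RunConfig", "LibraryResult", "PipelineError", "run_library", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name and code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _from_dict(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise PipelineError("config", "unknown_key", f"{section}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class FragmapConfig:
    bin_size: int = 1000
    min_reads_per_bin: int = 2
    max_gap_bins: int = 4
    min_fragment_length: int = 10_000
    mapping_mode: str = "fast"  # or "strict"

    def streak_params(self) -> fragmap.StreakParams:
        return fragmap.StreakParams(
            min_reads_per_bin=self.min_reads_per_bin,
            max_gap_bins=self.max_gap_bins,
            min_fragment_length=self.min_fragment_length,
            bin_size=self.bin_size,
        )


@dataclass
class PhaseConfig:
    strong_min_reads: int = 3
    strong_min_wells: int = 2
    strong_min_frac: float = 0.2
    max_contradiction_frac: float = 0.25
    min_link_support: int = 2

    def strong_params(self) -> phasemap.StrongHetParams:
        return phasemap.StrongHetParams(
            strong_min_reads=self.strong_min_reads,
            strong_min_wells=self.strong_min_wells,
            strong_min_frac=self.strong_min_frac,
        )

    def phase_params(self) -> phasemap.PhaseParams:
        return phasemap.PhaseParams(
            max_contradiction_frac=self.max_contradiction_frac,
            min_link_support=self.min_link_support,
        )


@dataclass
class QcConfig:
    min_total_snps: int = 1_000_000


@dataclass
class RunConfig:
    simulate: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    fragmap: FragmapConfig = field(default_factory=FragmapConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    call: varcall.CallParams = field(default_factory=varcall.CallParams)
    filters: filt.FilterConfig = field(default_factory=filt.FilterConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "simulate": simulate.SimConfig,
            "fragmap": FragmapConfig,
            "phase": PhaseConfig,
            "call": varcall.CallParams,
            "filters": filt.FilterConfig,
            "qc": QcConfig,
        }
        kwargs = {}
        for key, klass in sections.items():
            if key in data:
                kwargs[key] = _from_dict(klass, data.pop(key) or {}, key)
        for key in ("rng_seed", "log_level"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise PipelineError("config", "unknown_key", f"top level: {sorted(data)}")
        cfg = cls(**kwargs)
        cfg.simulate = dataclasses.replace(cfg.simulate, rng_seed=cfg.rng_seed)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LibraryResult:
    """Everything one library run produces, in memory."""

    genome: simulate.DiploidGenome
    fragments_true: simulate.FragmentSet
    reads: simulate.ReadSet
    placed: fragmap.PlacedReads
    coverage: fragmap.WellCoverageMap
    fragments: list
    secondmap: phasemap.SecondMapResult
    strong_hets: list
    contigs: list
    records: list
    kept: list
    rejected: list
    blocks: dict
    metrics: qc.GenomeMetrics


def run_library(
    genome: simulate.DiploidGenome,
    config: RunConfig,
    library_seed: int | None = None,
) -> LibraryResult:
    """Run the full pipeline for one library of ``genome``.

    ``library_seed`` overrides the simulation seed so several independent
    libraries can be drawn from one genome.
    """
    simcfg = config.simulate
    if library_seed is not None:
        simcfg = simcfg.with_seed(library_seed)

    frags_true = simulate.sample_fragments(genome, simcfg)
    reads = simulate.generate_reads(genome, frags_true, simcfg)

    placed = fragmap.first_map(
        reads,
        reference=genome.ref,
        mode=config.fragmap.mapping_mode,
        gap_min=simcfg.gap_min,
        gap_max=simcfg.gap_max,
    )
    cov = fragmap.build_coverage_map(
        placed,
        bin_size=config.fragmap.bin_size,
        genome_length=len(genome),
        n_wells=simcfg.n_wells,
    )
    fragments = fragmap.call_fragments(cov, config.fragmap.streak_params())

    sm = phasemap.second_map(reads, placed, fragments, genome.ref)
    strong = phasemap.collect_strong_hets(sm, config.phase.strong_params())
    fragments, contigs = phasemap.assign_alleles(
        strong, fragments, sm, config.phase.phase_params()
    )

    records, _ = varcall.call_sites(
        sm,
        contigs,
        varcall.fragment_allele_array(fragments),
        genome.ref,
        params=config.call,
    )
    kept, rejected = filt.apply_filters(records, config.filters)
    blocks = filt.extract_haplotype_blocks(kept, config.filters)
    # phasing rate follows the variant file itself (block-size retention only);
    # the well-count cascade defines the high-confidence subset, not phasing
    blocks_all = filt.extract_haplotype_blocks(records, config.filters)

    frag_stats = fragmap.fragment_length_stats(
        fragments, min_fragment_length=config.fragmap.min_fragment_length
    )
    metrics = qc.GenomeMetrics(
        genome_call_rate=qc.genome_call_rate(sm, len(genome)),
        phasing_rate=qc.phasing_rate(records, blocks_all),
        n50_kb=qc.haplotype_n50(blocks.values()),
        mean_fragment_len_kb=frag_stats.get("mean_length_kb", float("nan")),
        cells_of_dna=qc.cells_of_dna(fragments, len(genome)),
        het_hom_ratio=qc.het_hom_ratio(records),
        ts_tv_ratio=qc.ts_tv_ratio(records),
    )
    return LibraryResult(
        genome=genome,
        fragments_true=frags_true,
        reads=reads,
        placed=placed,
        coverage=cov,
        fragments=fragments,
        secondmap=sm,
        strong_hets=strong,
        contigs=contigs,
        records=records,
        kept=kept,
        rejected=rejected,
        blocks=blocks,
        metrics=metrics,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path, write_reads: bool = True) -> dict:
    """End-to-end run with on-disk outputs and a checksummed manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = simulate.generate_diploid_genome(config.simulate)
    res = run_library(genome, config)

    io.write_fasta(genome.ref, out / "reference.fa")
    io.write_truth_vcf(genome, out / "truth.vcf")
    io.write_truth_fragments_bed(res.fragments_true, out / "truth_fragments.bed")
    if write_reads:
        io.write_reads_tsv(res.reads, out / "reads.tsv")
    io.write_coverage_tsv(res.coverage, out / "coverage_map.tsv")
    io.write_called_fragments_bed(res.fragments, out / "fragments.bed")
    io.write_contigs_tsv(res.contigs, out / "phased_contigs.tsv")
    io.write_var_tsv(res.records, out / "var-LFR-ASM.tsv_with_wellcount_exc.txt")
    io.write_var_tsv(res.kept, out / "var-LFR-ASM.highconfidence.tsv_with_wellcount_exc.txt")
    io.write_variants_vcf(res.records, len(genome), out / "variants.vcf")
    contig_summary = phasemap.phase_breakpoints(res.contigs)
    report = {
        "metrics": res.metrics.to_dict(),
        "contigs": contig_summary,
        "n_records": len(res.records),
        "n_kept": len(res.kept),
        "n_rejected": len(res.rejected),
        "config": config.to_dict(),
    }
    with open(out / "qc_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {"files": {name: _sha256(out / name) for name in files}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report["manifest"] = manifest
    return report
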