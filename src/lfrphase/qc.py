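"""Genome/haplotype quality metrics and replicate switch-discordance QC.

Two independently prepared libraries of the same genome should reconstruct
the same haplotypes.  Comparing the phase of het SNPs in completely
overlapping filtered blocks, a single out-of-phase SNP is a short switch
(one discordant SNP) while a run of two or more consecutively flipped SNPs
is one long switch event.  The short rate divides total discordant single
SNPs, and the long rate total long events, by the total number of phased
SNPs compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .filters import HaplotypeBlock
from .phasemap import n50
from .varcall import LfrVariantRecord

__all__ = [
    "DiscordanceReport",
    "GenomeMetrics",
    "phasing_rate",
    "haplotype_n50",
    "compare_replicates",
    "cells_of_dna",
    "genome_call_rate",
    "ts_tv_ratio",
    "het_hom_ratio",
]

_TALLY_BINS = ("0", "1", "2-3", ">=4")


def _tally_bin(k: int) -> str:
    if k == 0:
        return "0"
    if k == 1:
        return "1"
    if k <= 3:
        return "2-3"
    return ">=4"


@dataclass
class DiscordanceReport:
    """Switch-discordance summary over all compared block pairs."""

    n_compared_blocks: int = 0
    n_phased_snps_compared: int = 0
    n_discordant_snps: int = 0  # isolated flipped SNPs (short switches)
    n_long_switch_events: int = 0  # runs of >= 2 flipped SNPs, one event each
    short_rate: float = 0.0
    long_rate: float = 0.0
    below_threshold: bool = False  # fewer total SNPs than min_total_snps
    per_block_short: dict = field(default_factory=lambda: {b: 0 for b in _TALLY_BINS})
    per_block_long: dict = field(default_factory=lambda: {b: 0 for b in _TALLY_BINS})

    def to_dict(self) -> dict:
        return {
            "n_compared_blocks": self.n_compared_blocks,
            "n_phased_snps_compared": self.n_phased_snps_compared,
            "n_discordant_snps": self.n_discordant_snps,
            "n_long_switch_events": self.n_long_switch_events,
            "short_rate": self.short_rate,
            "long_rate": self.long_rate,
            "below_threshold": self.below_threshold,
            "per_block_short": dict(self.per_block_short),
            "per_block_long": dict(self.per_block_long),
        }


@dataclass
class GenomeMetrics:
    genome_call_rate: float
    phasing_rate: float
    n50_kb: float
    mean_fragment_len_kb: float
    cells_of_dna: float
    het_hom_ratio: float = float("nan")
    ts_tv_ratio: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "genome_call_rate", "phasing_rate", "n50_kb", "mean_fragment_len_kb",
            "cells_of_dna", "het_hom_ratio", "ts_tv_ratio",
        )}


def phasing_rate(
    records: Sequence[LfrVariantRecord],
    blocks: dict[int, HaplotypeBlock] | None = None,
) -> float:
    """Fraction of het SNP calls placed into (retained) haplotype blocks.

    With ``blocks`` given, the numerator counts het records whose
    (contig, position) appears in a retained block; otherwise any non-empty
    hapLink counts.
    """
    hets = [r for r in records if r.is_het]
    if not hets:
        return 0.0
    if blocks is None:
        n_phased = sum(1 for r in hets if r.is_phased)
    else:
        member: set[tuple[int, int]] = set()
        for blk in blocks.values():
            for p in blk.positions:
                member.add((blk.contig_id, int(p)))
        n_phased = sum(
            1
            for r in hets
            if r.contig_id is not None and (r.contig_id, r.position) in member
        )
    return n_phased / len(hets)


def haplotype_n50(blocks: Iterable[HaplotypeBlock]) -> float:
    """N50 of block spans (first-to-last SNP), in kb."""
    return n50([b.span for b in blocks]) / 1000.0


def _pair_blocks(
    blocks_a: dict[int, HaplotypeBlock], blocks_b: dict[int, HaplotypeBlock]
) -> list[tuple[HaplotypeBlock, HaplotypeBlock]]:
    """Every positionally overlapping block pair, ordered by overlap size.

    Blocks within one replicate are disjoint (one per phased contig), so a
    SNP position shared by both replicates belongs to exactly one (a, b)
    pair: comparing all overlapping pairs counts every co-phased SNP once
    and is symmetric in the two replicates.
    """
    cands = []
    for ka, a in blocks_a.items():
        for kb, b in blocks_b.items():
            if a.n_snps == 0 or b.n_snps == 0:
                continue
            ov = min(a.positions[-1], b.positions[-1]) - max(a.positions[0], b.positions[0])
            if ov > 0:
                cands.append((int(ov), ka, kb))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(blocks_a[ka], blocks_b[kb]) for _, ka, kb in cands]


def _mismatch_runs(mismatch: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True."""
    runs = []
    count = 0
    for m in mismatch:
        if m:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def compare_replicates(
    blocks_a: dict[int, HaplotypeBlock],
    blocks_b: dict[int, HaplotypeBlock],
    min_block_snps: int = 10,
    min_total_snps: int = 1_000_000,
) -> DiscordanceReport:
    """Switch discordance between two replicate phasings.

    Blocks are paired one-to-one by positional overlap; each pair is
    compared over het sites present in both with identical ref/alt alleles,
    after choosing the relative label orientation that minimizes mismatches
    (allele labels are arbitrary per contig).  Mismatching sites are
    partitioned into maximal runs: length-1 runs are short switches, longer
    runs one long switch event each (their SNPs enter neither short tally).
    """
    report = DiscordanceReport()
    for a, b in _pair_blocks(blocks_a, blocks_b):
        common, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
        if common.size == 0:
            continue
        same_allele = np.array(
            [a.ref[i] == b.ref[j] and a.alt[i] == b.alt[j] for i, j in zip(ia, ib)]
        )
        ia, ib = ia[same_allele], ib[same_allele]
        n_shared = ia.size
        if n_shared < min_block_snps:
            continue
        mismatch = a.hap[ia] != b.hap[ib]
        if mismatch.sum() * 2 > n_shared:
            mismatch = ~mismatch
        runs = _mismatch_runs(mismatch)
        n_short = sum(1 for r in runs if r == 1)
        n_long = sum(1 for r in runs if r >= 2)
        report.n_compared_blocks += 1
        report.n_phased_snps_compared += int(n_shared)
        report.n_discordant_snps += n_short
        report.n_long_switch_events += n_long
        report.per_block_short[_tally_bin(n_short)] += 1
        report.per_block_long[_tally_bin(n_long)] += 1
    if report.n_phased_snps_compared:
        report.short_rate = report.n_discordant_snps / report.n_phased_snps_compared
        report.long_rate = report.n_long_switch_events / report.n_phased_snps_compared
    report.below_threshold = report.n_phased_snps_compared < min_total_snps
    return report


def cells_of_dna(fragments, genome_length: int) -> float:
    """Diploid genome equivalents of DNA represented by the fragments."""
    if hasattr(fragments, "total_bp"):
        total = int(fragments.total_bp)
    else:
        total = int(sum(f.length for f in fragments))
    return total / (2.0 * genome_length)


def genome_call_rate(result, genome_length: int) -> float:
    """Fraction of reference positions covered by at least one placed arm."""
    k = result.reads.arm_len
    starts = np.concatenate(
        [result.reads.arm1_pos[result.read_rows], result.reads.arm2_pos[result.read_rows]]
    )
    if starts.size == 0:
        return 0.0
    delta = np.zeros(genome_length + 1, dtype=np.int32)
    np.add.at(delta, np.clip(starts, 0, genome_length), 1)
    np.add.at(delta, np.clip(starts + k, 0, genome_length), -1)
    covered = np.cumsum(delta[:-1]) > 0
    return float(covered.mean())


_PURINES = {"A", "G"}


def ts_tv_ratio(records: Sequence[LfrVariantRecord]) -> float:
    ts = tv = 0
    for r in records:
        if (r.ref in _PURINES) == (r.alt in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts / tv if tv else float("nan")


def het_hom_ratio(records: Sequence[LfrVariantRecord]) -> float:
    het = sum(1 for r in records if r.is_het)
    hom = sum(1 for r in records if not r.is_het)
    return het / hom if hom else float("nan")
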