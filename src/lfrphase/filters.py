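"""High-confidence haplotype filtering of LFR variant records.

The cascade keeps a record only if (1) its varFilter is PASS, (2) the
variant call — and for heterozygous SNPs also the reference call — is
supported by at least ``min_well_count`` wells, and (3) for heterozygous
SNPs the shared-well count is at most ``shared_frac`` × (min-exclusive +
shared) wells.  Rule 2 exploits the fact that random polymerase/MDA errors
are unlikely to recur in several independent wells; rule 3 flags mapping
errors, which produce an excess of wells calling both bases.  Rules are
applied in this fixed order so each rejection reason is deterministic.
Surviving het records grouped by phased contig form haplotype blocks;
blocks with fewer than ``min_block_snps`` SNPs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .varcall import LfrVariantRecord

__all__ = ["FilterConfig", "HaplotypeBlock", "apply_filters", "extract_haplotype_blocks"]


@dataclass
class FilterConfig:
    require_pass: bool = True
    min_well_count: int = 6
    shared_frac: float = 0.25
    min_block_snps: int = 10

    def __post_init__(self) -> None:
        if self.min_well_count < 0:
            raise ValueError("min_well_count must be >= 0")
        if not 0.0 <= self.shared_frac <= 1.0:
            raise ValueError("shared_frac must be in [0, 1]")
        if self.min_block_snps < 1:
            raise ValueError("min_block_snps must be >= 1")


_REQUIRED_FIELDS = (
    "var_filter",
    "well_count_var",
    "well_count_ref",
    "shared_well_count",
    "min_exclusive_well_count",
    "genotype",
)


def _first_failure(rec: LfrVariantRecord, cfg: FilterConfig) -> str | None:
    for f in _REQUIRED_FIELDS:
        if getattr(rec, f, None) is None:
            return "malformed"
    if cfg.require_pass and rec.var_filter != "PASS":
        return "varFilter"
    if rec.well_count_var < cfg.min_well_count:
        return "wellCount"
    if rec.is_het and rec.well_count_ref < cfg.min_well_count:
        return "wellCount"
    if rec.is_het:
        bound = cfg.shared_frac * (rec.min_exclusive_well_count + rec.shared_well_count)
        if rec.shared_well_count > bound:
            return "sharedWellCount"
    return None


def apply_filters(
    records: Sequence[LfrVariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[LfrVariantRecord], list[tuple[LfrVariantRecord, str]]]:
    """Split records into (kept, rejected-with-first-failing-rule)."""
    if cfg is None:
        cfg = FilterConfig()
    kept: list[LfrVariantRecord] = []
    rejected: list[tuple[LfrVariantRecord, str]] = []
    for rec in records:
        reason = _first_failure(rec, cfg)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


@dataclass
class HaplotypeBlock:
    """Phased het SNPs of one contig: positions, alleles, haplotype digits."""

    contig_id: int
    positions: np.ndarray
    ref: tuple
    alt: tuple
    hap: np.ndarray  # hapLink final digit: contig haplotype carrying alt

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)

    @property
    def span(self) -> int:
        return int(self.positions[-1] - self.positions[0]) if self.n_snps else 0


def extract_haplotype_blocks(
    records: Sequence[LfrVariantRecord], cfg: FilterConfig | None = None
) -> dict[int, HaplotypeBlock]:
    """Group phased het records by contig; drop blocks below min_block_snps."""
    if cfg is None:
        cfg = FilterConfig()
    by_contig: dict[int, list[LfrVariantRecord]] = {}
    for rec in records:
        if rec.is_het and rec.is_phased and rec.contig_id is not None:
            by_contig.setdefault(rec.contig_id, []).append(rec)
    blocks: dict[int, HaplotypeBlock] = {}
    for cid, recs in by_contig.items():
        if len(recs) < cfg.min_block_snps:
            continue
        recs.sort(key=lambda r: r.position)
        blocks[cid] = HaplotypeBlock(
            contig_id=cid,
            positions=np.array([r.position for r in recs], dtype=np.int64),
            ref=tuple(r.ref for r in recs),
            alt=tuple(r.alt for r in recs),
            hap=np.array([r.phase for r in recs], dtype=np.int8),
        )
    return blocks
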