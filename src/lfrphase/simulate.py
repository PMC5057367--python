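"""Synthetic co-barcoded (LFR-style) library simulator.

A long-fragment-read library disperses ~200 pg of high-molecular-weight DNA
(roughly 30 diploid cells' worth) across a 384-well plate, so that each well
receives a sparse sample of long fragments.  All short mate-pair reads
amplified from one well share that well's barcode, which is what makes
whole-genome phasing possible downstream.

This module generates the full ground truth for that process:

* a diploid genome — a random reference plus two haplotype allele vectors
  over SNP sites;
* long fragments per well with exponentially distributed lengths (decay
  length 20–50 kb is typical of real libraries) and Poisson per-well counts;
* barcoded mate-pair reads sampled uniformly along each fragment, with
  i.i.d. per-base substitution errors and optional well cross-contamination.

Everything is deterministic given ``SimConfig.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .seq import decode_seq

__all__ = [
    "SimConfig",
    "DiploidGenome",
    "TrueFragment",
    "FragmentSet",
    "BarcodedMatePair",
    "ReadSet",
    "GT_HET_HAP0_ALT",
    "GT_HET_HAP1_ALT",
    "GT_HOM_ALT",
    "fragments_per_well_for_cell_equivalents",
    "generate_diploid_genome",
    "sample_fragments",
    "generate_reads",
]

# genotype codes for variant sites
GT_HET_HAP0_ALT = 0  # heterozygous, alternate allele on haplotype 0
GT_HET_HAP1_ALT = 1  # heterozygous, alternate allele on haplotype 1
GT_HOM_ALT = 2  # homozygous alternate


def fragments_per_well_for_cell_equivalents(
    cell_equivalents: float,
    genome_length: int,
    decay_length_kb: float,
    n_wells: int,
) -> float:
    """Mean fragments per well delivering ``cell_equivalents`` of diploid DNA.

    One cell-equivalent is two haploid genome copies; total fragment bp is
    converted to a count via the mean fragment length (the exponential decay
    length).
    """
    total_bp = cell_equivalents * 2.0 * genome_length
    return total_bp / (decay_length_kb * 1000.0) / n_wells


@dataclass
class SimConfig:
    """Parameters of one simulated LFR library.

    The defaults model the library scale of a real 384-well experiment:
    ~0.54 pg of DNA per well (~200 pg per library, about 30 diploid
    cell-equivalents) with a 30 kb fragment-length decay, scaled to whatever
    ``genome_length`` is simulated.
    """

    genome_length: int = 5_000_000
    het_snp_density: float = 1.0 / 1500.0
    hom_snp_density: float = 1.0 / 2250.0  # het/hom ratio ~1.5
    n_wells: int = 384
    decay_length_kb: float = 30.0
    cell_equivalents: float = 30.0
    mean_fragments_per_well: float | None = None  # derived from cells if None
    reads_per_kb_of_fragment: float = 10.0
    arm_len: int = 35
    gap_min: int = 100
    gap_max: int = 500
    per_base_error_rate: float = 0.005
    well_contamination_rate: float = 0.002
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.het_snp_density <= 0.01:
            raise ValueError("het_snp_density must be in [0, 0.01]")
        if not 0.0 <= self.hom_snp_density <= 0.01:
            raise ValueError("hom_snp_density must be in [0, 0.01]")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.decay_length_kb <= 0:
            raise ValueError("decay_length_kb must be positive")
        if self.arm_len < 10:
            raise ValueError("arm_len must be >= 10")
        if self.gap_min > self.gap_max or self.gap_min < 0:
            raise ValueError("need 0 <= gap_min <= gap_max")
        for name in ("per_base_error_rate", "well_contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def fragments_per_well(self) -> float:
        if self.mean_fragments_per_well is not None:
            return self.mean_fragments_per_well
        return fragments_per_well_for_cell_equivalents(
            self.cell_equivalents, self.genome_length, self.decay_length_kb, self.n_wells
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, rng_seed=seed)

    def _rng(self, stream: int) -> np.random.Generator:
        # independent deterministic streams per simulation stage
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(stream,))
        )


class DiploidGenome:
    """Reference sequence plus two haplotype allele vectors at SNP sites."""

    def __init__(
        self,
        ref: np.ndarray,
        positions: np.ndarray,
        alt_bases: np.ndarray,
        genotypes: np.ndarray,
    ) -> None:
        self.ref = np.asarray(ref, dtype=np.uint8)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.alt_bases = np.asarray(alt_bases, dtype=np.uint8)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self._hap_cache: dict[int, np.ndarray] = {}
        self._validate()

    def _validate(self) -> None:
        if self.positions.size:
            if not (np.diff(self.positions) > 0).all():
                raise ValueError("variant positions must be strictly increasing")
            if self.positions[0] < 0 or self.positions[-1] >= self.ref.size:
                raise ValueError("variant position outside reference")
            if (self.ref[self.positions] == self.alt_bases).any():
                raise ValueError("alt allele must differ from reference allele")
        if not np.isin(self.genotypes, [GT_HET_HAP0_ALT, GT_HET_HAP1_ALT, GT_HOM_ALT]).all():
            raise ValueError("invalid genotype code")

    def __len__(self) -> int:
        return int(self.ref.size)

    @property
    def ref_seq(self) -> str:
        return decode_seq(self.ref)

    @property
    def ref_bases(self) -> np.ndarray:
        """Reference base at each variant site."""
        return self.ref[self.positions]

    @property
    def is_het(self) -> np.ndarray:
        return self.genotypes != GT_HOM_ALT

    @property
    def het_positions(self) -> np.ndarray:
        return self.positions[self.is_het]

    def alt_on_haplotype(self, hap: int) -> np.ndarray:
        """Boolean vector: does haplotype ``hap`` carry the alternate allele?"""
        if hap == 0:
            return (self.genotypes == GT_HET_HAP0_ALT) | (self.genotypes == GT_HOM_ALT)
        if hap == 1:
            return (self.genotypes == GT_HET_HAP1_ALT) | (self.genotypes == GT_HOM_ALT)
        raise ValueError("haplotype must be 0 or 1")

    def haplotype(self, hap: int) -> np.ndarray:
        """Allele vector (base codes) of one haplotype over the variant sites."""
        alleles = self.ref_bases.copy()
        on = self.alt_on_haplotype(hap)
        alleles[on] = self.alt_bases[on]
        return alleles

    def haplotype_seq(self, hap: int) -> np.ndarray:
        """Full-length sequence of one haplotype (uint8 codes, cached)."""
        if hap not in self._hap_cache:
            seq = self.ref.copy()
            seq[self.positions] = self.haplotype(hap)
            self._hap_cache[hap] = seq
        return self._hap_cache[hap]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiploidGenome):
            return NotImplemented
        return (
            np.array_equal(self.ref, other.ref)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alt_bases, other.alt_bases)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class TrueFragment:
    """One physical long DNA fragment dispensed into a well (ground truth)."""

    fragment_id: int
    well: int
    haplotype: int
    start: int
    end: int  # half-open

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """Column-oriented collection of :class:`TrueFragment`."""

    def __init__(
        self,
        well: np.ndarray,
        haplotype: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
    ) -> None:
        self.well = np.asarray(well, dtype=np.int32)
        self.haplotype = np.asarray(haplotype, dtype=np.int8)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if not (self.end > self.start).all():
            raise ValueError("fragments must have positive length")

    def __len__(self) -> int:
        return int(self.well.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def __getitem__(self, i: int) -> TrueFragment:
        return TrueFragment(
            fragment_id=int(i),
            well=int(self.well[i]),
            haplotype=int(self.haplotype[i]),
            start=int(self.start[i]),
            end=int(self.end[i]),
        )

    def __iter__(self) -> Iterator[TrueFragment]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_fragments(cls, fragments: Sequence[TrueFragment]) -> "FragmentSet":
        return cls(
            well=np.array([f.well for f in fragments], dtype=np.int32),
            haplotype=np.array([f.haplotype for f in fragments], dtype=np.int8),
            start=np.array([f.start for f in fragments], dtype=np.int64),
            end=np.array([f.end for f in fragments], dtype=np.int64),
        )


@dataclass(frozen=True)
class BarcodedMatePair:
    """One mate-pair read: two short arms plus the well barcode."""

    well: int
    arm1_pos: int
    arm2_pos: int
    arm1_bases: str
    arm2_bases: str
    fragment_id_truth: int

    @property
    def arm_len(self) -> int:
        return len(self.arm1_bases)

    @property
    def mate_gap(self) -> int:
        return self.arm2_pos - (self.arm1_pos + self.arm_len)


class ReadSet:
    """Column-oriented collection of barcoded mate pairs.

    ``arm1_bases``/``arm2_bases`` are ``(n, arm_len)`` uint8 code matrices.
    """

    def __init__(
        self,
        well: np.ndarray,
        arm1_pos: np.ndarray,
        arm2_pos: np.ndarray,
        arm1_bases: np.ndarray,
        arm2_bases: np.ndarray,
        fragment_id_truth: np.ndarray,
    ) -> None:
        self.well = np.asarray(well, dtype=np.int32)
        self.arm1_pos = np.asarray(arm1_pos, dtype=np.int64)
        self.arm2_pos = np.asarray(arm2_pos, dtype=np.int64)
        self.arm1_bases = np.asarray(arm1_bases, dtype=np.uint8)
        self.arm2_bases = np.asarray(arm2_bases, dtype=np.uint8)
        self.fragment_id_truth = np.asarray(fragment_id_truth, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.well.size)

    @property
    def arm_len(self) -> int:
        return int(self.arm1_bases.shape[1])

    @property
    def mate_gap(self) -> np.ndarray:
        return self.arm2_pos - (self.arm1_pos + self.arm_len)

    def __getitem__(self, i: int) -> BarcodedMatePair:
        return BarcodedMatePair(
            well=int(self.well[i]),
            arm1_pos=int(self.arm1_pos[i]),
            arm2_pos=int(self.arm2_pos[i]),
            arm1_bases=decode_seq(self.arm1_bases[i]),
            arm2_bases=decode_seq(self.arm2_bases[i]),
            fragment_id_truth=int(self.fragment_id_truth[i]),
        )

    def __iter__(self) -> Iterator[BarcodedMatePair]:
        for i in range(len(self)):
            yield self[i]


def generate_diploid_genome(config: SimConfig) -> DiploidGenome:
    """Draw a random reference and plant het / hom-alt SNPs on it.

    Each position independently becomes a het SNP with probability
    ``het_snp_density`` (alt allele assigned to haplotype 0 or 1 with equal
    probability) or, otherwise, a hom-alt SNP with probability
    ``hom_snp_density``.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10000")
    rng = config._rng(0)
    L = config.genome_length
    ref = rng.integers(0, 4, size=L, dtype=np.uint8)

    u = rng.random(L)
    het_mask = u < config.het_snp_density
    hom_mask = (~het_mask) & (u < config.het_snp_density + config.hom_snp_density)
    positions = np.flatnonzero(het_mask | hom_mask).astype(np.int64)

    n = positions.size
    alt = (ref[positions] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    genotypes = np.where(het_mask[positions], 0, GT_HOM_ALT).astype(np.int8)
    hap1 = rng.random(n) < 0.5
    genotypes[(genotypes != GT_HOM_ALT) & hap1] = GT_HET_HAP1_ALT
    return DiploidGenome(ref=ref, positions=positions, alt_bases=alt, genotypes=genotypes)


def sample_fragments(genome: DiploidGenome, config: SimConfig) -> FragmentSet:
    """Disperse long fragments into wells.

    Per-well fragment counts are Poisson(``fragments_per_well``); lengths are
    exponential with mean ``decay_length_kb`` kb; starts are uniform; the
    haplotype of origin is a fair coin.  The simulated window is treated as a
    region excised from a longer chromosome: a fragment may begin before the
    window and is clipped at both window edges, so fragment coverage is
    stationary (Poisson) across the whole window rather than ramping up from
    zero at the left edge.
    """
    if not 1.0 <= config.decay_length_kb <= 200.0:
        raise ValueError("decay_length_kb outside sane range [1, 200]")
    rng = config._rng(1)
    L = len(genome)
    counts = rng.poisson(config.fragments_per_well, size=config.n_wells)
    n = int(counts.sum())
    well = np.repeat(np.arange(1, config.n_wells + 1, dtype=np.int32), counts)
    lengths = np.maximum(
        1, np.round(rng.exponential(config.decay_length_kb * 1000.0, size=n)).astype(np.int64)
    )
    raw_start = np.floor(rng.random(n) * (L + lengths) - lengths).astype(np.int64)
    start = np.maximum(raw_start, 0)
    end = np.minimum(raw_start + lengths, L)
    ok = end > start
    well, lengths, start, end = well[ok], lengths[ok], start[ok], end[ok]
    n = int(ok.sum())
    haplotype = rng.integers(0, 2, size=n, dtype=np.int8)
    return FragmentSet(well=well, haplotype=haplotype, start=start, end=end)


def generate_reads(
    genome: DiploidGenome, fragments: FragmentSet, config: SimConfig
) -> ReadSet:
    """Sample barcoded mate pairs from each fragment.

    Pair counts per fragment are Poisson(``reads_per_kb_of_fragment`` ×
    length/1000); the pair layout is ``arm1 | gap | arm2`` with the gap
    uniform in [gap_min, gap_max], placed uniformly inside the fragment.
    Bases are copied from the fragment's haplotype sequence, substitution
    errors are injected i.i.d. at ``per_base_error_rate`` (uniform over the
    three other bases), and a ``well_contamination_rate`` fraction of pairs
    is reassigned to a uniformly random other well.  Fragments too short for
    ``2*arm_len + gap`` yield no reads.
    """
    rng = config._rng(2)
    arm = config.arm_len
    flens = fragments.lengths
    n_pairs = rng.poisson(config.reads_per_kb_of_fragment * flens / 1000.0)
    frag_idx = np.repeat(np.arange(len(fragments)), n_pairs)
    n = frag_idx.size

    gap = rng.integers(config.gap_min, config.gap_max + 1, size=n, dtype=np.int64)
    span = 2 * arm + gap
    max_off = flens[frag_idx] - span
    keep = max_off >= 0
    frag_idx, gap, span, max_off = frag_idx[keep], gap[keep], span[keep], max_off[keep]
    n = frag_idx.size

    offset = np.floor(rng.random(n) * (max_off + 1)).astype(np.int64)
    arm1_pos = fragments.start[frag_idx] + offset
    arm2_pos = arm1_pos + arm + gap

    haps = np.stack([genome.haplotype_seq(0), genome.haplotype_seq(1)])
    hap_of_read = fragments.haplotype[frag_idx].astype(np.intp)
    col = np.arange(arm, dtype=np.int64)
    arm1_bases = haps[hap_of_read[:, None], arm1_pos[:, None] + col]
    arm2_bases = haps[hap_of_read[:, None], arm2_pos[:, None] + col]

    e = config.per_base_error_rate
    if e > 0:
        for bases in (arm1_bases, arm2_bases):
            mask = rng.random(bases.shape) < e
            n_err = int(mask.sum())
            if n_err:
                bases[mask] = (bases[mask] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4

    well = fragments.well[frag_idx].astype(np.int32)
    c = config.well_contamination_rate
    if c > 0 and config.n_wells > 1:
        cmask = rng.random(n) < c
        n_c = int(cmask.sum())
        if n_c:
            shift = rng.integers(1, config.n_wells, size=n_c, dtype=np.int64)
            well = well.copy()
            well[cmask] = ((well[cmask] - 1 + shift) % config.n_wells + 1).astype(np.int32)

    return ReadSet(
        well=well,
        arm1_pos=arm1_pos,
        arm2_pos=arm2_pos,
        arm1_bases=arm1_bases,
        arm2_bases=arm2_bases,
        fragment_id_truth=frag_idx.astype(np.int64),
    )
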