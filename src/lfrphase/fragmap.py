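"""Unphased fragment map: first mapping step, well coverage map, streak calling.

The first mapping step places each mate pair by requiring an exact match of
the entire pair against the reference with a gap in the known mate-gap
range; only uniquely placed pairs are used, and each is assigned the average
of its two arm positions.  Binning placements per well at 1 kb yields the
well coverage map, in which the original long fragments appear as vertical
streaks of consecutive well-populated bins.  A run-length scan over each
well's bin vector, tolerating short interior gaps, recovers fragment
intervals; fragments shorter than 10 kb are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import ReadSet

__all__ = [
    "PlacedReads",
    "WellCoverageMap",
    "CalledFragment",
    "StreakParams",
    "first_map",
    "build_coverage_map",
    "call_fragments",
    "fragment_length_stats",
    "fragment_coverage_histogram",
]

_HASH_MULT = np.uint64(1099511628211)  # FNV-1a prime; 64-bit wraparound rolling hash


@dataclass
class PlacedReads:
    """Uniquely placed mate pairs (indices refer to the source ReadSet)."""

    reads: ReadSet
    idx: np.ndarray  # rows of ``reads`` that were placed
    pos: np.ndarray  # placement position = mean of the two arm positions
    counters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.idx.size)

    @property
    def well(self) -> np.ndarray:
        return self.reads.well[self.idx]


@dataclass
class WellCoverageMap:
    """Per-well histogram of mate-pair placements in fixed-size bins.

    ``counts`` has shape ``(n_wells + 1, n_bins)``; row 0 is reserved for
    reads whose well was not called and is excluded from fragment calling.
    """

    counts: np.ndarray
    bin_size: int
    genome_length: int

    @property
    def n_wells(self) -> int:
        return int(self.counts.shape[0]) - 1

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[1])

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CalledFragment:
    """One streak of well-populated bins: an inferred long-fragment interval.

    ``allele`` is ``None`` until the phasing step assigns the fragment to a
    parental allele (0/1); fragments it cannot place stay unassigned.
    """

    well: int
    start_bin: int
    end_bin: int  # inclusive
    bin_size: int
    support: int
    allele: int | None = None

    @property
    def start_bp(self) -> int:
        return self.start_bin * self.bin_size

    @property
    def end_bp(self) -> int:
        return (self.end_bin + 1) * self.bin_size

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class StreakParams:
    """Streak-detection tuning.

    ``min_reads_per_bin`` is the "well-populated" threshold, ``max_gap_bins``
    the number of consecutive under-threshold bins tolerated inside one
    fragment, and ``min_fragment_length`` the discard threshold (10 kb).
    """

    min_reads_per_bin: int = 2
    max_gap_bins: int = 4
    min_fragment_length: int = 10_000
    bin_size: int = 1000

    def __post_init__(self) -> None:
        if self.bin_size < 100:
            raise ValueError("bin_size must be >= 100")
        if self.min_fragment_length < self.bin_size:
            raise ValueError("min_fragment_length must be >= bin_size")
        if self.min_reads_per_bin < 1 or self.max_gap_bins < 0:
            raise ValueError("invalid streak parameters")


def _rolling_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """64-bit polynomial hash of every length-``k`` window (wraparound)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    x = codes.astype(np.uint64)
    for j in range(k):
        h = h * _HASH_MULT + x[j : j + n]
    return h


def _hash_rows(bases: np.ndarray) -> np.ndarray:
    h = np.zeros(bases.shape[0], dtype=np.uint64)
    for j in range(bases.shape[1]):
        h = h * _HASH_MULT + bases[:, j].astype(np.uint64)
    return h


def first_map(
    reads: ReadSet,
    reference: np.ndarray | None = None,
    mode: str = "fast",
    gap_min: int = 100,
    gap_max: int = 500,
) -> PlacedReads:
    """Place mate pairs on the reference (first mapping step).

    ``strict`` mode enforces the exact-match contract: each arm must occur
    exactly once in the reference as an exact match (so a read overlapping a
    repeat, or carrying any sequencing error or non-reference allele, is
    dropped), and the implied mate gap must fall in ``[gap_min, gap_max]``.
    ``fast`` mode trusts the simulator's true arm positions and places every
    pair; it is the pipeline default since strict mapping at realistic error
    rates discards a large fraction of short-arm pairs.

    The placement position is the average of the two arm positions.
    """
    n = len(reads)
    if mode == "fast":
        pos = (reads.arm1_pos + reads.arm2_pos) // 2
        counters = {"n_input": n, "n_placed": n, "n_nonunique": 0, "n_gap": 0}
        return PlacedReads(reads=reads, idx=np.arange(n), pos=pos, counters=counters)
    if mode != "strict":
        raise ValueError("mode must be 'fast' or 'strict'")
    if reference is None:
        raise ValueError("strict mode requires the reference sequence")

    k = reads.arm_len
    ref_hashes = _rolling_hashes(np.asarray(reference, dtype=np.uint8), k)
    order = np.argsort(ref_hashes, kind="stable")
    sorted_h = ref_hashes[order]

    def locate(bases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (position, unique flag) of each arm's exact occurrence."""
        q = _hash_rows(bases)
        lo = np.searchsorted(sorted_h, q, side="left")
        hi = np.searchsorted(sorted_h, q, side="right")
        unique = (hi - lo) == 1
        pos = np.full(q.size, -1, dtype=np.int64)
        cand = order[np.minimum(lo, sorted_h.size - 1)]
        pos[unique] = cand[unique]
        # guard against hash collisions: verify the single candidate exactly
        if unique.any():
            rows = np.flatnonzero(unique)
            ref_arr = np.asarray(reference, dtype=np.uint8)
            seg = ref_arr[pos[rows, None] + np.arange(k)]
            ok = (seg == bases[rows]).all(axis=1)
            unique[rows[~ok]] = False
        return pos, unique

    p1, u1 = locate(reads.arm1_bases)
    p2, u2 = locate(reads.arm2_bases)
    unique = u1 & u2
    gap = p2 - (p1 + k)
    gap_ok = (gap >= gap_min) & (gap <= gap_max)
    placed = unique & gap_ok
    idx = np.flatnonzero(placed)
    pos = (p1[idx] + p2[idx]) // 2
    counters = {
        "n_input": n,
        "n_placed": int(idx.size),
        "n_nonunique": int((~unique).sum()),
        "n_gap": int((unique & ~gap_ok).sum()),
    }
    return PlacedReads(reads=reads, idx=idx, pos=pos, counters=counters)


def build_coverage_map(
    placed: PlacedReads,
    bin_size: int = 1000,
    genome_length: int | None = None,
    n_wells: int | None = None,
) -> WellCoverageMap:
    """Bin placements per well into the well coverage map."""
    if bin_size < 100:
        raise ValueError("bin_size must be >= 100")
    if genome_length is None:
        genome_length = int(placed.pos.max()) + 1 if len(placed) else bin_size
    if n_wells is None:
        n_wells = int(placed.well.max()) if len(placed) else 1
    n_bins = -(-genome_length // bin_size)
    counts = np.zeros((n_wells + 1, n_bins), dtype=np.int32)
    if len(placed):
        bins = placed.pos // bin_size
        flat = placed.well.astype(np.int64) * n_bins + bins
        bc = np.bincount(flat, minlength=(n_wells + 1) * n_bins)
        counts += bc.reshape(n_wells + 1, n_bins).astype(np.int32)
    return WellCoverageMap(counts=counts, bin_size=bin_size, genome_length=genome_length)


def call_fragments(cov: WellCoverageMap, params: StreakParams | None = None) -> list[CalledFragment]:
    """Detect fragments as streaks of well-populated bins per well.

    Within each well (well 0, the uncalled barcode, is skipped) maximal runs
    of bins with count >= ``min_reads_per_bin`` are found; runs separated by
    at most ``max_gap_bins`` under-threshold bins are merged.  Fragments whose
    bin-quantized extent is shorter than ``min_fragment_length`` are
    discarded.  ``support`` is the total pair count over the full extent.
    """
    if params is None:
        params = StreakParams(bin_size=cov.bin_size)
    if params.bin_size != cov.bin_size:
        raise ValueError("StreakParams.bin_size does not match the coverage map")
    out: list[CalledFragment] = []
    for w in range(1, cov.n_wells + 1):
        row = cov.counts[w]
        populated = np.flatnonzero(row >= params.min_reads_per_bin)
        if populated.size == 0:
            continue
        splits = np.flatnonzero(np.diff(populated) > params.max_gap_bins + 1) + 1
        for run in np.split(populated, splits):
            start_bin, end_bin = int(run[0]), int(run[-1])
            length = (end_bin - start_bin + 1) * cov.bin_size
            if length < params.min_fragment_length:
                continue
            out.append(
                CalledFragment(
                    well=w,
                    start_bin=start_bin,
                    end_bin=end_bin,
                    bin_size=cov.bin_size,
                    support=int(row[start_bin : end_bin + 1].sum()),
                )
            )
    return out


def fragment_length_stats(
    fragments: Sequence[CalledFragment] | np.ndarray,
    min_fragment_length: int = 0,
) -> dict:
    """Decay-length estimate and exponential goodness of fit.

    The left truncation at ``min_fragment_length`` is corrected through the
    memorylessness of the exponential: the mean excess over the truncation
    point is an unbiased estimate of the decay length.  The KS p-value is
    computed against an exponential with the estimated decay (approximate,
    since the parameter is estimated from the same data).
    """
    if isinstance(fragments, np.ndarray):
        lengths = fragments.astype(float)
    else:
        lengths = np.array([f.length for f in fragments], dtype=float)
    if lengths.size == 0:
        return {"n": 0, "decay_estimate_kb": float("nan"), "ks_pvalue_vs_exponential": float("nan")}
    excess = lengths - float(min_fragment_length)
    if (excess < 0).any():
        raise ValueError("fragment shorter than the stated truncation length")
    decay_bp = float(excess.mean())
    if decay_bp > 0:
        ks = stats.kstest(excess, "expon", args=(0.0, decay_bp))
        ks_p = float(ks.pvalue)
    else:
        ks_p = 0.0
    return {
        "n": int(lengths.size),
        "decay_estimate_kb": decay_bp / 1000.0,
        "mean_length_kb": float(lengths.mean()) / 1000.0,
        "ks_pvalue_vs_exponential": ks_p,
    }


def fragment_coverage_histogram(
    fragments,
    genome_length: int,
    probe_points: np.ndarray,
) -> dict:
    """Fragment-depth histogram at probe positions with a Poisson fit.

    The fitted Poisson mean is the analytic ``total fragment bp / genome
    length``; the chi-square statistic compares the observed depth histogram
    with that Poisson (tail cells merged to keep expected counts >= 5).
    """
    probe_points = np.asarray(probe_points, dtype=np.int64)
    if hasattr(fragments, "start"):  # FragmentSet
        starts = np.sort(np.asarray(fragments.start, dtype=np.int64))
        ends = np.sort(np.asarray(fragments.end, dtype=np.int64))
        total_bp = int(fragments.total_bp)
    else:
        starts = np.sort(np.array([f.start_bp for f in fragments], dtype=np.int64))
        ends = np.sort(np.array([f.end_bp for f in fragments], dtype=np.int64))
        total_bp = int((ends - starts).sum()) if starts.size else 0
    depth = np.searchsorted(starts, probe_points, side="right") - np.searchsorted(
        ends, probe_points, side="right"
    )
    lam = total_bp / genome_length if genome_length > 0 else 0.0
    hist = np.bincount(depth.astype(np.int64)) if depth.size else np.zeros(1, dtype=np.int64)

    chi2_p = float("nan")
    if depth.size and lam > 0:
        kmax = hist.size - 1
        ks = np.arange(kmax + 1)
        probs = stats.poisson.pmf(ks, lam)
        probs[-1] += stats.poisson.sf(kmax, lam)
        expected = probs * depth.size
        # merge low-expectation cells from both tails
        obs_list, exp_list = [], []
        acc_o = acc_e = 0.0
        for o, ex in zip(hist, expected):
            acc_o += o
            acc_e += ex
            if acc_e >= 5.0:
                obs_list.append(acc_o)
                exp_list.append(acc_e)
                acc_o = acc_e = 0.0
        if acc_e > 0 and obs_list:
            obs_list[-1] += acc_o
            exp_list[-1] += acc_e
        if len(obs_list) >= 2:
            obs_arr = np.array(obs_list, dtype=float)
            exp_arr = np.array(exp_list, dtype=float) * (obs_arr.sum() / sum(exp_list))
            chi2, chi2_p = stats.chisquare(obs_arr, exp_arr)
            chi2_p = float(chi2_p)
    return {
        "depths": depth,
        "histogram": hist,
        "poisson_mean": lam,
        "chi2_pvalue": chi2_p,
    }
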