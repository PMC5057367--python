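"""First mapping, coverage map, streak calling and distribution diagnostics."""

import dataclasses

import numpy as np
import pytest

from lfrphase.fragmap import (
    StreakParams,
    WellCoverageMap,
    build_coverage_map,
    call_fragments,
    first_map,
    fragment_coverage_histogram,
    fragment_length_stats,
)
from lfrphase.simulate import (
    SimConfig,
    generate_diploid_genome,
    generate_reads,
    sample_fragments,
)

from conftest import make_reads


def brute_force_streaks(row, min_reads, max_gap, min_len_bins):
    """Independent run-length oracle over one well's bin vector."""
    populated = [i for i, v in enumerate(row) if v >= min_reads]
    if not populated:
        return []
    groups = [[populated[0]]]
    for i in populated[1:]:
        if i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [
        (g[0], g[-1]) for g in groups if g[-1] - g[0] + 1 >= min_len_bins
    ]


def cov_from_rows(rows: dict[int, np.ndarray], bin_size=1000) -> WellCoverageMap:
    n_wells = max(rows)
    n_bins = max(r.size for r in rows.values())
    counts = np.zeros((n_wells + 1, n_bins), dtype=np.int32)
    for w, r in rows.items():
        counts[w, : r.size] = r
    return WellCoverageMap(counts=counts, bin_size=bin_size, genome_length=n_bins * bin_size)


class TestFirstMap:
    def test_position_is_mean_of_arm_positions(self):
        ref = np.zeros(5000, dtype=np.uint8)
        reads = make_reads(ref, [(5, 1000, {})], arm_len=20, gap=480)  # arms at 1000 and 1500
        placed = first_map(reads, mode="fast")
        assert placed.pos[0] == 1250
        assert placed.pos[0] // 1000 == 1

    def test_strict_mode_places_unique_and_drops_repeat(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 4, 30_000, dtype=np.uint8)
        ref[20_000:20_100] = ref[1_000:1_100]  # planted repeat
        arm, gap = 35, 165
        specs = [
            (1, 5_000, {}),  # unique
            (1, 1_010, {}),  # arm1 inside the repeat -> two exact hits
            (1, 8_000, {8_005: int(ref[8_005]) ^ 1}),  # sequencing error -> no exact hit
        ]
        reads = make_reads(ref, specs, arm_len=arm, gap=gap)
        bad_gap = make_reads(ref, [(1, 12_000, {})], arm_len=arm, gap=700)
        placed = first_map(reads, reference=ref, mode="strict", gap_min=100, gap_max=500)
        assert placed.pos.tolist() == [(5_000 + 5_000 + arm + gap) // 2]
        assert placed.counters["n_nonunique"] == 2
        placed2 = first_map(bad_gap, reference=ref, mode="strict", gap_min=100, gap_max=500)
        assert len(placed2) == 0 and placed2.counters["n_gap"] == 1

    def test_strict_mode_recovers_errorfree_library(self):
        cfg = SimConfig(
            genome_length=200_000,
            het_snp_density=0.0,
            hom_snp_density=0.0,
            cell_equivalents=3.0,
            per_base_error_rate=0.0,
            well_contamination_rate=0.0,
            rng_seed=21,
        )
        g = generate_diploid_genome(cfg)
        fr = sample_fragments(g, cfg)
        rd = generate_reads(g, fr, cfg)
        placed = first_map(rd, reference=g.ref, mode="strict",
                           gap_min=cfg.gap_min, gap_max=cfg.gap_max)
        assert len(placed) / len(rd) >= 0.99
        truth_pos = (rd.arm1_pos[placed.idx] + rd.arm2_pos[placed.idx]) // 2
        assert np.array_equal(placed.pos, truth_pos)


class TestCoverageMap:
    def test_floor_binning(self):
        ref = np.zeros(5000, dtype=np.uint8)
        arm, gap = 20, 100
        # place arm1 so that the pair midpoint is 500, 999, 1000
        mid_off = (arm + gap) // 2
        specs = [(5, p - mid_off, {}) for p in (500, 999, 1000)]
        placed = first_map(make_reads(ref, specs, arm_len=arm, gap=gap), mode="fast")
        cov = build_coverage_map(placed, bin_size=1000, genome_length=5000, n_wells=6)
        assert cov.counts[5, 0] == 2 and cov.counts[5, 1] == 1

    def test_empty_input_all_zero(self):
        ref = np.zeros(2000, dtype=np.uint8)
        placed = first_map(make_reads(ref, []), mode="fast")
        cov = build_coverage_map(placed, bin_size=1000, genome_length=2000, n_wells=3)
        assert cov.total() == 0

    def test_total_conserved(self, small_noisy_run):
        _, res, cfg = small_noisy_run
        assert res.coverage.total() == len(res.placed)


class TestCallFragments:
    def test_single_clean_streak(self):
        row = np.zeros(200, dtype=np.int32)
        row[10:30] = 5
        frags = call_fragments(cov_from_rows({1: row}))
        assert len(frags) == 1
        f = frags[0]
        assert (f.start_bp, f.end_bp) == (10_000, 30_000)
        assert f.support == 100

    def test_streak_below_10kb_discarded(self):
        row = np.zeros(200, dtype=np.int32)
        row[10:19] = 5  # 9 kb
        assert call_fragments(cov_from_rows({1: row})) == []

    @pytest.mark.parametrize("max_gap,expected", [(2, 1), (1, 2)])
    def test_gap_merging(self, max_gap, expected):
        row = np.zeros(200, dtype=np.int32)
        row[10:21] = 3  # bins 10-20
        row[23:36] = 3  # bins 23-35 (gap of 2 bins: 21, 22)
        params = StreakParams(min_reads_per_bin=2, max_gap_bins=max_gap)
        frags = call_fragments(cov_from_rows({1: row}), params)
        assert len(frags) == expected
        if expected == 1:
            assert (frags[0].start_bin, frags[0].end_bin) == (10, 35)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(33)
        for _ in range(300):
            n = int(rng.integers(1, 201))
            row = rng.integers(0, 5, n).astype(np.int32) * (rng.random(n) < 0.4)
            max_gap = int(rng.integers(0, 5))
            min_len = int(rng.integers(1, 30))
            params = StreakParams(
                min_reads_per_bin=2, max_gap_bins=max_gap, min_fragment_length=min_len * 1000
            )
            got = [
                (f.start_bin, f.end_bin)
                for f in call_fragments(cov_from_rows({1: row.astype(np.int32)}), params)
            ]
            assert got == brute_force_streaks(row, 2, max_gap, min_len)

    def test_never_shorter_than_min_length(self, small_noisy_run):
        _, res, cfg = small_noisy_run
        assert all(f.length >= cfg.fragmap.min_fragment_length for f in res.fragments)

    def test_recovery_of_true_fragments(self):
        # noise-free, >= 10 reads/kb: >= 95 % of true fragments >= 15 kb
        # recovered with <= 2 bins of boundary error at each end
        cfg = SimConfig(
            genome_length=1_000_000,
            cell_equivalents=3.0,
            per_base_error_rate=0.0,
            well_contamination_rate=0.0,
            rng_seed=22,
        )
        g = generate_diploid_genome(cfg)
        fr = sample_fragments(g, cfg)
        rd = generate_reads(g, fr, cfg)
        placed = first_map(rd, mode="fast")
        cov = build_coverage_map(placed, genome_length=len(g), n_wells=cfg.n_wells)
        called = call_fragments(cov)
        by_well: dict[int, list] = {}
        for f in called:
            by_well.setdefault(f.well, []).append(f)
        tol = 2 * 1000
        n_target = n_found = 0
        for i in range(len(fr)):
            if fr.lengths[i] < 15_000:
                continue
            n_target += 1
            for f in by_well.get(int(fr.well[i]), []):
                if abs(f.start_bp - fr.start[i]) <= tol and abs(f.end_bp - fr.end[i]) <= tol:
                    n_found += 1
                    break
        assert n_target > 50
        assert n_found / n_target >= 0.95


class TestDistributions:
    def test_truncated_decay_estimate(self):
        rng = np.random.default_rng(7)
        lengths = rng.exponential(30_000, 40_000)
        lengths = lengths[lengths >= 10_000][:10_000]
        stats_d = fragment_length_stats(lengths, min_fragment_length=10_000)
        assert stats_d["decay_estimate_kb"] == pytest.approx(30.0, rel=0.05)

    def test_degenerate_lengths_rejected_by_ks(self):
        stats_d = fragment_length_stats(np.full(500, 25_000.0))
        assert stats_d["ks_pvalue_vs_exponential"] < 0.01

    def test_zero_fragments_coverage(self):
        from lfrphase.simulate import FragmentSet

        frags = FragmentSet(
            np.empty(0, dtype=np.int32),
            np.empty(0, dtype=np.int8),
            np.empty(0, dtype=np.int64),
            np.empty(1, dtype=np.int64)[:0],
        )
        out = fragment_coverage_histogram(frags, 10_000, np.arange(0, 10_000, 100))
        assert (out["depths"] == 0).all()

    def test_poisson_coverage_fit(self):
        # probes must sit several decay lengths apart to be ~independent,
        # otherwise the chi-square statistic is inflated by autocorrelation
        cfg = SimConfig(genome_length=20_000_000, het_snp_density=0.0001, rng_seed=23)
        g = generate_diploid_genome(cfg)
        fr = sample_fragments(g, cfg)
        probes = np.arange(50_000, len(g), 100_000)
        out = fragment_coverage_histogram(fr, len(g), probes)
        assert out["chi2_pvalue"] >= 0.01
        analytic = fr.total_bp / len(g)
        assert out["poisson_mean"] == pytest.approx(analytic)
        assert abs(out["depths"].mean() - analytic) / analytic < 0.05
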