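"""Second mapping, strong het collection, allele assignment and contigs."""

import numpy as np
import pytest

from lfrphase.phasemap import (
    PhaseParams,
    StrongHetParams,
    StrongHetSite,
    assign_alleles,
    collect_strong_hets,
    minimize_contradictions,
    n50,
    phase_breakpoints,
)

from conftest import controlled_secondmap, truth_hap_of_alt

C, G = 1, 2  # base codes on an all-A reference


def oracle_cost(s, f, b, colors) -> int:
    """Contradictions of a labeling: per-site best-orientation minority count."""
    total = 0
    for site in np.unique(s):
        sel = s == site
        tab = np.zeros((2, 2), dtype=int)
        np.add.at(tab, (b[sel], colors[f[sel]]), 1)
        total += min(tab[0, 1] + tab[1, 0], tab[0, 0] + tab[1, 1])
    return int(total)


class TestSecondMap:
    def test_planted_snp_yields_one_discordance(self, flat_ref):
        frags = [(1, 0, 10_000)]
        reads = [(1, 490, {500: C})]
        sm, _, _ = controlled_secondmap(flat_ref, frags, reads)
        assert len(sm) == 1
        assert sm.disc_pos.tolist() == [500]
        assert sm.disc_base.tolist() == [C]
        assert sm.disc_well.tolist() == [1]

    def test_two_mismatches_in_one_arm_rejected(self, flat_ref):
        frags = [(1, 0, 10_000)]
        reads = [(1, 490, {500: C, 505: G})]
        sm, _, _ = controlled_secondmap(flat_ref, frags, reads)
        assert len(sm) == 0
        assert sm.counters["n_mismatch"] == 1

    def test_read_outside_own_wells_fragments_dropped(self, flat_ref):
        # well 2 has no fragment covering the read position, well 1 does
        frags = [(1, 0, 10_000)]
        reads = [(2, 490, {})]
        sm, _, _ = controlled_secondmap(flat_ref, frags, reads)
        assert len(sm) == 0
        assert sm.counters["n_no_fragment"] == 1


class TestStrongHets:
    def _mk(self, flat_ref, alt_specs, ref_specs, pos=500):
        frag_specs = [(w, 0, 10_000) for w in range(1, 13)]
        reads = [(w, pos - 10, {pos: C}) for w in alt_specs]
        reads += [(w, pos - 10, {}) for w in ref_specs]
        return controlled_secondmap(flat_ref, frag_specs, reads)

    def test_clear_het_is_strong(self, flat_ref):
        # ref: 12 reads over 6 wells; alt: 9 reads over 5 wells
        alt_wells = [1, 1, 2, 2, 3, 3, 4, 4, 5]
        ref_wells = [6, 6, 7, 7, 8, 8, 9, 9, 10, 10, 11, 11]
        sm, _, _ = self._mk(flat_ref, alt_wells, ref_wells)
        sites = collect_strong_hets(sm, StrongHetParams())
        assert len(sites) == 1
        s = sites[0]
        assert s.position == 500
        assert {s.base_a, s.base_b} == {0, C}
        assert {s.support_a, s.support_b} == {12, 9}
        assert set(s.wells_b if s.base_b == C else s.wells_a) == {1, 2, 3, 4, 5}

    def test_single_well_alt_not_strong(self, flat_ref):
        # MDA-like artifact: alt reads concentrated in one well
        sm, _, _ = self._mk(flat_ref, [1, 1, 1], [2, 2, 3, 3, 4, 4, 5, 5])
        assert collect_strong_hets(sm, StrongHetParams()) == []

    def test_hom_alt_not_strong(self, flat_ref):
        sm, _, _ = self._mk(flat_ref, [1, 1, 2, 2, 3, 3, 4, 4], [])
        assert collect_strong_hets(sm, StrongHetParams()) == []

    def test_low_fraction_base_not_strong(self, flat_ref):
        # 3 alt reads in 3 wells but buried under 30 ref reads
        alt = [1, 2, 3]
        ref = [w for w in range(4, 12) for _ in range(4)]
        sm, _, _ = self._mk(flat_ref, alt, ref)
        assert collect_strong_hets(sm, StrongHetParams(strong_min_frac=0.2)) == []


def two_allele_library(flat_ref, n_per_side=2, sites=(1000, 2000, 3000), flip=()):
    """Fragments in wells 1..2n observing opposite bases at each site.

    Wells 1..n carry C, wells n+1..2n carry G; ``flip`` lists (well, site)
    observations to invert.
    """
    wells = list(range(1, 2 * n_per_side + 1))
    frag_specs = [(w, 0, 10_000) for w in wells]
    reads = []
    for w in wells:
        for p in sites:
            base = C if w <= n_per_side else G
            if (w, p) in flip:
                base = G if base == C else C
            reads.append((w, p - 5, {p: base}))
    sm, frags, _ = controlled_secondmap(flat_ref, frag_specs, reads)
    strong = [
        StrongHetSite(position=p, base_a=C, base_b=G, support_a=n_per_side,
                      support_b=n_per_side, wells_a=(), wells_b=())
        for p in sites
    ]
    return sm, frags, strong


class TestAssignAlleles:
    def test_clean_overlap_opposite_alleles_zero_contradictions(self, flat_ref):
        sm, frags, strong = two_allele_library(flat_ref)
        frags, contigs = assign_alleles(strong, frags, sm)
        assert len(contigs) == 1
        assert contigs[0].contradiction_count == 0
        alleles = [f.allele for f in frags]
        assert sorted(alleles) == [0, 0, 1, 1]
        assert alleles[0] == alleles[1] != alleles[2] == alleles[3]

    def test_single_flipped_observation_counted_and_fragment_kept(self, flat_ref):
        sites = (1000, 2000, 3000, 4000, 5000)
        sm, frags, strong = two_allele_library(flat_ref, n_per_side=5, sites=sites,
                                               flip=((1, 3000),))
        frags, contigs = assign_alleles(strong, frags, sm)
        assert sum(c.contradiction_count for c in contigs) == 1
        assert frags[0].allele is not None  # 1 of 5 observations = 0.2 <= 0.25

    def test_unlinked_regions_make_two_contigs(self, flat_ref):
        frag_specs = [(1, 0, 10_000), (2, 0, 10_000), (3, 10_000, 20_000), (4, 10_000, 20_000)]
        reads = [
            (1, 995, {1000: C}), (2, 995, {1000: G}),
            (3, 15_000 - 5, {15_000: C}), (4, 15_000 - 5, {15_000: G}),
        ]
        sm, frags, _ = controlled_secondmap(flat_ref, frag_specs, reads)
        strong = [
            StrongHetSite(1000, C, G, 1, 1, (), ()),
            StrongHetSite(15_000, C, G, 1, 1, (), ()),
        ]
        frags, contigs = assign_alleles(strong, frags, sm)
        assert len(contigs) == 2

    def test_high_contradiction_fragment_unassigned(self, flat_ref):
        sites = (1000, 2000)
        sm, frags, strong = two_allele_library(
            flat_ref, n_per_side=4, sites=sites, flip=((1, 1000),)
        )
        # fragment 1 disagrees at 1 of its 2 sites: fraction 0.5 > 0.25
        frags, _ = assign_alleles(strong, frags, sm, PhaseParams(max_contradiction_frac=0.25))
        assert frags[0].allele is None
        assert all(f.allele is not None for f in frags[1:])

    def test_lowering_tolerance_never_assigns_more(self, flat_ref):
        sites = (1000, 2000, 3000, 4000)
        flips = ((1, 1000), (3, 2000), (6, 3000))
        counts = []
        for frac in (0.5, 0.25, 0.1, 0.0):
            sm, frags, strong = two_allele_library(flat_ref, n_per_side=4, sites=sites, flip=flips)
            frags, _ = assign_alleles(strong, frags, sm, PhaseParams(max_contradiction_frac=frac))
            counts.append(sum(f.allele is not None for f in frags))
        assert counts == sorted(counts, reverse=True)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        s = rng.integers(0, 6, 40)
        f = rng.integers(0, 8, 40)
        b = rng.integers(0, 2, 40)
        _, i = np.unique(s * 100 + f, return_index=True)
        s, f, b = s[i], f[i], b[i]
        colors, cost = minimize_contradictions(s, f, b, 6, 8)
        assert oracle_cost(s, f, b, colors) == cost
        assert oracle_cost(s, f, b, 1 - colors) == cost

    def test_zero_noise_assignments_match_truth(self, small_noisefree_run):
        genome, res, _ = small_noisefree_run
        truth = truth_hap_of_alt(genome)
        # every contig's haplotype-0 base vector matches one true haplotype
        pos_idx = {int(p): i for i, p in enumerate(genome.positions)}
        h0, h1 = genome.haplotype(0), genome.haplotype(1)
        n_sites = 0
        for c in res.contigs:
            sel = [(i, pos_idx[int(p)]) for i, p in enumerate(c.site_positions)
                   if int(p) in pos_idx]
            if not sel:
                continue
            ci, vi = map(np.array, zip(*sel))
            a0 = c.site_allele0_base[ci]
            assert (a0 == h0[vi]).all() or (a0 == h1[vi]).all()
            n_sites += len(ci)
        assert n_sites > 20


class TestContigSummaries:
    def test_n50_bruteforce_examples(self):
        assert n50([100, 200, 300]) == 300
        assert n50([500]) == 500
        assert n50([]) == 0
        # brute-force definition on random inputs
        rng = np.random.default_rng(2)
        for _ in range(50):
            lengths = rng.integers(1, 1000, rng.integers(1, 20)).tolist()
            got = n50(lengths)
            total = sum(lengths)
            covered = sum(x for x in lengths if x >= got)
            assert covered * 2 >= total
            bigger = [x for x in lengths if x > got]
            assert sum(bigger) * 2 < total or not bigger

    def test_phase_breakpoints_empty(self):
        out = phase_breakpoints([])
        assert out == {"count": 0, "n50_bp": 0, "max_bp": 0, "total_bp": 0}
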