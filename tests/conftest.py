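"""Shared fixtures: controlled mini-libraries built from explicit read specs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lfrphase.fragmap import CalledFragment, first_map
from lfrphase.phasemap import second_map
from lfrphase.pipeline import RunConfig, run_library
from lfrphase.simulate import ReadSet, generate_diploid_genome


def make_reads(
    ref: np.ndarray,
    specs: list,
    arm_len: int = 20,
    gap: int = 100,
) -> ReadSet:
    """Build a ReadSet from (well, arm1_pos, substitutions) tuples.

    ``substitutions`` maps absolute genome position -> base code and is
    applied wherever it falls inside either arm.  The second arm is placed
    ``gap`` bp after the first.  A 4th tuple element, if present, is the
    true fragment id.
    """
    n = len(specs)
    well = np.empty(n, dtype=np.int32)
    p1 = np.empty(n, dtype=np.int64)
    p2 = np.empty(n, dtype=np.int64)
    b1 = np.empty((n, arm_len), dtype=np.uint8)
    b2 = np.empty((n, arm_len), dtype=np.uint8)
    fid = np.zeros(n, dtype=np.int64)
    for i, spec in enumerate(specs):
        w, a1, subs = spec[0], spec[1], spec[2]
        if len(spec) > 3:
            fid[i] = spec[3]
        a2 = a1 + arm_len + gap
        well[i], p1[i], p2[i] = w, a1, a2
        arm1 = ref[a1 : a1 + arm_len].copy()
        arm2 = ref[a2 : a2 + arm_len].copy()
        for pos, base in (subs or {}).items():
            if a1 <= pos < a1 + arm_len:
                arm1[pos - a1] = base
            if a2 <= pos < a2 + arm_len:
                arm2[pos - a2] = base
        b1[i], b2[i] = arm1, arm2
    return ReadSet(well, p1, p2, b1, b2, fid)


def make_fragments(frag_specs: list, bin_size: int = 1000) -> list[CalledFragment]:
    """CalledFragments from (well, start_bp, end_bp) with bp on bin boundaries."""
    out = []
    for w, start_bp, end_bp in frag_specs:
        assert start_bp % bin_size == 0 and end_bp % bin_size == 0
        out.append(
            CalledFragment(
                well=w,
                start_bin=start_bp // bin_size,
                end_bin=end_bp // bin_size - 1,
                bin_size=bin_size,
                support=0,
            )
        )
    return out


def controlled_secondmap(ref, frag_specs, read_specs, arm_len=20, gap=100):
    """Run the real first/second mapping over a hand-built mini library."""
    reads = make_reads(ref, read_specs, arm_len=arm_len, gap=gap)
    frags = make_fragments(frag_specs)
    placed = first_map(reads, mode="fast")
    return second_map(reads, placed, frags, ref), frags, reads


@pytest.fixture(scope="session")
def flat_ref():
    """An all-A reference so any substitution is a visible discordance."""
    return np.zeros(20_000, dtype=np.uint8)


@pytest.fixture(scope="session")
def small_noisefree_run():
    """Zero-noise 400 kb library, fully processed."""
    cfg = RunConfig()
    cfg.simulate = dataclasses.replace(
        cfg.simulate,
        genome_length=400_000,
        cell_equivalents=12.0,
        per_base_error_rate=0.0,
        well_contamination_rate=0.0,
        rng_seed=91,
    )
    genome = generate_diploid_genome(cfg.simulate)
    return genome, run_library(genome, cfg), cfg


@pytest.fixture(scope="session")
def small_noisy_run():
    """Default-noise 400 kb library at ~15 cell-equivalents, fully processed."""
    cfg = RunConfig()
    cfg.simulate = dataclasses.replace(
        cfg.simulate, genome_length=400_000, cell_equivalents=15.0, rng_seed=17
    )
    genome = generate_diploid_genome(cfg.simulate)
    return genome, run_library(genome, cfg), cfg


def truth_hap_of_alt(genome) -> dict[int, int]:
    """Map het position -> haplotype (0/1) carrying the alternate allele."""
    out = {}
    on0 = genome.alt_on_haplotype(0)
    for i, p in enumerate(genome.positions):
        if genome.is_het[i]:
            out[int(p)] = 0 if on0[i] else 1
    return out
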