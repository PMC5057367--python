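"""Phased fragment map: second mapping, strong het SNPs, allele assignment.

The second mapping step re-places each well's mate pairs only against the
regions covered by that well's called fragments, tolerating at most one
mismatch per arm, and records every discordance with the reference.
Positions with robust support for exactly two different bases ("strong"
heterozygous SNPs) anchor the phasing: fragments observing the same base at
a strong het belong to the same parental allele, fragments observing
opposite bases to opposite alleles.  Assigning every fragment to an allele
so as to minimize the number of contradicted observations is a max-cut-like
two-coloring problem; we use greedy BFS seeding plus single-fragment flip
refinement, re-optimizing each site's base-to-allele orientation in closed
form.  Regions phased without a break form phased contigs; allele labels are
arbitrary (and independently swappable) per contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fragmap import CalledFragment, PlacedReads
from .simulate import ReadSet

__all__ = [
    "SecondMapResult",
    "StrongHetSite",
    "StrongHetParams",
    "PhaseParams",
    "PhasedContig",
    "second_map",
    "collect_strong_hets",
    "assign_alleles",
    "phase_breakpoints",
    "minimize_contradictions",
    "n50",
    "contig_of_positions",
]


@dataclass
class SecondMapResult:
    """Reads placed inside a fragment of their own well, with discordances.

    Arrays are aligned: row ``i`` describes the i-th kept mate pair.  The
    discordance table lists every tracked mismatch against the reference as
    parallel arrays (position, observed base, well, fragment, read row).
    """

    reads: ReadSet
    read_rows: np.ndarray  # indices into ``reads``
    well: np.ndarray
    frag: np.ndarray  # index into the fragment list given to second_map
    disc_pos: np.ndarray
    disc_base: np.ndarray
    disc_well: np.ndarray
    disc_frag: np.ndarray
    disc_read: np.ndarray
    counters: dict = field(default_factory=dict)
    # sorted arm index for pileup queries
    _arm_start: np.ndarray | None = None
    _arm_read: np.ndarray | None = None
    _arm_which: np.ndarray | None = None
    _frag_of_read_row: dict | None = None

    def __len__(self) -> int:
        return int(self.read_rows.size)

    def _build_arm_index(self) -> None:
        starts = np.concatenate(
            [self.reads.arm1_pos[self.read_rows], self.reads.arm2_pos[self.read_rows]]
        )
        rows = np.concatenate([self.read_rows, self.read_rows])
        which = np.concatenate(
            [np.zeros(len(self), dtype=np.int8), np.ones(len(self), dtype=np.int8)]
        )
        frag2 = np.concatenate([self.frag, self.frag])
        order = np.argsort(starts, kind="stable")
        self._arm_start = starts[order]
        self._arm_read = rows[order]
        self._arm_which = which[order]
        self._arm_frag = frag2[order]

    def pileup(self, positions: np.ndarray) -> dict:
        """All base observations overlapping each query position.

        Returns parallel arrays ``site`` (index into ``positions``), ``pos``,
        ``base``, ``well``, ``frag``, ``read_row``.
        """
        if self._arm_start is None:
            self._build_arm_index()
        positions = np.asarray(positions, dtype=np.int64)
        k = self.reads.arm_len
        lo = np.searchsorted(self._arm_start, positions - k + 1, side="left")
        hi = np.searchsorted(self._arm_start, positions, side="right")
        counts = hi - lo
        site = np.repeat(np.arange(positions.size), counts)
        if site.size == 0:
            empty = np.empty(0, dtype=np.int64)
            return {
                "site": empty, "pos": empty, "base": empty.astype(np.uint8),
                "well": empty, "frag": empty, "read_row": empty,
            }
        arm_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        pos = positions[site]
        start = self._arm_start[arm_idx]
        rows = self._arm_read[arm_idx]
        which = self._arm_which[arm_idx]
        off = pos - start
        base = np.where(
            which == 0,
            self.reads.arm1_bases[rows, off],
            self.reads.arm2_bases[rows, off],
        ).astype(np.uint8)
        return {
            "site": site,
            "pos": pos,
            "base": base,
            "well": self.reads.well[rows].astype(np.int64),
            "frag": self._arm_frag[arm_idx],
            "read_row": rows,
        }

    def candidate_positions(self, min_alt_reads: int = 2) -> np.ndarray:
        """Positions where some single non-reference base is seen >= ``min_alt_reads`` times."""
        if self.disc_pos.size == 0:
            return np.empty(0, dtype=np.int64)
        key = self.disc_pos * 4 + self.disc_base
        uniq, cnt = np.unique(key, return_counts=True)
        return np.unique(uniq[cnt >= min_alt_reads] // 4)


def second_map(
    reads: ReadSet,
    placed: PlacedReads,
    fragments: Sequence[CalledFragment],
    reference: np.ndarray,
    max_mismatch_per_arm: int = 1,
    chunk: int = 500_000,
) -> SecondMapResult:
    """Map each well's pairs to that well's fragment intervals.

    A pair is kept only if its first-map position falls inside a called
    fragment of its own well and each arm has at most
    ``max_mismatch_per_arm`` mismatches against the reference.  Every
    mismatch of a kept pair is recorded in the discordance table.
    """
    reference = np.asarray(reference, dtype=np.uint8)
    L = reference.size
    nfrag = len(fragments)
    if nfrag == 0:
        empty = np.empty(0, dtype=np.int64)
        return SecondMapResult(
            reads=reads, read_rows=empty, well=empty, frag=empty,
            disc_pos=empty, disc_base=empty.astype(np.uint8),
            disc_well=empty, disc_frag=empty, disc_read=empty,
            counters={"n_input": len(placed), "n_no_fragment": len(placed), "n_mismatch": 0},
        )
    fw = np.array([f.well for f in fragments], dtype=np.int64)
    fs = np.array([f.start_bp for f in fragments], dtype=np.int64)
    fe = np.array([f.end_bp for f in fragments], dtype=np.int64)
    order = np.lexsort((fs, fw))
    fw_s, fs_s, fe_s = fw[order], fs[order], fe[order]
    span = np.int64(L + 1)
    keys = fw_s * span + fs_s

    rows = placed.idx
    q = placed.well.astype(np.int64) * span + placed.pos
    j = np.searchsorted(keys, q, side="right") - 1
    jc = np.clip(j, 0, nfrag - 1)
    inside = (j >= 0) & (fw_s[jc] == placed.well) & (placed.pos < fe_s[jc])
    rows_in = rows[inside]
    frag_in = order[jc[inside]]

    k = reads.arm_len
    col = np.arange(k, dtype=np.int64)
    keep_chunks, disc = [], {"pos": [], "base": [], "well": [], "frag": [], "read": []}
    for c0 in range(0, rows_in.size, chunk):
        rr = rows_in[c0 : c0 + chunk]
        ff = frag_in[c0 : c0 + chunk]
        mism = []
        for arm_pos, arm_bases in (
            (reads.arm1_pos, reads.arm1_bases),
            (reads.arm2_pos, reads.arm2_bases),
        ):
            seg = reference[arm_pos[rr][:, None] + col]
            mism.append(seg != arm_bases[rr])
        ok = (mism[0].sum(axis=1) <= max_mismatch_per_arm) & (
            mism[1].sum(axis=1) <= max_mismatch_per_arm
        )
        keep_chunks.append(rr[ok])
        for which, (arm_pos, arm_bases) in enumerate(
            ((reads.arm1_pos, reads.arm1_bases), (reads.arm2_pos, reads.arm2_bases))
        ):
            mrow, moff = np.nonzero(mism[which] & ok[:, None])
            disc["pos"].append(arm_pos[rr[mrow]] + moff)
            disc["base"].append(arm_bases[rr[mrow], moff])
            disc["well"].append(reads.well[rr[mrow]].astype(np.int64))
            disc["frag"].append(ff[mrow])
            disc["read"].append(rr[mrow])

    kept_all = np.concatenate(keep_chunks) if keep_chunks else np.empty(0, dtype=np.int64)
    mask = np.zeros(len(reads), dtype=bool)
    mask[kept_all] = True
    sel = mask[rows_in]
    kept = rows_in[sel]
    kept_frag = frag_in[sel]

    res = SecondMapResult(
        reads=reads,
        read_rows=kept,
        well=reads.well[kept].astype(np.int64),
        frag=kept_frag,
        disc_pos=np.concatenate(disc["pos"]) if disc["pos"] else np.empty(0, dtype=np.int64),
        disc_base=np.concatenate(disc["base"]).astype(np.uint8)
        if disc["base"]
        else np.empty(0, dtype=np.uint8),
        disc_well=np.concatenate(disc["well"]) if disc["well"] else np.empty(0, dtype=np.int64),
        disc_frag=np.concatenate(disc["frag"]) if disc["frag"] else np.empty(0, dtype=np.int64),
        disc_read=np.concatenate(disc["read"]) if disc["read"] else np.empty(0, dtype=np.int64),
        counters={
            "n_input": len(placed),
            "n_no_fragment": int((~inside).sum()),
            "n_mismatch": int(rows_in.size - kept.size),
        },
    )
    frag_of_row = np.full(len(reads), -1, dtype=np.int64)
    frag_of_row[kept] = kept_frag
    res._frag_of_read_row = frag_of_row
    return res


@dataclass(frozen=True)
class StrongHetSite:
    """A position with robust support for exactly two different bases."""

    position: int
    base_a: int
    base_b: int
    support_a: int
    support_b: int
    wells_a: tuple
    wells_b: tuple


@dataclass
class StrongHetParams:
    """Thresholds defining "strong" support for a base at a site.

    Each of the two bases must be seen in >= ``strong_min_reads`` reads from
    >= ``strong_min_wells`` distinct wells and make up >= ``strong_min_frac``
    of the site's reads.  The well threshold suppresses single-well MDA /
    polymerase artifacts; the fraction floor suppresses coincident
    sequencing errors at high depth.
    """

    strong_min_reads: int = 3
    strong_min_wells: int = 2
    strong_min_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.strong_min_reads < 2 or self.strong_min_wells < 2:
            raise ValueError("strong_min_reads and strong_min_wells must be >= 2")
        if not 0.0 <= self.strong_min_frac <= 0.5:
            raise ValueError("strong_min_frac must be in [0, 0.5]")


def collect_strong_hets(
    result: SecondMapResult,
    params: StrongHetParams | None = None,
    candidate_positions: np.ndarray | None = None,
) -> list[StrongHetSite]:
    """Collect strong heterozygous SNP sites from tracked discordances."""
    if params is None:
        params = StrongHetParams()
    if candidate_positions is None:
        candidate_positions = result.candidate_positions(
            min_alt_reads=min(2, params.strong_min_reads)
        )
    if candidate_positions.size == 0:
        return []
    obs = result.pileup(candidate_positions)
    if obs["site"].size == 0:
        return []
    df = pd.DataFrame({"site": obs["site"], "base": obs["base"], "well": obs["well"]})
    per_base = df.groupby(["site", "base"]).agg(
        reads=("well", "size"), wells=("well", "nunique")
    )
    site_tot = df.groupby("site").size()
    out: list[StrongHetSite] = []
    well_sets = (
        df.drop_duplicates(["site", "base", "well"])
        .groupby(["site", "base"])["well"]
        .agg(lambda s: tuple(sorted(s)))
    )
    for site, grp in per_base.groupby(level=0):
        tot = site_tot.loc[site]
        qual = []
        for (s, base), row in grp.iterrows():
            if (
                row["reads"] >= params.strong_min_reads
                and row["wells"] >= params.strong_min_wells
                and row["reads"] >= params.strong_min_frac * tot
            ):
                qual.append((int(base), int(row["reads"])))
        if len(qual) != 2:
            continue
        qual.sort(key=lambda t: (-t[1], t[0]))
        (ba, sa), (bb, sb) = qual
        out.append(
            StrongHetSite(
                position=int(candidate_positions[site]),
                base_a=ba,
                base_b=bb,
                support_a=sa,
                support_b=sb,
                wells_a=well_sets.loc[(site, ba)],
                wells_b=well_sets.loc[(site, bb)],
            )
        )
    out.sort(key=lambda s: s.position)
    return out


@dataclass
class PhaseParams:
    """Allele-assignment tuning.

    A fragment whose fraction of contradicted observations exceeds
    ``max_contradiction_frac`` is left unassigned.  Consecutive strong hets
    co-observed by fewer than ``min_link_support`` assigned fragments start a
    new phased contig.
    """

    max_contradiction_frac: float = 0.25
    min_link_support: int = 2
    max_refine_passes: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_contradiction_frac <= 1.0:
            raise ValueError("max_contradiction_frac must be in [0, 1]")
        if self.min_link_support < 1:
            raise ValueError("min_link_support must be >= 1")


@dataclass
class PhasedContig:
    """A region phased without a break; allele labels are contig-local."""

    contig_id: int
    start: int
    end: int
    site_positions: np.ndarray
    site_allele0_base: np.ndarray
    site_allele1_base: np.ndarray
    fragment_alleles: dict
    contradiction_count: int

    @property
    def n_sites(self) -> int:
        return int(self.site_positions.size)

    @property
    def length(self) -> int:
        return int(self.end - self.start)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _fragment_site_observations(
    result: SecondMapResult, strong_hets: Sequence[StrongHetSite]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Majority base (as 0/1 index into the site's base pair) per fragment per site."""
    positions = np.array([s.position for s in strong_hets], dtype=np.int64)
    obs = result.pileup(positions)
    if obs["site"].size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e
    base_a = np.array([s.base_a for s in strong_hets], dtype=np.uint8)
    base_b = np.array([s.base_b for s in strong_hets], dtype=np.uint8)
    is_a = obs["base"] == base_a[obs["site"]]
    is_b = obs["base"] == base_b[obs["site"]]
    sel = is_a | is_b
    s, f = obs["site"][sel], obs["frag"][sel]
    b = np.where(is_b[sel], 1, 0).astype(np.int64)
    df = pd.DataFrame({"s": s, "f": f, "b": b})
    g = df.groupby(["s", "f"])["b"].agg(["sum", "size"]).reset_index()
    maj_b = np.where(g["sum"] * 2 > g["size"], 1, np.where(g["sum"] * 2 < g["size"], 0, -1))
    keep = maj_b >= 0
    return (
        g["s"].to_numpy()[keep],
        g["f"].to_numpy()[keep],
        maj_b[keep].astype(np.int64),
    )


class _ColoringProblem:
    """Observation-level contradiction minimization for one instance.

    Greedy seeding colors fragments in genomic order (a single left-to-right
    growth front), then two local moves are iterated to convergence: single
    fragment flips, and suffix flips (invert every fragment from a genomic
    cut point rightwards).  The suffix move is what repairs long-switch
    errors — an internally inverted segment is a deep local minimum for
    single flips, since only the sites straddling the segment boundary
    change cost when the whole segment is flipped.
    """

    def __init__(
        self,
        s: np.ndarray,
        f: np.ndarray,
        b: np.ndarray,
        n_sites: int,
        n_frags: int,
        frag_pos: np.ndarray | None = None,
    ):
        self.s, self.f, self.b = s, f, b
        self.n_sites, self.n_frags = n_sites, n_frags
        self.frag_pos = (
            np.arange(n_frags, dtype=np.int64) if frag_pos is None else frag_pos
        )
        order = np.argsort(f, kind="stable")
        self.frag_obs_s = s[order]
        self.frag_obs_b = b[order]
        self.frag_ptr = np.searchsorted(f[order], np.arange(n_frags + 1))
        # site -> fragments (for component detection)
        order_s = np.argsort(s, kind="stable")
        self.site_obs_f = f[order_s]
        self.site_ptr = np.searchsorted(s[order_s], np.arange(n_sites + 1))

    def obs_of(self, frag: int) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.frag_ptr[frag], self.frag_ptr[frag + 1]
        return self.frag_obs_s[a:b], self.frag_obs_b[a:b]

    def has_obs(self, frag: int) -> bool:
        return self.frag_ptr[frag + 1] > self.frag_ptr[frag]

    @staticmethod
    def _site_cost(n: np.ndarray) -> np.ndarray:
        # n: (n_sites, 2 bases, 2 colors); orientation 0 maps base k -> allele k
        cost0 = n[:, 0, 1] + n[:, 1, 0]
        cost1 = n[:, 0, 0] + n[:, 1, 1]
        return np.minimum(cost0, cost1)

    def total_cost(self, colors: np.ndarray) -> int:
        n = np.zeros((self.n_sites, 2, 2), dtype=np.int64)
        ok = colors[self.f] >= 0
        np.add.at(n, (self.s[ok], self.b[ok], colors[self.f[ok]].astype(np.int64)), 1)
        return int(self._site_cost(n).sum())

    def solve(self, max_passes: int, restarts: int | None = None) -> tuple[np.ndarray, int]:
        members = [i for i in range(self.n_frags) if self.has_obs(i)]
        members.sort(key=lambda i: (self.frag_pos[i], i))
        if restarts is None:
            restarts = 8 if len(members) <= 64 else 1
        best_colors, best_cost = None, None
        rng = np.random.default_rng(len(members))  # deterministic restart orders
        for r in range(max(1, restarts)):
            order = list(members) if r == 0 else [members[i] for i in rng.permutation(len(members))]
            colors, cost = self._solve_once(order, members, max_passes)
            if best_cost is None or cost < best_cost:
                best_colors, best_cost = colors, cost
            if best_cost == 0:
                break
        return best_colors, best_cost

    def _solve_once(
        self, seed_order: list[int], members: list[int], max_passes: int
    ) -> tuple[np.ndarray, int]:
        n = np.zeros((self.n_sites, 2, 2), dtype=np.int64)
        colors = np.full(self.n_frags, -1, dtype=np.int8)

        def add(frag: int, color: int, sign: int) -> None:
            ss, bb = self.obs_of(frag)
            np.add.at(n, (ss, bb, color), sign)

        def delta_for(frag: int, color: int) -> int:
            ss, bb = self.obs_of(frag)
            d = 0
            for s_i, b_i in zip(ss, bb):
                m = n[s_i]
                before = min(m[0, 1] + m[1, 0], m[0, 0] + m[1, 1])
                m2 = m.copy()
                m2[b_i, color] += 1
                after = min(m2[0, 1] + m2[1, 0], m2[0, 0] + m2[1, 1])
                d += after - before
            return d

        # greedy seeding (genomic order on the first start)
        for frag in seed_order:
            d0, d1 = delta_for(frag, 0), delta_for(frag, 1)
            c = 0 if d0 <= d1 else 1
            colors[frag] = c
            add(frag, c, +1)

        def single_flip_pass() -> bool:
            improved = False
            for frag in members:
                c = colors[frag]
                add(frag, c, -1)
                d_stay = delta_for(frag, c)
                d_flip = delta_for(frag, 1 - c)
                if d_flip < d_stay:
                    colors[frag] = 1 - c
                    add(frag, 1 - c, +1)
                    improved = True
                else:
                    add(frag, c, +1)
            return improved

        def best_suffix_flip() -> tuple[int, int]:
            """(delta, cut index into members) for the best suffix flip."""
            # nR: tallies of the flipped (right) set, colors inverted
            nL = n.copy()
            nR = np.zeros_like(n)
            cost_now = self._site_cost(n)
            best_delta, best_cut = 0, -1
            delta = 0
            touched_cost = {}
            for cut in range(len(members) - 1, 0, -1):
                frag = members[cut]
                ss, bb = self.obs_of(frag)
                c = int(colors[frag])
                for s_i, b_i in zip(ss, bb):
                    nL[s_i, b_i, c] -= 1
                    nR[s_i, b_i, 1 - c] += 1
                    m = nL[s_i] + nR[s_i]
                    after = min(m[0, 1] + m[1, 0], m[0, 0] + m[1, 1])
                    prev = touched_cost.get(s_i, int(cost_now[s_i]))
                    delta += after - prev
                    touched_cost[s_i] = after
                if delta < best_delta:
                    best_delta, best_cut = delta, cut
            return best_delta, best_cut

        def pair_flip_pass() -> bool:
            # joint flips of fragment pairs escape two-fragment local minima;
            # only affordable for modest component sizes
            if len(members) > 64:
                return False
            improved = False
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    fa, fb = members[ai], members[bi]
                    ca, cb = colors[fa], colors[fb]
                    add(fa, ca, -1)
                    add(fb, cb, -1)
                    d_stay = delta_for(fa, ca) + _delta_with(fa, ca, fb, cb)
                    d_flip = delta_for(fa, 1 - ca) + _delta_with(fa, 1 - ca, fb, 1 - cb)
                    if d_flip < d_stay:
                        colors[fa], colors[fb] = 1 - ca, 1 - cb
                        add(fa, 1 - ca, +1)
                        add(fb, 1 - cb, +1)
                        improved = True
                    else:
                        add(fa, ca, +1)
                        add(fb, cb, +1)
            return improved

        def _delta_with(fa: int, ca: int, fb: int, cb: int) -> int:
            # delta of adding fb as cb given fa already re-added as ca
            add(fa, ca, +1)
            d = delta_for(fb, cb)
            add(fa, ca, -1)
            return d

        for _ in range(max_passes):
            improved = single_flip_pass()
            d, cut = best_suffix_flip()
            if d < 0:
                for frag in members[cut:]:
                    c = colors[frag]
                    add(frag, c, -1)
                    colors[frag] = 1 - c
                    add(frag, 1 - c, +1)
                improved = True
            if not improved and not pair_flip_pass():
                break
        total = int(self._site_cost(n).sum())
        return colors, total


def minimize_contradictions(
    s: np.ndarray,
    f: np.ndarray,
    b: np.ndarray,
    n_sites: int,
    n_frags: int,
    frag_pos: np.ndarray | None = None,
    max_passes: int = 50,
    restarts: int | None = None,
) -> tuple[np.ndarray, int]:
    """Two-color fragments to minimize contradicted observations.

    ``s``/``f``/``b`` are parallel arrays: fragment ``f[i]`` observed base
    index ``b[i]`` (0 or 1, indexing the site's two strong bases) at strong
    het ``s[i]``.  Returns (colors, total contradictions), where the
    contradiction count of a labeling is the sum over sites of the smaller
    side of the 2x2 base-by-color table under the better of the two
    base-to-allele orientations.  Greedy seeding in ``frag_pos`` order plus
    single-fragment, suffix and pair flips; exact on small instances,
    heuristic in general (the underlying problem is max-cut-like).
    """
    prob = _ColoringProblem(s, f, b, n_sites, n_frags, frag_pos=frag_pos)
    return prob.solve(max_passes, restarts=restarts)


def assign_alleles(
    strong_hets: Sequence[StrongHetSite],
    fragments: Sequence[CalledFragment],
    result: SecondMapResult,
    params: PhaseParams | None = None,
) -> tuple[list[CalledFragment], list[PhasedContig]]:
    """Two-color fragments into alleles, minimizing contradicted observations.

    Mutates ``fragments`` in place (sets ``allele``) and returns the phased
    fragment list together with the phased contigs.  Allele labels 0/1 are
    consistent within each contig and arbitrary across contigs.
    """
    if params is None:
        params = PhaseParams()
    fragments = list(fragments)
    for f in fragments:
        f.allele = None
    if not strong_hets:
        return fragments, []

    s, f, b = _fragment_site_observations(result, strong_hets)
    n_sites, n_frags = len(strong_hets), len(fragments)
    if s.size == 0:
        return fragments, []

    prob = _ColoringProblem(s, f, b, n_sites, n_frags)

    uf = _UnionFind(n_frags)
    for si in range(n_sites):
        a, bnd = prob.site_ptr[si], prob.site_ptr[si + 1]
        frs = prob.site_obs_f[a:bnd]
        for j in range(1, frs.size):
            uf.union(int(frs[0]), int(frs[j]))
    comp_of = np.array(
        [uf.find(i) if prob.frag_ptr[i + 1] > prob.frag_ptr[i] else -1 for i in range(n_frags)]
    )

    frag_pos = np.array(
        [getattr(frag, "start_bp", i) for i, frag in enumerate(fragments)], dtype=np.int64
    )
    colors = np.full(n_frags, -1, dtype=np.int8)
    for comp in np.unique(comp_of[comp_of >= 0]):
        members = np.flatnonzero(comp_of == comp)
        sel = np.isin(f, members)
        comp_colors, comp_cost = minimize_contradictions(
            s[sel], f[sel], b[sel], n_sites, n_frags,
            frag_pos=frag_pos, max_passes=params.max_refine_passes,
        )
        colors[members] = comp_colors[members]
        # degenerate component: no coloring beats chance
        n_obs_comp = int(sel.sum())
        if comp_cost * 2 >= n_obs_comp and n_obs_comp > 0:
            colors[members] = -1

    # final per-site tallies and orientations over colored fragments
    colored = colors[f] >= 0
    n_tab = np.zeros((n_sites, 2, 2), dtype=np.int64)
    np.add.at(n_tab, (s[colored], b[colored], colors[f[colored]].astype(np.int64)), 1)
    cost0 = n_tab[:, 0, 1] + n_tab[:, 1, 0]
    cost1 = n_tab[:, 0, 0] + n_tab[:, 1, 1]
    orient = (cost1 < cost0).astype(np.int64)  # 0: base_a->allele0

    # per-fragment contradiction fractions under the final orientations
    expected_color = np.where(orient[s] == 0, b, 1 - b)
    contrad = colored & (colors[f] != expected_color)
    n_obs_f = np.bincount(f, weights=colored.astype(float), minlength=n_frags)
    n_bad_f = np.bincount(f, weights=contrad.astype(float), minlength=n_frags)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_obs_f > 0, n_bad_f / np.maximum(n_obs_f, 1), 0.0)
    colors[(frac > params.max_contradiction_frac)] = -1

    # rebuild tallies over assigned fragments only
    assigned = colors[f] >= 0
    n_tab = np.zeros((n_sites, 2, 2), dtype=np.int64)
    np.add.at(n_tab, (s[assigned], b[assigned], colors[f[assigned]].astype(np.int64)), 1)
    cost0 = n_tab[:, 0, 1] + n_tab[:, 1, 0]
    cost1 = n_tab[:, 0, 0] + n_tab[:, 1, 1]
    orient = (cost1 < cost0).astype(np.int64)
    site_cost = np.minimum(cost0, cost1)
    site_has_support = n_tab.sum(axis=(1, 2)) > 0

    for i, frag in enumerate(fragments):
        frag.allele = int(colors[i]) if colors[i] >= 0 else None

    # contig construction: break wherever the relative orientation of two
    # consecutive strong hets is not reliably supported.  A fragment
    # observing bases (b1, b2) at the two sites votes for relative
    # orientation b1 XOR b2 irrespective of its own color; the junction is
    # kept only if votes agreeing with the solved orientation outnumber
    # disagreeing votes by at least min_link_support.  Ambiguous junctions
    # (typically chimeric merged fragments in sparse-het regions) thus end a
    # phased contig instead of risking a long switch across it.
    positions = np.array([sh.position for sh in strong_hets], dtype=np.int64)
    site_order = np.argsort(positions, kind="stable")
    live = [int(i) for i in site_order if site_has_support[i]]
    site_rank = {si: r for r, si in enumerate(live)}

    # per-fragment observations over live sites (all fragments vote on links)
    frag_votes: dict[int, list[tuple[int, int]]] = {}
    for si, fi, bi in zip(s, f, b):
        r = site_rank.get(int(si))
        if r is not None:
            frag_votes.setdefault(int(fi), []).append((r, int(bi)))
    net_link: dict[tuple[int, int], int] = {}
    live_arr = np.array(live, dtype=np.int64)
    for fi, votes in frag_votes.items():
        votes.sort()
        for (r1, b1), (r2, b2) in zip(votes, votes[1:]):
            if r2 == r1 + 1:
                rel = int(orient[live_arr[r1]] ^ orient[live_arr[r2]])
                agree = 1 if (b1 ^ b2) == rel else -1
                key = (r1, r2)
                net_link[key] = net_link.get(key, 0) + agree

    # assigned fragments' member sites (for the per-contig assignment table)
    frag_sites: dict[int, list[int]] = {}
    for si, fi in zip(s[assigned], f[assigned]):
        frag_sites.setdefault(int(fi), []).append(int(si))

    contigs: list[PhasedContig] = []
    if live:
        groups: list[list[int]] = [[live[0]]]
        for r in range(1, len(live)):
            if net_link.get((r - 1, r), 0) >= params.min_link_support:
                groups[-1].append(live[r])
            else:
                groups.append([live[r]])
        base_a = np.array([sh.base_a for sh in strong_hets], dtype=np.uint8)
        base_b = np.array([sh.base_b for sh in strong_hets], dtype=np.uint8)
        for cid, grp in enumerate(groups):
            g = np.array(grp, dtype=np.int64)
            a0 = np.where(orient[g] == 0, base_a[g], base_b[g]).astype(np.uint8)
            a1 = np.where(orient[g] == 0, base_b[g], base_a[g]).astype(np.uint8)
            member = set(grp)
            frag_alleles = {
                fi: int(colors[fi])
                for fi, sites_of_f in frag_sites.items()
                if member & set(sites_of_f)
            }
            contigs.append(
                PhasedContig(
                    contig_id=cid,
                    start=int(positions[g[0]]),
                    end=int(positions[g[-1]]) + 1,
                    site_positions=positions[g],
                    site_allele0_base=a0,
                    site_allele1_base=a1,
                    fragment_alleles=frag_alleles,
                    contradiction_count=int(site_cost[g].sum()),
                )
            )
    return fragments, contigs


def n50(lengths: Sequence[int]) -> int:
    """Length L such that pieces >= L cover at least half the total."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def phase_breakpoints(contigs: Sequence[PhasedContig]) -> dict:
    """Contig-length summary: count, N50, maximum, total (bp)."""
    lengths = [c.length for c in contigs]
    return {
        "count": len(lengths),
        "n50_bp": n50(lengths),
        "max_bp": max(lengths) if lengths else 0,
        "total_bp": int(sum(lengths)),
    }


def contig_of_positions(
    contigs: Sequence[PhasedContig], positions: np.ndarray
) -> np.ndarray:
    """Index of the contig whose span contains each position (-1 if none)."""
    positions = np.asarray(positions, dtype=np.int64)
    out = np.full(positions.size, -1, dtype=np.int64)
    if not contigs:
        return out
    starts = np.array([c.start for c in contigs], dtype=np.int64)
    ends = np.array([c.end for c in contigs], dtype=np.int64)
    j = np.searchsorted(starts, positions, side="right") - 1
    jc = np.clip(j, 0, len(contigs) - 1)
    ok = (j >= 0) & (positions < ends[jc])
    out[ok] = jc[ok]
    return out
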