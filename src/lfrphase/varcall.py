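"""Phasing-aware diallelic variant calling with well-count annotations.

Each candidate site is scored over the 16 ordered allele hypotheses
H = (A0, A1).  For a mate pair not assigned to an allele the hypothesis
probability uses the equal-prior mixture

    P(H | mate-pair) ∝ (P(mate-pair | A0) + P(mate-pair | A1)) / 2

while a pair whose fragment was phased to allele 0 uses

    P(H | mate-pair) ∝ (1 − μ) P(mate-pair | A0) + μ P(mate-pair | A1)

(and symmetrically for allele 1), where μ is small (default 0.01) and
reflects the residual uncertainty of the fragment phasing.  At μ = 0.5 the
phased form reduces exactly to the unphased one.  Because the phased form is
not invariant under swapping A0 and A1, hypothesis evaluation takes phasing
into account automatically and calls are intrinsically phased within each
phased contig.

Every call carries the per-well evidence fields (wellCount, wellIDs,
exclusive / shared well counts and their locus min/max) used downstream to
reject single-well amplification artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phasemap import PhasedContig, SecondMapResult, contig_of_positions
from .seq import BASES

__all__ = [
    "MuParam",
    "CallParams",
    "LfrVariantRecord",
    "pair_likelihood",
    "hypothesis_prob_unphased",
    "hypothesis_prob_phased",
    "compute_well_fields",
    "call_site",
    "call_sites",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class MuParam:
    """Fragment-phasing uncertainty μ; 0.5 disables phasing information."""

    mu: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError("mu must be in [0, 0.5]")


@dataclass
class CallParams:
    """Variant-calling tuning: error model, priors, no-call margin."""

    mu: float = 0.01
    error_rate: float = 0.005
    het_prior: float = 1e-3
    hom_alt_prior: float = 5e-4
    nonref_het_factor: float = 1e-3  # extra penalty for het pairs without the reference base
    min_margin_db: float = 10.0  # no-call below this log-odds margin (decibels)
    library_id: int = 1

    def __post_init__(self) -> None:
        MuParam(self.mu)
        if not 0.0 < self.error_rate < 0.75:
            raise ValueError("error_rate must be in (0, 0.75)")


@dataclass
class LfrVariantRecord:
    """One called variant with phasing and per-well evidence fields.

    ``position`` is 0-based internally (1-based only in exported files).
    ``phase`` is the contig haplotype (0/1) carrying the alternate allele for
    phased het calls; ``hap_link`` is the matching "Phased_#_#_#" label.
    """

    position: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    gt_string: str
    var_filter: str
    hap_link: str
    well_count_var: int
    well_count_ref: int
    well_ids: tuple
    exclusive_well_count_var: int
    exclusive_well_count_ref: int
    shared_well_count: int
    min_exclusive_well_count: int
    max_exclusive_well_count: int
    phase: int | None = None
    contig_id: int | None = None
    qual_db: float = 0.0

    @property
    def is_het(self) -> bool:
        return self.genotype == "het"

    @property
    def is_phased(self) -> bool:
        return self.hap_link != ""


def pair_likelihood(observed_base: int, allele_base: int, error_rate: float) -> float:
    """P(observed base | true allele base) under uniform substitution errors."""
    return 1.0 - error_rate if observed_base == allele_base else error_rate / 3.0


def hypothesis_prob_unphased(lik_a0: float, lik_a1: float) -> float:
    """Equal-prior mixture over the two alleles (unphased mate pair)."""
    return (lik_a0 + lik_a1) / 2.0


def hypothesis_prob_phased(
    lik_a0: float, lik_a1: float, assigned_allele: int, mu: float = 0.01
) -> float:
    """Phasing-weighted mixture for a pair assigned to one allele.

    ``assigned_allele`` 0 gives (1-μ)·P(mp|A0) + μ·P(mp|A1); allele 1 the
    mirror image.  Reduces to the unphased form at μ = 0.5.
    """
    MuParam(mu)
    if assigned_allele == 0:
        return (1.0 - mu) * lik_a0 + mu * lik_a1
    if assigned_allele == 1:
        return mu * lik_a0 + (1.0 - mu) * lik_a1
    raise ValueError("assigned_allele must be 0 or 1; score unassigned pairs unphased")


def compute_well_fields(
    wells: Sequence[int], bases: Sequence[int], ref_base: int, alt_base: int
) -> dict:
    """The six per-well evidence fields at one locus.

    A well is variant-exclusive if it has reads calling only the variant
    allele, reference-exclusive if only the reference allele, shared if it
    contains reads calling both.
    """
    wells = np.asarray(wells, dtype=np.int64)
    bases = np.asarray(bases, dtype=np.int64)
    w_alt = set(wells[bases == alt_base].tolist())
    w_ref = set(wells[bases == ref_base].tolist())
    shared = w_alt & w_ref
    excl_alt = len(w_alt - shared)
    excl_ref = len(w_ref - shared)
    return {
        "well_count_var": len(w_alt),
        "well_count_ref": len(w_ref),
        "well_ids": tuple(sorted(w_alt)),
        "exclusive_well_count_var": excl_alt,
        "exclusive_well_count_ref": excl_ref,
        "shared_well_count": len(shared),
        "min_exclusive_well_count": min(excl_alt, excl_ref),
        "max_exclusive_well_count": max(excl_alt, excl_ref),
    }


# ordered hypothesis table (A0, A1), row-major over 4x4 bases
_HYPS = [(a0, a1) for a0 in range(4) for a1 in range(4)]
_GID = [(min(h), max(h)) for h in _HYPS]  # unordered genotype of each hypothesis


def _log_priors_for_ref(ref_base: int, params: CallParams) -> np.ndarray:
    """Log genotype prior for each of the 16 ordered hypotheses."""
    hom_ref_prior = max(1.0 - params.het_prior - params.hom_alt_prior, _LOG_FLOOR)
    out = np.empty(16)
    for i, (a0, a1) in enumerate(_HYPS):
        if a0 == a1:
            p = hom_ref_prior if a0 == ref_base else params.hom_alt_prior / 3.0
        elif ref_base in (a0, a1):
            p = params.het_prior / 6.0
        else:
            p = params.het_prior * params.nonref_het_factor / 6.0
        out[i] = np.log(max(p, _LOG_FLOOR))
    return out


def call_sites(
    result: SecondMapResult,
    contigs: Sequence[PhasedContig],
    fragment_alleles: np.ndarray,
    reference: np.ndarray,
    positions: np.ndarray | None = None,
    params: CallParams | None = None,
) -> tuple[list[LfrVariantRecord], dict]:
    """Call variants at candidate positions; hom-ref sites yield no record.

    ``fragment_alleles`` maps fragment index to 0/1 (or -1 when unassigned);
    reads inherit the allele of the fragment they were placed in.  Returns
    the variant records plus counters (sites evaluated, hom-ref, no-call).
    """
    if params is None:
        params = CallParams()
    reference = np.asarray(reference, dtype=np.uint8)
    if positions is None:
        positions = result.candidate_positions(min_alt_reads=2)
    positions = np.asarray(positions, dtype=np.int64)
    stats = {"n_candidates": int(positions.size), "n_hom_ref": 0, "n_records": 0}
    if positions.size == 0:
        return [], stats

    obs = result.pileup(positions)
    n_per_site = np.bincount(obs["site"], minlength=positions.size)
    covered = n_per_site > 0
    # re-index to covered sites only (pileup output is site-sorted)
    positions = positions[covered]
    old_to_new = np.cumsum(covered) - 1
    site = old_to_new[obs["site"]]
    n_sites = positions.size
    if n_sites == 0:
        return [], stats
    starts = np.searchsorted(site, np.arange(n_sites))

    base = obs["base"].astype(np.int64)
    allele = fragment_alleles[obs["frag"]]
    e = params.error_rate
    n_obs = base.size
    lik = np.full((n_obs, 4), e / 3.0)
    lik[np.arange(n_obs), base] = 1.0 - e

    mu = params.mu
    is_un = allele < 0
    is_a0 = allele == 0
    ll = np.empty((16, n_sites))
    for i, (a0, a1) in enumerate(_HYPS):
        l0, l1 = lik[:, a0], lik[:, a1]
        p = np.where(
            is_un,
            0.5 * (l0 + l1),
            np.where(is_a0, (1 - mu) * l0 + mu * l1, mu * l0 + (1 - mu) * l1),
        )
        ll[i] = np.add.reduceat(np.log(np.maximum(p, _LOG_FLOOR)), starts)

    ref_at = reference[positions].astype(np.int64)
    prior_cache = {r: _log_priors_for_ref(r, params) for r in range(4)}
    logprior = np.stack([prior_cache[r] for r in ref_at], axis=1)  # (16, n_sites)
    post = ll + logprior

    cidx = contig_of_positions(contigs, positions)
    gid_arr = np.array([g[0] * 4 + g[1] for g in _GID])

    best = np.argmax(post, axis=0)
    records: list[LfrVariantRecord] = []
    ln10 = np.log(10.0)
    for si in range(n_sites):
        b = int(best[si])
        a0, a1 = _HYPS[b]
        r = int(ref_at[si])
        if a0 == a1 == r:
            stats["n_hom_ref"] += 1
            continue
        # margin vs the best hypothesis of any other unordered genotype
        others = gid_arr != gid_arr[b]
        margin_db = 10.0 * (post[b, si] - post[others, si].max()) / ln10
        var_filter = "PASS" if margin_db >= params.min_margin_db else "VQLOW"

        lo, hi = starts[si], starts[si + 1] if si + 1 < n_sites else n_obs
        site_wells = obs["well"][lo:hi]
        site_bases = base[lo:hi]

        if a0 == a1:
            genotype, alt = "hom", a0
        elif r in (a0, a1):
            genotype, alt = "het", a1 if a0 == r else a0
        else:  # het without the reference base: report the better-supported base
            genotype = "het"
            alt = a0 if (site_bases == a0).sum() >= (site_bases == a1).sum() else a1

        phase: int | None = None
        hap_link = ""
        contig_id: int | None = None
        gt = "1/1" if genotype == "hom" else "0/1"
        if genotype == "het" and cidx[si] >= 0:
            swapped = _HYPS.index((a1, a0))
            if abs(post[b, si] - post[swapped, si]) > 1e-9:
                phase = 0 if a0 == alt else 1
                contig_id = int(contigs[cidx[si]].contig_id)
                hap_link = f"Phased_{params.library_id}_{contig_id}_{phase}"
                gt = "1|0" if phase == 0 else "0|1"

        wf = compute_well_fields(site_wells, site_bases, r, alt)
        records.append(
            LfrVariantRecord(
                position=int(positions[si]),
                ref=BASES[r],
                alt=BASES[alt],
                genotype=genotype,
                gt_string=gt,
                var_filter=var_filter,
                hap_link=hap_link,
                phase=phase,
                contig_id=contig_id,
                qual_db=float(margin_db),
                **wf,
            )
        )
    stats["n_records"] = len(records)
    return records, stats


def call_site(
    result: SecondMapResult,
    contigs: Sequence[PhasedContig],
    fragment_alleles: np.ndarray,
    reference: np.ndarray,
    position: int,
    params: CallParams | None = None,
) -> LfrVariantRecord | None:
    """Call a single site; ``None`` for hom-ref or uncovered sites."""
    recs, _ = call_sites(
        result,
        contigs,
        fragment_alleles,
        reference,
        positions=np.array([position], dtype=np.int64),
        params=params,
    )
    return recs[0] if recs else None


def fragment_allele_array(fragments) -> np.ndarray:
    """Pack per-fragment allele assignments into an int array (-1 = unassigned)."""
    return np.array(
        [f.allele if f.allele is not None else -1 for f in fragments], dtype=np.int64
    )
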