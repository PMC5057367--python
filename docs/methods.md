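# Methods

## The measurement being modeled

A co-barcoded (LFR-style) library spreads long genomic DNA across 384 wells
so thinly (~0.54 pg/well, ~200 pg ≈ 30 diploid cell-equivalents per
library) that the two parental alleles of a locus essentially never share a
well. All mate-pair reads from one well carry the well's barcode. The
analysis problem is to reconstruct, from barcoded short reads alone: the
long-fragment intervals per well, the assignment of each fragment to a
parental allele, phased variant calls, and quality metrics that certify the
phasing. This package implements that chain plus a generative simulator
that provides exact ground truth.

## Simulator

The diploid genome is a uniform random A/C/G/T sequence with SNPs planted
by independent per-base Bernoulli draws: heterozygous at density 1/1500 bp
(alternate allele on haplotype 0 or 1 with equal probability) and
homozygous-alternate at 1/2250 bp (giving a het/hom ratio of 1.5, in the
range reported for human genomes). Alternate alleles are uniform over the
three non-reference bases, so the simulated Ts/Tv is 0.5, not the ~2.1 of
real data; nothing downstream uses Ts/Tv.

Fragments: per-well counts are Poisson with mean set by the library mass —
by default 30 cell-equivalents, i.e. `30 × 2 × genome_length /
(decay_length × n_wells)` fragments per well, from ~200 pg per library ÷
6.6 pg per diploid cell. Lengths are exponential (default decay 30 kb,
within the 20–50 kb range typical of these libraries). The simulated window
is treated as a region cut out of a longer chromosome: fragment starts are
uniform over `[-length, genome_length)` and clipped at both window edges,
which makes fragment coverage stationary Poisson across the window instead
of ramping up from zero at the left edge. Haplotype of origin is a fair
coin per fragment.

Reads: pair counts per fragment are Poisson at 10 pairs/kb; the layout is
two 35 bp arms separated by a uniform 100–500 bp gap, placed uniformly
inside the fragment. Bases are copied from the fragment's haplotype, then
substituted i.i.d. at 0.005/base (uniform over the other three bases);
0.002 of pairs have their well id replaced by a uniform random other well
(cross-well contamination). No read-level parameters are taken from the
source experiment (it used a proprietary platform); these defaults make
fragments stand out clearly at 1 kb binning while keeping desk-scale
runtimes. The simulator does not model amplification (MDA) chimeras, GC or
amplification bias, or base-quality scores; passing tests therefore say
nothing about robustness to those artifacts.

## Fragment map

First mapping demands a unique exact match of the entire pair with a
consistent gap; the pair position is the average of the two arm positions.
Two modes exist: `strict` re-derives positions by exact search (a 64-bit
rolling-hash index of all arm-length windows; candidate hits are verified
exactly, so hash collisions cannot create false placements), and `fast`
trusts the simulator's true positions. Fast is the pipeline default: with
2×35 bp pairs at error 0.005 the exact-match rule discards ~30 % of pairs,
which 100X production data absorbs but a desk-scale simulation should not.
Strict mode is exercised by tests (uniqueness, planted repeats, gap
violations).

Fragment calling scans each well's 1 kb bin vector for maximal runs of bins
with ≥ 2 pairs, tolerating ≤ 4 consecutive under-threshold bins inside a
run, and discards extents under 10 kb. The thresholds for "well-populated"
and the tolerated gap are not fixed by the source description and are
exposed in `StreakParams`; the defaults were chosen for ≥ 10 reads/kb
libraries (each fully covered bin then holds ~10 pair midpoints, so a
threshold of 2 separates signal from contamination background) before any
acceptance measurement. Fragment extents are bin-quantized.

Two diagnostics mirror the expected library statistics: the fragment-length
decay is estimated as the mean excess over the 10 kb truncation point
(memorylessness of the exponential), and fragment coverage at probe points
is compared with Poisson(total fragment bp / genome length) by chi-square.
The chi-square is only calibrated when probe points sit several decay
lengths apart; closer probes are autocorrelated and inflate the statistic.

A known desk-scale artifact: with a 5 Mb window, one well's fragments
occupy ~15 % of the window (vs ~1 % for a real genome), so two same-well
fragments occasionally merge into one called "chimeric" fragment. This is
why zero-noise runs can still show a handful of contradictions.

## Phasing

Second mapping places each pair only within its own well's called
fragments, allows at most one mismatch per arm, and records every
mismatch. Consequence: two true variants within one arm length of each
other are invisible (any alt read has two mismatches in one arm); resolving
those requires local assembly, which is out of scope here, and accounts for
a ~4 % loss of callable variants at default density.

Strong het sites are positions where exactly two bases each have ≥ 3 reads
from ≥ 2 distinct wells and ≥ 20 % of the site's reads. The well floor
rejects single-well (amplification-artifact-like) support; the fraction
floor was added because at ~40X depth, coincident sequencing errors
(0.005/3 per alternative base) otherwise fabricate thousands of spurious
two-read "strong" sites. Both thresholds predate any acceptance
measurement and are exposed in `StrongHetParams`.

Allele assignment minimizes contradicted observations. An observation is a
(fragment, site, base) majority vote of that fragment's reads at that
strong het. Given fragment colors (alleles), each site's base→allele
orientation has a closed-form optimum, so the objective is the sum over
sites of the minority count of the 2×2 base-by-color table under the better
orientation. The solver is greedy seeding in genomic order followed by
three local moves iterated to convergence: single-fragment flips,
suffix flips (invert every fragment from a genomic cut point rightwards),
and pair flips (for components ≤ 64 fragments), with 8 deterministic
restarts on small components. The suffix move matters: an internally
inverted segment — exactly a long-switch error — is a deep local minimum
for single flips, since only sites straddling the segment's boundary change
cost when the segment flips as a whole. On random instances with ≤ 12
fragments the search attains the exhaustive minimum (property-tested); at
scale it is heuristic, as the underlying problem is max-cut-like and
NP-hard. Ties are broken deterministically (lowest fragment id, color 0),
so identical inputs give identical phasings.

Fragments whose contradicted-observation fraction exceeds 0.25 are left
unassigned ("too many contradictions"); a component whose best coloring is
no better than chance is dropped entirely. Phased contigs then break
wherever the relative orientation of two consecutive strong hets is not
reliably established: every fragment observing both sites votes for their
relative orientation (the XOR of its two observed base indices — a quantity
independent of the fragment's own color), and the junction survives only if
agreeing votes outnumber disagreeing ones by ≥ 2 (`min_link_support`).
Junctions dominated by chimeric fragments or a het desert thus end the
contig instead of risking a long switch across it. Allele labels are
meaningful only within a contig.

## Variant calling

Sites with ≥ 2 reads of some non-reference base are scored over all 16
ordered hypotheses (A0, A1). Per-read likelihoods are 1−e for a matching
base and e/3 otherwise (e = 0.005 by default, matching the simulator).
Reads from assigned fragments use the phasing-weighted mixture with
μ = 0.01; unassigned reads use the equal-prior mixture; μ = 0.5 provably
reduces the former to the latter, and a test asserts the resulting calls
are identical. Genotype priors are flat within class (het 10⁻³, hom-alt
5×10⁻⁴, hets not containing the reference base a further 10⁻³ down); the
winning hypothesis must beat the best competing unordered genotype by
10 dB of log-odds or the record is marked `VQLOW` instead of `PASS`.
Priors, margin, and μ are configurable (`CallParams`); the numbers above
are package defaults documented here, not fitted values. Hom-ref winners
produce no record but are counted. For het calls inside a contig the
winning ordered pair fixes which contig haplotype carries the alternate
allele; that digit is exported as the final field of the
`Phased_<library>_<contig>_<hap>` hapLink and as a phased GT with a PS tag.
The per-well fields are set-theoretic counts over the wells observed at the
locus (variant wells, reference wells, exclusive/shared, locus min/max of
the exclusive counts).

## Filters and QC

The high-confidence cascade applies, in fixed order: varFilter = PASS;
wellCount ≥ 6 for the variant call and (het sites only) the reference
call; and, for het sites, SharedWellCount ≤ 0.25 × (MinExclusiveWellCount
+ SharedWellCount). The 6-well and 0.25 constants are the published filter
settings and are configurable for sensitivity analyses. The reference-call
wellCount requirement is applied to het sites only, following the filter's
own wording (a hom-alt site has no reference reads to count). Haplotype
blocks are the phased het survivors grouped by contig, dropping blocks
under 10 SNPs.

The phasing rate reported by the pipeline is the fraction of *called* het
SNPs that land in retained (≥ 10-SNP) blocks of the variant records
themselves. The well-count cascade is deliberately not part of this metric:
it selects a high-confidence subset whose pass fraction is set by library
mass (wells per allele ~ Poisson with mean ≈ cell-equivalents/2), not by
phasing quality. The cascade *is* applied before replicate comparison,
matching how the published replicate analysis was filtered.

Replicate discordance compares haplotype blocks from two libraries of the
same genome. Blocks within one replicate are disjoint, so every
positionally overlapping block pair is compared (each co-phased SNP is then
counted exactly once and the comparison is symmetric); a pair needs ≥ 10
shared het sites with identical alleles. Per pair, the label orientation
minimizing mismatches is chosen, mismatching sites are partitioned into
maximal runs, runs of length 1 count as short switches (one discordant SNP
each) and runs of length ≥ 2 as one long switch event each — long-run SNPs
do not enter the short numerator (the published definition leaves this
ambiguous; excluding them is documented here). Rates divide by total
compared phased SNPs. Comparisons under `min_total_snps` (default 10⁶, the
published inclusion cutoff) are reported but flagged `below_threshold`;
desk-scale runs always carry that flag.

`cells_of_dna` is recovered fragment bp / (2 × genome length) — diploid
genome equivalents, computed from the called fragment map, so it
undercounts the configured mass by whatever the 10 kb filter and window
clipping remove (a few percent at 5 Mb, more on very small windows).

## Problem sizes and determinism

Simulation-based tests use windows of 0.4–5 Mb; the replicate-discordance
and phasing-rate checks use one 5 Mb genome and two full default-scale
libraries (~2.9 M read pairs each, ~20 s/library on one CPU), and the
distribution-recovery checks use ~10⁴ fragments. These sizes were chosen so
the whole suite runs on a laptop-class machine; all statistical assertions
are written with explicit oracles (binomial/Poisson/exponential moments,
chi-square at α = 0.01, exhaustive enumeration on small instances). Every
stochastic component is driven by numpy Generators derived from a single
seed through named SeedSequence streams, so any run is bit-reproducible
from its config.

## Known limitations

- No indels, structural variants, or CNVs; SNP-only by design.
- No mapping with mismatches at the first mapping step, and no local
  assembly: clustered variants (< 1 arm length apart) are not callable.
- The simulator omits MDA chimeras and coverage biases; discordance rates
  measured here bound only the algorithmic error sources (sequencing error,
  well contamination, chimeric streak merges), not amplification artifacts.
- Single concatenated reference sequence; run per chromosome for
  multi-chromosome genomes.
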