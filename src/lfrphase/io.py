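"""Readers/writers for every file dialect the pipeline touches.

Formats: reference FASTA; reads TSV (well, arm positions, arm bases); BED6
fragment maps; the var-TSV variant dialect carrying the per-well evidence
fields (including the historical ``ecxclusiveWellCount`` header, preserved
verbatim); VCF 4.2 with phased GT/PS and cleaned INFO keys; coverage-map and
contig TSVs.  Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fragmap import CalledFragment, WellCoverageMap
from .phasemap import PhasedContig
from .seq import decode_seq, encode_seq
from .simulate import DiploidGenome, FragmentSet, ReadSet
from .varcall import LfrVariantRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_reads_tsv",
    "read_reads_tsv",
    "write_truth_fragments_bed",
    "write_called_fragments_bed",
    "read_called_fragments_bed",
    "write_truth_vcf",
    "write_variants_vcf",
    "write_var_tsv",
    "read_var_tsv",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_contigs_tsv",
    "plot_coverage_map",
]

CHROM = "sim1"


def write_fasta(codes: np.ndarray, path: str | Path, name: str = CHROM, width: int = 70) -> None:
    seq = decode_seq(codes)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> np.ndarray:
    """First sequence of a FASTA file as uint8 codes (parsed with pysam)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            return encode_seq(entry.sequence)
    raise ValueError(f"no sequence found in {path}")


_READS_COLS = ["well", "arm1_pos", "arm2_pos", "arm1_bases", "arm2_bases", "fragment_id"]


def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_READS_COLS)
        for i in range(len(reads)):
            w.writerow(
                [
                    int(reads.well[i]),
                    int(reads.arm1_pos[i]),
                    int(reads.arm2_pos[i]),
                    decode_seq(reads.arm1_bases[i]),
                    decode_seq(reads.arm2_bases[i]),
                    int(reads.fragment_id_truth[i]),
                ]
            )


def read_reads_tsv(path: str | Path) -> ReadSet:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != _READS_COLS:
            raise ValueError(f"unexpected reads-TSV header: {header}")
        rows = list(r)
    n = len(rows)
    arm = len(rows[0][3]) if n else 0
    well = np.empty(n, dtype=np.int32)
    p1 = np.empty(n, dtype=np.int64)
    p2 = np.empty(n, dtype=np.int64)
    b1 = np.empty((n, arm), dtype=np.uint8)
    b2 = np.empty((n, arm), dtype=np.uint8)
    fid = np.empty(n, dtype=np.int64)
    for i, row in enumerate(rows):
        well[i], p1[i], p2[i], fid[i] = int(row[0]), int(row[1]), int(row[2]), int(row[5])
        b1[i] = encode_seq(row[3])
        b2[i] = encode_seq(row[4])
    return ReadSet(well, p1, p2, b1, b2, fid)


def write_truth_fragments_bed(fragments: FragmentSet, path: str | Path, chrom: str = CHROM) -> None:
    """Ground-truth fragments as BED6; name = well:haplotype."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{chrom}\t{f.start}\t{f.end}\t{f.well}:{f.haplotype}\t0\t.\n"
            )


def write_called_fragments_bed(
    fragments: Sequence[CalledFragment], path: str | Path, chrom: str = CHROM
) -> None:
    """Called fragment map as BED6; name = well:allele ('.' when unassigned)."""
    with open(path, "w") as fh:
        for f in fragments:
            allele = "." if f.allele is None else str(f.allele)
            fh.write(
                f"{chrom}\t{f.start_bp}\t{f.end_bp}\t{f.well}:{allele}\t{f.support}\t.\n"
            )


def read_called_fragments_bed(path: str | Path, bin_size: int = 1000) -> list[CalledFragment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _, start, end, name, score, _ = line.rstrip("\n").split("\t")
            well_s, allele_s = name.split(":")
            out.append(
                CalledFragment(
                    well=int(well_s),
                    start_bin=int(start) // bin_size,
                    end_bin=int(end) // bin_size - 1,
                    bin_size=bin_size,
                    support=int(score),
                    allele=None if allele_s == "." else int(allele_s),
                )
            )
    return out


def _vcf_header(length: int, sample: str, extra_info: Sequence[str] = ()) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM},length={length}>",
        '##FILTER=<ID=VQLOW,Description="Best hypothesis below the log-odds margin">',
        '##INFO=<ID=HL,Number=1,Type=String,Description="LFR phased-contig haplotype link">',
        '##INFO=<ID=WCV,Number=1,Type=Integer,Description="Wells with reads calling the variant allele">',
        '##INFO=<ID=WCR,Number=1,Type=Integer,Description="Wells with reads calling the reference allele">',
        '##INFO=<ID=EWCV,Number=1,Type=Integer,Description="Wells calling only the variant allele">',
        '##INFO=<ID=EWCR,Number=1,Type=Integer,Description="Wells calling only the reference allele">',
        '##INFO=<ID=SWC,Number=1,Type=Integer,Description="Wells calling both alleles">',
        '##INFO=<ID=MINEWC,Number=1,Type=Integer,Description="Locus minimum exclusive well count">',
        '##INFO=<ID=MAXEWC,Number=1,Type=Integer,Description="Locus maximum exclusive well count">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set (phased contig id)">',
    ]
    lines.extend(extra_info)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return "\n".join(lines) + "\n"


def write_truth_vcf(genome: DiploidGenome, path: str | Path, sample: str = "TRUTH") -> None:
    """Ground-truth variants as a fully phased VCF (PS=0 throughout)."""
    from .seq import BASES

    with open(path, "w") as fh:
        fh.write(_vcf_header(len(genome), sample))
        ref_bases = genome.ref_bases
        on0 = genome.alt_on_haplotype(0)
        on1 = genome.alt_on_haplotype(1)
        for i, pos in enumerate(genome.positions):
            gt = f"{int(on0[i])}|{int(on1[i])}"
            fh.write(
                f"{CHROM}\t{int(pos) + 1}\t.\t{BASES[ref_bases[i]]}\t"
                f"{BASES[genome.alt_bases[i]]}\t.\tPASS\t.\tGT:PS\t{gt}:0\n"
            )


def write_variants_vcf(
    records: Sequence[LfrVariantRecord],
    genome_length: int,
    path: str | Path,
    sample: str = "LFR",
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(genome_length, sample))
        for r in sorted(records, key=lambda x: x.position):
            info = (
                f"WCV={r.well_count_var};WCR={r.well_count_ref};"
                f"EWCV={r.exclusive_well_count_var};EWCR={r.exclusive_well_count_ref};"
                f"SWC={r.shared_well_count};MINEWC={r.min_exclusive_well_count};"
                f"MAXEWC={r.max_exclusive_well_count}"
            )
            if r.hap_link:
                info = f"HL={r.hap_link};" + info
            if r.contig_id is not None and "|" in r.gt_string:
                fmt, val = "GT:PS", f"{r.gt_string}:{r.contig_id}"
            else:
                fmt, val = "GT", r.gt_string
            fh.write(
                f"{CHROM}\t{r.position + 1}\t.\t{r.ref}\t{r.alt}\t"
                f"{r.qual_db:.2f}\t{r.var_filter}\t{info}\t{fmt}\t{val}\n"
            )


# var-TSV dialect: the historical field name "ecxclusiveWellCount" is preserved verbatim
_VAR_TSV_COLS = [
    "position",
    "reference",
    "variant",
    "genotype",
    "gt",
    "varFilter",
    "hapLink",
    "wellCount",
    "wellIDs",
    "ecxclusiveWellCount",
    "SharedWellCount",
    "MinExclusiveWellCountInThisLocus",
    "MaxExclusiveWellCountInThisLocus",
    "refWellCount",
    "refExclusiveWellCount",
    "phase",
    "contigId",
    "qualDb",
]


def write_var_tsv(records: Sequence[LfrVariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VAR_TSV_COLS)
        for r in sorted(records, key=lambda x: x.position):
            w.writerow(
                [
                    r.position + 1,
                    r.ref,
                    r.alt,
                    r.genotype,
                    r.gt_string,
                    r.var_filter,
                    r.hap_link,
                    r.well_count_var,
                    ";".join(str(x) for x in r.well_ids),
                    r.exclusive_well_count_var,
                    r.shared_well_count,
                    r.min_exclusive_well_count,
                    r.max_exclusive_well_count,
                    r.well_count_ref,
                    r.exclusive_well_count_ref,
                    "" if r.phase is None else r.phase,
                    "" if r.contig_id is None else r.contig_id,
                    repr(r.qual_db),
                ]
            )


def read_var_tsv(path: str | Path) -> list[LfrVariantRecord]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != _VAR_TSV_COLS:
            raise ValueError(f"malformed var-TSV header in {path}: {header}")
        out = []
        for row in r:
            d = dict(zip(_VAR_TSV_COLS, row))
            out.append(
                LfrVariantRecord(
                    position=int(d["position"]) - 1,
                    ref=d["reference"],
                    alt=d["variant"],
                    genotype=d["genotype"],
                    gt_string=d["gt"],
                    var_filter=d["varFilter"],
                    hap_link=d["hapLink"],
                    well_count_var=int(d["wellCount"]),
                    well_count_ref=int(d["refWellCount"]),
                    well_ids=tuple(int(x) for x in d["wellIDs"].split(";") if x != ""),
                    exclusive_well_count_var=int(d["ecxclusiveWellCount"]),
                    exclusive_well_count_ref=int(d["refExclusiveWellCount"]),
                    shared_well_count=int(d["SharedWellCount"]),
                    min_exclusive_well_count=int(d["MinExclusiveWellCountInThisLocus"]),
                    max_exclusive_well_count=int(d["MaxExclusiveWellCountInThisLocus"]),
                    phase=None if d["phase"] == "" else int(d["phase"]),
                    contig_id=None if d["contigId"] == "" else int(d["contigId"]),
                    qual_db=float(d["qualDb"]),
                )
            )
    return out


def write_coverage_tsv(cov: WellCoverageMap, path: str | Path) -> None:
    """Sparse TSV (well, bin, count) of the non-zero coverage-map cells."""
    wells, bins = np.nonzero(cov.counts)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["well", "bin", "count"])
        w.writerow(["#bin_size", cov.bin_size, cov.genome_length])
        for we, bi in zip(wells, bins):
            w.writerow([int(we), int(bi), int(cov.counts[we, bi])])


def read_coverage_tsv(path: str | Path) -> WellCoverageMap:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != ["well", "bin", "count"]:
            raise ValueError(f"malformed coverage TSV header: {header}")
        meta = next(r)
        bin_size, genome_length = int(meta[1]), int(meta[2])
        rows = [(int(a), int(b), int(c)) for a, b, c in r]
    n_bins = -(-genome_length // bin_size)
    n_wells = max((w for w, _, _ in rows), default=1)
    counts = np.zeros((n_wells + 1, n_bins), dtype=np.int32)
    for w_, b_, c_ in rows:
        counts[w_, b_] = c_
    return WellCoverageMap(counts=counts, bin_size=bin_size, genome_length=genome_length)


def write_contigs_tsv(contigs: Sequence[PhasedContig], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "start", "end", "n_sites", "contradiction_count"])
        for c in contigs:
            w.writerow([c.contig_id, c.start, c.end, c.n_sites, c.contradiction_count])


def plot_coverage_map(cov: WellCoverageMap, path: str | Path, vmax: int | None = None) -> None:
    """Heat map with wells as columns and genomic position on the vertical axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 10))
    ax.imshow(
        cov.counts.T,
        aspect="auto",
        origin="lower",
        cmap="Greys",
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xlabel("well")
    ax.set_ylabel(f"position ({cov.bin_size} bp bins)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
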