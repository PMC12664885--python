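"""Readers and writers for the standard formats around the pipeline.

SAM I/O goes through pysam; coordinates are converted to the internal
0-based half-open convention at this boundary.  The conversion space of
a read is taken from a configurable SAM tag (default ``XC``, values
``CT``/``GA``) when present and inferred from the mismatch pattern
otherwise.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .conversion import (
    AlignedConvertedRead,
    ConversionSpace,
    classify_read_space,
    encode_seq,
)
from .phasing import HetVariant, PhasedBlock, PseudoRead, VariantKind

DEFAULT_SPACE_TAG = "XC"


def write_fasta(name: str, sequence: str, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None:
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}


def _cigar_from_pairs(
    read_offsets: np.ndarray, ref_positions: np.ndarray, read_length: int
) -> list[tuple[int, int]]:
    """Rebuild a CIGAR (pysam op codes) from matched alignment columns.

    Unaligned read bases before the first / after the last match become
    soft clips; internal read jumps are insertions and reference jumps
    deletions.
    """
    cigar: list[tuple[int, int]] = []
    if read_offsets[0] > 0:
        cigar.append((4, int(read_offsets[0])))  # S
    run = 1
    for k in range(1, len(read_offsets)):
        dq = int(read_offsets[k] - read_offsets[k - 1])
        dr = int(ref_positions[k] - ref_positions[k - 1])
        if dq == 1 and dr == 1:
            run += 1
            continue
        cigar.append((0, run))  # M
        if dq > 1:
            cigar.append((1, dq - 1))  # I
        if dr > 1:
            cigar.append((2, dr - 1))  # D
        run = 1
    cigar.append((0, run))
    tail = read_length - int(read_offsets[-1]) - 1
    if tail > 0:
        cigar.append((4, tail))
    return cigar


def write_sam(
    reads: Iterable[AlignedConvertedRead],
    path,
    reference_name: str,
    reference_length: int,
    space_tag: str = DEFAULT_SPACE_TAG,
) -> int:
    """Write aligned converted reads as a coordinate-sorted SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    reads = sorted(reads, key=lambda r: r.start)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.read_id
            a.query_sequence = read.read_bases
            a.reference_id = 0
            a.reference_start = read.start
            a.mapping_quality = read.mapq
            a.cigartuples = _cigar_from_pairs(
                read.read_offsets, read.ref_positions, len(read.read_bases)
            )
            a.flag = 0 if read.is_primary else 0x100
            if read.space is not ConversionSpace.UNKNOWN:
                a.set_tag(space_tag, read.space.value)
            fh.write(a)
            n += 1
    return n


def read_sam(
    path,
    reference: str | np.ndarray | None = None,
    space_tag: str = DEFAULT_SPACE_TAG,
    min_mapq: int = 0,
) -> list[AlignedConvertedRead]:
    """Load aligned converted reads from SAM/BAM.

    The space tag is trusted when present; otherwise the read is
    classified from its mismatch pattern against ``reference`` (required
    in that case).  Unmapped reads are skipped.
    """
    ref = encode_seq(reference) if isinstance(reference, str) else reference
    out: list[AlignedConvertedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.mapping_quality < min_mapq:
                continue
            pairs = aln.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            read = AlignedConvertedRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                read_offsets=np.array([p[0] for p in pairs], dtype=np.int64),
                ref_positions=np.array([p[1] for p in pairs], dtype=np.int64),
                read_bases=aln.query_sequence,
                is_primary=not (aln.is_secondary or aln.is_supplementary),
                mapq=aln.mapping_quality,
            )
            if aln.has_tag(space_tag):
                read.space = ConversionSpace(aln.get_tag(space_tag))
            elif ref is not None:
                read.space = classify_read_space(read, ref)
            out.append(read)
    return out


def write_pseudo_sam(
    pseudo_reads: Iterable[PseudoRead],
    path,
    reference_name: str,
    reference_length: int,
) -> int:
    """Export pseudo reads as SAM for an external read-backed phaser."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    ordered = sorted(pseudo_reads, key=lambda r: r.start)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for pr in ordered:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = pr.read_id
            a.query_sequence = pr.bases
            a.reference_id = 0
            a.reference_start = pr.start
            a.mapping_quality = 60
            a.cigartuples = _cigar_from_pairs(
                pr.read_offsets, pr.ref_positions, len(pr.bases)
            )
            fh.write(a)
            n += 1
    return n


def read_pseudo_sam(path) -> list[PseudoRead]:
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            pairs = aln.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            out.append(
                PseudoRead(
                    aln.query_name,
                    aln.reference_name,
                    np.array([p[0] for p in pairs], dtype=np.int64),
                    np.array([p[1] for p in pairs], dtype=np.int64),
                    aln.query_sequence,
                )
            )
    return out


_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##contig=<ID={chrom},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    variants: Sequence[HetVariant],
    path,
    chrom_length: int,
    phase_bits: Sequence[int] | None = None,
    phase_sets: Sequence[int] | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write biallelic SNVs as VCF; het SNPs phased when bits are given.

    ``phase_bits[i]`` is the allele on haplotype 1 (0=ref, 1=alt); with
    ``phase_sets`` a PS tag groups variants into phased blocks.
    """
    if not variants:
        chrom = "unknown"
    else:
        chrom = variants[0].chrom
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=chrom_length, sample=sample))
        for i, v in enumerate(variants):
            if phase_bits is not None:
                bit = int(phase_bits[i])
                gt = f"{bit}|{1 - bit}"
                if phase_sets is not None:
                    fmt, val = "GT:PS", f"{gt}:{int(phase_sets[i])}"
                else:
                    fmt, val = "GT", gt
            else:
                fmt, val = "GT", "0/1"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t{val}\n"
            )


def read_vcf(path, kind: VariantKind = VariantKind.HET_SNP):
    """Load biallelic SNVs; returns (variants, phase_bits, phase_sets).

    Phase entries are None for unphased records.
    """
    variants: list[HetVariant] = []
    bits: list[int | None] = []
    sets: list[int | None] = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            if len(rec.alts or ()) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            variants.append(HetVariant(rec.chrom, rec.pos - 1, ref, alt, kind))
            sample = rec.samples[0] if rec.samples else None
            if sample is not None and sample.phased and None not in sample["GT"]:
                bits.append(int(sample["GT"][0]))
                sets.append(
                    int(sample["PS"]) if "PS" in sample and sample["PS"] is not None else 0
                )
            else:
                bits.append(None)
                sets.append(None)
    return variants, bits, sets


def blocks_from_phased_vcf(path, variants: Sequence[HetVariant]) -> list[PhasedBlock]:
    """Rebuild phased blocks from a PS-tagged VCF against a variant list."""
    vcf_vars, bits, sets = read_vcf(path)
    index = {(v.chrom, v.pos): i for i, v in enumerate(variants)}
    groups: dict[tuple[str, int], dict[int, int]] = {}
    for v, bit, ps in zip(vcf_vars, bits, sets):
        if bit is None:
            continue
        vi = index.get((v.chrom, v.pos))
        if vi is None:
            continue
        groups.setdefault((v.chrom, ps or 0), {})[vi] = bit
    blocks = []
    for key in sorted(groups):
        bits_map = groups[key]
        if len(bits_map) >= 2:
            blocks.append(PhasedBlock(len(blocks), sorted(bits_map), bits_map))
    return blocks


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bedgraph(cpg_counts: pd.DataFrame, path) -> None:
    """Per-CpG rates in the common methylation-extractor bedGraph dialect.

    Columns: chrom, start, end (start+1), rate in percent, n_meth,
    n_unmeth; only covered CpGs are emitted.
    """
    with open(path, "w") as fh:
        for row in cpg_counts.itertuples():
            cov = row.n_meth + row.n_unmeth
            if cov == 0:
                continue
            rate = 100.0 * row.n_meth / cov
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{rate:.6g}\t"
                f"{row.n_meth}\t{row.n_unmeth}\n"
            )


def read_bedgraph(path, chrom: str | None = None) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 6:
                continue
            if chrom is not None and parts[0] != chrom:
                continue
            rows.append(
                (parts[0], int(parts[1]), int(parts[4]), int(parts[5]))
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])


def read_tss(path) -> pd.DataFrame:
    """TSS annotation from a 4-column TSV (gene, chrom, pos, strand) or BED.

    BED input uses the interval start as the TSS for + strand and end-1
    for - strand.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if path.suffix == ".bed" or (parts[1].isdigit() and parts[2].isdigit()):
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                gene = parts[3] if len(parts) > 3 else f"{chrom}:{start}"
                strand = parts[5] if len(parts) > 5 else "+"
                pos = start if strand != "-" else end - 1
            else:
                gene, chrom, pos, strand = (
                    parts[0],
                    parts[1],
                    int(parts[2]),
                    parts[3] if len(parts) > 3 else "+",
                )
            rows.append((gene, chrom, pos, strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])


def aln_records_from_sam(path) -> list:
    """Load QC alignment records (see :mod:`emcap.qc`) from SAM/BAM."""
    from .qc import AlnRecord

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            cig = aln.cigartuples or []
            clip_left = sum(n for op, n in cig[:1] if op in (4, 5))
            clip_right = sum(n for op, n in cig[-1:] if op in (4, 5))
            out.append(
                AlnRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    is_reverse=aln.is_reverse,
                    clip_left=clip_left,
                    clip_right=clip_right,
                    blocks=[(s, e) for s, e in aln.get_blocks()],
                    read_length=aln.infer_read_length() or 0,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    is_duplicate=aln.is_duplicate,
                )
            )
    return out
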