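"""Pseudo-read construction, haplotype phasing and read haplotagging.

Converted reads cannot be phased directly by standard read-backed
phasers because conversion confounds the variant alleles.  The approach
implemented here restores the ref/alt allele at each heterozygous SNP a
read covers -- taking the read's conversion space into account -- and
replaces every other base with N, yielding *pseudo reads* that any
phaser can consume.  An internal spanning-forest phaser is provided for
self-contained runs; the pseudo-read SAM export preserves coordinates
and CIGAR so an external phaser (e.g. WhatsHap) can be substituted.
Only primary alignments participate, which keeps complex structural
variants (primary + supplementary combinations) out of the phase signal.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conversion import (
    AlignedConvertedRead,
    AlleleSupport,
    ConversionSpace,
    allele_support,
)


class VariantKind(enum.Enum):
    HET_SNP = "HET_SNP"
    SOMATIC_SNV = "SOMATIC_SNV"


@dataclass(frozen=True)
class HetVariant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    kind: VariantKind = VariantKind.HET_SNP

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.chrom}:{self.pos}: ref == alt")


class Haplotype(enum.Enum):
    H1 = "H1"
    H2 = "H2"
    UNTAGGED = "UNTAGGED"


class SNVClass(enum.Enum):
    SNV_PLUS = "SNV_PLUS"
    SNV_MINUS = "SNV_MINUS"
    UNASSIGNED = "UNASSIGNED"


class AlleleMatrix:
    """Sparse read x variant table of conversion-aware allele support.

    Only REF/ALT cells carry phase information; AMBIGUOUS and OTHER cells
    are recorded but inert.  Restricted to primary alignments.
    """

    def __init__(self, variants: Sequence[HetVariant]):
        self.variants = list(variants)
        for i in range(1, len(self.variants)):
            a, b = self.variants[i - 1], self.variants[i]
            if a.chrom == b.chrom and a.pos >= b.pos:
                raise ValueError("variants must be sorted and unique per chrom")
        self.cells: dict[str, dict[int, AlleleSupport]] = {}

    def set(self, read_id: str, variant_index: int, support: AlleleSupport) -> None:
        self.cells.setdefault(read_id, {})[variant_index] = support

    def informative(self, read_id: str) -> dict[int, int]:
        """Map variant_index -> allele bit (0=REF, 1=ALT) for one read."""
        out = {}
        for idx, sup in self.cells.get(read_id, {}).items():
            if sup is AlleleSupport.REF:
                out[idx] = 0
            elif sup is AlleleSupport.ALT:
                out[idx] = 1
        return out

    @property
    def n_reads(self) -> int:
        return len(self.cells)


def build_allele_matrix(
    reads: Iterable[AlignedConvertedRead],
    variants: Sequence[HetVariant],
    reference_length: int | None = None,
) -> AlleleMatrix:
    """Extract conversion-aware allele support at every covered variant."""
    if reference_length is not None:
        for v in variants:
            if v.pos < 0 or v.pos >= reference_length:
                raise ValueError(f"variant {v.chrom}:{v.pos} outside reference bounds")
    matrix = AlleleMatrix(variants)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {v.chrom for v in variants}:
        idx = np.array(
            [i for i, v in enumerate(variants) if v.chrom == chrom], dtype=np.int64
        )
        pos = np.array([variants[i].pos for i in idx], dtype=np.int64)
        by_chrom[chrom] = (pos, idx)
    for read in reads:
        if not read.is_primary or read.space is ConversionSpace.UNKNOWN:
            continue
        if read.chrom not in by_chrom:
            continue
        pos, idx = by_chrom[read.chrom]
        lo = np.searchsorted(pos, read.start)
        hi = np.searchsorted(pos, read.end)
        if hi <= lo:
            continue
        observed = read.codes_at(pos[lo:hi])
        for k, obs_code in enumerate(observed):
            vi = int(idx[lo + k])
            v = matrix.variants[vi]
            sup = allele_support(read.space, v.ref, v.alt, chr(obs_code))
            matrix.set(read.read_id, vi, sup)
    return matrix


@dataclass
class PseudoRead:
    """Coordinate-preserving read: restored alleles at variants, N elsewhere."""

    read_id: str
    chrom: str
    read_offsets: np.ndarray
    ref_positions: np.ndarray
    bases: str  # over the read frame; non-N only at het-variant positions

    @property
    def start(self) -> int:
        return int(self.ref_positions[0])

    def informative_positions(self) -> dict[int, str]:
        out = {}
        for off, pos in zip(self.read_offsets, self.ref_positions):
            b = self.bases[off]
            if b != "N":
                out[int(pos)] = b
        return out


def make_pseudo_reads(
    matrix: AlleleMatrix, reads: Iterable[AlignedConvertedRead]
) -> list[PseudoRead]:
    """One pseudo read per input read with at least one REF/ALT cell."""
    var_pos = {i: v.pos for i, v in enumerate(matrix.variants)}
    var_allele = {
        i: (v.ref, v.alt) for i, v in enumerate(matrix.variants)
    }
    out = []
    for read in reads:
        info = matrix.informative(read.read_id)
        if not info:
            continue
        n_bases = int(read.read_offsets[-1]) + 1
        bases = ["N"] * n_bases
        pos_to_off = dict(zip(read.ref_positions.tolist(), read.read_offsets.tolist()))
        for vi, bit in info.items():
            p = var_pos[vi]
            off = pos_to_off.get(p)
            if off is not None:
                bases[off] = var_allele[vi][bit]
        out.append(
            PseudoRead(
                read.read_id,
                read.chrom,
                read.read_offsets.copy(),
                read.ref_positions.copy(),
                "".join(bases),
            )
        )
    return out


@dataclass
class PhasedBlock:
    """Contiguous het SNPs with a relative haplotype assignment.

    ``hap1_allele[i]`` is the allele bit carried by haplotype 1 at
    variant index ``i`` (0=REF, 1=ALT); the global flip of a block is
    arbitrary, only relative orientation is meaningful.
    """

    block_id: int
    variant_indices: list[int]
    hap1_allele: dict[int, int]


def phase_blocks(matrix: AlleleMatrix, min_link: int = 2) -> list[PhasedBlock]:
    """Greedy spanning-forest phasing of the allele matrix.

    For every variant pair co-covered informatively by a read, cis
    (same-allele) and trans (opposite-allele) observations are counted.
    Edges weighted |cis - trans| below ``min_link`` are dropped --
    single-read links are unreliable at nanopore error rates -- and a
    maximum-weight spanning forest orients each tree into one block.
    """
    cis: dict[tuple[int, int], int] = defaultdict(int)
    trans: dict[tuple[int, int], int] = defaultdict(int)
    for read_id in matrix.cells:
        info = matrix.informative(read_id)
        if len(info) < 2:
            continue
        items = sorted(info.items())
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                (i, bi), (j, bj) = items[a], items[b]
                if matrix.variants[i].chrom != matrix.variants[j].chrom:
                    continue
                if bi == bj:
                    cis[(i, j)] += 1
                else:
                    trans[(i, j)] += 1
    edges = []
    for key in set(cis) | set(trans):
        c, t = cis.get(key, 0), trans.get(key, 0)
        weight = abs(c - t)
        if weight >= min_link:
            edges.append((weight, key[0], key[1], 1 if c > t else -1))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adjacency: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for weight, i, j, sign in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[ri] = rj
        adjacency[i].append((j, sign))
        adjacency[j].append((i, sign))

    blocks: list[PhasedBlock] = []
    seen: set[int] = set()
    for root in sorted(adjacency):
        if root in seen:
            continue
        bits = {root: 0}
        stack = [root]
        seen.add(root)
        while stack:
            node = stack.pop()
            for nbr, sign in adjacency[node]:
                if nbr in seen:
                    continue
                bits[nbr] = bits[node] if sign > 0 else 1 - bits[node]
                seen.add(nbr)
                stack.append(nbr)
        indices = sorted(bits)
        if len(indices) >= 2:
            blocks.append(PhasedBlock(len(blocks), indices, bits))
    return blocks


class HaplotagMode(enum.Enum):
    PHASED_ONLY = "PHASED_ONLY"
    WITH_UNPHASED_SNPS = "WITH_UNPHASED_SNPS"


@dataclass
class HaplotagResult:
    assignments: dict[str, Haplotype]
    n_informative: dict[str, int]
    # block each read was scored on (phase is relative per block)
    block_of: dict[str, int] = field(default_factory=dict)
    # per unphased singleton het SNP: read_id -> allele bit (0=REF, 1=ALT)
    site_groups: dict[int, dict[str, int]] = field(default_factory=dict)


def haplotag_reads(
    matrix: AlleleMatrix,
    blocks: Sequence[PhasedBlock],
    mode: HaplotagMode = HaplotagMode.PHASED_ONLY,
    min_sites: int = 1,
) -> HaplotagResult:
    """Assign each read to H1/H2 by majority vote over phased SNP alleles.

    A read spanning several blocks is scored on the block where it covers
    the most informative sites; the assignment requires a vote margin of
    at least one, otherwise the read stays UNTAGGED.  In
    WITH_UNPHASED_SNPS mode, reads are additionally partitioned at
    singleton (unphased) het SNPs into per-site allele groups, which is
    useful when phased blocks are short.
    """
    var_block: dict[int, tuple[int, int]] = {}
    for block in blocks:
        for vi in block.variant_indices:
            var_block[vi] = (block.block_id, block.hap1_allele[vi])
    phased = set(var_block)
    assignments: dict[str, Haplotype] = {}
    n_informative: dict[str, int] = {}
    block_of: dict[str, int] = {}
    for read_id in matrix.cells:
        info = matrix.informative(read_id)
        votes: dict[int, list[int]] = defaultdict(list)  # block -> h1-match flags
        for vi, bit in info.items():
            if vi in phased:
                block_id, h1_bit = var_block[vi]
                votes[block_id].append(1 if bit == h1_bit else 0)
        if not votes:
            assignments[read_id] = Haplotype.UNTAGGED
            n_informative[read_id] = 0
            continue
        block_id = max(votes, key=lambda b: (len(votes[b]), -b))
        flags = votes[block_id]
        block_of[read_id] = block_id
        n_informative[read_id] = len(flags)
        h1 = sum(flags)
        h2 = len(flags) - h1
        if len(flags) < min_sites or h1 == h2:
            assignments[read_id] = Haplotype.UNTAGGED
        else:
            assignments[read_id] = Haplotype.H1 if h1 > h2 else Haplotype.H2
    result = HaplotagResult(assignments, n_informative, block_of)
    if mode is HaplotagMode.WITH_UNPHASED_SNPS:
        singleton = {
            i
            for i, v in enumerate(matrix.variants)
            if v.kind is VariantKind.HET_SNP and i not in phased
        }
        for read_id in matrix.cells:
            for vi, bit in matrix.informative(read_id).items():
                if vi in singleton:
                    result.site_groups.setdefault(vi, {})[read_id] = bit
    return result


def classify_by_snv(
    matrix: AlleleMatrix, per_locus: bool = False
) -> dict[str, SNVClass] | dict[int, dict[str, SNVClass]]:
    """Separate reads with and without somatic SNVs.

    Genome-wide mode (default): a read supporting ALT at any covered SNV
    is SNV_PLUS; one supporting REF at every covered SNV (and covering at
    least one) is SNV_MINUS; reads covering SNVs only ambiguously, or not
    at all, are UNASSIGNED.  Classification is independent of allele
    frequency.  ``per_locus`` returns the same dichotomy per SNV site.
    """
    snv_indices = {
        i for i, v in enumerate(matrix.variants) if v.kind is VariantKind.SOMATIC_SNV
    }
    if per_locus:
        out_locus: dict[int, dict[str, SNVClass]] = {i: {} for i in snv_indices}
        for read_id in matrix.cells:
            for vi, bit in matrix.informative(read_id).items():
                if vi in snv_indices:
                    out_locus[vi][read_id] = (
                        SNVClass.SNV_PLUS if bit == 1 else SNVClass.SNV_MINUS
                    )
        return out_locus
    out: dict[str, SNVClass] = {}
    for read_id in matrix.cells:
        info = matrix.informative(read_id)
        snv_bits = [bit for vi, bit in info.items() if vi in snv_indices]
        if any(bit == 1 for bit in snv_bits):
            out[read_id] = SNVClass.SNV_PLUS
        elif snv_bits:
            out[read_id] = SNVClass.SNV_MINUS
        else:
            out[read_id] = SNVClass.UNASSIGNED
    return out


@dataclass
class PhasingMetrics:
    switch_error_rate: float | None
    n_comparable_pairs: int
    n_switches: int
    block_n50_length: int


def _block_maps(
    blocks: Sequence[PhasedBlock],
) -> dict[int, tuple[int, int]]:
    out = {}
    for block in blocks:
        for vi in block.variant_indices:
            out[vi] = (block.block_id, block.hap1_allele[vi])
    return out


def switch_error_rate(
    test: Sequence[PhasedBlock],
    truth: Sequence[PhasedBlock],
    variants: Sequence[HetVariant],
) -> PhasingMetrics:
    """Switch errors of a test phasing against a truth phasing.

    For consecutive variant pairs phased in both inputs -- and lying
    within one test block and one truth block -- a switch is counted when
    the relative orientation of the pair differs.  Phase is relative, so
    the metric is invariant to flipping any block globally.  Block N50 is
    reported over the genomic spans of the test blocks.
    """
    test_map = _block_maps(test)
    truth_map = _block_maps(truth)
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    n_pairs = 0
    n_switches = 0
    for a, b in zip(order, order[1:]):
        if variants[a].chrom != variants[b].chrom:
            continue
        if a not in test_map or b not in test_map or a not in truth_map or b not in truth_map:
            continue
        if test_map[a][0] != test_map[b][0] or truth_map[a][0] != truth_map[b][0]:
            continue
        rel_test = test_map[a][1] ^ test_map[b][1]
        rel_truth = truth_map[a][1] ^ truth_map[b][1]
        n_pairs += 1
        if rel_test != rel_truth:
            n_switches += 1
    spans = sorted(
        (
            variants[block.variant_indices[-1]].pos
            - variants[block.variant_indices[0]].pos
            + 1
            for block in test
        ),
        reverse=True,
    )
    n50 = 0
    if spans:
        half = sum(spans) / 2
        acc = 0
        for s in spans:
            acc += s
            if acc >= half:
                n50 = s
                break
    rate = n_switches / n_pairs if n_pairs else None
    return PhasingMetrics(rate, n_pairs, n_switches, n50)


def haplotag_accuracy(
    result: HaplotagResult, truth_haplotype: Mapping[str, int]
) -> float | None:
    """Fraction of tagged reads matching a truth haplotype assignment.

    Haplotype labels are only defined up to a global flip within each
    phased block, so agreement is scored per scoring block under its
    best orientation.  Returns None when no read was tagged.
    """
    per_block: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    for read_id, tag in result.assignments.items():
        if tag is Haplotype.UNTAGGED or read_id not in truth_haplotype:
            continue
        called = 0 if tag is Haplotype.H1 else 1
        counts = per_block[result.block_of[read_id]]
        counts[called == truth_haplotype[read_id]] += 1
    total = sum(a + b for a, b in per_block.values())
    if total == 0:
        return None
    correct = sum(max(a, b) for a, b in per_block.values())
    return correct / total


def truth_blocks_from_phase(
    variants: Sequence[HetVariant], phase_bits: Mapping[int, int] | np.ndarray
) -> list[PhasedBlock]:
    """Build one truth block per chromosome from simulated phase bits."""
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, v in enumerate(variants):
        if v.kind is VariantKind.HET_SNP:
            by_chrom[v.chrom].append(i)
    blocks = []
    for chrom in sorted(by_chrom):
        indices = by_chrom[chrom]
        if len(indices) < 2:
            continue
        bits = {i: int(phase_bits[i]) for i in indices}
        blocks.append(PhasedBlock(len(blocks), indices, bits))
    return blocks
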