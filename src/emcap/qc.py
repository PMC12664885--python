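"""Duplicate marking and hybridization-capture enrichment metrics.

Single-end long-read PCR duplicates are identified by a shared
(chromosome, orientation, unclipped 5' start) key, the long-read analogue
of the common single-end duplicate definition; an optional end-aware
mode also requires the 3' ends to agree within a tolerance, for
libraries where start-jitter alone over-merges.  Enrichment metrics
follow the standard hybrid-selection definitions:

    mean bait coverage = on-target aligned bases / target territory
    fold enrichment    = (on-target aligned bases / total aligned bases)
                         / (territory / genome size)

computed over non-duplicate primary alignments with clipped bases
excluded.  The on-target overlap rate counts mapped reads intersecting
any target by at least one base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class AlnRecord:
    """Minimal single-end alignment record for QC purposes.

    ``blocks`` are the reference-consuming aligned segments (half-open);
    ``clip_left``/``clip_right`` are soft+hard clip lengths on the
    reference-left/right side of the alignment.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    is_reverse: bool = False
    clip_left: int = 0
    clip_right: int = 0
    blocks: list[tuple[int, int]] = field(default_factory=list)
    read_length: int = 0
    is_primary: bool = True
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            self.blocks = [(self.start, self.end)]
        if not self.read_length:
            self.read_length = sum(e - s for s, e in self.blocks)

    @property
    def unclipped_5p(self) -> int:
        """Unclipped position of the read's 5' end on the reference."""
        if self.is_reverse:
            return self.end + self.clip_right
        return self.start - self.clip_left

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


class TargetSet:
    """Merged, disjoint capture-target intervals with fast overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        territory = 0
        for chrom, ivs in by_chrom.items():
            merged: list[tuple[int, int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self.starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self.ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)
            territory += int(sum(e - s for s, e in merged))
        if territory <= 0:
            raise ValueError("target territory must be positive")
        self.territory = territory

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.starts):
            for s, e in zip(self.starts[chrom], self.ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) inside the targets."""
        if chrom not in self.starts:
            return 0
        starts, ends = self.starts[chrom], self.ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0
        for i in range(lo, hi):
            total += max(0, min(end, int(ends[i])) - max(start, int(starts[i])))
        return total

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.starts:
            return False
        starts, ends = self.starts[chrom], self.ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        return lo < len(starts) and int(starts[lo]) < end


@dataclass
class HsMetrics:
    mean_bait_coverage: float
    fold_enrichment: float
    on_target_read_rate: float
    duplicate_rate: float
    read_n50: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mark_duplicates(
    alignments: Sequence[AlnRecord],
    end_tolerance: int | None = None,
) -> float:
    """Flag PCR duplicates in coordinate-sorted primary alignments.

    Duplicates share (chrom, orientation, unclipped 5' start); with
    ``end_tolerance`` set, the 3' ends must additionally agree within the
    tolerance, so distinct molecules with a coincidental shared start are
    kept apart.  The representative of each group is the longest aligned
    span (ties broken by read_id); re-running is a no-op.  Returns the
    duplicate rate (flagged / total primary).
    """
    last: dict[str, int] = {}
    for aln in alignments:
        if aln.chrom in last and aln.start < last[aln.chrom]:
            raise ValueError("alignments must be coordinate-sorted")
        last[aln.chrom] = aln.start
    groups: dict[tuple, list[AlnRecord]] = {}
    primaries = [a for a in alignments if a.is_primary]
    for aln in primaries:
        aln.is_duplicate = False
        groups.setdefault((aln.chrom, aln.is_reverse, aln.unclipped_5p), []).append(aln)
    flagged = 0
    for members in groups.values():
        if end_tolerance is not None:
            subgroups: list[list[AlnRecord]] = []
            for aln in sorted(members, key=lambda a: a.end):
                placed = False
                for sub in subgroups:
                    if abs(aln.end - sub[-1].end) <= end_tolerance:
                        sub.append(aln)
                        placed = True
                        break
                if not placed:
                    subgroups.append([aln])
        else:
            subgroups = [members]
        for sub in subgroups:
            if len(sub) < 2:
                continue
            rep = max(sub, key=lambda a: (a.end - a.start, a.read_id))
            for aln in sub:
                if aln is not rep:
                    aln.is_duplicate = True
                    flagged += 1
    return flagged / len(primaries) if primaries else 0.0


def _usable(alignments: Iterable[AlnRecord], include_duplicates: bool) -> list[AlnRecord]:
    return [
        a
        for a in alignments
        if a.is_primary and (include_duplicates or not a.is_duplicate)
    ]


def hs_metrics(
    alignments: Sequence[AlnRecord],
    targets: TargetSet,
    genome_size: int,
    include_duplicates: bool = False,
) -> HsMetrics:
    """Hybrid-selection metrics over non-duplicate primary alignments."""
    if genome_size < targets.territory:
        raise ValueError("genome_size must be >= target territory")
    usable = _usable(alignments, include_duplicates)
    total_aligned = sum(a.aligned_bases for a in usable)
    if total_aligned == 0:
        warnings.warn("no aligned bases; reporting zero metrics", stacklevel=2)
        return HsMetrics(0.0, 0.0, 0.0, _dup_rate(alignments), 0)
    on_target = 0
    for aln in usable:
        for s, e in aln.blocks:
            on_target += targets.overlap_bases(aln.chrom, s, e)
    mean_bait_cov = on_target / targets.territory
    fold = (on_target / total_aligned) / (targets.territory / genome_size)
    on_rate = overlap_rate(alignments, targets, include_duplicates)
    _, _, n50 = read_length_stats([a.read_length for a in usable])
    return HsMetrics(mean_bait_cov, fold, on_rate, _dup_rate(alignments), n50)


def _dup_rate(alignments: Sequence[AlnRecord]) -> float:
    primaries = [a for a in alignments if a.is_primary]
    if not primaries:
        return 0.0
    return sum(a.is_duplicate for a in primaries) / len(primaries)


def overlap_rate(
    alignments: Sequence[AlnRecord],
    targets: TargetSet,
    include_duplicates: bool = False,
) -> float:
    """Fraction of mapped primary reads overlapping any target by >= 1 bp."""
    usable = _usable(alignments, include_duplicates)
    if not usable:
        return 0.0
    n_on = sum(targets.overlaps(a.chrom, a.start, a.end) for a in usable)
    return n_on / len(usable)


def cpg_read_coverage(
    alignments: Sequence[AlnRecord],
    cpg_positions: np.ndarray,
    chrom: str,
    include_duplicates: bool = False,
) -> np.ndarray:
    """Read coverage at each CpG position (the C) on one chromosome."""
    pos = np.asarray(cpg_positions, dtype=np.int64)
    cov = np.zeros(len(pos), dtype=np.int64)
    for aln in _usable(alignments, include_duplicates):
        if aln.chrom != chrom:
            continue
        for s, e in aln.blocks:
            lo = np.searchsorted(pos, s)
            hi = np.searchsorted(pos, e)
            cov[lo:hi] += 1
    return cov


def cpg_coverage_fraction(
    coverage: np.ndarray, thresholds: Sequence[int]
) -> dict[int, float]:
    """Fraction of CpGs with coverage >= t for each threshold t."""
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be increasing")
    cov = np.asarray(coverage)
    n = len(cov)
    if n == 0:
        return {t: 0.0 for t in thresholds}
    return {t: float(np.count_nonzero(cov >= t) / n) for t in thresholds}


def read_length_stats(lengths: Sequence[int]) -> tuple[int, int, int]:
    """(total bases, read count, N50).

    N50 is the largest length L such that reads of length >= L together
    contain at least half of all sequenced bases.
    """
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        return 0, 0, 0
    if any(x < 0 for x in lengths):
        raise ValueError("read lengths must be non-negative")
    total = sum(lengths)
    half = total / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return total, len(lengths), L
    return total, len(lengths), lengths[-1]
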