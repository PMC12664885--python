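"""Base-conversion semantics of enzymatic methyl sequencing (EM-seq).

In an EM-seq library every unmethylated cytosine is enzymatically
deaminated to uracil and amplified as thymine, while 5-methylcytosine is
protected.  A double-stranded library therefore yields reads in one of two
*conversion spaces*: reads from the original top strand show C->T changes
relative to the reference (``CT`` space) and reads from the original
bottom strand show G->A changes (``GA`` space).  Everything downstream --
allele assignment at heterozygous SNPs, somatic-SNV read classification
and per-CpG methylation calling -- must reason inside this asymmetric
observation model, which is what this module encodes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# uint8 ASCII codes used for vectorised sequence work
A, C, G, T, N = 65, 67, 71, 84, 78
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_VALID = frozenset("ACGT")


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 ASCII array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode_seq(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class ConversionSpace(enum.Enum):
    """Which strand-conversion frame an aligned converted read lives in."""

    CT = "CT"
    GA = "GA"
    UNKNOWN = "UNKNOWN"


class AlleleSupport(enum.Enum):
    """Outcome of comparing an observed base with a ref/alt pair."""

    REF = "REF"
    ALT = "ALT"
    AMBIGUOUS = "AMBIGUOUS"
    OTHER = "OTHER"


class MethylState(enum.Enum):
    METHYLATED = "METHYLATED"
    UNMETHYLATED = "UNMETHYLATED"
    UNINFORMATIVE = "UNINFORMATIVE"


def _require_known_space(space: ConversionSpace) -> None:
    if space is ConversionSpace.UNKNOWN:
        raise ValueError("conversion space must be CT or GA, not UNKNOWN")


def convert_base(base: str, space: ConversionSpace, methylated: bool) -> str:
    """Apply the EM-seq conversion rule to a single reference base.

    In CT space an unmethylated C reads as T (deaminated to U, amplified
    as T) and a methylated C is protected; in GA space the same rule acts
    on the complementary strand, so G reads as A when the paired C was
    unmethylated.  All other bases pass through unchanged.
    """
    _require_known_space(space)
    if base not in _VALID:
        raise ValueError(f"invalid base {base!r}")
    if space is ConversionSpace.CT and base == "C":
        return "C" if methylated else "T"
    if space is ConversionSpace.GA and base == "G":
        return "G" if methylated else "A"
    return base


def observation_set(allele: str, space: ConversionSpace) -> frozenset[str]:
    """All read bases an allele can produce (closure over methylation state)."""
    _require_known_space(space)
    if allele not in _VALID:
        raise ValueError(f"invalid allele {allele!r}")
    if space is ConversionSpace.CT and allele == "C":
        return frozenset("CT")
    if space is ConversionSpace.GA and allele == "G":
        return frozenset("GA")
    return frozenset(allele)


def allele_support(
    space: ConversionSpace, ref: str, alt: str, observed: str
) -> AlleleSupport:
    """Classify an observed base against a biallelic site under conversion.

    Any genomic C (CpG or not) is treated as possibly methylated, so the
    observation set of C in CT space is {C, T}; this is the conservative
    choice because EM-seq gives no guarantee about the methylation state
    of a specific cytosine.  A base reachable from both alleles is
    AMBIGUOUS (e.g. T at a C/T site in CT space), one reachable from
    neither is OTHER.  N is always OTHER.
    """
    _require_known_space(space)
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if observed == "N":
        return AlleleSupport.OTHER
    if observed not in _VALID:
        raise ValueError(f"invalid observed base {observed!r}")
    obs_ref = observation_set(ref, space)
    obs_alt = observation_set(alt, space)
    in_ref = observed in obs_ref
    in_alt = observed in obs_alt
    if in_ref and in_alt:
        return AlleleSupport.AMBIGUOUS
    if in_ref:
        return AlleleSupport.REF
    if in_alt:
        return AlleleSupport.ALT
    return AlleleSupport.OTHER


def restore_base(space: ConversionSpace, ref: str, alt: str, observed: str) -> str:
    """Restore the original base at a variant site, or N when ambiguous."""
    support = allele_support(space, ref, alt, observed)
    if support is AlleleSupport.REF:
        return ref
    if support is AlleleSupport.ALT:
        return alt
    return "N"


@dataclass
class AlignedConvertedRead:
    """An aligned converted read plus its conversion space.

    ``read_offsets`` and ``ref_positions`` are the matched (M) columns of
    the alignment, both strictly increasing; insertions and deletions are
    simply absent, so a lookup at a deleted reference position returns N.
    Coordinates are 0-based.
    """

    read_id: str
    chrom: str
    read_offsets: np.ndarray
    ref_positions: np.ndarray
    read_bases: str
    is_primary: bool = True
    space: ConversionSpace = ConversionSpace.UNKNOWN
    mapq: int = 60
    _codes: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.read_offsets = np.asarray(self.read_offsets, dtype=np.int64)
        self.ref_positions = np.asarray(self.ref_positions, dtype=np.int64)
        if len(self.read_offsets) != len(self.ref_positions):
            raise ValueError("read_offsets and ref_positions length mismatch")
        if len(self.ref_positions) == 0:
            raise ValueError("read has no aligned bases")
        if np.any(np.diff(self.ref_positions) <= 0):
            raise ValueError("reference positions must be strictly increasing")
        if np.any(np.diff(self.read_offsets) <= 0):
            raise ValueError("read offsets must be strictly increasing")
        if self._codes is None:
            self._codes = encode_seq(self.read_bases)

    @property
    def start(self) -> int:
        """Smallest aligned reference position."""
        return int(self.ref_positions[0])

    @property
    def end(self) -> int:
        """One past the largest aligned reference position."""
        return int(self.ref_positions[-1]) + 1

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.read_offsets.tolist(), self.ref_positions.tolist()))

    def codes_at(self, positions: np.ndarray) -> np.ndarray:
        """uint8 base codes at reference positions (N where unaligned)."""
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.ref_positions, positions)
        idx_clip = np.minimum(idx, len(self.ref_positions) - 1)
        hit = self.ref_positions[idx_clip] == positions
        out = np.full(len(positions), N, dtype=np.uint8)
        if hit.any():
            out[hit] = self._codes[self.read_offsets[idx_clip[hit]]]
        return out

    def base_at(self, position: int) -> str:
        return chr(self.codes_at(np.array([position]))[0])


def classify_read_space(
    read: AlignedConvertedRead,
    reference: np.ndarray | str,
    variant_positions: Iterable[int] = (),
    min_count: int = 10,
    ratio: float = 0.8,
) -> ConversionSpace:
    """Infer a read's conversion space from its mismatch pattern.

    Counts reference-C positions read as T (CT evidence) and reference-G
    positions read as A (GA evidence), excluding known variant sites, and
    requires both an absolute count and a dominance ratio.  Converted
    multi-kilobase reads carry hundreds of conversions, so the defaults
    are generous; reads failing them are UNKNOWN and excluded downstream.
    """
    ref = encode_seq(reference) if isinstance(reference, str) else reference
    ref_b = ref[read.ref_positions]
    read_b = read._codes[read.read_offsets]
    var = np.fromiter(variant_positions, dtype=np.int64) if variant_positions else None
    if var is not None and len(var):
        keep = ~np.isin(read.ref_positions, var)
        ref_b, read_b = ref_b[keep], read_b[keep]
    n_ct = int(np.count_nonzero((ref_b == C) & (read_b == T)))
    n_ga = int(np.count_nonzero((ref_b == G) & (read_b == A)))
    total = n_ct + n_ga
    if total == 0:
        return ConversionSpace.UNKNOWN
    if n_ct >= min_count and n_ct / total >= ratio:
        return ConversionSpace.CT
    if n_ga >= min_count and n_ga / total >= ratio:
        return ConversionSpace.GA
    return ConversionSpace.UNKNOWN


def cpg_call_for_read(
    read: AlignedConvertedRead, cpg_position: int
) -> MethylState:
    """Vote of one read at one top-strand CpG (the C at ``cpg_position``).

    CT-space reads are informative through the C itself (C = methylated,
    T = unmethylated); GA-space reads through the paired G one base
    downstream (G = methylated, A = unmethylated).  Anything else --
    including a deleted base or an UNKNOWN-space read -- is uninformative.
    """
    if read.space is ConversionSpace.CT:
        b = read.base_at(cpg_position)
        if b == "C":
            return MethylState.METHYLATED
        if b == "T":
            return MethylState.UNMETHYLATED
    elif read.space is ConversionSpace.GA:
        b = read.base_at(cpg_position + 1)
        if b == "G":
            return MethylState.METHYLATED
        if b == "A":
            return MethylState.UNMETHYLATED
    return MethylState.UNINFORMATIVE


def call_cpg_methylation(
    reads: Iterable[AlignedConvertedRead],
    cpg_positions: Sequence[int] | np.ndarray,
    reference: np.ndarray | str,
    exclude_variants: Iterable[int] = (),
    chrom: str = "",
) -> pd.DataFrame:
    """Destranded per-CpG methylated/unmethylated counts for one read group.

    Votes from both conversion spaces are pooled into a single record
    keyed by the position of the top-strand C.  CpGs overlapping
    ``exclude_variants`` (at the C or the G) are dropped, since a variant
    there breaks the observation model.  Only primary reads with a known
    conversion space contribute.

    Returns a DataFrame with columns chrom, pos, n_meth, n_unmeth, rate.
    """
    ref = encode_seq(reference) if isinstance(reference, str) else reference
    pos = np.asarray(cpg_positions, dtype=np.int64)
    bad = (ref[pos] != C) | (ref[np.minimum(pos + 1, len(ref) - 1)] != G) | (
        pos + 1 >= len(ref)
    )
    if bad.any():
        raise ValueError(
            f"position {int(pos[bad][0])} is not a C followed by G in the reference"
        )
    excl = set(exclude_variants)
    if excl:
        keep = np.array([p not in excl and p + 1 not in excl for p in pos])
        pos = pos[keep]
    n_meth = np.zeros(len(pos), dtype=np.int64)
    n_unmeth = np.zeros(len(pos), dtype=np.int64)
    for read in reads:
        if not read.is_primary or read.space is ConversionSpace.UNKNOWN:
            continue
        lo = np.searchsorted(pos, read.start - 1)
        hi = np.searchsorted(pos, read.end)
        if hi <= lo:
            continue
        idx = np.arange(lo, hi)
        if read.space is ConversionSpace.CT:
            obs = read.codes_at(pos[idx])
            meth, unmeth = obs == C, obs == T
        else:
            obs = read.codes_at(pos[idx] + 1)
            meth, unmeth = obs == G, obs == A
        np.add.at(n_meth, idx[meth], 1)
        np.add.at(n_unmeth, idx[unmeth], 1)
    cov = n_meth + n_unmeth
    with np.errstate(invalid="ignore"):
        rate = np.where(cov > 0, n_meth / np.maximum(cov, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
            "rate": rate,
        }
    )
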