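"""Synthetic targeted long-read EM-seq experiments with full ground truth.

The generator emulates the whole wet-lab stack at desk scale: a single
synthetic chromosome with CpG-island-bearing capture targets, phased
heterozygous SNPs, clonal somatic SNVs inside the targets, a
per-haplotype per-CpG methylome with planted allele-specific (ASM),
between-sample and SNV-linked differential regions, and a capture
library of converted long reads with PCR duplicates, nanopore-like
errors and, in multiplex mode, dual-index barcodes inside retained
P5/P7 flanks.

Methylation is drawn per molecule per CpG from the probability table, so
allele- and SNV-linked patterns are coherent along each molecule, as
long reads require.  Every emitted read has exactly one truth record,
and a running tally of molecule-level methylation states at covered CpGs
supports exact comparisons against the methylation caller.

Default parameters describe the experiment the generator emulates:
5 Mb genome, het SNPs at 1/1,500 bp, lognormal fragments with a 5 kb
N50, 30x coverage, 90% on-target capture, conversion efficiency 0.995
with 0.005 over-conversion, and 1%/0.5%/0.5% substitution/insertion/
deletion error.  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .conversion import (
    A,
    C,
    G,
    T,
    AlignedConvertedRead,
    ConversionSpace,
    decode_seq,
    reverse_complement,
)
from .demux import P5_FLANK, P7_FLANK, BarcodePair, FastqRecord
from .phasing import HetVariant, VariantKind

_BASES = np.array([A, C, G, T], dtype=np.uint8)
_CODE_TO_IDX = np.zeros(128, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE_TO_IDX[_b] = _i


@dataclass
class PlantConfig:
    """A family of planted differential-methylation regions."""

    n_regions: int = 0
    n_cpgs: int = 20
    diff: float = 0.8


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "sim1"
    genome_length: int = 5_000_000
    gc_content: float = 0.41
    n_targets: int = 40
    target_length: int = 3_000
    island_length: int = 1_000
    het_snp_rate: float = 1.0 / 1500.0
    n_somatic_snvs: int = 50
    snv_vaf: float = 0.3
    fragment_n50: int = 5_000
    fragment_sigma: float = 0.4
    min_fragment: int = 500
    coverage: float = 30.0
    p_on_target: float = 0.9
    duplicate_rate: float = 0.1
    conversion_efficiency: float = 0.995
    over_conversion_rate: float = 0.005
    substitution_rate: float = 0.01
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005
    samples: tuple[str, ...] = ("S1",)
    barcodes: tuple[BarcodePair, ...] | None = None
    index_hop_rate: float = 0.0
    distinguishable_only: bool = False
    asm: PlantConfig = field(default_factory=lambda: PlantConfig(4, 20, 0.8))
    group_dmr: PlantConfig = field(default_factory=PlantConfig)
    snv_linked: PlantConfig = field(default_factory=PlantConfig)

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "het_snp_rate",
            "snv_vaf",
            "p_on_target",
            "duplicate_rate",
            "conversion_efficiency",
            "over_conversion_rate",
            "substitution_rate",
            "insertion_rate",
            "deletion_rate",
            "index_hop_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.barcodes is not None:
            self.samples = tuple(b.sample_id for b in self.barcodes)
        if self.genome_length < 10 * self.fragment_n50:
            raise ValueError("genome_length must be >= 10x the fragment N50")


@dataclass
class Reference:
    chrom: str
    codes: np.ndarray  # uint8
    cpg_positions: np.ndarray
    targets: list[tuple[int, int]]
    islands: list[tuple[int, int]]

    @property
    def sequence(self) -> str:
        return decode_seq(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class VariantSet:
    hets: list[HetVariant]
    phase: np.ndarray  # allele bit on haplotype 1 per het SNP
    snvs: list[HetVariant]

    @property
    def all_variants(self) -> list[HetVariant]:
        return sorted(self.hets + self.snvs, key=lambda v: v.pos)


@dataclass
class PlantTruth:
    kind: str  # ASM | GROUP | SNV
    start: int
    end: int
    cpg_lo: int  # CpG index range [lo, hi)
    cpg_hi: int
    diff: float
    detail: str = ""


@dataclass
class Methylome:
    """Per-sample, per-haplotype CpG methylation probabilities."""

    probs: np.ndarray  # (n_samples, 2, n_cpgs)
    snv_overrides: list[tuple[int, int, float, float]]  # lo, hi, p_carrier, p_clean
    plants: list[PlantTruth]

    def molecule_probs(
        self, sample: int, hap: int, carrier: bool, lo: int, hi: int
    ) -> np.ndarray:
        p = self.probs[sample, hap, lo:hi].copy()
        for olo, ohi, p_car, p_clean in self.snv_overrides:
            s, e = max(lo, olo), min(hi, ohi)
            if s < e:
                p[s - lo : e - lo] = p_car if carrier else p_clean
        return p


def simulate_reference(config: SimConfig, rng: np.random.Generator) -> Reference:
    """Synthetic chromosome with CpG islands centred in capture targets."""
    L = config.genome_length
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = _BASES[np.searchsorted(np.cumsum(p), rng.random(L), side="right")]
    targets: list[tuple[int, int]] = []
    islands: list[tuple[int, int]] = []
    if config.n_targets:
        spacing = L // (config.n_targets + 1)
        if config.target_length >= spacing or config.island_length > config.target_length:
            raise ValueError("infeasible target geometry for this genome length")
        for i in range(1, config.n_targets + 1):
            center = i * spacing
            targets.append(
                (center - config.target_length // 2, center + config.target_length // 2)
            )
            islands.append(
                (center - config.island_length // 2, center + config.island_length // 2)
            )
        # CpG-island sequence: GC-rich background plus explicit CpG planting
        for s, e in islands:
            n = e - s
            pgc = np.array([0.175, 0.325, 0.325, 0.175])
            codes[s:e] = _BASES[
                np.searchsorted(np.cumsum(pgc), rng.random(n), side="right")
            ]
            plant = np.nonzero(rng.random(n - 1) < 0.08)[0]
            codes[s + plant] = C
            codes[s + plant + 1] = G
    cpg = np.nonzero((codes[:-1] == C) & (codes[1:] == G))[0]
    return Reference(config.chrom, codes, cpg, targets, islands)


_AMBIGUOUS_PAIRS = {frozenset("CT"), frozenset("GA")}


def _draw_alt(ref_code: int, rng: np.random.Generator, distinguishable_only: bool) -> str:
    ref_base = chr(ref_code)
    options = [b for b in "ACGT" if b != ref_base]
    if distinguishable_only:
        options = [
            b for b in options if frozenset((ref_base, b)) not in _AMBIGUOUS_PAIRS
        ]
    return options[rng.integers(len(options))]


def simulate_variants(
    config: SimConfig, reference: Reference, rng: np.random.Generator
) -> VariantSet:
    """Phased het SNPs genome-wide and clonal somatic SNVs inside islands."""
    L = len(reference)
    het_pos = np.nonzero(rng.random(L - 1) < config.het_snp_rate)[0]
    hets = [
        HetVariant(
            reference.chrom,
            int(p),
            chr(reference.codes[p]),
            _draw_alt(reference.codes[p], rng, config.distinguishable_only),
            VariantKind.HET_SNP,
        )
        for p in het_pos
    ]
    phase = rng.integers(0, 2, size=len(hets))
    snvs: list[HetVariant] = []
    if config.n_somatic_snvs and reference.islands:
        island_pos = np.concatenate(
            [np.arange(s, e - 1) for s, e in reference.islands]
        )
        island_pos = np.setdiff1d(island_pos, het_pos)
        if len(island_pos) < config.n_somatic_snvs:
            raise ValueError("not enough island positions for requested SNVs")
        chosen = np.sort(
            rng.choice(island_pos, size=config.n_somatic_snvs, replace=False)
        )
        snvs = [
            HetVariant(
                reference.chrom,
                int(p),
                chr(reference.codes[p]),
                _draw_alt(reference.codes[p], rng, config.distinguishable_only),
                VariantKind.SOMATIC_SNV,
            )
            for p in chosen
        ]
    return VariantSet(hets, phase, snvs)


def _cpg_index_range(
    cpg_positions: np.ndarray, start: int, end: int
) -> tuple[int, int]:
    return (
        int(np.searchsorted(cpg_positions, start)),
        int(np.searchsorted(cpg_positions, end)),
    )


def simulate_methylome(
    config: SimConfig,
    reference: Reference,
    variants: VariantSet,
    rng: np.random.Generator,
) -> Methylome:
    """Per-haplotype methylome with planted ASM / group / SNV-linked regions.

    Island CpGs are hypomethylated (Beta(1, 10)) and open-sea CpGs
    hypermethylated (Beta(10, 1)), the canonical vertebrate pattern.  The
    baseline is shared across samples and haplotypes so that only planted
    regions are truly differential.  Plants occupy whole islands (one
    plant per island) so they sit inside covered targets; overlap is
    excluded by construction and checked.
    """
    cpg = reference.cpg_positions
    n_cpgs = len(cpg)
    n_samples = len(config.samples)
    base = np.empty(n_cpgs)
    in_island = np.zeros(n_cpgs, dtype=bool)
    for s, e in reference.islands:
        lo, hi = _cpg_index_range(cpg, s, e)
        in_island[lo:hi] = True
    base[in_island] = rng.beta(1, 10, size=int(in_island.sum()))
    base[~in_island] = rng.beta(10, 1, size=int((~in_island).sum()))
    probs = np.broadcast_to(base, (n_samples, 2, n_cpgs)).copy()

    snv_pos = np.array([v.pos for v in variants.snvs], dtype=np.int64)
    plants: list[PlantTruth] = []
    overrides: list[tuple[int, int, float, float]] = []
    used: set[int] = set()

    def island_slots(require_snv: bool, n_cpgs_needed: int) -> list[int]:
        out = []
        for k, (s, e) in enumerate(reference.islands):
            if k in used:
                continue
            lo, hi = _cpg_index_range(cpg, s, e)
            if hi - lo < n_cpgs_needed:
                continue
            if require_snv and not np.any((snv_pos >= s) & (snv_pos < e)):
                continue
            out.append(k)
        return out

    def take_window(k: int, n: int) -> tuple[int, int]:
        s, e = reference.islands[k]
        lo, hi = _cpg_index_range(cpg, s, e)
        mid = (lo + hi) // 2
        wlo = max(lo, mid - n // 2)
        return wlo, wlo + n

    for spec_name, spec in (("ASM", config.asm), ("GROUP", config.group_dmr)):
        for _ in range(spec.n_regions):
            slots = island_slots(False, spec.n_cpgs)
            if not slots:
                raise ValueError(
                    f"not enough islands for requested {spec_name} plants"
                )
            k = slots[int(rng.integers(len(slots)))]
            used.add(k)
            lo, hi = take_window(k, spec.n_cpgs)
            p_high = 0.5 + spec.diff / 2
            p_low = 0.5 - spec.diff / 2
            if spec_name == "ASM":
                high_hap = int(rng.integers(2))
                probs[:, high_hap, lo:hi] = p_high
                probs[:, 1 - high_hap, lo:hi] = p_low
                detail = f"high_hap=H{high_hap + 1}"
            else:
                high_sample = int(rng.integers(n_samples))
                probs[:, :, lo:hi] = p_low
                probs[high_sample, :, lo:hi] = p_high
                detail = f"high_sample={config.samples[high_sample]}"
            plants.append(
                PlantTruth(
                    spec_name,
                    int(cpg[lo]),
                    int(cpg[hi - 1]) + 2,
                    lo,
                    hi,
                    spec.diff,
                    detail,
                )
            )
    for _ in range(config.snv_linked.n_regions):
        spec = config.snv_linked
        slots = island_slots(True, spec.n_cpgs)
        if not slots:
            raise ValueError("not enough SNV-bearing islands for SNV-linked plants")
        k = slots[int(rng.integers(len(slots)))]
        used.add(k)
        lo, hi = take_window(k, spec.n_cpgs)
        p_high = 0.5 + spec.diff / 2
        p_low = 0.5 - spec.diff / 2
        overrides.append((lo, hi, p_high, p_low))
        plants.append(
            PlantTruth(
                "SNV", int(cpg[lo]), int(cpg[hi - 1]) + 2, lo, hi, spec.diff, ""
            )
        )
    return Methylome(probs, overrides, plants)


@dataclass
class ReadTruth:
    read_id: str
    sample: str
    haplotype: int  # 0 = H1, 1 = H2
    carrier: bool
    space: str
    start: int
    end: int
    duplicate_of: str | None
    on_target: bool


@dataclass
class SimulatedRead:
    read: AlignedConvertedRead
    fastq: FastqRecord
    truth: ReadTruth


class CpGTruthTally:
    """Molecule-level methylation states at CpGs covered informatively.

    Mirrors the methylation caller's informativity rule -- CT-space reads
    count at the C, GA-space reads at the paired G -- but uses the drawn
    molecule states instead of read bases, giving the exact truth the
    caller should reproduce on error-free input.
    """

    def __init__(self, n_samples: int, n_cpgs: int):
        self.n_meth = np.zeros((n_samples, 2, 2, n_cpgs), dtype=np.int64)
        self.n_unmeth = np.zeros((n_samples, 2, 2, n_cpgs), dtype=np.int64)

    def add(
        self,
        sample: int,
        hap: int,
        carrier: bool,
        cpg_idx: np.ndarray,
        states: np.ndarray,
    ) -> None:
        car = int(carrier)
        np.add.at(self.n_meth[sample, hap, car], cpg_idx[states], 1)
        np.add.at(self.n_unmeth[sample, hap, car], cpg_idx[~states], 1)

    def counts(
        self,
        sample: int | None = None,
        hap: int | None = None,
        carrier: bool | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sum counts over the unspecified axes."""

        def collapse(arr: np.ndarray) -> np.ndarray:
            x = arr
            x = x[sample] if sample is not None else x.sum(axis=0)
            x = x[hap] if hap is not None else x.sum(axis=0)
            x = x[int(carrier)] if carrier is not None else x.sum(axis=0)
            return x

        return collapse(self.n_meth), collapse(self.n_unmeth)


def _apply_errors(
    frag: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (read codes, read offsets of matches, fragment offsets of matches)."""
    n = len(frag)
    keep = rng.random(n) >= del_rate if del_rate > 0 else np.ones(n, dtype=bool)
    frag_idx = np.nonzero(keep)[0]
    bases = frag[keep].copy()
    m = len(bases)
    if m == 0:
        return np.empty(0, np.uint8), np.empty(0, np.int64), frag_idx
    if sub_rate > 0:
        sub = np.nonzero(rng.random(m) < sub_rate)[0]
        if len(sub):
            shift = rng.integers(1, 4, size=len(sub))
            bases[sub] = _BASES[(_CODE_TO_IDX[bases[sub]] + shift) % 4]
    if ins_rate > 0:
        ins_before = (rng.random(m + 1) < ins_rate).astype(np.int64)
    else:
        ins_before = np.zeros(m + 1, dtype=np.int64)
    offsets = np.arange(m) + np.cumsum(ins_before[:m])
    total = m + int(ins_before.sum())
    read = _BASES[rng.integers(0, 4, size=total)]
    read[offsets] = bases
    return read, offsets, frag_idx


class LibrarySimulator:
    """Streams converted reads from a reference + variants + methylome."""

    def __init__(
        self,
        config: SimConfig,
        reference: Reference,
        variants: VariantSet,
        methylome: Methylome,
        rng: np.random.Generator,
    ):
        self.config = config
        self.reference = reference
        self.variants = variants
        self.methylome = methylome
        self.rng = rng
        self.tally = CpGTruthTally(len(config.samples), len(reference.cpg_positions))
        self.het_pos = np.array([v.pos for v in variants.hets], dtype=np.int64)
        self.het_alt = np.array(
            [ord(v.alt) for v in variants.hets], dtype=np.uint8
        )
        self.snv_pos = np.array([v.pos for v in variants.snvs], dtype=np.int64)
        self.snv_alt = np.array(
            [ord(v.alt) for v in variants.snvs], dtype=np.uint8
        )
        sigma = config.fragment_sigma
        self.mu = math.log(config.fragment_n50) - sigma**2
        self.mean_fragment = math.exp(self.mu + sigma**2 / 2)

    @property
    def n_molecules(self) -> int:
        return int(
            round(
                self.config.coverage
                * self.config.genome_length
                / self.mean_fragment
            )
        )

    def _fragment(self) -> tuple[int, int, bool]:
        cfg, rng = self.config, self.rng
        L = len(self.reference)
        length = int(rng.lognormal(self.mu, cfg.fragment_sigma))
        length = max(cfg.min_fragment, min(length, L // 2))
        on_target = bool(self.reference.targets) and rng.random() < cfg.p_on_target
        if on_target:
            t = self.reference.targets[int(rng.integers(len(self.reference.targets)))]
            anchor = int(rng.integers(t[0], t[1]))
            start = min(max(0, anchor - length // 2), L - length)
        else:
            start = int(rng.integers(0, L - length + 1))
        return start, length, on_target

    def _molecule(self, read_id: str, sample: int):
        cfg, rng = self.config, self.rng
        cpg = self.reference.cpg_positions
        start, length, on_target = self._fragment()
        frag = self.reference.codes[start : start + length].copy()
        hap = int(rng.integers(2))
        lo = np.searchsorted(self.het_pos, start)
        hi = np.searchsorted(self.het_pos, start + length)
        if hi > lo:
            bits = self.variants.phase[lo:hi]
            on_this_hap = bits == 1 if hap == 0 else bits == 0
            rel = self.het_pos[lo:hi][on_this_hap] - start
            frag[rel] = self.het_alt[lo:hi][on_this_hap]
        carrier = bool(len(self.snv_pos)) and rng.random() < cfg.snv_vaf
        if carrier:
            slo = np.searchsorted(self.snv_pos, start)
            shi = np.searchsorted(self.snv_pos, start + length)
            frag[self.snv_pos[slo:shi] - start] = self.snv_alt[slo:shi]
        # molecule methylation states over CpGs whose C or G falls in the span
        ilo = int(np.searchsorted(cpg, start - 1))
        ihi = int(np.searchsorted(cpg, start + length))
        probs = self.methylome.molecule_probs(sample, hap, carrier, ilo, ihi)
        states = rng.random(ihi - ilo) < probs
        space = ConversionSpace.CT if rng.integers(2) == 0 else ConversionSpace.GA
        meth_here = np.zeros(length, dtype=bool)
        if space is ConversionSpace.CT:
            sel = np.nonzero((cpg[ilo:ihi] >= start) & (cpg[ilo:ihi] < start + length))[0]
            rel = cpg[ilo + sel] - start
            base_mask = frag == C
            convert_from, convert_to = C, T
        else:
            sel = np.nonzero(
                (cpg[ilo:ihi] + 1 >= start) & (cpg[ilo:ihi] + 1 < start + length)
            )[0]
            rel = cpg[ilo + sel] + 1 - start
            base_mask = frag == G
            convert_from, convert_to = G, A
        meth_here[rel] = states[sel]
        p_conv = np.where(
            meth_here, cfg.over_conversion_rate, cfg.conversion_efficiency
        )
        conv = base_mask & (rng.random(length) < p_conv)
        converted = frag.copy()
        converted[conv] = convert_to
        return (
            start,
            length,
            on_target,
            hap,
            carrier,
            space,
            converted,
            ilo,
            sel,
            rel,
            states,
        )

    def _emit(
        self,
        read_id: str,
        sample: int,
        molecule,
        duplicate_of: str | None,
    ) -> SimulatedRead | None:
        cfg, rng = self.config, self.rng
        (start, length, on_target, hap, carrier, space, converted, ilo, sel, rel,
         states) = molecule
        read_codes, offsets, frag_idx = _apply_errors(
            converted,
            cfg.substitution_rate,
            cfg.insertion_rate,
            cfg.deletion_rate,
            rng,
        )
        if len(offsets) == 0:
            return None
        ref_positions = start + frag_idx
        read = AlignedConvertedRead(
            read_id=read_id,
            chrom=self.reference.chrom,
            read_offsets=offsets,
            ref_positions=ref_positions,
            read_bases=decode_seq(read_codes),
            is_primary=True,
            space=space,
            mapq=60,
        )
        # truth tally at CpGs whose informative base survived sequencing
        kept = np.zeros(length, dtype=bool)
        kept[frag_idx] = True
        informative = kept[rel]
        self.tally.add(sample, hap, carrier, ilo + sel[informative], states[sel[informative]])
        truth = ReadTruth(
            read_id,
            self.config.samples[sample],
            hap,
            carrier,
            space.value,
            int(ref_positions[0]),
            int(ref_positions[-1]) + 1,
            duplicate_of,
            on_target,
        )
        fastq = self._to_fastq(read_id, read_codes, sample)
        return SimulatedRead(read, fastq, truth)

    def _noisy(self, seq: str) -> str:
        cfg = self.config
        codes, _, _ = _apply_errors(
            np.frombuffer(seq.encode(), dtype=np.uint8).copy(),
            cfg.substitution_rate,
            cfg.insertion_rate,
            cfg.deletion_rate,
            self.rng,
        )
        return decode_seq(codes)

    def _to_fastq(
        self, read_id: str, read_codes: np.ndarray, sample: int
    ) -> FastqRecord:
        cfg, rng = self.config, self.rng
        seq = decode_seq(read_codes)
        if cfg.barcodes is not None:
            pair = cfg.barcodes[sample]
            i7 = pair.i7
            if cfg.index_hop_rate and rng.random() < cfg.index_hop_rate:
                others = [b for b in cfg.barcodes if b.sample_id != pair.sample_id]
                if others:
                    i7 = others[int(rng.integers(len(others)))].i7
            # flanks and barcodes see the same error process as the insert
            seq = (
                self._noisy(P5_FLANK + pair.i5)
                + seq
                + self._noisy(reverse_complement(i7) + reverse_complement(P7_FLANK))
            )
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
        return FastqRecord(read_id, seq, "I" * len(seq))

    def __iter__(self) -> Iterator[SimulatedRead]:
        cfg, rng = self.config, self.rng
        extra_p = (
            cfg.duplicate_rate / (1 - cfg.duplicate_rate)
            if cfg.duplicate_rate < 1
            else 0.0
        )
        counter = 0
        for _ in range(self.n_molecules):
            sample = int(rng.integers(len(cfg.samples)))
            molecule = self._molecule(f"r{counter:08d}", sample)
            first_id: str | None = None
            n_copies = 1 + int(rng.random() < extra_p) if extra_p else 1
            for _copy in range(n_copies):
                read_id = f"r{counter:08d}"
                counter += 1
                emitted = self._emit(
                    read_id, sample, molecule, duplicate_of=first_id
                )
                if emitted is None:
                    continue
                if first_id is None:
                    first_id = read_id
                yield emitted


@dataclass
class Simulation:
    config: SimConfig
    reference: Reference
    variants: VariantSet
    methylome: Methylome
    reads: list[SimulatedRead]
    tally: CpGTruthTally

    @property
    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.truth.__dict__ for r in self.reads])


def simulate_experiment(
    config: SimConfig, materialize: bool = True
) -> Simulation | LibrarySimulator:
    """Run all simulation stages from one seed.

    With ``materialize`` the reads are collected into a :class:`Simulation`;
    otherwise the :class:`LibrarySimulator` is returned for streaming
    consumption at scales where holding every read is wasteful.
    """
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    variants = simulate_variants(config, reference, rng)
    methylome = simulate_methylome(config, reference, variants, rng)
    sim = LibrarySimulator(config, reference, variants, methylome, rng)
    if not materialize:
        return sim
    reads = list(sim)
    return Simulation(config, reference, variants, methylome, reads, sim.tally)


def simulate_cpg_counts(
    probs: np.ndarray,
    mean_coverage: float,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
    spacing: int = 50,
    chrom: str = "sim1",
) -> pd.DataFrame:
    """Binomial per-CpG count table straight from a probability vector.

    A shortcut for statistics-level experiments (null calibration,
    planted-region recovery) that do not need read-level simulation:
    coverage is Poisson around ``mean_coverage`` and methylated counts
    are Binomial(coverage, p).
    """
    n = len(probs)
    if positions is None:
        positions = np.arange(n, dtype=np.int64) * spacing
    cov = rng.poisson(mean_coverage, size=n)
    n_meth = rng.binomial(cov, probs)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "n_meth": n_meth,
            "n_unmeth": cov - n_meth,
        }
    )
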