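"""Configuration, orchestration and run reports for the two workflows.

A run is described by a YAML/dict config validated up front (all
violations reported together, not one at a time).  The pipeline executes
the stages in the order of the targeted-capture workflow: simulation (or
file input) -> conversion-space classification -> allele matrix ->
haplotype phasing / SNV splitting -> per-group methylation -> coverage
filter -> DMR calling -> merge + filter cascade + TSS annotation -> QC.
Sample comparisons use a >=5-read CpG coverage floor; allele-resolved
comparisons (haplotype or SNV class) use >=3 because splitting reads by
allele roughly halves the usable depth.
"""

from __future__ import annotations

import enum
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import dmr as dmr_mod
from . import io as io_mod
from . import qc as qc_mod
from .conversion import call_cpg_methylation
from .dmr import CpGTable, DMRFilterSpec
from .phasing import (
    Haplotype,
    HaplotagMode,
    SNVClass,
    build_allele_matrix,
    classify_by_snv,
    haplotag_reads,
    make_pseudo_reads,
    phase_blocks,
    switch_error_rate,
    truth_blocks_from_phase,
)
from .simulate import PlantConfig, SimConfig, simulate_experiment

__version__ = "0.1.0"


class RunMode(enum.Enum):
    SAMPLE_DMR = "SAMPLE_DMR"
    HAPLOTYPE_DMR = "HAPLOTYPE_DMR"
    SNV_DMR = "SNV_DMR"


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(violations))


@dataclass
class StageParams:
    # phasing
    min_link: int = 2
    haplotag_mode: str = "PHASED_ONLY"
    # dmr
    min_cov: int | None = None  # defaulted by mode when None
    max_gap: int = 300
    min_cpgs: int = 10
    min_diff: float = 0.1
    q_cut: float = 0.01
    # filter cascade
    any_pair_diff: float | None = 0.5
    tss_window: int = 10_000
    # demux
    window: int = 60
    max_edit: int = 1


@dataclass
class RunConfig:
    mode: RunMode
    seed: int = 0
    out_dir: str = "emcap_run"
    simulate: SimConfig | None = None
    tss_file: str | None = None
    params: StageParams = field(default_factory=StageParams)

    @property
    def min_cov(self) -> int:
        if self.params.min_cov is not None:
            return self.params.min_cov
        return 5 if self.mode is RunMode.SAMPLE_DMR else 3


_TOP_KEYS = {"mode", "seed", "out_dir", "simulate", "tss_file", "params"}
_PLANT_KEYS = {"n_regions", "n_cpgs", "diff"}


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Build a fully defaulted RunConfig, reporting every violation at once."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    violations: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        violations.append(
            f"unknown key(s) {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    mode = None
    try:
        mode = RunMode(raw.get("mode", "SAMPLE_DMR"))
    except ValueError:
        violations.append(
            f"mode must be one of {[m.value for m in RunMode]}, got {raw.get('mode')!r}"
        )
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        violations.append(f"seed must be a non-negative integer, got {seed!r}")
    params = StageParams()
    for key, value in (raw.get("params") or {}).items():
        if not hasattr(params, key):
            violations.append(f"unknown params key {key!r}")
            continue
        setattr(params, key, value)
    for key in ("min_cpgs", "max_gap", "window", "max_edit", "min_link", "tss_window"):
        v = getattr(params, key)
        if not isinstance(v, int) or v < 0:
            violations.append(f"params.{key} must be a non-negative integer, got {v!r}")
    if params.min_cov is not None and (
        not isinstance(params.min_cov, int) or params.min_cov < 1
    ):
        violations.append(f"params.min_cov must be >= 1, got {params.min_cov!r}")
    for key in ("min_diff", "q_cut"):
        v = getattr(params, key)
        if not isinstance(v, (int, float)) or not 0 <= v <= 1:
            violations.append(f"params.{key} must be in [0, 1], got {v!r}")
    sim_cfg = None
    sim_raw = raw.get("simulate")
    if sim_raw is not None:
        sim_kwargs = dict(sim_raw)
        for plant in ("asm", "group_dmr", "snv_linked"):
            if plant in sim_kwargs:
                block = sim_kwargs[plant]
                bad = set(block) - _PLANT_KEYS
                if bad:
                    violations.append(f"simulate.{plant}: unknown key(s) {sorted(bad)}")
                else:
                    sim_kwargs[plant] = PlantConfig(**block)
        if "samples" in sim_kwargs:
            sim_kwargs["samples"] = tuple(sim_kwargs["samples"])
        try:
            sim_kwargs.setdefault("seed", seed if isinstance(seed, int) else 0)
            sim_cfg = SimConfig(**sim_kwargs)
        except (TypeError, ValueError) as exc:
            violations.append(f"simulate: {exc}")
    tss_file = raw.get("tss_file")
    if tss_file is not None and not Path(tss_file).exists():
        violations.append(f"tss_file does not exist: {tss_file}")
    if violations:
        raise ConfigError(violations)
    return RunConfig(
        mode=mode,
        seed=seed,
        out_dir=str(raw.get("out_dir", "emcap_run")),
        simulate=sim_cfg,
        tss_file=tss_file,
        params=params,
    )


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    seconds: float
    detail: dict = field(default_factory=dict)


@dataclass
class RunReport:
    mode: str
    seed: int
    config_hash: str
    version: str = __version__
    stages: list[StageRecord] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def add(self, name: str, n_in: int, n_out: int, t0: float, **detail) -> None:
        self.stages.append(
            StageRecord(name, n_in, n_out, round(time.perf_counter() - t0, 3), detail)
        )

    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "version": self.version,
            "config_hash": self.config_hash,
            "stages": [asdict(s) for s in self.stages],
            "metrics": self.metrics,
        }
        return json.dumps(payload, indent=2, default=float)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "value"):
            return o.value
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured workflow end to end on simulated input.

    Outputs (bedGraph tables, DMR BED, merged/filtered tables, QC JSON
    and the run report) are written under ``config.out_dir``; re-running
    with identical config and seed reproduces them byte for byte.
    """
    if config.simulate is None:
        raise ConfigError(["run_pipeline currently requires a 'simulate' block"])
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.mode.value, config.seed, _config_hash(config))
    p = config.params

    t0 = time.perf_counter()
    sim = simulate_experiment(config.simulate)
    report.add("simulate", 0, len(sim.reads), t0, genome=config.simulate.genome_length)

    # duplicate marking on truth alignments
    t0 = time.perf_counter()
    alns = sorted(
        (
            qc_mod.AlnRecord(
                read_id=r.read.read_id,
                chrom=r.read.chrom,
                start=r.read.start,
                end=r.read.end,
                # GA-space reads come from the original bottom strand
                is_reverse=r.read.space is not None
                and r.read.space.value == "GA",
                read_length=len(r.read.read_bases),
            )
            for r in sim.reads
        ),
        key=lambda a: (a.chrom, a.start),
    )
    dup_rate = qc_mod.mark_duplicates(alns)
    dup_ids = {a.read_id for a in alns if a.is_duplicate}
    reads = [r for r in sim.reads if r.read.read_id not in dup_ids]
    report.add("dedup", len(sim.reads), len(reads), t0, duplicate_rate=dup_rate)

    if sim.reference.targets:
        targets = qc_mod.TargetSet(
            (sim.reference.chrom, s, e) for s, e in sim.reference.targets
        )
        metrics = qc_mod.hs_metrics(alns, targets, len(sim.reference))
        report.metrics["qc"] = metrics.to_dict()
        (out / "qc.json").write_text(json.dumps(metrics.to_dict(), indent=2))

    variants = sim.variants.all_variants
    t0 = time.perf_counter()
    matrix = build_allele_matrix(
        (r.read for r in reads), variants, reference_length=len(sim.reference)
    )
    report.add("allele_matrix", len(reads), matrix.n_reads, t0)

    ref_codes = sim.reference.codes
    cpg = sim.reference.cpg_positions
    var_positions = {v.pos for v in variants}
    min_cov = config.min_cov

    def table_for(read_subset, name):
        counts = call_cpg_methylation(
            (r.read for r in read_subset),
            cpg,
            ref_codes,
            exclude_variants=var_positions,
            chrom=sim.reference.chrom,
        )
        io_mod.write_bedgraph(counts, out / f"cpg_{name}.bedgraph")
        return counts

    dmr_kwargs = dict(
        max_gap=p.max_gap, min_cpgs=p.min_cpgs, min_diff=p.min_diff, q_cut=p.q_cut
    )
    filter_spec = DMRFilterSpec(
        any_pair_diff=p.any_pair_diff, tss_window=p.tss_window
    )

    t0 = time.perf_counter()
    if config.mode is RunMode.SAMPLE_DMR:
        samples = list(config.simulate.samples)
        counts = {
            s: table_for([r for r in reads if r.truth.sample == s], s)
            for s in samples
        }
        table = CpGTable.from_counts(counts)
        filtered = dmr_mod.coverage_filter(table, min_cov)
        dmr_sets = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                dmr_sets.append(
                    dmr_mod.call_dmrs(filtered, samples[i], samples[j], **dmr_kwargs)
                )
        merged = dmr_mod.merge_dmrs(dmr_sets, table, min_cov, samples)
        value_cols = samples
    elif config.mode is RunMode.HAPLOTYPE_DMR:
        blocks = phase_blocks(matrix, min_link=p.min_link)
        tags = haplotag_reads(
            matrix, blocks, HaplotagMode(p.haplotag_mode)
        ).assignments
        truth = truth_blocks_from_phase(variants, _phase_map(sim, variants))
        phasing_metrics = switch_error_rate(blocks, truth, variants)
        report.metrics["phasing"] = {
            "switch_error_rate": phasing_metrics.switch_error_rate,
            "n_comparable_pairs": phasing_metrics.n_comparable_pairs,
            "block_n50_length": phasing_metrics.block_n50_length,
        }
        samples = list(config.simulate.samples)
        counts = {}
        value_cols = []
        dmr_sets = []
        for s in samples:
            for hap, tag in (("H1", Haplotype.H1), ("H2", Haplotype.H2)):
                subset = [
                    r
                    for r in reads
                    if r.truth.sample == s and tags.get(r.read.read_id) is tag
                ]
                counts[f"{s}_{hap}"] = table_for(subset, f"{s}_{hap}")
        table = CpGTable.from_counts(counts)
        filtered = dmr_mod.coverage_filter(table, min_cov)
        for s in samples:
            dmr_sets.append(
                dmr_mod.call_dmrs(filtered, f"{s}_H1", f"{s}_H2", **dmr_kwargs)
            )
        merged = dmr_mod.merge_dmrs(
            dmr_sets, table, min_cov, [f"{s}_{h}" for s in samples for h in ("H1", "H2")]
        )
        for s in samples:
            merged[f"{s}_diff"] = (merged[f"{s}_H1"] - merged[f"{s}_H2"]).abs()
        value_cols = [f"{s}_diff" for s in samples]
    else:  # SNV_DMR
        classes = classify_by_snv(matrix)
        counts = {
            name: table_for(
                [r for r in reads if classes.get(r.read.read_id) is klass], name
            )
            for name, klass in (
                ("SNV_plus", SNVClass.SNV_PLUS),
                ("SNV_minus", SNVClass.SNV_MINUS),
            )
        }
        table = CpGTable.from_counts(counts)
        filtered = dmr_mod.coverage_filter(table, min_cov)
        dmr_sets = [
            dmr_mod.call_dmrs(filtered, "SNV_plus", "SNV_minus", **dmr_kwargs)
        ]
        merged = dmr_mod.merge_dmrs(dmr_sets, table, min_cov)
        merged["snv_diff"] = (merged["SNV_plus"] - merged["SNV_minus"]).abs()
        value_cols = ["snv_diff"]
    n_dmrs = sum(len(d) for d in dmr_sets)
    report.add(
        "dmr",
        len(filtered),
        n_dmrs,
        t0,
        min_cov=min_cov,
        q_cut=p.q_cut,
        n_merged=len(merged),
    )

    t0 = time.perf_counter()
    selected = dmr_mod.apply_filter_cascade(merged, filter_spec, value_cols)
    if config.tss_file is not None:
        tss = io_mod.read_tss(config.tss_file)
        selected = dmr_mod.annotate_tss(selected, tss, window=p.tss_window)
        selected = selected[selected["within_window"]]
    report.add("filter_cascade", len(merged), len(selected), t0)

    all_dmrs = [d for dset in dmr_sets for d in dset]
    _write_dmr_bed(all_dmrs, out / "dmrs.bed")
    merged.to_csv(out / "dmrs_merged.tsv", sep="\t", index=False)
    selected.to_csv(out / "dmrs_selected.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
    return report


def _phase_map(sim, variants) -> dict[int, int]:
    het_bits = {}
    het_iter = iter(zip(sim.variants.hets, sim.variants.phase))
    lookup = {(v.chrom, v.pos): int(b) for v, b in het_iter}
    for i, v in enumerate(variants):
        bit = lookup.get((v.chrom, v.pos))
        if bit is not None:
            het_bits[i] = bit
    return het_bits


def _write_dmr_bed(dmrs, path) -> None:
    """BED6+ per-sample DMRs: name, -log10 q, strand '.', then stats."""
    with open(path, "w") as fh:
        for i, d in enumerate(sorted(dmrs, key=lambda d: (d.chrom, d.start))):
            score = -np.log10(max(d.q_value, 1e-300))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tDMR{i + 1}\t{score:.3f}\t.\t"
                f"{d.n_cpgs}\t{d.mean_a:.4f}\t{d.mean_b:.4f}\t{d.mean_diff:.4f}\t"
                f"{d.p_value:.3g}\t{d.q_value:.3g}\n"
            )


__all__ = [
    "ConfigError",
    "RunConfig",
    "RunMode",
    "RunReport",
    "StageParams",
    "run_pipeline",
    "validate_config",
    "make_pseudo_reads",
]
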