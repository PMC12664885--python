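"""Per-CpG methylation aggregation and differential-methylation-region calling.

Two read groups (samples, haplotypes, or SNV+/SNV- pools) are compared on
their per-CpG methylation rates.  CpGs must reach a minimum coverage in
every compared group (>=5 reads for sample comparisons, >=3 for allele
comparisons, where allele splitting halves the effective depth).  Shared
CpGs are pre-segmented into runs broken at gaps larger than ``max_gap``;
within each run the contiguous window of at least ``min_cpgs`` CpGs
maximising the absolute mean rate difference is extracted greedily, its
two per-CpG rate vectors are compared with a two-sided Mann-Whitney U
test, and the procedure recurses on the flanks.  P-values are
Benjamini-Hochberg adjusted genome-wide across all extracted windows and
regions with q below ``q_cut`` (0.01) are reported.  A merge step unions
DMRs called across samples, and a configurable filter cascade applies
per-sample difference rules, a measurable-in-all-samples requirement and
a +/-10 kb TSS-proximity window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CpGTable:
    """Per-CpG methylated/unmethylated counts for one or more groups.

    Wraps a DataFrame with columns ``chrom``, ``pos`` and, per group
    ``g``, ``{g}_meth`` / ``{g}_unmeth``.  Rows are sorted by position.
    """

    def __init__(self, df: pd.DataFrame, groups: Sequence[str]):
        self.groups = list(groups)
        for g in self.groups:
            for col in (f"{g}_meth", f"{g}_unmeth"):
                if col not in df.columns:
                    raise ValueError(f"missing column {col}")
                if (df[col] < 0).any():
                    raise ValueError(f"negative counts in {col}")
        self.df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)

    @classmethod
    def from_counts(cls, counts: Mapping[str, pd.DataFrame]) -> "CpGTable":
        """Outer-join per-group count frames (chrom, pos, n_meth, n_unmeth)."""
        merged: pd.DataFrame | None = None
        for group, frame in counts.items():
            part = frame[["chrom", "pos", "n_meth", "n_unmeth"]].rename(
                columns={"n_meth": f"{group}_meth", "n_unmeth": f"{group}_unmeth"}
            )
            merged = part if merged is None else merged.merge(
                part, on=["chrom", "pos"], how="outer"
            )
        merged = merged.fillna(0)
        for group in counts:
            for col in (f"{group}_meth", f"{group}_unmeth"):
                merged[col] = merged[col].astype(np.int64)
        return cls(merged, list(counts))

    def coverage(self, group: str) -> pd.Series:
        return self.df[f"{group}_meth"] + self.df[f"{group}_unmeth"]

    def rate(self, group: str) -> pd.Series:
        cov = self.coverage(group)
        return (self.df[f"{group}_meth"] / cov.where(cov > 0)).rename(group)

    def __len__(self) -> int:
        return len(self.df)


def coverage_filter(
    table: CpGTable, min_cov: int, groups: Sequence[str] | None = None
) -> CpGTable:
    """Keep CpGs where every compared group reaches ``min_cov`` reads."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    groups = list(groups) if groups is not None else table.groups
    mask = np.ones(len(table), dtype=bool)
    for g in groups:
        mask &= (table.coverage(g) >= min_cov).to_numpy()
    return CpGTable(table.df[mask].reset_index(drop=True), table.groups)


@dataclass
class DMR:
    chrom: str
    start: int
    end: int  # half-open, covers the CpG dinucleotides
    n_cpgs: int
    mean_a: float
    mean_b: float
    mean_diff: float  # signed, mean_a - mean_b
    p_value: float
    q_value: float = float("nan")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_cpgs", "mean_a", "mean_b",
            "mean_diff", "p_value", "q_value"]
    return pd.DataFrame([d.to_dict() for d in dmrs], columns=cols)


def _mwu_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    # constant, identical vectors carry no signal: p = 1 by convention
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    method = "exact" if (len(a) < 8 and len(b) < 8) else "asymptotic"
    try:
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    except ValueError:
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )


def _best_window(
    diff: np.ndarray, min_cpgs: int, min_diff: float
) -> tuple[int, int, float] | None:
    """Best window [i, j] of length >= min_cpgs, or None.

    Candidate windows must have |mean(diff)| >= min_diff; among those the
    one maximising |mean| * sqrt(length) wins, a standardised-difference
    score that extends a sustained difference to its full extent instead
    of clipping it at the minimum window size.
    """
    n = len(diff)
    prefix = np.concatenate([[0.0], np.cumsum(diff)])
    best: tuple[int, int, float] | None = None
    best_score = 0.0
    for i in range(0, n - min_cpgs + 1):
        lens = np.arange(min_cpgs, n - i + 1)
        means = (prefix[i + lens] - prefix[i]) / lens
        ok = np.abs(means) >= min_diff
        if not ok.any():
            continue
        scores = np.where(ok, np.abs(means) * np.sqrt(lens), -1.0)
        k = int(np.argmax(scores))
        if scores[k] > best_score:
            best_score = float(scores[k])
            best = (i, i + int(lens[k]) - 1, abs(float(means[k])))
    return best


def call_dmrs(
    table: CpGTable,
    group_a: str,
    group_b: str,
    max_gap: int = 300,
    min_cpgs: int = 10,
    min_diff: float = 0.1,
    q_cut: float = 0.01,
) -> list[DMR]:
    """Two-group DMR calling by greedy max-difference segmentation.

    The input should already be coverage-filtered; rows lacking coverage
    in either group are ignored.  Windows whose maximal absolute mean
    difference falls below ``min_diff`` stop the recursion on that run.
    """
    covered = (table.coverage(group_a) > 0) & (table.coverage(group_b) > 0)
    df = table.df[covered.to_numpy()]
    candidates: list[DMR] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        cov_a = (sub[f"{group_a}_meth"] + sub[f"{group_a}_unmeth"]).to_numpy()
        cov_b = (sub[f"{group_b}_meth"] + sub[f"{group_b}_unmeth"]).to_numpy()
        rate_a = sub[f"{group_a}_meth"].to_numpy() / cov_a
        rate_b = sub[f"{group_b}_meth"].to_numpy() / cov_b
        breaks = np.nonzero(np.diff(pos) > max_gap)[0]
        run_bounds = zip(
            np.concatenate([[0], breaks + 1]),
            np.concatenate([breaks, [len(pos) - 1]]),
        )
        stack = [(int(lo), int(hi)) for lo, hi in run_bounds]
        while stack:
            lo, hi = stack.pop()
            if hi - lo + 1 < min_cpgs:
                continue
            d = rate_a[lo : hi + 1] - rate_b[lo : hi + 1]
            found = _best_window(d, min_cpgs, min_diff)
            if found is None:
                continue
            i, j, _ = found
            i += lo
            j += lo
            a_vec, b_vec = rate_a[i : j + 1], rate_b[i : j + 1]
            candidates.append(
                DMR(
                    chrom=str(chrom),
                    start=int(pos[i]),
                    end=int(pos[j]) + 2,
                    n_cpgs=j - i + 1,
                    mean_a=float(a_vec.mean()),
                    mean_b=float(b_vec.mean()),
                    mean_diff=float(a_vec.mean() - b_vec.mean()),
                    p_value=_mwu_pvalue(a_vec, b_vec),
                )
            )
            stack.append((lo, i - 1))
            stack.append((j + 1, hi))
    if not candidates:
        return []
    pvals = np.array([c.p_value for c in candidates])
    qvals = stats.false_discovery_control(pvals, method="bh")
    for c, q in zip(candidates, qvals):
        c.q_value = float(q)
    selected = [c for c in candidates if c.q_value < q_cut]
    selected.sort(key=lambda d: (d.chrom, d.start))
    return selected


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Union overlapping or bookended half-open intervals."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def merge_dmrs(
    dmr_sets: Sequence[Sequence[DMR] | Sequence[tuple[str, int, int]]],
    table: CpGTable,
    min_cov: int,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Merge per-sample DMR lists and re-score every sample on the union.

    Overlapping/bookended intervals are unioned; per merged interval and
    per group, the mean of per-CpG rates passing ``min_cov`` is computed.
    Groups with no passing CpG in the interval are NaN (not measurable).
    """
    groups = list(groups) if groups is not None else table.groups
    raw: list[tuple[str, int, int]] = []
    for dset in dmr_sets:
        for d in dset:
            if isinstance(d, DMR):
                raw.append((d.chrom, d.start, d.end))
            else:
                raw.append(tuple(d))
    merged = merge_intervals(raw)
    rows = []
    for chrom, start, end in merged:
        sub = table.df[
            (table.df["chrom"] == chrom)
            & (table.df["pos"] >= start)
            & (table.df["pos"] < end)
        ]
        row: dict = {"chrom": chrom, "start": start, "end": end}
        for g in groups:
            cov = (sub[f"{g}_meth"] + sub[f"{g}_unmeth"]).to_numpy()
            ok = cov >= min_cov
            if ok.any():
                row[g] = float((sub[f"{g}_meth"].to_numpy()[ok] / cov[ok]).mean())
            else:
                row[g] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", *groups])


@dataclass(frozen=True)
class FilterRule:
    """All listed columns must satisfy ``value <op> threshold``."""

    columns: tuple[str, ...]
    op: str  # "ge" or "lt"
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("ge", "lt"):
            raise ValueError(f"unknown op {self.op!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class DMRFilterSpec:
    """Difference-filter cascade applied to a merged DMR table.

    ``any_pair_diff`` keeps intervals whose max pairwise difference over
    ``value_columns`` reaches the threshold (the between-sample rule);
    ``rules`` express per-sample predicates such as "difference >= 0.4 in
    both tumours and < 0.1 in both normals".  Differences are taken as
    absolute values unless ``use_absolute`` is cleared.
    """

    rules: list[FilterRule] = field(default_factory=list)
    any_pair_diff: float | None = None
    require_measurable_in_all: bool = True
    use_absolute: bool = True
    tss_window: int = 10_000


def apply_filter_cascade(
    merged: pd.DataFrame,
    spec: DMRFilterSpec,
    value_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply a DMRFilterSpec to a merged interval table.

    ``value_columns`` are the per-sample columns the predicates read:
    mean rates for sample comparisons, per-sample allele differences for
    haplotype comparisons.
    """
    if value_columns is None:
        value_columns = [
            c for c in merged.columns if c not in ("chrom", "start", "end")
        ]
    referenced = set(value_columns)
    for rule in spec.rules:
        referenced.update(rule.columns)
    unknown = referenced - set(merged.columns)
    if unknown:
        raise ValueError(f"filter references unknown sample column(s): {sorted(unknown)}")
    out = merged.copy()
    if spec.require_measurable_in_all:
        out = out[out[list(referenced)].notna().all(axis=1)]
    if spec.any_pair_diff is not None and len(value_columns) >= 2:
        vals = out[list(value_columns)].to_numpy(dtype=float)
        spread = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
        out = out[spread >= spec.any_pair_diff]
    for rule in spec.rules:
        vals = out[list(rule.columns)].to_numpy(dtype=float)
        if spec.use_absolute:
            vals = np.abs(vals)
        if rule.op == "ge":
            keep = (vals >= rule.threshold).all(axis=1)
        else:
            keep = (vals < rule.threshold).all(axis=1)
        out = out[keep]
    return out.reset_index(drop=True)


def annotate_tss(
    intervals: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 10_000,
) -> pd.DataFrame:
    """Annotate intervals with nearest-TSS distance and gene name.

    ``tss`` needs columns gene, chrom, pos (0-based point; strand, if
    present, is ignored -- the +/-window rule is symmetric).  Distance is
    the gap between the interval and the TSS point, 0 when the TSS falls
    inside.  ``within_window`` uses a strict > comparison for exclusion,
    so a TSS exactly ``window`` away is still within.
    """
    if len(tss) == 0:
        raise ValueError("TSS list is empty")
    out = intervals.copy()
    distances: list[float] = []
    genes: list[str | None] = []
    tss_by_chrom = {c: sub for c, sub in tss.groupby("chrom")}
    for _, row in intervals.iterrows():
        sub = tss_by_chrom.get(row["chrom"])
        if sub is None:
            distances.append(np.inf)
            genes.append(None)
            continue
        pos = sub["pos"].to_numpy()
        gap = np.maximum(0, np.maximum(row["start"] - pos, pos - (row["end"] - 1)))
        k = int(np.argmin(gap))
        distances.append(int(gap[k]))
        genes.append(str(sub["gene"].iloc[k]))
    out["tss_distance"] = distances
    out["nearest_gene"] = genes
    out["within_window"] = [d <= window for d in distances]
    return out
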