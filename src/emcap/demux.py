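"""Adapter handling and dual-index demultiplexing of converted long reads.

Multiplexed capture libraries carry 8+8 bp unique dual indexes inside the
retained P5/P7 flanks at both ends of every molecule.  Because nanopore
reads come off the pore in random orientation and with a few percent
error, barcodes are searched as approximate substrings (edit distance)
within a fixed window at each read end, in both orientations.  A read
whose two ends point at different samples is an index-hopping candidate
("unexpected pair") and is removed, as is a read with no barcode at all.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib

from .conversion import reverse_complement

# P5/P7 flank fragments outside the index (Illumina library outer adapters)
P5_FLANK = "AATGATACGGCGACCACCGA"
P7_FLANK = "CAAGCAGAAGACGGCATACGA"
# internal sequencing adapters used for chimera splitting in single-plex mode
INNER_ADAPTER_1 = "TGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
INNER_ADAPTER_2 = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"


@dataclass(frozen=True)
class BarcodePair:
    sample_id: str
    i5: str
    i7: str


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"FASTQ record {self.read_id}: sequence and quality length differ"
            )


class DemuxOutcome(enum.Enum):
    ASSIGNED = "ASSIGNED"
    NO_BARCODE = "NO_BARCODE"
    UNEXPECTED_PAIR = "UNEXPECTED_PAIR"


@dataclass(frozen=True)
class BarcodeHit:
    sample_id: str
    barcode: str
    position: int
    edit_distance: int
    end: str  # "front" or "back"


@dataclass
class DemuxDecision:
    read_id: str
    outcome: DemuxOutcome
    sample_id: str | None = None
    i5_hit: BarcodeHit | None = None
    i7_hit: BarcodeHit | None = None


@dataclass
class DemuxReport:
    n_total: int = 0
    n_assigned: int = 0
    n_no_barcode: int = 0
    n_unexpected_pair: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def assignment_rate(self) -> float:
        return self.n_assigned / self.n_total if self.n_total else 0.0

    def add(self, decision: DemuxDecision) -> None:
        self.n_total += 1
        if decision.outcome is DemuxOutcome.ASSIGNED:
            self.n_assigned += 1
            self.per_sample[decision.sample_id] = (
                self.per_sample.get(decision.sample_id, 0) + 1
            )
        elif decision.outcome is DemuxOutcome.NO_BARCODE:
            self.n_no_barcode += 1
        else:
            self.n_unexpected_pair += 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_total": self.n_total,
                "n_assigned": self.n_assigned,
                "n_no_barcode": self.n_no_barcode,
                "n_unexpected_pair": self.n_unexpected_pair,
                "assignment_rate": self.assignment_rate,
                "per_sample": self.per_sample,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        lines.append(f"n_total\t{self.n_total}")
        lines.append(f"n_assigned\t{self.n_assigned}")
        lines.append(f"n_no_barcode\t{self.n_no_barcode}")
        lines.append(f"n_unexpected_pair\t{self.n_unexpected_pair}")
        lines.append(f"assignment_rate\t{self.assignment_rate:.4f}")
        for sample, n in sorted(self.per_sample.items()):
            lines.append(f"reads[{sample}]\t{n}")
        return "\n".join(lines) + "\n"


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def load_sheet(path_or_rows, max_edit: int = 1) -> list[BarcodePair]:
    """Load and validate a sample sheet (TSV: sample_id, i5, i7).

    Enforces the unique-dual design: every (i5, i7) pair, every i5 and
    every i7 belongs to exactly one sample.  Warns when any inter-barcode
    edit distance is small enough that ``max_edit`` could cause collisions.
    """
    if isinstance(path_or_rows, (str, Path)):
        rows = []
        with open(path_or_rows) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("sample_id"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"malformed sample sheet line: {line!r}")
                rows.append(BarcodePair(parts[0], parts[1].upper(), parts[2].upper()))
    else:
        rows = list(path_or_rows)
    if not rows:
        raise ValueError("empty sample sheet")
    lengths = {len(bc) for pair in rows for bc in (pair.i5, pair.i7)}
    if len(lengths) != 1:
        raise ValueError("all barcodes in a sheet must have the same length")
    pairs = [(p.i5, p.i7) for p in rows]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (i5, i7) barcode pairs in sheet")
    i5s = [p.i5 for p in rows]
    i7s = [p.i7 for p in rows]
    if len(set(i5s)) != len(i5s) or len(set(i7s)) != len(i7s):
        raise ValueError("unique-dual design violated: an index is reused")
    all_bcs = i5s + i7s
    for i in range(len(all_bcs)):
        for j in range(i + 1, len(all_bcs)):
            if all_bcs[i] != all_bcs[j] and _edit_distance(all_bcs[i], all_bcs[j]) <= 2 * max_edit:
                warnings.warn(
                    f"barcodes {all_bcs[i]} and {all_bcs[j]} are within edit "
                    f"distance {2 * max_edit}; collisions possible at max_edit={max_edit}",
                    stacklevel=2,
                )
    return rows


@dataclass(frozen=True)
class AdapterHit:
    start: int
    end: int  # half-open
    identity: float
    reverse: bool = False


def locate_adapter(
    read: str,
    adapter: str,
    min_identity: float = 0.75,
    search_rc: bool = False,
) -> list[AdapterHit]:
    """Locate non-overlapping approximate copies of an adapter in a read.

    Semi-global alignment (adapter global, read local); hits with
    identity >= ``min_identity`` are returned best-first.  Multiple hits
    are found by masking each accepted hit and re-searching.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 nt")
    max_dist = int(len(adapter) * (1.0 - min_identity))
    queries = [(adapter, False)]
    if search_rc:
        queries.append((reverse_complement(adapter), True))
    hits: list[AdapterHit] = []
    work = list(read)
    for query, is_rc in queries:
        while True:
            res = edlib.align(query, "".join(work), mode="HW", task="locations", k=max_dist)
            if res["editDistance"] < 0 or not res["locations"]:
                break
            s, e = res["locations"][0]
            e += 1  # edlib locations are inclusive
            hits.append(
                AdapterHit(s, e, 1.0 - res["editDistance"] / len(adapter), is_rc)
            )
            for i in range(s, e):
                work[i] = "#"
    hits.sort(key=lambda h: (-h.identity, h.start))
    return hits


def split_on_internal_adapters(
    record: FastqRecord,
    inner_adapters: Sequence[str] = (INNER_ADAPTER_1, INNER_ADAPTER_2),
    min_identity: float = 0.75,
    min_internal_offset: int = 100,
    min_len: int = 200,
    search_rc: bool = True,
) -> list[FastqRecord]:
    """Cut a read at internal adapter copies (chimera splitting).

    Adapter spans are excised; a hit near a read end just trims that end.
    Sub-reads shorter than ``min_len``, and end fragments shorter than
    ``min_internal_offset``, are discarded.  Qualities are sliced in
    register with the sequence.
    """
    seq, qual = record.sequence, record.quality
    hits: list[AdapterHit] = []
    for adapter in inner_adapters:
        hits.extend(locate_adapter(seq, adapter, min_identity, search_rc=search_rc))
    if not hits:
        return [record]
    # subtract hit spans from the read
    kept: list[tuple[int, int]] = []
    cursor = 0
    for h in sorted(hits, key=lambda h: h.start):
        if h.start > cursor:
            kept.append((cursor, h.start))
        cursor = max(cursor, h.end)
    if cursor < len(seq):
        kept.append((cursor, len(seq)))
    out = []
    for i, (s, e) in enumerate(kept):
        length = e - s
        touches_end = s == 0 or e == len(seq)
        if length < min_len or (touches_end and length < min_internal_offset):
            continue
        suffix = f"/{i + 1}" if len(kept) > 1 else ""
        out.append(FastqRecord(record.read_id + suffix, seq[s:e], qual[s:e]))
    return out


def _search_barcode(window: str, barcode: str, max_edit: int) -> tuple[int, int] | None:
    """Best (position, edit_distance) of barcode in window, or None."""
    res = edlib.align(barcode, window, mode="HW", task="locations", k=max_edit)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    return res["locations"][0][0], res["editDistance"]


def assign_read(
    sequence: str,
    sheet: Sequence[BarcodePair],
    read_id: str = "",
    window: int = 60,
    max_edit: int = 1,
    strict_pair: bool = False,
) -> DemuxDecision:
    """Assign one read to a sample from its end barcodes.

    Every barcode (and its reverse complement) is searched within the
    first and last ``window`` bases.  Per end, the best hit wins (lowest
    edit distance, then the hit nearest the read end).  One detected
    barcode suffices for assignment unless ``strict_pair`` is set; two
    hits naming different samples are an unexpected pair and the read is
    removed.
    """
    bc_len = len(sheet[0].i5)
    if window < bc_len:
        raise ValueError("window must be at least the barcode length")
    w = min(window, len(sequence))
    front = sequence[:w]
    back = sequence[-w:]
    back_offset = len(sequence) - w

    def best_hit(segment: str, end: str) -> BarcodeHit | None:
        best: BarcodeHit | None = None
        for pair in sheet:
            for barcode in (pair.i5, pair.i7):
                for query in (barcode, reverse_complement(barcode)):
                    found = _search_barcode(segment, query, max_edit)
                    if found is None:
                        continue
                    pos, dist = found
                    if end == "back":
                        pos += back_offset
                    hit = BarcodeHit(pair.sample_id, barcode, pos, dist, end)
                    if best is None or (dist, _end_rank(hit, end)) < (
                        best.edit_distance,
                        _end_rank(best, end),
                    ):
                        best = hit
        return best

    def _end_rank(hit: BarcodeHit, end: str) -> int:
        # prefer the hit closest to the read end on ties
        return hit.position if end == "front" else -hit.position

    front_hit = best_hit(front, "front")
    back_hit = best_hit(back, "back")

    if front_hit is None and back_hit is None:
        return DemuxDecision(read_id, DemuxOutcome.NO_BARCODE)
    if front_hit is not None and back_hit is not None:
        if front_hit.sample_id != back_hit.sample_id:
            return DemuxDecision(
                read_id, DemuxOutcome.UNEXPECTED_PAIR, None, front_hit, back_hit
            )
        return DemuxDecision(
            read_id, DemuxOutcome.ASSIGNED, front_hit.sample_id, front_hit, back_hit
        )
    if strict_pair:
        return DemuxDecision(read_id, DemuxOutcome.NO_BARCODE, None, front_hit, back_hit)
    hit = front_hit or back_hit
    return DemuxDecision(
        read_id, DemuxOutcome.ASSIGNED, hit.sample_id, front_hit, back_hit
    )


def iter_fastq(path) -> Iterator[FastqRecord]:
    """Iterate a FASTQ file (gzip-aware via pysam)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRecord(entry.name, entry.sequence, entry.quality or "")


def write_fastq(records: Iterable[FastqRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def demultiplex(
    reads: Iterable[FastqRecord] | str | Path,
    sheet: Sequence[BarcodePair],
    out_dir: str | Path | None = None,
    window: int = 60,
    max_edit: int = 1,
    strict_pair: bool = False,
) -> tuple[DemuxReport, dict[str, list[FastqRecord]]]:
    """Split reads into per-sample streams plus a discard stream.

    Every input read lands in exactly one output stream; the report
    totals are consistent with the stream sizes by construction.  When
    ``out_dir`` is given, per-sample FASTQ files, an ``unassigned.fastq``
    and TSV/JSON reports are written there.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    report = DemuxReport()
    streams: dict[str, list[FastqRecord]] = {p.sample_id: [] for p in sheet}
    streams["unassigned"] = []
    for rec in reads:
        decision = assign_read(
            rec.sequence, sheet, rec.read_id, window, max_edit, strict_pair
        )
        report.add(decision)
        if decision.outcome is DemuxOutcome.ASSIGNED:
            streams[decision.sample_id].append(rec)
        else:
            streams["unassigned"].append(rec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, recs in streams.items():
            write_fastq(recs, out_dir / f"{name}.fastq")
        (out_dir / "demux_report.json").write_text(report.to_json())
        (out_dir / "demux_report.tsv").write_text(report.to_tsv())
    return report, streams
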