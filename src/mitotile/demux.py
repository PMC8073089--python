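"""Dual-index demultiplexing, run-level QC gates and the bait-index
carryover check.

Each library carries an i7/i5 index pair (8 nt each).  A read is assigned to
a sample sheet entry iff both indexes match within the configured mismatch
tolerance and the assignment is unique; everything else lands in the
unassigned bin, so assigned + unassigned always equals the input total.

Run QC gates follow the recommended instrument ranges (cluster density
400-1650 K/mm², clusters passing filter >= 80%, phasing <= 0.25%,
pre-phasing <= 0.15%); a metric outside its range is a warning, never an
error — such runs can still produce usable calls.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .simulate import ReadPair

INDEX_LENGTH = 8


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class IndexPair:
    i7: str
    i5: str

    def __post_init__(self) -> None:
        for idx in (self.i7, self.i5):
            if len(idx) != INDEX_LENGTH or set(idx) - set("ACGT"):
                raise DemuxError(f"index {idx!r} must be 8 nt over ACGT")


@dataclass
class SheetEntry:
    sample_id: str
    index: IndexPair
    role: str = "sample"  # sample | ntc | bait


def read_sample_sheet(path: str | Path) -> list[SheetEntry]:
    entries: list[SheetEntry] = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            entries.append(
                SheetEntry(
                    sample_id=row["Sample_ID"],
                    index=IndexPair(row["index"], row["index2"]),
                    role=row.get("role", "sample") or "sample",
                )
            )
    return entries


def sheet_from_rows(rows: Sequence[dict]) -> list[SheetEntry]:
    return [
        SheetEntry(
            sample_id=r["Sample_ID"],
            index=IndexPair(r["index"], r["index2"]),
            role=r.get("role", "sample"),
        )
        for r in rows
    ]


@dataclass
class DemuxResult:
    per_sample: dict[str, list[ReadPair]]
    unassigned: list[ReadPair]
    counts: dict[tuple[str, str], int]  # per index pair, including baits
    entries: list[SheetEntry]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.per_sample.values()) + len(self.unassigned)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def demultiplex(
    reads: Sequence[ReadPair],
    sheet: Sequence[SheetEntry],
    max_mismatch_per_index: int = 1,
) -> DemuxResult:
    """Assign reads to sheet entries by dual-index match.

    A read is assigned iff exactly one entry matches both indexes within
    ``max_mismatch_per_index``; ambiguous or non-matching reads are
    unassigned.  Sheets whose index pairs could collide under the tolerance
    (either index pair within 2x the tolerance on both reads) are refused.
    """
    pairs = [(e.index.i7, e.index.i5) for e in sheet]
    if len(set(pairs)) != len(pairs):
        raise DemuxError("duplicate index pairs in sample sheet")
    for i, a in enumerate(sheet):
        for b in sheet[i + 1 :]:
            if (
                _hamming(a.index.i7, b.index.i7) <= 2 * max_mismatch_per_index
                and _hamming(a.index.i5, b.index.i5) <= 2 * max_mismatch_per_index
            ):
                raise DemuxError(
                    f"indexes of {a.sample_id} and {b.sample_id} are within "
                    f"{2 * max_mismatch_per_index} mismatches: ambiguous sheet"
                )
    per_sample: dict[str, list[ReadPair]] = {e.sample_id: [] for e in sheet}
    counts: dict[tuple[str, str], int] = {p: 0 for p in pairs}
    unassigned: list[ReadPair] = []
    for rp in reads:
        hits = [
            e
            for e in sheet
            if len(rp.i7) == INDEX_LENGTH
            and len(rp.i5) == INDEX_LENGTH
            and _hamming(rp.i7, e.index.i7) <= max_mismatch_per_index
            and _hamming(rp.i5, e.index.i5) <= max_mismatch_per_index
        ]
        if len(hits) == 1:
            e = hits[0]
            per_sample[e.sample_id].append(rp)
            counts[(e.index.i7, e.index.i5)] += 1
        else:
            unassigned.append(rp)
    return DemuxResult(
        per_sample=per_sample, unassigned=unassigned, counts=counts, entries=list(sheet)
    )


@dataclass(frozen=True)
class RunQCMetrics:
    cluster_density: float  # K/mm^2
    clusters_passing_filter: float  # percent
    phasing: float  # percent
    prephasing: float  # percent

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise DemuxError(f"negative QC metric {name}")


QC_TARGETS = {
    "cluster_density": (400.0, 1650.0),
    "clusters_passing_filter": (80.0, None),  # >= 80
    "phasing": (None, 0.25),  # <= 0.25
    "prephasing": (None, 0.15),  # <= 0.15
}


def evaluate_run_qc(metrics: RunQCMetrics) -> dict:
    """Per-metric pass / outside-target statuses and an overall flag.

    Outside-target is advisory only; the overall flag is ``pass`` iff every
    metric is in range, else ``outside-target``.
    """
    statuses = {}
    for name, (lo, hi) in QC_TARGETS.items():
        v = getattr(metrics, name)
        ok = (lo is None or v >= lo) and (hi is None or v <= hi)
        statuses[name] = "pass" if ok else "outside-target"
    overall = "pass" if all(s == "pass" for s in statuses.values()) else "outside-target"
    return {"metrics": statuses, "overall": overall}


def carryover_check(
    demux: DemuxResult, bait_indexes: Optional[Sequence[tuple[str, str]]] = None
) -> dict[tuple[str, str], int]:
    """Read counts observed for bait index pairs (sheet entries with no
    physical library).  All-zero counts mean no detectable carryover or
    crosstalk into the bait combinations."""
    if bait_indexes is None:
        bait_indexes = [
            (e.index.i7, e.index.i5) for e in demux.entries if e.role == "bait"
        ]
    out: dict[tuple[str, str], int] = {}
    for pair in bait_indexes:
        if pair not in demux.counts:
            raise DemuxError(f"bait index pair {pair} not in sample sheet")
        out[pair] = demux.counts[pair]
    return out
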