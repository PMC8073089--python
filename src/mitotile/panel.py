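"""Tiled amplicon panels over a circular target.

A panel is an ordered list of short amplicons whose *inserts* (the target
sequence between the two primer footprints) tile a region of the circle with
a guaranteed minimum overlap between genomic neighbours, so that no target
base is lost when primers are trimmed bioinformatically.  Amplicons are split
into two staggered sets (set 1 / set 2) amplified in separate reactions, which
prevents short overlap byproducts between neighbouring amplicons and lets a
variant sitting under one set's primer be recovered from the other set.

Primer *sequences* are deliberately not modelled (commercial panels do not
publish them); a primer is a coordinate footprint of configurable length.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .reference import CircularGenome, Region, region_length

DEFAULT_PRIMER_LEN = 20


class PanelError(ValueError):
    pass


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Amplicon:
    """One tiled amplicon: primer-to-primer span plus the trimmed insert."""

    id: str
    outer: Region
    insert: Region
    fwd_primer_len: int
    rev_primer_len: int
    set_id: int  # 1 or 2 (staggered PCR sets)
    efficiency: float = 1.0

    def validate(self, genome_length: int) -> None:
        self.outer.validate(genome_length)
        self.insert.validate(genome_length)
        expected = (
            self.fwd_primer_len
            + region_length(self.insert, genome_length)
            + self.rev_primer_len
        )
        if region_length(self.outer, genome_length) != expected:
            raise PanelError(
                f"amplicon {self.id}: outer length != primers + insert length"
            )
        if self.set_id not in (1, 2):
            raise PanelError(f"amplicon {self.id}: set_id must be 1 or 2")


@dataclass
class Panel:
    """Ordered amplicons tiling ``target`` on genome ``genome_name``."""

    amplicons: list[Amplicon]
    target: Region
    genome_name: str = ""

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def by_id(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def validate(self, genome_length: int, min_overlap: int = 3) -> None:
        if not self.amplicons:
            raise PanelError("empty panel")
        for a in self.amplicons:
            a.validate(genome_length)
        gaps = coverage_check(self, self.target, genome_length)
        if gaps:
            raise PanelError(f"panel leaves target gaps: {gaps}")
        for ov in _adjacent_overlaps(self, genome_length):
            if ov < min_overlap:
                raise PanelError(f"adjacent insert overlap {ov} < {min_overlap}")
        for prev, cur in zip(self.amplicons, self.amplicons[1:]):
            if prev.set_id == cur.set_id:
                raise PanelError("adjacent amplicons must alternate set_id")

    def primer_regions(self, amplicon_id: str, genome_length: int) -> list[Region]:
        """The two primer footprints of an amplicon, in genome coordinates."""
        a = self.by_id(amplicon_id)
        L = genome_length
        fwd_end = (a.outer.start - 1 + a.fwd_primer_len - 1) % L + 1
        rev_start = (a.outer.end - 1 - a.rev_primer_len + 1) % L + 1
        return [
            Region(a.outer.start, fwd_end, f"{amplicon_id}:fwd"),
            Region(rev_start, a.outer.end, f"{amplicon_id}:rev"),
        ]


@dataclass(frozen=True)
class PanelStats:
    n_amplicons: int
    mean_length: float
    min_length: int
    max_length: int
    mean_overlap: float
    min_overlap: int
    n_overlaps: int


def _target_offset(target: Region, genome_length: int):
    """Map a 1-based genome position to its 0-based offset along the target."""
    L = genome_length

    def offset(pos: int) -> int:
        return (pos - target.start) % L

    return offset


def _adjacent_overlaps(panel: Panel, genome_length: int) -> list[int]:
    """Insert overlaps between genomically adjacent amplicons, in tiling order."""
    if len(panel) < 2:
        return []
    off = _target_offset(panel.target, genome_length)
    ordered = sorted(panel.amplicons, key=lambda a: off(a.insert.start))
    overlaps = []
    pairs = list(zip(ordered, ordered[1:]))
    if panel.target.wraps or region_length(panel.target, genome_length) == genome_length:
        pairs.append((ordered[-1], ordered[0]))
    target_len = region_length(panel.target, genome_length)
    full_circle = target_len == genome_length
    for prev, cur in pairs:
        prev_end = off(prev.insert.start) + region_length(prev.insert, genome_length) - 1
        cur_start = off(cur.insert.start)
        if (prev, cur) == (ordered[-1], ordered[0]) and full_circle:
            cur_start += genome_length  # wrap-around neighbour
        overlaps.append(prev_end - cur_start + 1)
    if not full_circle and len(pairs) > len(ordered) - 1:
        overlaps = overlaps[: len(ordered) - 1]
    return overlaps


def design_tiled_panel(
    genome: CircularGenome,
    target: Region,
    min_len: int = 60,
    max_len: int = 150,
    min_overlap: int = 3,
    seed: int = 0,
    fwd_primer_len: int = DEFAULT_PRIMER_LEN,
    rev_primer_len: int = DEFAULT_PRIMER_LEN,
    mean_overlap: int = 17,
) -> Panel:
    """Design a staggered two-set tiled panel covering ``target``.

    Amplicon outer lengths are drawn uniformly in ``[min_len, max_len]``;
    each next insert starts so that it overlaps its predecessor by at least
    ``min_overlap`` bases (mean overlap near ``mean_overlap``).  Deterministic
    for a fixed seed.  Raises :class:`PanelError` on infeasible constraints.
    """
    L = genome.length
    target.validate(L)
    target_len = region_length(target, L)
    primer_total = fwd_primer_len + rev_primer_len
    if min_len < primer_total + 1:
        raise PanelError("min_len must allow a non-empty insert between primers")
    if max_len < min_len:
        raise PanelError("max_len < min_len")
    if target_len < min_len:
        raise PanelError(f"target of {target_len} bp shorter than min_len {min_len}")
    if min_overlap >= min_len - primer_total:
        raise PanelError("min_overlap >= minimum insert length: tiling cannot advance")

    rng = random.Random(seed)
    full_circle = target_len == L
    amplicons: list[Amplicon] = []
    cur = 0  # insert start offset along the target
    rank = 0
    while True:
        outer_len = rng.randint(min_len, max_len)
        insert_len = outer_len - primer_total
        insert_end = cur + insert_len - 1
        last = False
        if full_circle:
            # the final insert must wrap far enough to overlap the first insert
            if insert_end >= target_len - 1 + min_overlap:
                last = True
        elif insert_end >= target_len - 1:
            last = True
        start_pos = (target.start - 1 + cur) % L + 1
        end_pos = (target.start - 1 + cur + insert_len - 1) % L + 1
        insert = Region(start_pos, end_pos)
        outer = Region(
            (start_pos - 1 - fwd_primer_len) % L + 1,
            (end_pos - 1 + rev_primer_len) % L + 1,
        )
        rank += 1
        amplicons.append(
            Amplicon(
                id=f"A{rank:03d}",
                outer=outer,
                insert=insert,
                fwd_primer_len=fwd_primer_len,
                rev_primer_len=rev_primer_len,
                set_id=1 if rank % 2 else 2,
            )
        )
        if last:
            break
        max_ov = min(insert_len - 1, max(min_overlap, 2 * mean_overlap - min_overlap))
        overlap = rng.randint(min_overlap, max_ov)
        cur = cur + insert_len - overlap
        if rank > 10 * (target_len // max(1, min_len - primer_total) + 2):
            raise PanelError("tiling failed to terminate; constraints infeasible")
    panel = Panel(amplicons=amplicons, target=target, genome_name=genome.name)
    return panel


def panel_stats(panel: Panel, genome_length: int) -> PanelStats:
    """Summary statistics over outer lengths and adjacent insert overlaps."""
    if not panel.amplicons:
        raise PanelError("empty panel")
    lengths = [region_length(a.outer, genome_length) for a in panel.amplicons]
    overlaps = _adjacent_overlaps(panel, genome_length)
    return PanelStats(
        n_amplicons=len(panel),
        mean_length=_round_half_up(sum(lengths) / len(lengths), 1),
        min_length=min(lengths),
        max_length=max(lengths),
        mean_overlap=_round_half_up(sum(overlaps) / len(overlaps), 1) if overlaps else 0.0,
        min_overlap=min(overlaps) if overlaps else 0,
        n_overlaps=len(overlaps),
    )


def coverage_check(panel: Panel, target: Region, genome_length: int) -> list[Region]:
    """Uncovered target regions (empty list iff every target position lies in
    at least one insert).  Runs that span the origin are returned as a single
    wrapping region."""
    covered = set()
    for a in panel.amplicons:
        covered.update(a.insert.positions(genome_length))
    uncovered_runs: list[Region] = []
    run: list[int] = []
    for pos in target.positions(genome_length):
        if pos in covered:
            if run:
                uncovered_runs.append(Region(run[0], run[-1]))
                run = []
        else:
            run.append(pos)
    if run:
        uncovered_runs.append(Region(run[0], run[-1]))
    return uncovered_runs


def dropout_rate(
    n_dropout_amplicons: int, amplicons_per_sample: int, n_samples: int
) -> float:
    """Percentage of targeted amplicons lost to primer-binding-site dropout,
    rounded half-up to two decimals: 100·n / (amplicons·samples)."""
    if min(n_dropout_amplicons, amplicons_per_sample, n_samples) < 0:
        raise PanelError("counts must be non-negative")
    denom = amplicons_per_sample * n_samples
    if denom == 0:
        raise PanelError("zero amplicon-sample denominator")
    return _round_half_up(100.0 * n_dropout_amplicons / denom, 2)


_TSV_COLUMNS = [
    "id",
    "outer_start",
    "outer_end",
    "insert_start",
    "insert_end",
    "fwd_primer_len",
    "rev_primer_len",
    "set_id",
    "efficiency",
]


def write_panel_tsv(panel: Panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        fh.write(f"#target\t{panel.target.start}\t{panel.target.end}"
                 f"\t{panel.genome_name}\n")
        for a in panel.amplicons:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.id,
                        a.outer.start,
                        a.outer.end,
                        a.insert.start,
                        a.insert.end,
                        a.fwd_primer_len,
                        a.rev_primer_len,
                        a.set_id,
                        a.efficiency,
                    )
                )
                + "\n"
            )


def read_panel_tsv(path: str | Path) -> Panel:
    amplicons: list[Amplicon] = []
    target = None
    genome_name = ""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise PanelError(f"unexpected panel TSV header in {path}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#target":
                target = Region(int(fields[1]), int(fields[2]), "target")
                genome_name = fields[3] if len(fields) > 3 else ""
                continue
            amplicons.append(
                Amplicon(
                    id=fields[0],
                    outer=Region(int(fields[1]), int(fields[2])),
                    insert=Region(int(fields[3]), int(fields[4])),
                    fwd_primer_len=int(fields[5]),
                    rev_primer_len=int(fields[6]),
                    set_id=int(fields[7]),
                    efficiency=float(fields[8]),
                )
            )
    if target is None:
        raise PanelError(f"panel TSV {path} missing #target line")
    return Panel(amplicons=amplicons, target=target, genome_name=genome_name)


def write_inserts_bed(panel: Panel, genome_length: int, path: str | Path) -> None:
    """Export inserts as 6-column BED (0-based half-open); wrapping inserts
    split into two lines."""
    with open(path, "w") as fh:
        for a in panel.amplicons:
            name = a.id
            score = "0"
            strand = "+"
            chrom = panel.genome_name or "mt"
            r = a.insert
            if r.wraps:
                spans = [(r.start - 1, genome_length), (0, r.end)]
            else:
                spans = [(r.start - 1, r.end)]
            for s, e in spans:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")
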