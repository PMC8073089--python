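"""Stranded pileups and threshold-based forensic variant calling.

Calling is deliberately non-probabilistic: a base (or deletion, or insertion
ordinal) at a position is *detected* when its fraction of the total read
depth meets the analytical threshold (AT), is *interpretable* at the
interpretation threshold (IT), and the position itself must carry at least
the minimum read count to be called at all.  Two or more detected bases at a
position are reported as the IUPAC mixed code (point heteroplasmy);
insertion ordinals carried by only part of the reads render lowercase
(length heteroplasmy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .align import AlignedRead
from .nomenclature import (
    Haplotype,
    VariantToken,
    iupac_code,
    positions_to_regions,
)
from .panel import Panel
from .reference import CircularGenome, Region, region_length


def _round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class CallError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Analysis method settings.

    Presets used throughout: control region {AT 10%, IT 10%, min 64 reads},
    whole genome {AT 6%, IT 6%, min 45 reads}; minimum base quality Q30 in
    both.
    """

    analytical_threshold: float = 10.0  # percent of total depth
    interpretation_threshold: float = 10.0
    min_read_count: int = 64
    min_q: int = 30

    def __post_init__(self) -> None:
        at, it = self.analytical_threshold, self.interpretation_threshold
        if not (0 <= at <= it <= 100):
            raise CallError("need 0 <= AT <= IT <= 100")
        if self.min_read_count < 0:
            raise CallError("min_read_count must be >= 0")


CONTROL_REGION_THRESHOLDS = Thresholds(10.0, 10.0, 64, 30)
WHOLE_GENOME_THRESHOLDS = Thresholds(6.0, 6.0, 45, 30)

_BASES = ("A", "C", "G", "T", "del")
_STRAND = {"+": 0, "-": 1}


@dataclass
class Pileup:
    """Per-position, per-strand filtered counts plus insertion events."""

    genome_length: int
    # counts[pos][base] = [fwd, rev]; positions 1-based
    counts: dict[int, dict[str, list[int]]] = field(default_factory=dict)
    # insertions[(anchor_pos, ordinal, base)] = [fwd, rev]
    insertions: dict[tuple[int, int, str], list[int]] = field(default_factory=dict)

    def _slot(self, pos: int) -> dict[str, list[int]]:
        if pos not in self.counts:
            self.counts[pos] = {b: [0, 0] for b in _BASES}
        return self.counts[pos]

    def add_base(self, pos: int, base: str, strand: str) -> None:
        if base not in ("A", "C", "G", "T"):
            return  # N and friends never count
        self._slot(pos)[base][_STRAND[strand]] += 1

    def add_deletion(self, pos: int, strand: str) -> None:
        self._slot(pos)["del"][_STRAND[strand]] += 1

    def add_insertion(self, anchor: int, ordinal: int, base: str, strand: str) -> None:
        key = (anchor, ordinal, base.upper())
        self.insertions.setdefault(key, [0, 0])[_STRAND[strand]] += 1

    def total_depth(self, pos: int) -> int:
        slot = self.counts.get(pos)
        if not slot:
            return 0
        return sum(sum(v) for v in slot.values())

    def strand_totals(self, pos: int) -> tuple[int, int]:
        slot = self.counts.get(pos)
        if not slot:
            return 0, 0
        return (
            sum(v[0] for v in slot.values()),
            sum(v[1] for v in slot.values()),
        )

    def base_count(self, pos: int, base: str) -> int:
        slot = self.counts.get(pos)
        return sum(slot[base]) if slot else 0


def anchor_insertion(genome: CircularGenome, pos: int, bases: str) -> int:
    """Re-anchor an inserted homopolymer to the 3'-most position of the
    matching reference run (standard forensic alignment convention: a C
    inserted anywhere in the 303..309 run is named 309.1C)."""
    if not bases or len(set(bases)) != 1:
        return pos
    b = bases[0].upper()
    L = genome.length
    p = pos
    if genome.base(p) != b:
        nxt = p % L + 1
        if genome.base(nxt) != b:
            return pos
        p = nxt
    while True:
        nxt = p % L + 1
        if genome.base(nxt) == b and nxt != pos:
            p = nxt
        else:
            return p


def build_pileup(
    alignments: Iterable[AlignedRead],
    genome: CircularGenome,
    panel: Optional[Panel] = None,
) -> Pileup:
    """Count filtered alignment columns into a stranded pileup.

    Bases masked for quality, soft-clipped (primer or HVII rule), flagged as
    byproduct or NUMT, or on unaligned reads never contribute.
    """
    L = genome.length
    pile = Pileup(genome_length=L)
    for ar in alignments:
        if not ar.aligned:
            continue
        if ar.flags.get("byproduct_filtered") or ar.flags.get("numt_filtered"):
            continue
        strand = ar.strand
        for col in ar.walk(L):
            op, ref_pos = col[0], col[1]
            if op == "M":
                qoff = col[2]
                if qoff in ar.masked_offsets or qoff in ar.clipped_offsets:
                    continue
                pile.add_base(ref_pos, ar.seq[qoff], strand)
            elif op == "D":
                if ref_pos in ar.excluded_ref:
                    continue
                pile.add_deletion(ref_pos, strand)
            else:  # insertion
                qoff, length = col[2]
                offs = range(qoff, qoff + length)
                if any(o in ar.masked_offsets or o in ar.clipped_offsets for o in offs):
                    continue
                bases = ar.seq[qoff : qoff + length]
                anchor = anchor_insertion(genome, ref_pos, bases)
                for ordinal, b in enumerate(bases, start=1):
                    pile.add_insertion(anchor, ordinal, b, strand)
    return pile


@dataclass
class VariantCall:
    position: int
    kind: str  # substitution | insertion | deletion | reference | no_call
    called: str  # base(s)/IUPAC/del/inserted base; "" for no_call
    fraction: float  # percent of total depth supporting the call
    depth: int
    strand_depth: int
    status: str  # called | below_IT | no_call
    ordinal: int = 0
    lowercase: bool = False

    def token(self) -> Optional[VariantToken]:
        if self.status == "no_call" or self.kind == "reference":
            return None
        if self.kind == "deletion":
            return VariantToken(self.position, 0, "del")
        sym = self.called.lower() if self.lowercase else self.called.upper()
        return VariantToken(self.position, self.ordinal, sym)


def strand_depth(pileup: Pileup, position: int) -> int:
    """Read count of the majority strand at a position (ties report the
    forward strand's count)."""
    fwd, rev = pileup.strand_totals(position)
    return fwd if fwd >= rev else rev


def call_position(
    pileup: Pileup,
    position: int,
    thresholds: Thresholds,
    genome: CircularGenome,
) -> VariantCall:
    """Threshold calling at one position.

    Below the minimum read count the position is a no-call.  Otherwise every
    base/deletion at >= AT percent of total depth is retained: a single
    retained base calls directly, two or more render as the IUPAC mixed code,
    a retained deletion together with nothing else calls ``del``.  Retained
    non-reference evidence in [AT, IT) is flagged ``below_IT``.
    """
    depth = pileup.total_depth(position)
    sdepth = strand_depth(pileup, position)
    if depth < thresholds.min_read_count:
        return VariantCall(position, "no_call", "", 0.0, depth, sdepth, "no_call")
    slot = pileup.counts.get(position, {b: [0, 0] for b in _BASES})
    at = thresholds.analytical_threshold
    it = thresholds.interpretation_threshold
    fracs = {b: 100.0 * sum(v) / depth for b, v in slot.items()}
    retained = [b for b in _BASES if fracs[b] >= at and sum(slot[b]) > 0]
    ref_base = genome.base(position)
    if not retained:
        return VariantCall(position, "no_call", "", 0.0, depth, sdepth, "no_call")
    retained_bases = [b for b in retained if b != "del"]
    del_retained = "del" in retained
    nonref = [b for b in retained if b != ref_base]
    status = "called"
    if nonref and all(fracs[b] < it for b in nonref):
        status = "below_IT"
    if del_retained and not retained_bases:
        return VariantCall(
            position, "deletion", "del", _round_half_up(fracs["del"]),
            depth, sdepth, status,
        )
    if len(retained_bases) == 1:
        b = retained_bases[0]
        kind = "reference" if b == ref_base and not del_retained else "substitution"
        if b == ref_base and del_retained:
            # partial deletion alongside reference base: report the deletion
            # as length-variant (lowercase rendering handled by caller)
            return VariantCall(
                position, "deletion", "del", _round_half_up(fracs["del"]),
                depth, sdepth, status, lowercase=True,
            )
        frac = fracs[b] if b != ref_base else fracs[ref_base]
        return VariantCall(
            position, kind, b, _round_half_up(frac), depth, sdepth,
            "called" if kind == "reference" else status,
        )
    code = iupac_code(retained_bases)
    minor = min((fracs[b] for b in retained_bases if b != ref_base), default=fracs[code] if code in fracs else 0.0)
    return VariantCall(
        position, "substitution", code, _round_half_up(minor), depth, sdepth, status
    )


def insertion_calls(
    pileup: Pileup,
    thresholds: Thresholds,
    region: Optional[Region] = None,
    genome_length: Optional[int] = None,
) -> list[VariantCall]:
    """Insertion ordinals whose supporting fraction of the anchor's total
    depth meets AT.  Ordinals carried by fewer than (100 - AT) percent of
    reads render lowercase (length heteroplasmy)."""
    at = thresholds.analytical_threshold
    out: list[VariantCall] = []
    anchors = sorted({k[0] for k in pileup.insertions})
    for anchor in anchors:
        if region is not None and genome_length is not None:
            if not region.contains(anchor, genome_length):
                continue
        depth = pileup.total_depth(anchor)
        if depth < thresholds.min_read_count or depth == 0:
            continue
        by_ordinal: dict[int, dict[str, int]] = {}
        for (a, ordinal, base), counts in pileup.insertions.items():
            if a != anchor:
                continue
            by_ordinal.setdefault(ordinal, {})[base] = sum(counts)
        for ordinal in sorted(by_ordinal):
            base, count = max(by_ordinal[ordinal].items(), key=lambda kv: kv[1])
            frac = 100.0 * count / depth
            if frac < at:
                continue
            lowercase = frac < (100.0 - at)
            fwd = sum(
                c[0]
                for (a, o, b), c in pileup.insertions.items()
                if a == anchor and o == ordinal and b == base
            )
            rev = count - fwd
            out.append(
                VariantCall(
                    position=anchor,
                    kind="insertion",
                    called=base,
                    fraction=_round_half_up(frac),
                    depth=depth,
                    strand_depth=max(fwd, rev) if fwd != rev else fwd,
                    status="called" if frac >= thresholds.interpretation_threshold else "below_IT",
                    ordinal=ordinal,
                    lowercase=lowercase,
                )
            )
    return out


def length_heteroplasmy_calls(
    pileup: Pileup,
    region: Region,
    thresholds: Thresholds,
    genome: CircularGenome,
    declared_homopolymers: Sequence[Region] = (),
    uas_compat: bool = False,
) -> list[VariantCall]:
    """Insertion-ordinal calls inside a declared homopolymeric region, with
    the two documented compatibility corrections applied when
    ``uas_compat`` is on:

    * a fully deleted interrupting T with partial C insertion re-reports as
      the substituted T position (uppercase C) plus a lowercase terminal
      insertion (the "16189C + 16193c" form);
    * mixed base calls at the interrupting T of the HVII stretch (position
      310) re-anchor to insertion ordinals at 309.
    """
    declared = list(declared_homopolymers) or [region]
    if not any(
        r.start == region.start and r.end == region.end for r in declared
    ):
        raise CallError(
            f"region {region.start}..{region.end} is not a declared homopolymer"
        )
    calls = insertion_calls(pileup, thresholds, region, genome.length)
    if not uas_compat:
        return calls
    # correction 1: deletion of the interrupting T + partial C insertion
    t_pos = None
    for pos in region.positions(genome.length):
        if genome.base(pos) == "T":
            t_pos = pos
            break
    if t_pos is not None:
        depth = pileup.total_depth(t_pos)
        if depth >= thresholds.min_read_count and depth > 0:
            del_frac = 100.0 * pileup.base_count(t_pos, "del") / depth
            partial_c = [
                c
                for c in calls
                if c.kind == "insertion" and c.called == "C" and c.lowercase
            ]
            if del_frac >= 100.0 - thresholds.analytical_threshold and partial_c:
                calls = [c for c in calls if c.position != t_pos]
                calls.append(
                    VariantCall(
                        t_pos, "substitution", "C",
                        _round_half_up(del_frac), depth,
                        strand_depth(pileup, t_pos), "called",
                    )
                )
            else:
                # correction 2: a C/T mixed signal at the interrupting T is an
                # alignment-shifted insertion; re-anchor it to the 3' end of
                # the preceding C run as the next insertion ordinal
                at = thresholds.analytical_threshold
                c_frac = 100.0 * pileup.base_count(t_pos, "C") / depth
                t_frac = 100.0 * pileup.base_count(t_pos, "T") / depth
                prev_pos = (t_pos - 2) % genome.length + 1
                if c_frac >= at and t_frac >= at and genome.base(prev_pos) == "C":
                    anchor = anchor_insertion(genome, prev_pos, "C")
                    existing = [c.ordinal for c in calls if c.position == anchor]
                    calls.append(
                        VariantCall(
                            anchor, "insertion", "C",
                            _round_half_up(c_frac), depth,
                            strand_depth(pileup, t_pos), "called",
                            ordinal=max(existing, default=0) + 1,
                            lowercase=c_frac < (100.0 - at),
                        )
                    )
    return sorted(calls, key=lambda c: (c.position, c.ordinal))


@dataclass
class SampleResult:
    haplotype: Haplotype
    calls: list[VariantCall]
    no_call_regions: list[Region]
    coverage_percent: float
    per_amplicon_depth: dict[str, float] = field(default_factory=dict)


def _merge_no_calls(positions: list[int], target: Region, genome_length: int) -> list[Region]:
    """Merge no-call positions into regions following the target's circular
    order (a run across the origin becomes a single wrapping region)."""
    pos_set = set(positions)
    regions: list[Region] = []
    run: list[int] = []
    for p in target.positions(genome_length):
        if p in pos_set:
            run.append(p)
        elif run:
            regions.append(Region(run[0], run[-1]))
            run = []
    if run:
        regions.append(Region(run[0], run[-1]))
    return regions


def call_sample(
    pileup: Pileup,
    thresholds: Thresholds,
    target: Region,
    genome: CircularGenome,
    panel: Optional[Panel] = None,
    alignments: Optional[Sequence[AlignedRead]] = None,
) -> SampleResult:
    """Call every target position, merge no-calls into regions and render the
    haplotype in forensic nomenclature.

    ``coverage_percent`` is the share of target positions carrying an
    unambiguous call (depth >= minimum read count and a retained base),
    rounded half-up to one decimal.
    """
    L = genome.length
    calls: list[VariantCall] = []
    no_call_positions: list[int] = []
    for pos in target.positions(L):
        vc = call_position(pileup, pos, thresholds, genome)
        if vc.status == "no_call":
            no_call_positions.append(pos)
        elif vc.kind != "reference":
            calls.append(vc)
    calls.extend(insertion_calls(pileup, thresholds, target, L))
    calls.sort(key=lambda c: (c.position, c.ordinal))
    no_call_regions = _merge_no_calls(no_call_positions, target, L)
    target_len = region_length(target, L)
    covered = target_len - len(no_call_positions)
    coverage = _round_half_up(100.0 * covered / target_len, 1)
    covered_pos = sorted(
        set(target.positions(L)) - set(no_call_positions)
    )
    tokens = [t for t in (c.token() for c in calls) if t is not None]
    # deduplicate (position, ordinal) keeping the higher-fraction call
    dedup: dict[tuple[int, int], VariantToken] = {}
    for c in calls:
        t = c.token()
        if t is None:
            continue
        dedup[(t.position, t.ordinal)] = t
    hap = Haplotype(
        tokens=list(dedup.values()),
        covered_range=positions_to_regions(covered_pos),
    )
    per_amp: dict[str, float] = {}
    if panel is not None:
        for a in panel.amplicons:
            depths = [pileup.total_depth(p) for p in a.insert.positions(L)]
            per_amp[a.id] = _round_half_up(sum(depths) / len(depths), 1)
    return SampleResult(
        haplotype=hap,
        calls=calls,
        no_call_regions=no_call_regions,
        coverage_percent=coverage,
        per_amplicon_depth=per_amp,
    )


def write_variant_tsv(result: SampleResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tkind\tcall\tfraction\tdepth\tstrand_depth\tstatus\n")
        for c in result.calls:
            token = c.token()
            shown = str(token) if token else c.called
            fh.write(
                f"{c.position}\t{c.kind}\t{shown}\t{c.fraction}\t{c.depth}"
                f"\t{c.strand_depth}\t{c.status}\n"
            )


def write_no_call_bed(
    result: SampleResult, genome: CircularGenome, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for r in result.no_call_regions:
            if r.wraps:
                fh.write(f"{genome.name}\t{r.start - 1}\t{genome.length}\n")
                fh.write(f"{genome.name}\t0\t{r.end}\n")
            else:
                fh.write(f"{genome.name}\t{r.start - 1}\t{r.end}\n")


def write_vcf(
    result: SampleResult,
    genome: CircularGenome,
    path: str | Path,
    sample_name: str = "sample",
) -> None:
    """Minimal VCF 4.2 with the circular contig declared in the header."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={genome.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Variant fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in result.calls:
            if c.kind == "deletion":
                pos = c.position - 1 if c.position > 1 else genome.length
                ref = genome.base(pos) + genome.base(c.position)
                alt = genome.base(pos)
            elif c.kind == "insertion":
                pos = c.position
                ref = genome.base(pos)
                alt = ref + c.called.upper()
            else:
                pos = c.position
                ref = genome.base(pos)
                alt = c.called.upper()
                if alt == ref:
                    continue
            fh.write(
                f"{genome.name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"DP={c.depth};AF={c.fraction / 100.0:.4f}\n"
            )
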