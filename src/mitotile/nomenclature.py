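"""SWGDAM-style mitochondrial variant nomenclature.

Variants are written relative to the reference as whitespace-separated
tokens ``<pos>[.<ordinal>]<symbol>``:

* ``73G`` — substitution (symbol may be an IUPAC mixed-base code: ``497M``),
* ``315.1C`` — insertion of a C after position 315 (ordinal counts multiple
  inserted bases: ``309.1C 309.2C``),
* ``249del`` — deletion of the reference base,
* a lowercase base (``309.1c``, ``523a``) marks a length-heteroplasmic
  observation: the token is present in only part of the molecule population.

Tokens are ordered by (position, ordinal); formatting a parsed haplotype
returns the canonical single-spaced sorted string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .reference import CircularGenome, Region, subsequence

IUPAC2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}
IUPAC_MULTI = {
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_SYMBOLS = "ACGTRYMKWSBDHVN"
_TOKEN_RE = re.compile(
    rf"^(\d+)(?:\.(\d+))?(del|[{_SYMBOLS}{_SYMBOLS.lower()}])$", re.IGNORECASE
)


class NomenclatureError(ValueError):
    pass


def iupac_code(bases: Iterable[str]) -> str:
    """IUPAC code for a set of observed bases (2-base mixes Y/R/M/S/W/K,
    3+ bases B/D/H/V/N)."""
    s = frozenset(b.upper() for b in bases)
    if len(s) == 1:
        return next(iter(s))
    if s in IUPAC2:
        return IUPAC2[s]
    if s in IUPAC_MULTI:
        return IUPAC_MULTI[s]
    raise NomenclatureError(f"no IUPAC code for base set {sorted(s)}")


@dataclass(frozen=True, order=True)
class VariantToken:
    """One variant observation in forensic mtDNA notation."""

    position: int
    ordinal: int = 0  # >0 iff insertion
    symbol: str = ""  # single IUPAC letter (case preserved) or "del"

    @property
    def kind(self) -> str:
        if self.symbol.lower() == "del":
            return "deletion"
        return "insertion" if self.ordinal > 0 else "substitution"

    @property
    def lowercase(self) -> bool:
        """Length-heteroplasmy marker (token present in only part of reads)."""
        return self.symbol != "del" and self.symbol.islower()

    def __str__(self) -> str:
        ins = f".{self.ordinal}" if self.ordinal else ""
        return f"{self.position}{ins}{self.symbol}"


@dataclass
class Haplotype:
    """A sorted, duplicate-free collection of variant tokens plus the
    reference ranges over which the sample was actually covered."""

    tokens: list[VariantToken] = field(default_factory=list)
    covered_range: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tokens = sorted(self.tokens, key=lambda t: (t.position, t.ordinal))
        seen = set()
        for t in self.tokens:
            key = (t.position, t.ordinal)
            if key in seen:
                raise NomenclatureError(f"duplicate variant position {t}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def parse_token(text: str) -> VariantToken:
    m = _TOKEN_RE.match(text)
    if not m:
        raise NomenclatureError(f"malformed variant token: {text!r}")
    pos = int(m.group(1))
    ordinal = int(m.group(2)) if m.group(2) else 0
    symbol = m.group(3)
    if symbol.lower() == "del":
        if ordinal:
            raise NomenclatureError(f"deletion token cannot carry an ordinal: {text!r}")
        symbol = "del"
    return VariantToken(position=pos, ordinal=ordinal, symbol=symbol)


def parse_haplotype(text: str, genome: Optional[CircularGenome] = None) -> Haplotype:
    """Parse a whitespace-separated variant string.

    Positions are validated against the genome length when a genome is given.
    Case is preserved (lowercase = length heteroplasmy).
    """
    tokens = [parse_token(tok) for tok in text.split()]
    if genome is not None:
        for t in tokens:
            if not 1 <= t.position <= genome.length:
                raise NomenclatureError(
                    f"position {t.position} outside genome of length {genome.length}"
                )
    return Haplotype(tokens=tokens)


def format_haplotype(hap: Haplotype) -> str:
    """Canonical single-spaced, (position, ordinal)-sorted rendering."""
    return " ".join(str(t) for t in hap.tokens)


def _restrict(hap: Haplotype, regions: list[Region], genome_length: int) -> set[VariantToken]:
    out = set()
    for t in hap.tokens:
        if any(r.contains(t.position, genome_length) for r in regions):
            out.add(t)
    return out


def _intersect_covered(
    a: list[Region], b: list[Region], genome_length: int
) -> list[Region]:
    """Positions covered by both range lists, merged into regions."""
    pos_a = set()
    for r in a:
        pos_a.update(r.positions(genome_length))
    common = sorted(
        p for r in b for p in r.positions(genome_length) if p in pos_a
    )
    return positions_to_regions(common)


def positions_to_regions(positions: list[int]) -> list[Region]:
    """Merge a sorted list of 1-based positions into maximal linear runs."""
    regions: list[Region] = []
    run_start = prev = None
    for p in positions:
        if run_start is None:
            run_start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            regions.append(Region(run_start, prev))
            run_start = prev = p
    if run_start is not None:
        regions.append(Region(run_start, prev))
    return regions


def compare_haplotypes(
    a: Haplotype,
    b: Haplotype,
    genome_length: int,
    restrict: Optional[Region] = None,
):
    """Concordance between two haplotypes over their mutually covered range.

    Returns ``(concordance_percent, shared, only_a, only_b)``.  Concordance is
    100·|shared| / |union| of the variant sets restricted to the comparison
    region, rounded to one decimal; two identical (possibly empty) sets give
    100.0.  If the covered ranges of the two samples are disjoint the
    comparison is undefined and the percent is ``None``.
    """
    regions: list[Region]
    if a.covered_range and b.covered_range:
        regions = _intersect_covered(a.covered_range, b.covered_range, genome_length)
        if not regions:
            return None, set(), set(), set()
    else:
        regions = [Region(1, genome_length)]
    if restrict is not None:
        regions = _intersect_covered(regions, [restrict], genome_length)
        if not regions:
            return None, set(), set(), set()
    set_a = _restrict(a, regions, genome_length)
    set_b = _restrict(b, regions, genome_length)
    shared = set_a & set_b
    union = set_a | set_b
    if not union:
        pct = 100.0
    else:
        pct = round(100.0 * len(shared) / len(union), 1)
    return pct, shared, set_a - shared, set_b - shared


def reconstruct_sequence(
    genome: CircularGenome, region: Region, tokens: Iterable[VariantToken]
) -> str:
    """Apply variant tokens to the reference subsequence of ``region``.

    Substitutions replace the base (IUPAC codes kept verbatim), insertions are
    inserted after their anchor in ordinal order, deletions remove the base.
    Length = region length + insertions − deletions.
    """
    ref = subsequence(genome, region)
    positions = list(region.positions(genome.length))
    index = {p: i for i, p in enumerate(positions)}
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[tuple[int, str]]] = {}
    for t in tokens:
        if t.position not in index:
            continue
        if t.kind == "deletion":
            dels.add(t.position)
        elif t.kind == "insertion":
            ins.setdefault(t.position, []).append((t.ordinal, t.symbol.upper()))
        else:
            subs[t.position] = t.symbol.upper()
    out: list[str] = []
    for p in positions:
        if p in dels:
            pass
        elif p in subs:
            out.append(subs[p])
        else:
            out.append(ref[index[p]])
        if p in ins:
            out.extend(b for _, b in sorted(ins[p]))
    return "".join(out)


def empop_report(
    sample_name: str,
    haplotype: Haplotype,
    genome: CircularGenome,
    default_range: Optional[Region] = None,
) -> str:
    """Render the two-block population-database-compatible report.

    Block 1 is the reconstructed sample sequence for each covered sub-range in
    FASTA format; block 2 is the variant list headed by the covered range(s).
    """
    ranges = haplotype.covered_range or ([default_range] if default_range else [])
    if not ranges:
        raise NomenclatureError("empty coverage: nothing to report")
    lines: list[str] = []
    for r in ranges:
        seq = reconstruct_sequence(genome, r, haplotype.tokens)
        lines.append(f">{sample_name} {r.start}-{r.end}")
        for i in range(0, len(seq), 70):
            lines.append(seq[i : i + 70])
    range_header = "; ".join(f"{r.start}-{r.end}" for r in ranges)
    lines.append("")
    lines.append(f"# sample: {sample_name}")
    lines.append(f"# range: {range_header}")
    lines.append(format_haplotype(haplotype))
    return "\n".join(lines) + "\n"
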