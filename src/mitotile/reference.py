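"""Circular mitochondrial reference genome and 1-based coordinate arithmetic.

Forensic mtDNA work names every variant against a fixed circular reference
using 1-based inclusive positions (e.g. "73G" means the base at reference
position 73 is a G). The control region spans the replication origin, so a
region may *wrap*: ``start > end`` denotes the arc running from ``start``
through the origin to ``end`` (the canonical control region is 16024..576).

This module provides the genome container, region arithmetic on the circle,
and a deterministic synthetic stand-in for the 16,569 bp human reference
(see :func:`synthetic_reference`).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

MT_LENGTH = 16_569  # canonical human mitochondrial genome length (bp)

_IUPAC_REF = set("ACGTN")


class ReferenceError(ValueError):
    """Raised for malformed reference input (bad FASTA, bad coordinates)."""


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive arc on a circular genome.

    ``end < start`` denotes a wrap across the origin, e.g. ``Region(16024, 576)``
    is the ~1122 bp control region of the human mtGenome.
    """

    start: int
    end: int
    label: str = ""

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def validate(self, genome_length: int) -> None:
        if not (1 <= self.start <= genome_length and 1 <= self.end <= genome_length):
            raise ReferenceError(
                f"region {self.start}..{self.end} out of range for genome of "
                f"length {genome_length}"
            )

    def contains(self, position: int, genome_length: int) -> bool:
        """Circular membership test for a 1-based position."""
        self.validate(genome_length)
        if not 1 <= position <= genome_length:
            return False
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self, genome_length: int):
        """Iterate 1-based positions of the arc in circle order."""
        self.validate(genome_length)
        if self.wraps:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class CircularGenome:
    """An upper-case single-contig circular nucleotide sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ReferenceError("empty reference sequence")
        bad = set(seq) - _IUPAC_REF
        if bad:
            raise ReferenceError(f"non-IUPAC characters in reference: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ReferenceError(f"position {position} out of range 1..{self.length}")
        return self.sequence[position - 1]


def region_length(region: Region, genome_length: int) -> int:
    """Length in bp of a (possibly wrapping) region on a circle.

    Non-wrapping: ``end - start + 1``.  Wrapping: the suffix from ``start``
    to the origin plus the prefix through ``end``, i.e.
    ``(genome_length - start + 1) + end``.  The control region 16024..576 on
    a 16,569 bp circle therefore has length 1122.
    """
    region.validate(genome_length)
    if region.wraps:
        return (genome_length - region.start + 1) + region.end
    return region.end - region.start + 1


def subsequence(genome: CircularGenome, region: Region) -> str:
    """Extract the region's sequence; wrapping regions concatenate suffix+prefix."""
    region.validate(genome.length)
    if region.wraps:
        return genome.sequence[region.start - 1 :] + genome.sequence[: region.end]
    return genome.sequence[region.start - 1 : region.end]


def complement_region(region: Region, genome_length: int) -> Region:
    """The other arc of the circle, so the two lengths sum to the genome length."""
    region.validate(genome_length)
    start = region.end % genome_length + 1
    end = (region.start - 2) % genome_length + 1
    return Region(start, end, label=f"complement({region.start}..{region.end})")


@dataclass(frozen=True)
class NamedRegions:
    """Canonical forensic landmarks of the mitochondrial control region.

    Defaults follow standard human mtDNA coordinates: the control region wraps
    the origin, HVI/HVII are its hypervariable segments and the C-stretches /
    AC repeat are the homopolymeric hotspots that receive special handling in
    alignment and length-heteroplasmy calling.
    """

    control_region: Region = field(default=Region(16024, 576, "CR"))
    hv1: Region = field(default=Region(16024, 16365, "HVI"))
    hv2: Region = field(default=Region(57, 372, "HVII"))
    hv1_cstretch: Region = field(default=Region(16184, 16193, "HVI C-stretch"))
    hv2_cstretch: Region = field(default=Region(303, 315, "HVII C-stretch"))
    ac_repeat: Region = field(default=Region(515, 524, "AC repeat"))

    def validate(self, genome_length: int) -> None:
        for r in (
            self.control_region,
            self.hv1,
            self.hv2,
            self.hv1_cstretch,
            self.hv2_cstretch,
            self.ac_repeat,
        ):
            r.validate(genome_length)

    def hotspots(self) -> list[Region]:
        """Regions excluded when deriving background-noise maxima."""
        return [self.hv1_cstretch, self.hv2_cstretch, self.ac_repeat]


def load_fasta(path: str | Path) -> CircularGenome:
    """Load a single-record FASTA as a circular genome (sequence upper-cased)."""
    path = Path(path)
    if not path.exists():
        raise ReferenceError(f"no such FASTA file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return CircularGenome(name=rec.id, sequence=str(rec.seq))


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    seq = genome.sequence
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _motif_overwrite(seq: list[str], start: int, motif: str) -> None:
    seq[start - 1 : start - 1 + len(motif)] = list(motif)


def synthetic_reference(seed: int = 2021, length: int = MT_LENGTH) -> CircularGenome:
    """A deterministic synthetic circular genome standing in for the human
    mitochondrial reference.

    This is *synthetic* data: the true 16,569 bp reference sequence is not
    bundled, so a reproducible surrogate is generated with the structural
    motifs the pipeline logic depends on placed at their canonical
    coordinates:

    * HVII C-stretch 303..315 rendered as ``CCCCCCC T CCCCC`` (T at 310),
    * HVI C-stretch 16184..16193 rendered as ``CCCCC T CCCC`` (T at 16189),
    * AC dinucleotide repeat at 515..524,
    * an ``A`` at position 263 (site of the near-universal 263G variant).

    Elsewhere the sequence is random with homopolymer runs capped at three
    bases so that insertion anchoring is unambiguous outside the declared
    homopolymeric regions.
    """
    rng = random.Random(seed)
    bases = "ACGT"
    seq: list[str] = []
    for _ in range(length):
        choices = bases
        if len(seq) >= 3 and seq[-1] == seq[-2] == seq[-3]:
            choices = bases.replace(seq[-1], "")
        seq.append(rng.choice(choices))
    if length == MT_LENGTH:
        _motif_overwrite(seq, 303, "CCCCCCCTCCCCC")  # 303-309 C, 310 T, 311-315 C
        _motif_overwrite(seq, 16184, "CCCCCTCCCC")  # 16184-16188 C, 16189 T, 16190-16193 C
        _motif_overwrite(seq, 515, "ACACACACAC")  # AC repeat 515-524
        # keep motif flanks from extending the homopolymers
        _motif_overwrite(seq, 302, "A")
        _motif_overwrite(seq, 316, "G")
        _motif_overwrite(seq, 16183, "A")
        _motif_overwrite(seq, 16194, "G")
        _motif_overwrite(seq, 514, "T")
        _motif_overwrite(seq, 525, "G")
        _motif_overwrite(seq, 263, "A")
        _motif_overwrite(seq, 73, "A")
    return CircularGenome(name=f"synthetic-mt-{seed}", sequence="".join(seq))
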