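"""Synthetic tiled-amplicon sequencing runs with ground truth.

The simulator is the package's stand-in for the wet lab: it produces paired
FASTQ reads, sample sheets and truth sidecars with the structures the
analysis modules assume — single-source haplotypes, point and length
heteroplasmy, two-person mixtures, no-template controls, nuclear-insert
(NUMT) contamination, dual-index crosstalk and run-to-run carryover.

Model, fixed as the package's study conditions:

* each read pair derives from one amplicon molecule of one contributor;
  amplicons are chosen proportionally to their efficiency weights and
  contributors proportionally to their mixture weights;
* sub-unit variant fractions are realized per molecule as Bernoulli draws
  (heteroplasmy), fraction-1.0 variants are constitutive;
* base-call errors are substitutions at ``base_error_rate`` (default 1e-3);
  indel errors occur only inside homopolymer runs of >= 4 nt, one
  insertion/deletion per affected molecule at ``stutter_rate`` (default 0.01
  per run) — a stutter-like model that exercises C-stretch handling;
* qualities are drawn from a clipped normal (mean Q36, SD 3, floor Q2);
* read 1 is the forward strand from the amplicon 5' end, read 2 the reverse
  complement from the 3' end, both truncated at the cycle count (151 or 201).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .nomenclature import parse_haplotype
from .reference import CircularGenome, Region
from .panel import Panel

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class VariantSpec:
    """One variant to plant: substitution, insertion or deletion at a
    reference position, carried by ``fraction`` of molecules (1.0 = fixed)."""

    position: int
    kind: str  # substitution | insertion | deletion
    alt: str = ""  # inserted bases / substituted base; empty for deletion
    insertion_index: int = 0  # ordinal for pos.N naming
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise SimulationError(f"unknown variant kind {self.kind!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise SimulationError("fraction must be in (0, 1]")
        if self.kind == "insertion" and (not self.alt or self.insertion_index < 1):
            raise SimulationError("insertion needs alt bases and ordinal >= 1")
        if self.kind == "substitution" and len(self.alt) != 1:
            raise SimulationError("substitution needs a single alt base")
        if self.kind == "deletion" and self.alt:
            raise SimulationError("deletion carries no alt bases")


@dataclass
class HaplotypeSpec:
    """A named set of variants defining one contributor molecule."""

    name: str
    variants: list[VariantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        ins_by_pos: dict[int, list[int]] = {}
        for v in self.variants:
            if v.kind in ("substitution", "deletion"):
                if v.position in seen:
                    raise SimulationError(
                        f"conflicting variants at position {v.position}"
                    )
                seen.add(v.position)
            else:
                ins_by_pos.setdefault(v.position, []).append(v.insertion_index)
        for pos, ordinals in ins_by_pos.items():
            if sorted(ordinals) != list(range(1, len(ordinals) + 1)):
                raise SimulationError(
                    f"insertion ordinals at {pos} must be contiguous from 1"
                )

    @classmethod
    def from_string(
        cls, name: str, text: str, lowercase_fraction: float = 0.6
    ) -> "HaplotypeSpec":
        """Build a spec from a forensic variant string; lowercase tokens become
        sub-unit (length-heteroplasmic) fractions."""
        hap = parse_haplotype(text)
        variants = []
        for t in hap.tokens:
            frac = lowercase_fraction if t.lowercase else 1.0
            if t.kind == "deletion":
                variants.append(VariantSpec(t.position, "deletion", fraction=frac))
            elif t.kind == "insertion":
                variants.append(
                    VariantSpec(
                        t.position,
                        "insertion",
                        alt=t.symbol.upper(),
                        insertion_index=t.ordinal,
                        fraction=frac,
                    )
                )
            else:
                variants.append(
                    VariantSpec(t.position, "substitution", alt=t.symbol.upper(), fraction=frac)
                )
        return cls(name=name, variants=variants)


@dataclass
class QualityProfile:
    mean_q: float = 36.0
    sd_q: float = 3.0
    floor_q: int = 2
    ceil_q: int = 40


@dataclass
class LibrarySpec:
    """One library (sample) to simulate; ``total_read_pairs = 0`` models an
    amplification-negative control (NTC)."""

    sample_name: str
    contributors: list[tuple[HaplotypeSpec, float]]
    total_read_pairs: int
    per_amplicon_efficiency: dict[str, float] = field(default_factory=dict)
    base_error_rate: float = 0.001
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    stutter_rate: float = 0.01
    numt_fraction: float = 0.0
    read_length: int = 151
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_read_pairs < 0:
            raise SimulationError("total_read_pairs must be >= 0")
        if self.total_read_pairs > 0:
            wsum = sum(w for _, w in self.contributors)
            if abs(wsum - 1.0) > 1e-9:
                raise SimulationError("contributor weights must sum to 1")


@dataclass
class RunSpec:
    """A pooled sequencing run: libraries with dual indexes, bait index pairs
    with no physical library, optional crosstalk and carryover."""

    libraries: list[tuple[LibrarySpec, str, str]]  # (library, i7, i5)
    bait_indexes: list[tuple[str, str]] = field(default_factory=list)
    crosstalk_rate: float = 0.0
    carryover: Optional[tuple["RunSpec", float]] = None
    read_length: int = 151
    seed: int = 0

    def __post_init__(self) -> None:
        pairs = [(i7, i5) for _, i7, i5 in self.libraries] + list(self.bait_indexes)
        if len(set(pairs)) != len(pairs):
            raise SimulationError("index pairs must be unique within a run")


@dataclass
class ReadPair:
    name: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    i7: str = ""
    i5: str = ""
    truth: dict = field(default_factory=dict)


def apply_haplotype(
    genome: CircularGenome, hap: HaplotypeSpec
) -> tuple[str, dict[int, Optional[int]]]:
    """Apply the fixed (fraction = 1.0) variants of a haplotype to the genome.

    Returns the mutated sequence and a map from reference position (1-based)
    to 0-based index in the mutated sequence (``None`` for deleted bases).
    Sub-unit fractions are *not* applied here; they are realized per molecule
    in :func:`simulate_library`.
    """
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[tuple[int, str]]] = {}
    for v in hap.variants:
        if not 1 <= v.position <= genome.length:
            raise SimulationError(f"variant position {v.position} outside genome")
        if v.fraction < 1.0:
            continue
        if v.kind == "substitution":
            subs[v.position] = v.alt
        elif v.kind == "deletion":
            dels.add(v.position)
        else:
            ins.setdefault(v.position, []).append((v.insertion_index, v.alt))
    out: list[str] = []
    coord: dict[int, Optional[int]] = {}
    for pos in range(1, genome.length + 1):
        if pos in dels:
            coord[pos] = None
        else:
            coord[pos] = len(out)
            out.append(subs.get(pos, genome.base(pos)))
        for _, alt in sorted(ins.get(pos, [])):
            out.extend(alt)
    return "".join(out), coord


def _realized_variants(
    hap: HaplotypeSpec, rng: random.Random
) -> tuple[dict[int, str], set[int], dict[int, str]]:
    """Per-molecule realization: (substitutions, deletions, insertions).

    Insertion ordinals are realized in nested order (ordinal k requires
    k-1), giving a proper length distribution for length heteroplasmy.
    """
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins_parts: dict[int, dict[int, str]] = {}
    for v in hap.variants:
        take = v.fraction >= 1.0 or rng.random() < v.fraction
        if v.kind == "insertion":
            ins_parts.setdefault(v.position, {})[v.insertion_index] = (
                v.alt if take else ""
            )
        elif take:
            if v.kind == "substitution":
                subs[v.position] = v.alt
            else:
                dels.add(v.position)
    ins: dict[int, str] = {}
    for pos, parts in ins_parts.items():
        chunk = ""
        for k in sorted(parts):
            if parts[k] == "":
                break
            chunk += parts[k]
        if chunk:
            ins[pos] = chunk
    return subs, dels, ins


def _molecule_sequence(
    genome: CircularGenome,
    region: Region,
    subs: dict[int, str],
    dels: set[int],
    ins: dict[int, str],
) -> str:
    out: list[str] = []
    for pos in region.positions(genome.length):
        if pos not in dels:
            out.append(subs.get(pos, genome.base(pos)))
        if pos in ins:
            out.append(ins[pos])
    return "".join(out)


def _apply_stutter(seq: str, rng: random.Random, rate: float, min_run: int = 4) -> str:
    """Homopolymer stutter: per run of >= min_run identical bases, with
    probability ``rate`` insert or delete one base of the run."""
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= min_run and rng.random() < rate:
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def _qualities(n: int, profile: QualityProfile, qrng: np.random.Generator) -> str:
    q = np.rint(qrng.normal(profile.mean_q, profile.sd_q, n))
    q = np.clip(q, profile.floor_q, profile.ceil_q).astype(np.uint8) + 33
    return q.tobytes().decode("ascii")


def _with_errors(seq: str, rate: float, rng: random.Random, qrng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    hits = np.nonzero(qrng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        b = out[i]
        out[i] = rng.choice("ACGT".replace(b, "") if b in "ACGT" else "ACGT")
    return "".join(out)


def simulate_library(
    genome: CircularGenome, panel: Panel, spec: LibrarySpec
) -> list[ReadPair]:
    """Simulate the read pairs of one library with truth tags."""
    for amp_id in spec.per_amplicon_efficiency:
        panel.by_id(amp_id)  # raises KeyError for unknown ids
    rng = random.Random(spec.seed)
    qrng = np.random.default_rng([max(spec.seed, 0), 2021])
    if spec.total_read_pairs == 0:
        return []
    amps = list(panel.amplicons)
    weights = [
        a.efficiency * spec.per_amplicon_efficiency.get(a.id, 1.0) for a in amps
    ]
    contributors = spec.contributors
    cweights = [w for _, w in contributors]
    # reference molecule and variant relevance per amplicon, computed once
    from .reference import subsequence

    amp_ref = {a.id: subsequence(genome, a.outer) for a in amps}
    amp_positions = {a.id: set(a.outer.positions(genome.length)) for a in amps}
    relevant: dict[tuple[str, str], list[VariantSpec]] = {}
    for hap, _ in contributors:
        for a in amps:
            relevant[(hap.name, a.id)] = [
                v for v in hap.variants if v.position in amp_positions[a.id]
            ]
    pairs: list[ReadPair] = []
    for i in range(spec.total_read_pairs):
        hap = rng.choices(contributors, weights=cweights)[0][0]
        amp = rng.choices(amps, weights=weights)[0]
        local = relevant[(hap.name, amp.id)]
        if local:
            sub_hap = HaplotypeSpec(name=hap.name, variants=local)
            subs, dels, ins = _realized_variants(sub_hap, rng)
            mol = _molecule_sequence(genome, amp.outer, subs, dels, ins)
        else:
            mol = amp_ref[amp.id]
        mol = _apply_stutter(mol, rng, spec.stutter_rate)
        r1 = mol[: spec.read_length]
        r2 = revcomp(mol)[: spec.read_length]
        r1 = _with_errors(r1, spec.base_error_rate, rng, qrng)
        r2 = _with_errors(r2, spec.base_error_rate, rng, qrng)
        pairs.append(
            ReadPair(
                name=f"{spec.sample_name}:{i:06d}",
                r1_seq=r1,
                r1_qual=_qualities(len(r1), spec.quality_profile, qrng),
                r2_seq=r2,
                r2_qual=_qualities(len(r2), spec.quality_profile, qrng),
                truth={
                    "sample": spec.sample_name,
                    "contributor": hap.name,
                    "amplicon": amp.id,
                    "set_id": amp.set_id,
                },
            )
        )
    return pairs


def spike_numts(
    reads: list[ReadPair],
    numt_decoys: Sequence[tuple[str, str]],
    fraction: float,
    seed: int,
    genome: Optional[CircularGenome] = None,
    read_length: int = 151,
) -> list[ReadPair]:
    """Replace a Bernoulli(fraction) subset of read pairs with fragments drawn
    from nuclear-insert decoy sequences, tagged ``numt`` in truth.

    If a decoy is identical to a segment of the mitochondrial reference a
    warning is emitted: such reads cannot be separated by exclusion matching.
    """
    if not 0.0 <= fraction <= 1.0:
        raise SimulationError("fraction must be in [0, 1]")
    if fraction == 0:
        return reads
    if not numt_decoys:
        raise SimulationError("NUMT decoy set is empty")
    if genome is not None:
        doubled = genome.sequence * 2
        for label, seq in numt_decoys:
            if seq.upper() in doubled:
                warnings.warn(
                    f"NUMT decoy {label!r} is identical to a reference segment; "
                    "exclusion matching cannot detect reads from it"
                )
    rng = random.Random(seed)
    out: list[ReadPair] = []
    for rp in reads:
        if rng.random() >= fraction:
            out.append(rp)
            continue
        label, seq = numt_decoys[rng.randrange(len(numt_decoys))]
        frag_len = min(len(seq), rng.randint(60, 150))
        start = rng.randrange(0, len(seq) - frag_len + 1)
        frag = seq[start : start + frag_len].upper()
        qual = rp.r1_qual
        out.append(
            ReadPair(
                name=rp.name,
                r1_seq=frag[:read_length],
                r1_qual=qual[: len(frag[:read_length])].ljust(len(frag[:read_length]), "I"),
                r2_seq=revcomp(frag)[:read_length],
                r2_qual=qual[: len(frag[:read_length])].ljust(len(frag[:read_length]), "I"),
                i7=rp.i7,
                i5=rp.i5,
                truth={**rp.truth, "numt": label},
            )
        )
    return out


@dataclass
class RunResult:
    reads: list[ReadPair]
    sample_sheet: list[dict]
    truth: dict


def simulate_run(
    runspec: RunSpec, genome: CircularGenome, panel: Panel
) -> RunResult:
    """Simulate a pooled run: per-library reads under their dual indexes,
    optional index crosstalk (misassignment to a sheet entry sharing i5 or
    i7), optional carryover from a previous run, and bait sample-sheet rows
    that emit no reads of their own."""
    rng = random.Random(runspec.seed)
    sheet: list[dict] = []
    for lib, i7, i5 in runspec.libraries:
        role = "ntc" if lib.total_read_pairs == 0 else "sample"
        sheet.append(
            {"Sample_ID": lib.sample_name, "index": i7, "index2": i5, "role": role}
        )
    for n, (i7, i5) in enumerate(runspec.bait_indexes, start=1):
        sheet.append(
            {"Sample_ID": f"bait{n:02d}", "index": i7, "index2": i5, "role": "bait"}
        )
    all_pairs = [(row["index"], row["index2"]) for row in sheet]

    reads: list[ReadPair] = []
    crosstalk_events: list[str] = []
    for lib, i7, i5 in runspec.libraries:
        lib_reads = simulate_library(genome, panel, lib)
        for rp in lib_reads:
            rp.i7, rp.i5 = i7, i5
            if runspec.crosstalk_rate > 0 and rng.random() < runspec.crosstalk_rate:
                sharers = [
                    (a7, a5)
                    for a7, a5 in all_pairs
                    if (a7, a5) != (i7, i5) and (a7 == i7 or a5 == i5)
                ]
                if sharers:
                    rp.i7, rp.i5 = sharers[rng.randrange(len(sharers))]
                    rp.truth["crosstalk_from"] = lib.sample_name
                    crosstalk_events.append(rp.name)
            reads.append(rp)

    carryover_reads: list[str] = []
    if runspec.carryover is not None:
        prev, frac = runspec.carryover
        if frac < 0 or frac > 1:
            raise SimulationError("carryover fraction must be in [0, 1]")
        if frac > 0:
            for lib, i7, i5 in prev.libraries:
                n_carry = int(round(frac * lib.total_read_pairs))
                if n_carry == 0:
                    continue
                sub = LibrarySpec(
                    sample_name=lib.sample_name,
                    contributors=lib.contributors,
                    total_read_pairs=n_carry,
                    per_amplicon_efficiency=lib.per_amplicon_efficiency,
                    base_error_rate=lib.base_error_rate,
                    quality_profile=lib.quality_profile,
                    stutter_rate=lib.stutter_rate,
                    read_length=lib.read_length,
                    seed=rng.randrange(2**31),
                )
                for rp in simulate_library(genome, panel, sub):
                    rp.name = f"carry:{rp.name}"
                    rp.i7, rp.i5 = i7, i5
                    rp.truth["carryover"] = True
                    reads.append(rp)
                    carryover_reads.append(rp.name)

    truth = {
        "libraries": {
            lib.sample_name: {
                "i7": i7,
                "i5": i5,
                "read_pairs": lib.total_read_pairs,
                "contributors": [
                    {"name": h.name, "weight": w} for h, w in lib.contributors
                ],
            }
            for lib, i7, i5 in runspec.libraries
        },
        "baits": [{"i7": i7, "i5": i5} for i7, i5 in runspec.bait_indexes],
        "crosstalk_reads": crosstalk_events,
        "carryover_reads": carryover_reads,
    }
    return RunResult(reads=reads, sample_sheet=sheet, truth=truth)


def write_fastq_pair(
    reads: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write standard 4-line FASTQ; the comment carries the Illumina-style
    index annotation ``<mate>:N:0:<i7>+<i5>``."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rp in reads:
            idx = f"{rp.i7}+{rp.i5}" if rp.i7 else "NNNNNNNN+NNNNNNNN"
            f1.write(f"@{rp.name} 1:N:0:{idx}\n{rp.r1_seq}\n+\n{rp.r1_qual}\n")
            f2.write(f"@{rp.name} 2:N:0:{idx}\n{rp.r2_seq}\n+\n{rp.r2_qual}\n")


def write_sample_sheet(sheet: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Sample_ID,index,index2,role\n")
        for row in sheet:
            fh.write(
                f"{row['Sample_ID']},{row['index']},{row['index2']},"
                f"{row.get('role', 'sample')}\n"
            )


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
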