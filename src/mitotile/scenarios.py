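"""Ready-made simulation scenarios mirroring the validation study designs:
single-source runs, two-person mixtures at fixed ratios, dilution series
and carryover bait runs.

All scenario builders are deterministic in their ``seed`` argument and share
a compact demonstration target (a few hundred bases spanning the origin and
the HVII C-stretch) so that end-to-end analyses stay fast while exercising
circular coordinates, homopolymer handling and heteroplasmy calling.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

from .call import anchor_insertion
from .panel import Panel, design_tiled_panel
from .reference import CircularGenome, NamedRegions, Region, synthetic_reference
from .simulate import (
    HaplotypeSpec,
    LibrarySpec,
    RunSpec,
    VariantSpec,
)

#: compact demo target: wraps the origin and contains the HVII C-stretch
DEMO_TARGET = Region(16469, 380, "demo")


def default_genome(seed: int = 2021) -> CircularGenome:
    return synthetic_reference(seed=seed)


def demo_panel(
    genome: CircularGenome,
    target: Region = DEMO_TARGET,
    seed: int = 7,
    min_len: int = 80,
    max_len: int = 140,
) -> Panel:
    return design_tiled_panel(
        genome, target, min_len=min_len, max_len=max_len, min_overlap=3, seed=seed
    )


def control_region_panel(genome: CircularGenome, seed: int = 7) -> Panel:
    """A full control-region panel (16024..576, 60-150 bp amplicons)."""
    regions = NamedRegions()
    return design_tiled_panel(
        genome, regions.control_region, min_len=60, max_len=150, min_overlap=3, seed=seed
    )


def generate_index_pairs(n: int, seed: int = 0, min_distance: int = 3) -> list[tuple[str, str]]:
    """Generate ``n`` dual-index pairs whose i7 (and i5) sets are pairwise at
    least ``min_distance`` mismatches apart, so single-mismatch demultiplexing
    is unambiguous."""
    rng = random.Random(seed)

    def build_set(count: int) -> list[str]:
        out: list[str] = []
        while len(out) < count:
            cand = "".join(rng.choice("ACGT") for _ in range(8))
            if all(
                sum(1 for a, b in zip(cand, x) if a != b) >= min_distance for x in out
            ):
                out.append(cand)
        return out

    i7s = build_set(n)
    i5s = build_set(n)
    return list(zip(i7s, i5s))


def _eligible_positions(
    genome: CircularGenome, panel: Panel, avoid: Sequence[Region]
) -> list[int]:
    """Target positions suitable for planting unambiguous variants: inside
    the panel target, outside declared homopolymers, not inside reference
    homopolymer runs (where indel naming is alignment-dependent)."""
    L = genome.length
    out = []
    for pos in panel.target.positions(L):
        if any(r.contains(pos, L) for r in avoid):
            continue
        b = genome.base(pos)
        prev_b = genome.base((pos - 2) % L + 1)
        next_b = genome.base(pos % L + 1)
        if b == prev_b or b == next_b:
            continue
        out.append(pos)
    return out


def random_haplotype(
    genome: CircularGenome,
    panel: Panel,
    n_variants: int,
    seed: int,
    name: Optional[str] = None,
    include_indels: bool = True,
    regions: Optional[NamedRegions] = None,
) -> HaplotypeSpec:
    """A random single-source haplotype with fixed (fraction 1.0) variants at
    unambiguous positions; roughly one in four variants is an insertion or
    deletion when ``include_indels`` is set."""
    rng = random.Random(seed)
    regions = regions or NamedRegions()
    avoid = regions.hotspots()
    positions = _eligible_positions(genome, panel, avoid)
    rng.shuffle(positions)
    chosen: list[int] = []
    for p in positions:
        # keep planted variants at least 3 bp apart so alignments stay unambiguous
        if all(min((p - q) % genome.length, (q - p) % genome.length) > 3 for q in chosen):
            chosen.append(p)
        if len(chosen) == n_variants:
            break
    variants: list[VariantSpec] = []
    for p in sorted(chosen):
        ref = genome.base(p)
        roll = rng.random()
        if include_indels and roll < 0.125:
            variants.append(VariantSpec(p, "deletion"))
        elif include_indels and roll < 0.25:
            base = ref  # inserting the anchor's own base keeps naming stable
            anchor = anchor_insertion(genome, p, base)
            variants.append(
                VariantSpec(anchor, "insertion", alt=base, insertion_index=1)
            )
        else:
            alt = rng.choice("ACGT".replace(ref, ""))
            variants.append(VariantSpec(p, "substitution", alt=alt))
    # planted insertions may re-anchor onto an already used position; dedup
    seen: set[tuple[int, int]] = set()
    unique = []
    for v in variants:
        key = (v.position, v.insertion_index)
        if key not in seen:
            seen.add(key)
            unique.append(v)
    return HaplotypeSpec(name=name or f"hap{seed}", variants=unique)


def truth_string(hap: HaplotypeSpec) -> str:
    """Canonical forensic-notation rendering of a haplotype spec's fixed
    variants, for comparison against called haplotypes."""
    toks = []
    for v in sorted(hap.variants, key=lambda v: (v.position, v.insertion_index)):
        if v.kind == "deletion":
            toks.append(f"{v.position}del")
        elif v.kind == "insertion":
            toks.append(f"{v.position}.{v.insertion_index}{v.alt.upper()}")
        else:
            toks.append(f"{v.position}{v.alt.upper()}")
    return " ".join(toks)


def single_source_library(
    hap: HaplotypeSpec,
    total_read_pairs: int,
    sample_name: Optional[str] = None,
    seed: int = 0,
    read_length: int = 151,
    **kwargs,
) -> LibrarySpec:
    return LibrarySpec(
        sample_name=sample_name or hap.name,
        contributors=[(hap, 1.0)],
        total_read_pairs=total_read_pairs,
        seed=seed,
        read_length=read_length,
        **kwargs,
    )


def mixture_library(
    minor: HaplotypeSpec,
    major: HaplotypeSpec,
    minor_parts: int,
    major_parts: int,
    total_read_pairs: int,
    sample_name: str = "mixture",
    seed: int = 0,
    read_length: int = 151,
    **kwargs,
) -> LibrarySpec:
    """Two-person mixture with contributor weights minor:major."""
    total = minor_parts + major_parts
    return LibrarySpec(
        sample_name=sample_name,
        contributors=[(minor, minor_parts / total), (major, major_parts / total)],
        total_read_pairs=total_read_pairs,
        seed=seed,
        read_length=read_length,
        **kwargs,
    )


def ntc_library(sample_name: str = "NTC", seed: int = 0) -> LibrarySpec:
    return LibrarySpec(
        sample_name=sample_name, contributors=[], total_read_pairs=0, seed=seed
    )


def bait_run(
    genome: CircularGenome,
    panel: Panel,
    n_libraries: int = 12,
    n_baits: int = 35,
    read_pairs_per_library: int = 200,
    seed: int = 0,
) -> RunSpec:
    """A pooled run of real libraries plus bait index pairs carrying no
    physical library — the carryover/crosstalk detection design."""
    rng = random.Random(seed)
    index_pairs = generate_index_pairs(n_libraries + n_baits, seed=seed)
    libraries = []
    for i in range(n_libraries):
        hap = random_haplotype(genome, panel, 3, seed=seed * 1000 + i)
        lib = single_source_library(
            hap,
            read_pairs_per_library,
            sample_name=f"S{i + 1:02d}",
            seed=rng.randrange(2**31),
        )
        i7, i5 = index_pairs[i]
        libraries.append((lib, i7, i5))
    baits = index_pairs[n_libraries:]
    return RunSpec(libraries=libraries, bait_indexes=baits, seed=seed)


def sensitivity_series(
    genome: CircularGenome,
    panel: Panel,
    hap: HaplotypeSpec,
    depths: Sequence[int] = (2000, 1000, 500, 200, 100, 50),
    seed: int = 0,
) -> RunSpec:
    """Dilution series: one library per input level plus one NTC."""
    rng = random.Random(seed)
    n = len(depths) + 1
    index_pairs = generate_index_pairs(n, seed=seed)
    libraries = []
    for i, d in enumerate(depths):
        lib = single_source_library(
            hap, d, sample_name=f"dil{i + 1:02d}", seed=rng.randrange(2**31)
        )
        libraries.append((lib, *index_pairs[i]))
    libraries.append((ntc_library(seed=rng.randrange(2**31)), *index_pairs[-1]))
    return RunSpec(libraries=libraries, seed=seed)
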