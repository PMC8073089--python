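"""End-to-end analysis: demultiplex -> align -> filter -> pileup -> call.

This is the glue the CLI uses; every step is an ordinary library call so the
same workflow can be driven from Python.  Filter activity is counted per
sample (quality-masked bases, byproduct pairs, NUMT pairs, HVII clips) so
behaviour is auditable against simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .align import (
    AlignedRead,
    CircularIndex,
    NumtDB,
    align_read,
    filter_byproduct,
    hvii_softclip,
    mask_low_quality,
    numt_filter,
    trim_primers,
    write_sam,
)
from .call import (
    SampleResult,
    Thresholds,
    build_pileup,
    call_sample,
    write_no_call_bed,
    write_variant_tsv,
    write_vcf,
)
from .demux import DemuxResult, SheetEntry, demultiplex
from .nomenclature import empop_report
from .panel import Panel
from .reference import CircularGenome, NamedRegions, Region
from .simulate import ReadPair


@dataclass
class SampleAnalysis:
    result: SampleResult
    aligned: list[AlignedRead]
    pileup: object = None
    filter_counts: dict = field(default_factory=dict)


def analyze_sample(
    pairs: Sequence[ReadPair],
    genome: CircularGenome,
    panel: Panel,
    thresholds: Thresholds,
    index: Optional[CircularIndex] = None,
    numt_db: Optional[NumtDB] = None,
    regions: Optional[NamedRegions] = None,
    target: Optional[Region] = None,
    hvii_clip: bool = True,
) -> SampleAnalysis:
    """Run the full read-level workflow for one sample's read pairs."""
    regions = regions or NamedRegions()
    target = target or panel.target
    index = index or CircularIndex(genome)
    L = genome.length
    counts = {
        "pairs_total": len(pairs),
        "mates_unaligned": 0,
        "pairs_byproduct": 0,
        "pairs_numt": 0,
        "bases_quality_masked": 0,
        "reads_hvii_clipped": 0,
    }
    aligned: list[AlignedRead] = []
    for rp in pairs:
        a1 = align_read(f"{rp.name}/1", rp.r1_seq, rp.r1_qual, index, panel)
        a2 = align_read(f"{rp.name}/2", rp.r2_seq, rp.r2_qual, index, panel)
        counts["mates_unaligned"] += sum(1 for a in (a1, a2) if not a.aligned)
        if a1.aligned and a2.aligned:
            if not filter_byproduct(a1, a2, L):
                counts["pairs_byproduct"] += 1
                aligned.extend([a1, a2])
                continue
        if numt_db is not None and len(numt_db):
            if numt_filter(rp.r1_seq, numt_db, genome):
                a1.flags["numt_filtered"] = True
                a2.flags["numt_filtered"] = True
                counts["pairs_numt"] += 1
                aligned.extend([a1, a2])
                continue
        for a in (a1, a2):
            if not a.aligned:
                continue
            counts["bases_quality_masked"] += len(
                mask_low_quality(a, thresholds.min_q)
            )
            trim_primers(a, panel, L)
            if hvii_clip:
                hvii_softclip(a, genome, cstretch=regions.hv2_cstretch)
                if a.flags.get("hvii_softclipped"):
                    counts["reads_hvii_clipped"] += 1
            aligned.append(a)
    pile = build_pileup(aligned, genome, panel)
    result = call_sample(pile, thresholds, target, genome, panel=panel)
    return SampleAnalysis(
        result=result, aligned=aligned, pileup=pile, filter_counts=counts
    )


@dataclass
class RunAnalysis:
    demux: DemuxResult
    samples: dict[str, SampleAnalysis]


def analyze_run(
    reads: Sequence[ReadPair],
    sheet: Sequence[SheetEntry],
    genome: CircularGenome,
    panel: Panel,
    thresholds: Thresholds,
    numt_db: Optional[NumtDB] = None,
    regions: Optional[NamedRegions] = None,
    max_mismatch_per_index: int = 1,
) -> RunAnalysis:
    """Demultiplex a pooled run and analyze every non-bait sheet entry."""
    demux = demultiplex(reads, sheet, max_mismatch_per_index)
    index = CircularIndex(genome)
    samples: dict[str, SampleAnalysis] = {}
    for entry in sheet:
        if entry.role == "bait":
            continue
        samples[entry.sample_id] = analyze_sample(
            demux.per_sample.get(entry.sample_id, []),
            genome,
            panel,
            thresholds,
            index=index,
            numt_db=numt_db,
            regions=regions,
        )
    return RunAnalysis(demux=demux, samples=samples)


def write_sample_outputs(
    name: str,
    analysis: SampleAnalysis,
    genome: CircularGenome,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the per-sample report set: variant TSV, VCF, SAM, no-call BED,
    population-database report and a filter-count YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = analysis.result
    paths = {
        "variants": outdir / f"{name}.variants.tsv",
        "vcf": outdir / f"{name}.vcf",
        "sam": outdir / f"{name}.sam",
        "no_call": outdir / f"{name}.nocall.bed",
        "empop": outdir / f"{name}.empop.txt",
        "filters": outdir / f"{name}.filters.yaml",
    }
    write_variant_tsv(res, paths["variants"])
    write_vcf(res, genome, paths["vcf"], sample_name=name)
    write_sam(analysis.aligned, genome, paths["sam"])
    write_no_call_bed(res, genome, paths["no_call"])
    if res.haplotype.covered_range:
        with open(paths["empop"], "w") as fh:
            fh.write(empop_report(name, res.haplotype, genome))
    else:
        paths.pop("empop")
    with open(paths["filters"], "w") as fh:
        yaml.safe_dump(
            {
                **analysis.filter_counts,
                "coverage_percent": res.coverage_percent,
                "n_calls": len(res.calls),
            },
            fh,
            sort_keys=True,
        )
    return paths
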