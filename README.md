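# mitotile

Tiled-amplicon mitochondrial DNA haplotyping: simulation, circular
alignment, threshold-based forensic variant calling and interpretation.

## The problem

Forensic mitotyping sequences the human mitochondrial genome (mtGenome,
16,569 bp, circular) — most often its control region (CR, the ~1122 bp arc
16024..576 spanning the replication origin) — from challenging material:
rootless hairs, burned or interred bone, decades-old remains. Modern
workflows enrich the target with a *tiled amplicon* design: many short
(60–150 bp) overlapping amplicons split across two staggered PCR primer
sets, so that degraded templates still amplify and a variant under one
set's primer is recovered by the companion set. Calls are named against the
reference in SWGDAM-style nomenclature (`73G`, `315.1C`, `249del`, IUPAC
codes like `16093Y` for point heteroplasmy, lowercase like `309.1c` for
length heteroplasmy) and reported in EMPOP-compatible form.

`mitotile` implements this workflow end to end as an open, testable
library with a thin CLI: a coordinate-level panel designer, a read
simulator with ground truth (mixtures, heteroplasmy, no-template controls,
NUMT contamination, index crosstalk, run carryover), dual-index
demultiplexing with bait-index carryover checks, a circular seeded banded
aligner with the forensic read-level filters, threshold-based calling, and
the interpretation arithmetic used to derive those thresholds from control
runs. It is aimed at forensic genetics researchers and method developers
who need a transparent, scriptable counterpart to closed analysis software.

Because the true reference sequence is not bundled, the package generates a
deterministic **synthetic** 16,569 bp circular stand-in with the canonical
homopolymer structure (HVII C-stretch at 303–315 with the interrupting T at
310, HVI C-stretch at 16184–16193, AC repeat at 515–524). All coordinate
conventions, thresholds and algorithms are independent of the base content;
any single-record FASTA can be supplied instead.

## The calling model

A position is **callable** when its filtered read depth reaches the
minimum read count; a base, deletion or insertion ordinal is **detected**
when its fraction of total depth meets the analytical threshold (AT) and is
**interpretable** at the interpretation threshold (IT). Two or more
detected bases render as the IUPAC mixed code; insertion ordinals carried
by fewer than (100 − AT)% of reads render lowercase. Preset methods:
control region {AT 10%, IT 10%, minimum 64 reads} and whole genome
{AT 6%, IT 6%, minimum 45 reads}, minimum base quality Q30 in both.

The thresholds themselves are derived from control material:

* minimum read count = round(mean + k·SD) of no-template-control depth per
  position — a background of mean 34 reads with SD 30 at k = 1 gives 64;
* custom AT = mean + 3·SD of the unexpected-variant percentage in positive
  controls analysed at 0% thresholds — 0.7% + 3·1.0% = 3.7%, or
  0.7% + 3·0.5% = 2.2% → 3% when rounded up to a whole percent.

Reads pass four filters before pileup: per-base Q < 30 masking (strict),
discarding pairs with inferred insert < 40 nt (primer/adapter byproducts),
soft-clipping primer footprints so only insert sequence is counted, and
NUMT exclusion by nearest-reference classification against a decoy set.
Reverse-strand reads that start at the HVII amplicon boundary (position
262) and degrade across the C-stretch are soft-clipped after position 303,
so positions 304–353 retain roughly half coverage on that strand.

## Worked example

`examples/02_simulate_and_call.py` simulates a five-variant single-source
library at ~640× (ten times the minimum read count) and calls it back:

```text
simulated truth : 83T 122A 130C 16491.1G 16561del
called haplotype: 83T 122A 130C 16491.1G 16561del
coverage        : 100.0%
filter activity : {'pairs_total': 2900, 'mates_unaligned': 0,
                   'pairs_byproduct': 0, 'pairs_numt': 0,
                   'bases_quality_masked': 9259, 'reads_hvii_clipped': 0}
```

The called string equals the simulated truth: two substitutions before the
origin, one after it (the target wraps the circle), an insertion named with
its ordinal and a deletion. Coverage 100% means no position fell below the
64-read minimum. `examples/03_mixture_analysis.py` does the same for a 1:3
two-person mixture at a custom 3.7% AT:

```text
expected allele ratio  : 25:75 (minor:major)
minor variant detection: 100.0% (8 of 8)
mixed-base fraction    : 1.00
flagged as mixture     : True
```

Each minor variant surfaces as an IUPAC mixed-base call near 25% of reads;
a sample whose calls are mostly mixed-base is flagged as a likely mixture.
The other examples cover panel design, threshold derivation from simulated
control backgrounds, carryover bait runs and nomenclature reports.

The CLI wraps the same library calls:

```bash
mitotile simulate --preset mixture-1-3 --seed 1 --out run/
mitotile analyze --r1 run/R1.fastq --r2 run/R2.fastq \
    --sheet run/sample_sheet.csv --panel run/panel.tsv \
    --genome run/genome.fasta --out results/
mitotile derive-thresholds --ntc-depths depths.txt --out thresholds.yaml
mitotile compare "73G 263G" "73G 150T"
```

## Layout

```
src/mitotile/
  reference.py     circular genome, regions, synthetic reference
  panel.py         tiled amplicon design, stats, dropout accounting
  simulate.py      reads, runs, heteroplasmy, crosstalk, carryover, NUMTs
  demux.py         dual-index demultiplexing, run QC gates, bait checks
  align.py         seeded banded circular alignment + read filters
  call.py          pileups, thresholds, variant and no-call calling
  nomenclature.py  variant-string grammar, comparison, EMPOP reports
  interpret.py     threshold derivation, mixture metrics, precision
  pipeline.py      demux -> align -> filter -> call orchestration
  scenarios.py     ready-made study scenarios and random haplotypes
  cli.py           mitotile simulate | analyze | derive-thresholds | compare
examples/          one short narrative script per capability
docs/methods.md    model, assumptions, parameter choices, limitations
```
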