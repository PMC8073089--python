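# Methods

This note documents the models and numerical choices behind `mitotile`:
what each stage assumes, which parameters matter, what the simulator does
and does not emulate, and where behaviour was a genuine design decision
rather than a forced consequence of the problem.

## Coordinates and the reference

All positions are 1-based inclusive on a circular genome, matching forensic
mtDNA nomenclature ("73G" is position 73). A region with `end < start`
wraps the origin; the control region 16024..576 on the 16,569 bp circle has
length (16569 − 16024 + 1) + 576 = 1122. Wrap is encoded by `end < start`
rather than signed or out-of-range coordinates because that is how the
community writes these ranges.

The bundled reference is **synthetic**: a seeded random sequence of exactly
16,569 bp with homopolymer runs capped at three bases everywhere except the
canonical motifs, which are placed at their real coordinates — HVII
C-stretch 303..315 as `CCCCCCC T CCCCC` (interrupting T at 310), HVI
C-stretch 16184..16193 as `CCCCC T CCCC` (T at 16189), AC repeat
515..524, and an `A` at 263. The cap makes insertion/deletion naming
unambiguous outside declared homopolymers, which is what lets end-to-end
tests compare called strings to simulated truth exactly. Everything the
package computes — geometry, thresholds, filters, nomenclature — is
independent of base content, so a user-supplied single-record FASTA (e.g.
the real reference) drops in without code changes. What the synthetic
reference does *not* provide: real primer-binding-site sequence context,
real NUMT homology and the real distribution of homopolymers; conclusions
about those on real data require the real reference and decoy databases.

## Panel design

Amplicons are modelled as coordinate footprints: an outer (primer-to-primer)
span, an insert between the two primers (default footprint 20 bp each), a
set assignment alternating 1/2 along the tiling, and a relative efficiency
weight (default 1.0). Primer sequences are not modelled; commercial panels
do not publish them, and nothing downstream needs them. The designer draws
outer lengths uniformly in [min_len, max_len] (defaults 60–150) and places
each next insert to overlap its predecessor by at least `min_overlap`
(default 3, mean near 17); for a full-circle target the last insert must
wrap far enough to overlap the first. Infeasible constraints (target
shorter than an amplicon, overlap at least the minimum insert length)
raise instead of looping. Dropout percentages round half-up to two
decimals, the convention used in published accounting (7 of 17,395
amplicons → 0.04%).

For odd amplicon counts on a full circle, strict set alternation cannot
also hold across the wrap junction; alternation is enforced along the
ordered list only.

## Read simulation

The simulator fixes the study conditions rather than exposing every knob:

| parameter | default | rationale |
|---|---|---|
| base error rate | 0.001/base substitutions | typical sequencing-by-synthesis error scale |
| quality profile | N(36, 3) clipped to [2, 40] | places a small Q<30 tail so quality masking has work to do |
| homopolymer stutter | 0.01 per run ≥ 4 nt, ±1 base | exercises C-stretch logic; indel errors occur only in runs |
| read lengths | 151 (CR) / 201 (whole-genome) cycles | the two chemistry configurations |
| per-amplicon efficiency | 1.0, optionally perturbed | amplicon balance varies in practice but has no published distribution |

Each read pair derives from one amplicon of one contributor molecule:
amplicon chosen proportional to efficiency, contributor to mixture weight.
Variants with fraction 1.0 are constitutive; sub-unit fractions are
realized per molecule as Bernoulli draws, with insertion ordinals realized
in nested order (ordinal k requires k−1) so length heteroplasmy has a
proper length distribution. Read 1 is the forward strand from the amplicon
5' end; read 2 the reverse complement from the 3' end; both include primer
bases and truncate at the cycle count. Truth (contributor, amplicon, set,
crosstalk/carryover provenance) travels in a sidecar structure, never in
read names.

Index crosstalk reassigns a read pair, with the configured probability, to
a uniformly chosen sample-sheet entry sharing its i7 or i5; carryover
re-simulates the stated fraction of a previous run's pairs under their
original indexes. Bait entries exist only in the sheet and emit nothing.

Not emulated: flow-cell physics (cluster density, phasing enter only as
user-supplied QC numbers), PCR chimeras/"doublewide" products, template
damage patterns, and strand-specific error asymmetry in the C-stretch (the
HVII clipping rule is therefore exercised by constructed reads in tests,
not by the default simulator). Passing tests demonstrate algorithmic
correctness under this generative model, not performance on real libraries.

## Alignment

Reads are aligned by seed-and-extend against the doubled reference
sequence, which turns origin-spanning reads into ordinary contiguous
alignments. Four 15-mer seeds per orientation vote for candidate
diagonals; each candidate window is scored with a banded affine-gap fitting
alignment — query consumed end to end, reference flanks free — with match
+1, mismatch −4, gap open −6 (charged on the first gap base), extension −1,
band half-width 16. The same dynamic program run without a band is the
exact oracle; agreement between the two on random mutated instances is a
standing acceptance property. Alignments scoring below a third of the
maximum possible are flagged unalignable and excluded.

Two exact fast paths keep throughput acceptable in pure Python: windows
within two mismatches of the read are accepted as all-match alignments, and
reads carrying one clean indel are resolved by exact prefix/suffix matching
on shifted diagonals. Both produce the same score the DP would.

Insertions are right-normalized along the read after alignment (shifted 3'
while the read base matches the upcoming reference base). This matches the
forensic convention of anchoring insertions at the 3' end of a repeat and,
concretely, prevents a score-equivalent left-aligned placement from landing
inside a primer footprint, where trimming would silently discard the
insertion evidence for one of two overlapping amplicons. Deletions are not
re-normalized: the simulator plants them only at positions whose neighbours
differ, and C-stretch deletions are handled by the dedicated
length-heteroplasmy logic.

Filter order per pair: byproduct removal (inferred insert < 40 nt, strict),
NUMT exclusion, then per-mate quality masking, primer trimming and HVII
clipping. NUMT classification flags a read only when it matches a decoy
within 2 edits (edlib) *and* strictly closer than the mitochondrial
reference, the conservative reading of "known NUMT removal" given that no
matching rule is published. The HVII rule is operationalized as: reverse
strand, alignment start within 3 bp of position 262, and at least two
non-match alignment events inside 303..315 → counts kept only through 303.
The triggering condition in the original software is unpublished; both the
anchor and the event threshold are configurable.

## Calling

Pileups count per position, per strand: A/C/G/T, deletions, and insertion
events keyed (anchor, ordinal, base), with the anchor re-anchored to the
3'-most position of the matching reference homopolymer run. Masked,
clipped and flagged bases never reach a pileup — an invariant tested
directly.

Calling is pure thresholding. AT and IT both apply to fraction-of-depth;
since the preset defaults are equal, the only behavioural difference is the
`below_IT` status flag on calls in [AT, IT). Two retained bases render as
the two-base IUPAC code, three or more as B/D/H/V/N. A retained deletion
alone renders `del`; a partial deletion alongside the reference base is
reported as a length-variant deletion. Insertion ordinals at or above AT
but present in fewer than (100 − AT)% of reads render lowercase. Coverage
percent is positions with an unambiguous call over target length, rounded
half-up to one decimal; adjacent no-call positions merge into regions, a
run across the origin becoming one wrapping region. Strand depth displays
the majority strand's count, ties reporting the forward strand.

Two documented compatibility corrections are available behind a flag
(`uas_compat`): a fully deleted interrupting T in a C-stretch combined with
a partial C insertion re-reports as the uppercase substitution at the T
position plus the lowercase terminal insertion; and mixed calls at the HVII
T (position 310) re-anchor to 309.N ordinals. Off by default because they
are reporting conventions, not calling logic.

## Threshold derivation and interpretation

Sample (n−1) standard deviation is used throughout; the choice is
immaterial at printed precision for control runs of realistic size, but it
is fixed and documented. The minimum read count is round-half-up of
mean + k·SD of NTC per-position depth (k = 1 reproduces 64 from mean 34 /
SD 30). The analytical threshold is mean + 3·SD of positive-control
unexpected-variant percentages, kept at one decimal (3.7%) or rounded up to
a whole percent (3%), with hotspot regions (C-stretches, AC repeat)
excludable when reporting the background maximum. The whole-genome
minimum of 45 reads is treated as a configured preset default, not a
derived value: the stated derivation arithmetic (mean 1 + 3·SD 42 reads
per amplicon) does not reproduce it, and the derivation function
reproduces the arithmetic as stated.

Mixture arithmetic: expected minor percent is round-half-up of
100·m/(m+M) with the major as its complement; detection rate is
100·observed/expected at one decimal. A sample is flagged as a likely
mixture when more than half of its non-reference calls are mixed-base
(threshold configurable). The NTC depth estimate divides paired depth by
the amplicon count and doubles it; the per-region alternative for larger
multiplexes (where primer dimers inflate sample representation) is the
caller's responsibility via the pileup API. The precision metric prints
one decimal below 99.9% and two at or above, matching the published
table's conventions.

## Problem sizes in tests and acceptance

End-to-end checks run on a compact demonstration target (16469..380, 481 bp
wrapping the origin and containing the HVII C-stretch, ~9 amplicons) at
~640× depth — ten times the 64-read minimum — chosen once as a faithful
scaled-down configuration of the full control-region design; the full
16024..576 panel is exercised by the designer tests. Recovery is asserted
over 20 random five-variant haplotypes; mixture recovery at 1:3 uses 4,000
pairs with per-site binomial standard errors computed from the number of
read pairs covering the site (both mates of a pair are correlated, so pairs
— not reads — are the independent unit). The NTC-background property draws
1,157 positions from Normal(34, 30) truncated at zero, whose analytic
mean + SD is ≈ 65.8, and accepts derived minimums in [60, 68] across ten
seeds.

## Known limitations

* The aligner is pure Python; throughput is thousands, not millions, of
  reads per minute. The fast paths cover the common cases, but heavily
  divergent reads all pay the banded DP cost.
* Calling is threshold-based by design; there is no genotype-likelihood or
  probabilistic mixture-deconvolution model.
* Lowercase AC-repeat annotations (`523a 524c`) parse and round-trip
  verbatim but are not interpreted; their semantics are disputed.
* The two-base IUPAC rendering assumes at most one alternate allele class
  per position per contributor; three-contributor mixtures render as
  3/4-base codes but are not otherwise analysed.
* Haplogroup assignment and live population-database queries are out of
  scope; reports are emitted in compatible formats only.
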