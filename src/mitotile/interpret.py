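"""Threshold derivation from control runs and interpretation summaries.

The analysis thresholds are empirical, derived from control material:

* the minimum read count comes from no-template-control (NTC) background
  depth — the mean plus k standard deviations of reads per position
  (k = 1 gives the control-region default of 64 from a background of
  mean 34 / SD 30);
* the analytical threshold comes from positive-control runs analysed at
  AT/IT 0%: the mean unexpected-variant percentage plus k·SD (k = 3),
  either kept at one decimal (0.7% + 3·1.0% -> 3.7%) or rounded up to a
  whole percent (0.7% + 3·0.5% = 2.2% -> 3%).

Mixture arithmetic, NTC depth estimation, crosstalk candidate listing and
the precision metric follow the printed-report conventions (rounding
half-up at the stated precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np

from .call import SampleResult
from .demux import SheetEntry
from .reference import Region


class InterpretError(ValueError):
    pass


def _round_half_up(value: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _sample_sd(values: Sequence[float]) -> float:
    # sample (n-1) standard deviation; 0 for a single observation
    if len(values) < 2:
        return 0.0
    return float(np.std(np.asarray(values, dtype=float), ddof=1))


@dataclass
class ThresholdDerivation:
    observations: list[float]
    mean: float
    sd: float
    k: float
    percentile95: float
    maximum: float
    excluded_hotspots: list[Region] = field(default_factory=list)


def summarize_background(
    observations: Sequence[float], k: float, excluded_hotspots: Sequence[Region] = ()
) -> ThresholdDerivation:
    if len(observations) == 0:
        raise InterpretError("empty background observation set")
    arr = np.asarray(observations, dtype=float)
    return ThresholdDerivation(
        observations=list(map(float, observations)),
        mean=float(arr.mean()),
        sd=_sample_sd(observations),
        k=k,
        percentile95=float(np.percentile(arr, 95)),
        maximum=float(arr.max()),
        excluded_hotspots=list(excluded_hotspots),
    )


def derive_min_read_count(ntc_background: Sequence[float], k: float = 1.0) -> int:
    """Minimum read count = round(mean + k·SD) of NTC per-position depths,
    half-up to an integer (sample SD)."""
    if len(ntc_background) == 0:
        raise InterpretError("empty NTC background")
    if k < 0:
        raise InterpretError("k must be >= 0")
    arr = np.asarray(ntc_background, dtype=float)
    return int(_round_half_up(float(arr.mean()) + k * _sample_sd(ntc_background)))


def min_read_count_from_summary(mean: float, sd: float, k: float = 1.0) -> int:
    """Same arithmetic from pre-computed summary statistics
    (mean 34, SD 30, k 1 -> 64)."""
    return int(_round_half_up(mean + k * sd))


def derive_at(
    unexpected_pcts: Sequence[float],
    sd_multiplier: float = 3.0,
    rounding: str = "one-decimal",
    excluded_hotspots: Sequence[Region] = (),
) -> tuple[ThresholdDerivation, float]:
    """Custom analytical threshold from positive-control unexpected-variant
    percentages: mean + k·SD, kept at one decimal or rounded up to a whole
    percent."""
    summary = summarize_background(unexpected_pcts, sd_multiplier, excluded_hotspots)
    raw = summary.mean + sd_multiplier * summary.sd
    if rounding == "one-decimal":
        custom = _round_half_up(raw, 1)
    elif rounding == "ceil-to-integer":
        custom = float(math.ceil(raw))
    else:
        raise InterpretError(f"unknown rounding mode {rounding!r}")
    return summary, custom


def at_from_summary(
    mean: float, sd: float, k: float = 3.0, rounding: str = "one-decimal"
) -> float:
    """AT arithmetic from summary statistics (0.7 + 3·1.0 -> 3.7;
    0.7 + 3·0.5 = 2.2 -> 3 when rounded up)."""
    raw = mean + k * sd
    if rounding == "one-decimal":
        return _round_half_up(raw, 1)
    if rounding == "ceil-to-integer":
        return float(math.ceil(raw))
    raise InterpretError(f"unknown rounding mode {rounding!r}")


@dataclass(frozen=True)
class MixtureSpec:
    minor_parts: int
    major_parts: int
    expected_minor_variants: int

    def __post_init__(self) -> None:
        if self.minor_parts <= 0 or self.major_parts <= 0:
            raise InterpretError("mixture parts must be > 0")


def expected_mixture_ratio(spec: MixtureSpec) -> tuple[int, int]:
    """Expected minor:major allele percentages, minor rounded half-up to an
    integer and major as the complement (1:5 -> 17:83, 1:15 -> 6:94)."""
    minor = int(
        _round_half_up(100.0 * spec.minor_parts / (spec.minor_parts + spec.major_parts))
    )
    return minor, 100 - minor


def detection_rate(observed: int, expected: int) -> float:
    """Minor-variant detection rate, percent to one decimal half-up
    (15/27 -> 55.6)."""
    if expected <= 0:
        raise InterpretError("expected count must be > 0")
    if observed < 0:
        raise InterpretError("observed count must be >= 0")
    return _round_half_up(100.0 * observed / expected, 1)


@dataclass
class MixtureAssessment:
    observed_minor_variants: int
    detection_rate: Optional[float]
    mixed_base_fraction: float
    flagged_mixture: bool


_MIXED_CODES = set("RYMKWSBDHVN")


def flag_mixture(
    sample_result: SampleResult,
    expected_minor_variants: Optional[int] = None,
    observed_minor_variants: Optional[int] = None,
    mixed_fraction_threshold: float = 0.5,
) -> MixtureAssessment:
    """Flag a sample as a likely mixture when more than half of its
    non-reference calls are mixed-base (IUPAC) calls."""
    tokens = list(sample_result.haplotype.tokens)
    n_calls = len(tokens)
    mixed = sum(1 for t in tokens if t.symbol.upper() in _MIXED_CODES)
    frac = mixed / n_calls if n_calls else 0.0
    rate = None
    if expected_minor_variants:
        obs = observed_minor_variants if observed_minor_variants is not None else mixed
        rate = detection_rate(obs, expected_minor_variants)
    return MixtureAssessment(
        observed_minor_variants=observed_minor_variants if observed_minor_variants is not None else mixed,
        detection_rate=rate,
        mixed_base_fraction=frac,
        flagged_mixture=frac > mixed_fraction_threshold,
    )


def ntc_depth_estimate(paired_read_count: float, n_amplicons: int) -> float:
    """Average total depth per amplicon in an NTC: paired depth divided by
    the amplicon count, times two (both mates)."""
    if n_amplicons <= 0:
        raise InterpretError("n_amplicons must be > 0")
    return 2.0 * paired_read_count / n_amplicons


def crosstalk_candidates(
    sample_results: dict[str, SampleResult],
    sheet: Sequence[SheetEntry],
    ntc_results: dict[str, SampleResult],
    genome_length: int,
) -> list[dict]:
    """For each NTC with reads, list co-indexed samples (sharing i7 or i5)
    whose calls match the NTC's variants within the NTC's covered range.

    An NTC with reads but no matching co-indexed sample is reported with an
    ``unexplained`` note.
    """
    idx = {e.sample_id: e.index for e in sheet}
    out: list[dict] = []
    for ntc_name, ntc_res in ntc_results.items():
        if not ntc_res.haplotype.covered_range:
            continue
        ntc_tokens = set(ntc_res.haplotype.tokens)
        ntc_index = idx.get(ntc_name)
        matched = False
        for sample_name, res in sample_results.items():
            if sample_name == ntc_name or ntc_index is None:
                continue
            s_index = idx.get(sample_name)
            if s_index is None:
                continue
            shared = []
            if s_index.i7 == ntc_index.i7:
                shared.append("i7")
            if s_index.i5 == ntc_index.i5:
                shared.append("i5")
            if not shared:
                continue
            common = ntc_tokens & set(res.haplotype.tokens)
            covered = ntc_res.haplotype.covered_range
            common_in_range = {
                t
                for t in common
                if any(r.contains(t.position, genome_length) for r in covered)
            }
            if ntc_tokens and common_in_range == ntc_tokens or (
                not ntc_tokens and common_in_range == set()
            ):
                matched = True
                out.append(
                    {
                        "ntc": ntc_name,
                        "source": sample_name,
                        "shared_index": "+".join(shared),
                        "shared_variants": sorted(str(t) for t in common_in_range),
                    }
                )
        if not matched:
            out.append(
                {
                    "ntc": ntc_name,
                    "source": None,
                    "shared_index": None,
                    "shared_variants": [],
                    "note": "unexplained",
                }
            )
    return out


def precision_metric(avg_uncovered_bases: float, total_bases: int) -> float:
    """Bases covered as a fraction of bases expected, percent.

    Printed precision: one decimal below 99.9, two decimals at or above
    (356/16,569 lost -> 97.9; 4 lost -> 99.98)."""
    if total_bases <= 0:
        raise InterpretError("total_bases must be > 0")
    if not 0 <= avg_uncovered_bases <= total_bases:
        raise InterpretError("uncovered bases outside [0, total]")
    value = 100.0 * (total_bases - avg_uncovered_bases) / total_bases
    return _round_half_up(value, 2 if value >= 99.9 else 1)
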