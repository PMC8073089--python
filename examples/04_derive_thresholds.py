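"""Derive analysis thresholds from control-run background signal.

The minimum read count comes from no-template-control depth (mean + 1 SD:
a background of mean 34 reads/position with SD 30 yields 64).  The
analytical threshold comes from positive controls analysed at 0% thresholds
(mean unexpected-variant percentage + 3 SD).  Both are recomputed here from
freshly simulated backgrounds with those characteristics.
"""

from scipy import stats

from mitotile.interpret import (
    at_from_summary,
    derive_at,
    derive_min_read_count,
    min_read_count_from_summary,
)

# from published summary statistics
print("from summary statistics:")
print(f"  min read count (34 + 1x30)        : {min_read_count_from_summary(34, 30, 1)}")
print(f"  custom AT, one decimal (0.7+3x1.0): {at_from_summary(0.7, 1.0, 3)}%")
print(f"  custom AT, rounded up (0.7+3x0.5) : "
      f"{at_from_summary(0.7, 0.5, 3, 'ceil-to-integer'):.0f}%")

# from a simulated NTC background: Normal(34, 30) truncated at zero,
# observed over the 1157 evaluated control-region positions
a = (0 - 34.0) / 30.0
depths = stats.truncnorm.rvs(a, float("inf"), loc=34.0, scale=30.0,
                             size=1157, random_state=1)
print("from simulated NTC background (n=1157):")
print(f"  derived min read count            : {derive_min_read_count(depths, k=1)}")

# from simulated positive-control unexpected-variant percentages
pcts = stats.truncnorm.rvs(-0.7, float("inf"), loc=0.7, scale=1.0,
                           size=63, random_state=2)
summary, custom_at = derive_at(pcts, sd_multiplier=3.0)
print(f"  derived custom AT                 : {custom_at}% "
      f"(mean {summary.mean:.2f}, SD {summary.sd:.2f}, "
      f"p95 {summary.percentile95:.2f}, max {summary.maximum:.2f})")
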