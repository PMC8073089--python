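"""Analyze a simulated 1:3 two-person mixture at a custom 3.7% threshold.

The minor contributor's variants surface as IUPAC mixed-base calls at ~25%
of reads.  The mixture flag trips when more than half of all calls are
mixed-base — the hallmark separating two-person mixtures from single-source
samples with sporadic heteroplasmy.
"""

from mitotile import Thresholds, simulate_library, synthetic_reference
from mitotile.interpret import MixtureSpec, detection_rate, expected_mixture_ratio, flag_mixture
from mitotile.nomenclature import format_haplotype
from mitotile.pipeline import analyze_sample
from mitotile.scenarios import demo_panel, mixture_library, random_haplotype

genome = synthetic_reference()
panel = demo_panel(genome)

minor = random_haplotype(genome, panel, 8, seed=5, include_indels=False)
major = random_haplotype(genome, panel, 4, seed=77, include_indels=False)
reads = simulate_library(
    genome, panel, mixture_library(minor, major, 1, 3, total_read_pairs=4000, seed=1)
)

analysis = analyze_sample(reads, genome, panel, Thresholds(3.7, 3.7, 64, 30))
result = analysis.result

exp_minor, exp_major = expected_mixture_ratio(MixtureSpec(1, 3, len(minor.variants)))
called_positions = {t.position for t in result.haplotype}
major_pos = {v.position for v in major.variants}
diagnostic = [v for v in minor.variants if v.position not in major_pos]
observed = sum(1 for v in diagnostic if v.position in called_positions)

print(f"expected allele ratio  : {exp_minor}:{exp_major} (minor:major)")
print(f"called variants        : {format_haplotype(result.haplotype)}")
print(f"minor variant detection: {detection_rate(observed, len(diagnostic))}% "
      f"({observed} of {len(diagnostic)})")
assessment = flag_mixture(result)
print(f"mixed-base fraction    : {assessment.mixed_base_fraction:.2f}")
print(f"flagged as mixture     : {assessment.flagged_mixture}")
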