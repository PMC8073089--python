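"""Parse, compare and report haplotypes in forensic mtDNA nomenclature.

Variant strings use positions on the reference circle: substitutions (73G),
insertions with ordinals (315.1C), deletions (249del), IUPAC mixed-base
codes for point heteroplasmy (16093Y) and lowercase for length heteroplasmy
(309.1c).  The report writer emits the population-database-compatible pair
of blocks: the reconstructed sequence as FASTA plus the variant list.
"""

from mitotile import synthetic_reference
from mitotile.nomenclature import (
    compare_haplotypes,
    empop_report,
    format_haplotype,
    parse_haplotype,
)
from mitotile.reference import Region

genome = synthetic_reference()

s = "315.1C 263G 73G 16069T 309.1c"  # unsorted input
hap = parse_haplotype(s, genome)
print(f"canonical form : {format_haplotype(hap)}")

a = parse_haplotype("73G 150T 152C 263G 295T 315.1C 489C")
b = parse_haplotype("73G 150T 152C 263G 295T 315.1C 489C 16069T")
pct, shared, only_a, only_b = compare_haplotypes(a, b, genome.length)
print(f"concordance    : {pct}% ({len(shared)} shared, "
      f"{len(only_b)} only in b)")

hap.covered_range = [Region(16024, 576)]  # the control region
report = empop_report("example_sample", hap, genome)
print("report (tail):")
print("\n".join(report.strip().splitlines()[-3:]))
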