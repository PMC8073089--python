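"""Bundled datasets.

``published_cr_haplotypes()`` returns published forensic control-region
haplotype strings (well-characterized reference DNAs, mock-casework remains,
matched hair/buccal sets and population samples), recorded per sequencing
kit.  They serve as golden fixtures for nomenclature parsing/formatting and
cross-kit concordance.
"""

from __future__ import annotations

import csv
from importlib import resources


def published_cr_haplotypes() -> list[dict]:
    """Rows with keys ``set``, ``sample``, ``column``, ``haplotype``."""
    ref = resources.files("mitotile") / "data" / "published_cr_haplotypes.tsv"
    with ref.open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def crosskit_triples() -> dict[str, dict[str, str]]:
    """Per well-characterized sample: expected / cr_kit / wg_kit strings."""
    out: dict[str, dict[str, str]] = {}
    for row in published_cr_haplotypes():
        if row["set"] == "crosskit":
            out.setdefault(row["sample"], {})[row["column"]] = row["haplotype"]
    return out
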