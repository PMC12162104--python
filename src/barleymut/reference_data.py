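"""Published observed quantities from the sodium-azide barley mutagenesis study.

These are inputs to the enrichment calculations, not outputs of this
package: per-line variant counts surviving the isolation pipeline in the 11
resequenced M5 mutagenized lines, and the genome/callable sizes and
spontaneous mutation rates used by the selfing expectation model.
"""

from __future__ import annotations

import pandas as pd

#: SNVs and 1-296 bp indels surviving isolation, per mutagenized line.
#: Three lines (M01, M20, M29) were additionally linked-read sequenced,
#: which mostly affects indel recovery.
PER_LINE_COUNTS = pd.DataFrame(
    {
        "line": ["M01", "M20", "M29", "M02", "M11", "M14", "M28", "M35", "M36", "M39", "M41"],
        "snv": [1134, 3225, 3669, 1585, 1222, 1446, 2357, 2431, 1562, 1613, 3095],
        "indel": [441, 464, 445, 56, 54, 62, 80, 75, 64, 705, 63],
    }
)

#: pooled small-indel total reported for the cohort; exceeds the per-line
#: table's sum (2,509) because pooling across callers/platforms differs
TOTAL_SMALL_INDELS = 5376

N_LINES = 11

#: haploid assembly and callable-region sizes (bp) and their diploid doubles
GENOME_BP = 4_225_605_719
CALLABLE_BP = 820_594_305
DIPLOID_GENOME_BP = 8_451_211_438
DIPLOID_CALLABLE_BP = 1_641_188_610

#: selfing generations of the single-seed-descent design
GENERATIONS = 7

#: constraint-test codon counts behind the published Bonferroni thresholds
CONSTRAINT_TESTS = {"mutated": 611, "rare": 9716, "common": 14537}


def mean_snv_per_line() -> float:
    return float(PER_LINE_COUNTS["snv"].mean())


def mean_indel_per_line(pooled: bool = True) -> float:
    """Mean small indels per line; ``pooled`` uses the cohort total over 11
    lines, otherwise the per-line table."""
    if pooled:
        return TOTAL_SMALL_INDELS / N_LINES
    return float(PER_LINE_COUNTS["indel"].mean())
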