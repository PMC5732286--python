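"""Reference cohort layout of the Egyptian fat-tail sheep SNP50 study
design: per-population sample sizes and the regional cohort totals, used
for scaled-down simulation configs and bookkeeping checks."""

from __future__ import annotations

import pandas as pd

__all__ = ["EGYPTIAN_POPULATION_SIZES", "REGIONAL_COHORT_SIZES",
           "cohort_table", "total_egyptian", "total_cohort"]

#: Sample size of each Egyptian fat-tail population.
EGYPTIAN_POPULATION_SIZES: dict[str, int] = {
    "Barki": 181,
    "Saidi": 72,
    "Farafra": 62,
    "Souhagi": 49,
    "AHS": 30,
}

#: Regional cohort totals (individuals available for analysis).
REGIONAL_COHORT_SIZES: dict[str, int] = {
    "Egyptian": 394,
    "European": 565,
    "western_asia": 196,
    "east_african": 79,
}


def cohort_table() -> pd.DataFrame:
    """Egyptian populations with sizes and their group label."""
    return pd.DataFrame({
        "population": list(EGYPTIAN_POPULATION_SIZES),
        "n": list(EGYPTIAN_POPULATION_SIZES.values()),
        "group": "Egyptian",
    })


def total_egyptian() -> int:
    """Sum of the Egyptian per-population sample sizes."""
    return sum(EGYPTIAN_POPULATION_SIZES.values())


def total_cohort() -> int:
    """Sum of the regional cohort totals."""
    return sum(REGIONAL_COHORT_SIZES.values())
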