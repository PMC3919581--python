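"""Metadata of the TCGA cohorts the method was designed around.

Sample counts of the eight cancer types with unrestricted TCGA data
(March 2013 freeze). These are inputs for per-sample normalisation and
bookkeeping, not results of this package.
"""

from __future__ import annotations

#: cohort label -> number of patient samples
TCGA_COHORT_SAMPLES: dict[str, int] = {
    "BRCA": 775,  # breast cancer
    "KIRC": 219,  # clear cell kidney cancer
    "COAD": 84,   # colon adenocarcinoma
    "UCEC": 247,  # endometrial cancer
    "GBM": 290,   # glioblastoma multiforme
    "LUSC": 176,  # lung squamous carcinoma
    "OV": 151,    # ovarian cancer
    "READ": 38,   # rectal adenocarcinoma
}


def total_samples(cohorts: dict[str, int] = TCGA_COHORT_SAMPLES) -> int:
    return sum(cohorts.values())
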