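"""Published reference values for CSLV-based breast-cancer risk scoring.

These constants transcribe the headline evaluation of a published
CSLV breast-cancer risk model built on the NIH All of Us microarray
release (1,814,517 variants × 165,127 participants; 4,533 cases and
44,518 cancer-free controls): the quintile risk-stratification table
computed on its 2,015-woman held-out test set, and the reported AUCs.
The underlying individual-level data are controlled-access and cannot
ship here; the printed summary table, however, is a legitimate input
for arithmetic consistency checks — bin sizes, count conservation, and
the top-versus-bottom-quintile fold ratio behind the "nine times more
likely" headline.

Note: the printed odds-ratio column is not reproducible from the
printed counts by any standard 2×2 formula (quintile-vs-population
gives 4.13 for the top quintile, quintile-vs-rest 5.77, versus a
printed 3.47). This package therefore never claims to match that
column; the fold ratio is taken from the printed column itself.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "REFERENCE_QUINTILE_TABLE",
    "REFERENCE_TEST_SET_SIZE",
    "REFERENCE_AUC_K4",
    "REFERENCE_AUC_K4_CI",
    "REFERENCE_AUC_K1",
    "reference_fold_ratio",
]

# Quintile 5 = highest scores. Columns: cases, controls, printed OR + CI.
REFERENCE_QUINTILE_TABLE = pd.DataFrame(
    {
        "n_cases": [89, 113, 167, 221, 310],
        "n_controls": [314, 290, 236, 182, 93],
        "odds_ratio": [0.39, 0.56, 0.80, 1.45, 3.47],
        "ci_low": [0.36, 0.49, 0.74, 1.24, 2.88],
        "ci_high": [0.42, 0.62, 0.87, 1.67, 4.06],
    },
    index=pd.Index([1, 2, 3, 4, 5], name="quintile"),
)

REFERENCE_TEST_SET_SIZE = 2015

# Reported mean test AUCs for the 88-feature (k=4) and 22-feature (k=1) models.
REFERENCE_AUC_K4 = 0.70
REFERENCE_AUC_K4_CI = (0.67, 0.73)
REFERENCE_AUC_K1 = 0.60


def reference_fold_ratio() -> float:
    """Top-vs-bottom-quintile ratio of the printed odds ratios (≈ 8.9,
    the published "nine times more likely" headline)."""
    t = REFERENCE_QUINTILE_TABLE["odds_ratio"]
    return float(t.loc[5] / t.loc[1])
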