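"""Quintile risk stratification: rank scores, bin, and compute odds ratios.

The clinical readout of a risk score is not its AUC but how sharply it
separates the population: rank the test set by score, cut it into five
equal bins, and ask how the odds of disease in each bin compare with the
population. The odds ratio used here is *quintile odds versus
whole-test-population odds*,

    OR_q = (a_q / b_q) / (A / B)

with ``a_q``/``b_q`` cases/controls in quintile q and ``A``/``B`` the
test-set totals, with a Wald interval on the log odds ratio. A
quintile-versus-complement variant is available via ``method="rest"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QuintileTable", "assign_quintiles", "quintile_odds_ratios"]


@dataclass(frozen=True)
class QuintileTable:
    """Per-quintile contingency counts and odds ratios.

    ``table`` is indexed by quintile 1..n (n = highest scores) with
    columns n_cases, n_controls, n_total, odds_ratio, ci_low, ci_high.
    ``top_vs_bottom_fold`` is OR_top / OR_bottom.
    """

    table: pd.DataFrame
    top_vs_bottom_fold: float
    method: str = "population"


def assign_quintiles(scores: pd.Series, n_bins: int = 5) -> pd.Series:
    """Bin index per sample: bin ``n_bins`` holds the highest scores.

    Samples are ranked by score descending with ties broken by sample
    id; bin sizes differ by at most one, the larger bins going to the
    higher quintiles first (7 samples → sizes 2,2,1,1,1 from the top
    bin downward).
    """
    n = len(scores)
    if n < n_bins:
        raise ValueError(f"cannot split {n} samples into {n_bins} bins")
    order = (
        pd.DataFrame({"score": scores, "sample_id": scores.index.astype(str)})
        .sort_values(["score", "sample_id"], ascending=[False, True], kind="mergesort")
        .index
    )
    base, rem = divmod(n, n_bins)
    bins = np.empty(n, dtype=int)
    start = 0
    for j in range(n_bins):  # j=0 is the top bin
        size = base + (1 if j < rem else 0)
        bins[start : start + size] = n_bins - j
        start += size
    return pd.Series(bins, index=order, name="quintile").reindex(scores.index)


def _wald_or(a: float, b: float, big_a: float, big_b: float) -> tuple[float, float, float]:
    if min(a, b, big_a, big_b) == 0:
        a, b, big_a, big_b = a + 0.5, b + 0.5, big_a + 0.5, big_b + 0.5
    or_ = (a / b) / (big_a / big_b)
    se = math.sqrt(1 / a + 1 / b + 1 / big_a + 1 / big_b)
    z = 1.959963984540054
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


def quintile_odds_ratios(
    labels: pd.Series, bins: pd.Series, method: str = "population"
) -> QuintileTable:
    """Contingency counts and odds ratios per quintile.

    ``method="population"`` compares each quintile's odds with the whole
    test population's odds (the default definition used throughout this
    package); ``method="rest"`` compares with the complement of the
    quintile. Haldane–Anscombe +0.5 correction applies when a cell is 0.
    """
    if method not in ("population", "rest"):
        raise ValueError(f"unknown odds-ratio method {method!r}")
    labels = np.asarray(labels, dtype=int)
    bins = np.asarray(bins, dtype=int)
    big_a = int((labels == 1).sum())
    big_b = int((labels == 0).sum())
    if big_a == 0 or big_b == 0:
        raise ValueError("both classes must be present in the test set")

    rows = []
    for q in sorted(np.unique(bins)):
        in_q = bins == q
        a = int((labels[in_q] == 1).sum())
        b = int((labels[in_q] == 0).sum())
        if a + b == 0:
            raise RuntimeError(f"quintile {q} is empty; bins are malformed")
        ref = (big_a - a, big_b - b) if method == "rest" else (big_a, big_b)
        or_, lo, hi = _wald_or(a, b, *ref)
        rows.append(
            {
                "quintile": q,
                "n_cases": a,
                "n_controls": b,
                "n_total": a + b,
                "odds_ratio": or_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    table = pd.DataFrame(rows).set_index("quintile")
    top, bottom = table.index.max(), table.index.min()
    fold = table.loc[top, "odds_ratio"] / table.loc[bottom, "odds_ratio"]
    return QuintileTable(table=table, top_vs_bottom_fold=float(fold), method=method)
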