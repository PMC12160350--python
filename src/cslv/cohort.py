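"""Cohort assembly: age-matched control undersampling and train/test splits.

Case/control intensity datasets are typically heavily imbalanced (about
ten controls per case here). Training on the raw imbalance biases both
the classifier and its evaluation, so the modeling cohort keeps every
case and undersamples controls to a 40:60 case:control ratio, choosing
for each case its nearest-age unused controls so age cannot act as a
confounder. A label-stratified 80/20 split then separates the held-out
test set.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitSpec", "undersample_matched", "split_train_test"]


@dataclass(frozen=True)
class SplitSpec:
    """Cohort-assembly parameters.

    ``ratio_case``/``ratio_control`` define the post-undersampling class
    mix (default 40:60); ``test_fraction`` the held-out share.
    """

    seed: int = 0
    test_fraction: float = 0.2
    ratio_case: float = 0.4
    ratio_control: float = 0.6
    stratify_by_label: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.ratio_case <= 0 or self.ratio_control <= 0:
            raise ValueError("class ratios must be positive")
        if abs(self.ratio_case + self.ratio_control - 1.0) > 1e-9:
            raise ValueError("class ratios must sum to 1")


def _control_quotas(n_cases: int, n_needed: int) -> np.ndarray:
    """Controls drawn per case (in randomized case order).

    Every case draws at least ``n_needed // n_cases``; the remainder is
    spread one extra at a time over alternating positions (0, 2, 4, …
    then 1, 3, 5, …), so at the default 40:60 ratio cases draw 2 and 1
    controls alternately.
    """
    base, extra = divmod(n_needed, n_cases)
    quotas = np.full(n_cases, base, dtype=int)
    alternating = list(range(0, n_cases, 2)) + list(range(1, n_cases, 2))
    for j in range(extra):
        quotas[alternating[j]] += 1
    return quotas


def undersample_matched(cohort: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Keep all cases; select age-matched controls at the target ratio.

    Exactly ``ceil(n_cases * ratio_control / ratio_case)`` controls are
    chosen by greedy nearest-age matching: cases are visited in a
    seed-randomized order and each draws its quota of nearest-age,
    not-yet-used controls (ties broken by sample id). The result
    preserves the input row order.
    """
    cases = cohort[cohort["label"] == 1]
    controls = cohort[cohort["label"] == 0]
    n_cases = len(cases)
    if n_cases == 0:
        raise ValueError("cohort contains no cases")
    n_needed = math.ceil(n_cases * spec.ratio_control / spec.ratio_case)
    if len(controls) < n_needed:
        achievable = len(controls) / (n_cases + len(controls))
        raise ValueError(
            f"need {n_needed} controls for a {spec.ratio_case:.0%}:"
            f"{spec.ratio_control:.0%} ratio but only {len(controls)} available "
            f"(achievable control share {achievable:.1%})"
        )

    rng = np.random.default_rng(spec.seed)
    case_order = rng.permutation(n_cases)
    quotas = _control_quotas(n_cases, n_needed)

    # controls sorted by (age, sample_id); greedy nearest-age scan outward
    pool = controls.sort_values(["age", "sample_id"], kind="mergesort")
    pool_ages = pool["age"].to_list()
    pool_ids = pool["sample_id"].to_list()
    available = [True] * len(pool)
    chosen: list[str] = []

    case_ages = cases["age"].to_numpy()
    for rank, ci in enumerate(case_order):
        age = case_ages[ci]
        for _ in range(quotas[rank]):
            j = bisect_left(pool_ages, age)
            lo, hi = j - 1, j
            best = -1
            while lo >= 0 or hi < len(pool):
                lo_d = abs(pool_ages[lo] - age) if lo >= 0 else math.inf
                hi_d = abs(pool_ages[hi] - age) if hi < len(pool) else math.inf
                k = lo if lo_d <= hi_d else hi
                if available[k]:
                    best = k
                    break
                if lo_d <= hi_d:
                    lo -= 1
                else:
                    hi += 1
            available[best] = False
            chosen.append(pool_ids[best])

    keep = set(cases["sample_id"]) | set(chosen)
    return cohort[cohort["sample_id"].isin(keep)].reset_index(drop=True)


def split_train_test(
    cohort: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label-stratified train/test split, reproducible from the seed.

    Per label class, ``round(test_fraction * n_class)`` samples go to
    the test set. With stratification off a single plain split is made.
    A stratified class with fewer than 5 members is an error (the
    downstream default is 5-fold cross-validation).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(spec.seed)
    strata = (
        [cohort[cohort["label"] == v] for v in (1, 0)]
        if spec.stratify_by_label
        else [cohort]
    )
    test_ids: set[str] = set()
    for stratum in strata:
        if spec.stratify_by_label and 0 < len(stratum) < 5:
            raise ValueError(
                f"a label class has only {len(stratum)} members; "
                "at least 5 are required for stratified splitting"
            )
        n_test = int(round(spec.test_fraction * len(stratum)))
        picked = rng.permutation(len(stratum))[:n_test]
        test_ids.update(stratum["sample_id"].iloc[picked])
    in_test = cohort["sample_id"].isin(test_ids)
    return (
        cohort[~in_test].reset_index(drop=True),
        cohort[in_test].reset_index(drop=True),
    )
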