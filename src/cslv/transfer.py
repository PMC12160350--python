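"""Cross-population model transfer and feature importance.

Risk scores trained in one population routinely degrade in another:
the informative variation may differ in frequency or in kind between
groups. The transfer grid makes that measurable: for each training
group, assemble an age-matched cohort *within that group*, train on
its 80% split, then evaluate on (i) the group's own 20% holdout,
(ii) every other group in full, (iii) an "other" pool of samples
belonging to none of the named groups, and (iv) the "mixed" union, from
which training samples are excluded except the holdout. Repeating over
seeds gives a mean ± sd AUC per cell.

Feature importance is permutation importance on the held-out set: the
drop in test AUC when one feature column is shuffled, averaged over
repeats — a model-agnostic analogue of per-feature attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import SplitSpec, split_train_test, undersample_matched
from .model import FitResult, ModelSpec, _design_matrix, auc, fit, score

logger = logging.getLogger(__name__)

__all__ = [
    "TransferResult",
    "transfer_matrix",
    "ImportanceTable",
    "permutation_importance",
    "OTHER_GROUP",
    "MIXED_GROUP",
]

OTHER_GROUP = "other"
MIXED_GROUP = "mixed"


@dataclass(frozen=True)
class TransferResult:
    """Per-run and summarized cross-group AUCs.

    ``runs``: long format (train_group, test_group, run, auc).
    ``summary``: (train_group, test_group, mean_auc, sd_auc, n_runs).
    """

    runs: pd.DataFrame
    summary: pd.DataFrame


def _test_pool(
    cohort: pd.DataFrame,
    test_group: str,
    train_group: str,
    named_groups: set[str],
    holdout: pd.DataFrame,
) -> pd.DataFrame:
    if test_group == train_group:
        return holdout
    if test_group == MIXED_GROUP:
        external = cohort[cohort["group"] != train_group]
        return pd.concat([external, holdout], ignore_index=True)
    if test_group == OTHER_GROUP:
        return cohort[~cohort["group"].isin(named_groups)]
    return cohort[cohort["group"] == test_group]


def transfer_matrix(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    train_groups: list[str],
    test_groups: list[str] | None = None,
    split: SplitSpec | None = None,
    n_runs: int = 5,
    match_external: bool = False,
) -> TransferResult:
    """Train per group, test across groups, repeat over seeds.

    External groups are tested as-is by default (``match_external=True``
    applies the same age-matched undersampling to them first). Run ``r``
    offsets both the split seed and the model seed by ``r``.
    """
    split = split or SplitSpec()
    available = set(cohort["group"])
    absent = [g for g in train_groups if g not in available]
    if absent:
        raise ValueError(
            f"group(s) {absent} not in cohort; available: {sorted(available)}"
        )
    named = set(train_groups)
    if test_groups is None:
        test_groups = list(train_groups) + [OTHER_GROUP, MIXED_GROUP]

    rows = []
    for g in train_groups:
        for r in range(n_runs):
            split_r = replace(split, seed=split.seed + r)
            spec_r = replace(spec, seed=spec.seed + r)
            own = cohort[cohort["group"] == g]
            matched = undersample_matched(own, split_r)
            train, holdout = split_train_test(matched, split_r)
            result = fit(features, train, spec_r)
            for t in test_groups:
                pool = _test_pool(cohort, t, g, named, holdout)
                if match_external and t not in (g, MIXED_GROUP):
                    pool = undersample_matched(pool, split_r)
                if pool.empty or pool["label"].nunique() < 2:
                    logger.warning(
                        "skipping test group %r for train group %r: "
                        "needs both classes", t, g,
                    )
                    continue
                s = score(result, features, pool["sample_id"])
                rows.append(
                    {
                        "train_group": g,
                        "test_group": t,
                        "run": r,
                        "auc": auc(pool["label"].to_numpy(int), s.to_numpy()),
                    }
                )

    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby(["train_group", "test_group"], sort=False)["auc"]
        .agg(mean_auc="mean", sd_auc=lambda x: x.std(ddof=1), n_runs="count")
        .reset_index()
    )
    return TransferResult(runs=runs, summary=summary)


@dataclass(frozen=True)
class ImportanceTable:
    """Permutation importances: AUC drop per shuffled feature."""

    table: pd.DataFrame  # index: feature; columns: importance, rank


def permutation_importance(
    result: FitResult,
    features: pd.DataFrame,
    test: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Importance of each feature as mean test-AUC drop under shuffling.

    ``importance_f = baseline AUC − mean over n_repeats shuffles of the
    AUC with column f permuted``. Constant columns get importance 0
    with a warning. Ranks (1 = most important) break ties by feature
    name.
    """
    y = test["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("test cohort needs both classes")
    X = _design_matrix(features, test["sample_id"], result.feature_names, result.medians)
    baseline = auc(y, result.estimator.predict_proba(X)[:, 1])

    rng = np.random.default_rng(seed)
    importances = {}
    for f in result.feature_names:
        col = X[f].to_numpy()
        if np.unique(col).size <= 1:
            logger.warning("feature %r is constant on the test set; importance 0", f)
            importances[f] = 0.0
            continue
        drops = np.empty(n_repeats)
        shuffled = X.copy()
        for rep in range(n_repeats):
            shuffled[f] = rng.permutation(col)
            drops[rep] = auc(y, result.estimator.predict_proba(shuffled)[:, 1])
        importances[f] = baseline - float(drops.mean())

    table = pd.DataFrame({"importance": pd.Series(importances)})
    order = table.sort_values(
        "importance", ascending=False, kind="mergesort"
    ).index
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order)
    return ImportanceTable(table=table)
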