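"""Risk models over CSLV features.

The genetic risk score is whatever a classifier, trained on the 22·k
segment-mean features, assigns to a held-out genome: a number in [0, 1]
read as relative breast-cancer risk. A fixed model zoo (gradient
boosting, random forest, penalised logistic regression, and a logistic
stacked ensemble over the zoo's out-of-fold predictions) replaces an
AutoML search: the contract — 5-fold cross-validation on the training
split, AUC on the untouched 20% test split, repeated runs reported as
mean ± sd — is what matters, not the search procedure.

AUC here is always the Mann-Whitney statistic (probability a random
case outscores a random control, ties credited ½), with a stratified
percentile-bootstrap confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import SplitSpec, split_train_test, undersample_matched

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "FitResult",
    "fit",
    "score",
    "evaluate",
    "auc",
    "auc_ci",
    "repeated_runs",
    "RepeatedRuns",
]

ALGORITHMS = ("gradient_boosting", "random_forest", "logistic", "ensemble")


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to train and how to cross-validate it.

    ``hyperparameters`` are passed through to the underlying estimator.
    ``time_budget_s`` is an advisory cap echoed into reports; the fixed
    zoo trains far below it at desk scale.
    """

    algorithm: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)
    n_cv_folds: int = 5
    seed: int = 0
    time_budget_s: float = 900.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.n_cv_folds < 2:
            raise ValueError("need at least 2 cross-validation folds")


def _base_estimators(spec: ModelSpec):
    seed = spec.seed
    return [
        ("gradient_boosting", HistGradientBoostingClassifier(random_state=seed)),
        (
            "random_forest",
            RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
        ),
        (
            "logistic",
            make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
            ),
        ),
    ]


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "gradient_boosting":
        return HistGradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.algorithm == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=spec.seed, **hp),
        )
    # logistic stack over out-of-fold member predictions
    return StackingClassifier(
        estimators=_base_estimators(spec),
        final_estimator=LogisticRegression(max_iter=2000),
        cv=StratifiedKFold(spec.n_cv_folds, shuffle=True, random_state=spec.seed),
        stack_method="predict_proba",
        n_jobs=1,
    )


@dataclass
class FitResult:
    """A fitted risk model plus its evaluation record."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]
    medians: pd.Series  # train-set medians used for imputation
    cv_aucs: list[float]
    train_auc: float
    test_auc: float | None = None


def _design_matrix(
    features: pd.DataFrame, sample_ids: pd.Series, feature_names: list[str],
    medians: pd.Series | None = None,
) -> pd.DataFrame:
    missing = set(sample_ids) - set(features.index)
    if missing:
        raise ValueError(
            f"{len(missing)} sample(s) lack feature rows, e.g. {sorted(missing)[:5]}"
        )
    X = features.loc[sample_ids, feature_names]
    if medians is not None:
        X = X.fillna(medians)
    return X


def fit(features: pd.DataFrame, train: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Train a classifier with k-fold cross-validation on the train cohort.

    Missing feature values are imputed with the training-fold column
    median; all-missing columns are dropped with a warning. Per-fold CV
    AUCs come from fold-held-out predictions; the returned estimator is
    refit on the full training set. Deterministic given ``spec.seed``.
    """
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort has a single class")

    X_raw = _design_matrix(features, train["sample_id"], list(features.columns))
    all_missing = [c for c in X_raw.columns if X_raw[c].isna().all()]
    if all_missing:
        logger.warning("dropping %d all-missing feature column(s)", len(all_missing))
    feature_names = [c for c in X_raw.columns if c not in all_missing]
    X_raw = X_raw[feature_names]

    cv = StratifiedKFold(spec.n_cv_folds, shuffle=True, random_state=spec.seed)
    cv_aucs = []
    for tr_idx, va_idx in cv.split(X_raw, y):
        med = X_raw.iloc[tr_idx].median()
        est = clone(_make_estimator(spec))
        est.fit(X_raw.iloc[tr_idx].fillna(med), y[tr_idx])
        p = est.predict_proba(X_raw.iloc[va_idx].fillna(med))[:, 1]
        cv_aucs.append(auc(y[va_idx], p))

    medians = X_raw.median()
    estimator = _make_estimator(spec)
    estimator.fit(X_raw.fillna(medians), y)
    train_auc = auc(y, estimator.predict_proba(X_raw.fillna(medians))[:, 1])
    return FitResult(
        spec=spec,
        estimator=estimator,
        feature_names=feature_names,
        medians=medians,
        cv_aucs=cv_aucs,
        train_auc=train_auc,
    )


def score(
    result: FitResult, features: pd.DataFrame, sample_ids=None
) -> pd.Series:
    """Risk scores in [0, 1], one per sample, order-preserving."""
    if sample_ids is None:
        sample_ids = pd.Series(features.index)
    sample_ids = pd.Series(list(sample_ids))
    extra = set(result.feature_names) - set(features.columns)
    if extra:
        raise ValueError(
            f"feature table lacks {len(extra)} column(s) the model was trained on, "
            f"e.g. {sorted(extra)[:5]}"
        )
    X = _design_matrix(features, sample_ids, result.feature_names, result.medians)
    p = result.estimator.predict_proba(X)[:, 1]
    return pd.Series(p, index=sample_ids.to_numpy(), name="score")


def evaluate(result: FitResult, features: pd.DataFrame, test: pd.DataFrame) -> float:
    """Score the test cohort, record and return the test AUC."""
    s = score(result, features, test["sample_id"])
    result.test_auc = auc(test["label"].to_numpy(dtype=int), s.to_numpy())
    return result.test_auc


def auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(case score > control score) + ½·P(tie)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci(
    labels, scores, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC with a stratified percentile-bootstrap confidence interval."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    point = auc(y, s)
    rng = np.random.default_rng(seed)
    case_scores = s[y == 1]
    control_scores = s[y == 0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(case_scores, size=case_scores.size, replace=True)
        ks = rng.choice(control_scores, size=control_scores.size, replace=True)
        stats[b] = auc(
            np.r_[np.ones(cs.size, int), np.zeros(ks.size, int)], np.r_[cs, ks]
        )
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return point, float(lo), float(hi)


@dataclass(frozen=True)
class RepeatedRuns:
    """Test AUCs over repeated resample/split/fit runs."""

    aucs: list[float]
    mean: float
    sd: float
    results: list[FitResult]


def repeated_runs(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    split: SplitSpec | None = None,
    n_runs: int = 5,
    match: bool = True,
) -> RepeatedRuns:
    """Repeat (undersample, split, fit, test) ``n_runs`` times.

    Runs differ only in seed; run ``r`` uses base seed + r for both the
    cohort assembly and the model. Reports the mean and the sample
    standard deviation of the test AUCs.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs to report a standard deviation")
    split = split or SplitSpec()
    aucs, results = [], []
    for r in range(n_runs):
        split_r = replace(split, seed=split.seed + r)
        spec_r = replace(spec, seed=spec.seed + r)
        try:
            working = undersample_matched(cohort, split_r) if match else cohort
            train, test = split_train_test(working, split_r)
            res = fit(features, train, spec_r)
            evaluate(res, features, test)
        except Exception as exc:  # noqa: BLE001 - context required by contract
            raise RuntimeError(f"repeated run {r} failed: {exc}") from exc
        aucs.append(res.test_auc)
        results.append(res)
    arr = np.asarray(aucs)
    return RepeatedRuns(
        aucs=aucs, mean=float(arr.mean()), sd=float(arr.std(ddof=1)), results=results
    )
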