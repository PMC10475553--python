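"""Gradient-boosted tree engine: repeated CV, grid search, MDI and MDA.

All model performance is measured as AUC — the probability that the
classifier ranks a random positive above a random negative.  Repeated
stratified cross-validation (folds x repeats) yields a distribution of
validation AUCs; hyperparameters are tuned by grid search over the same
splits; random minority oversampling is applied inside each training fold
only, never to validation data, so duplicated rows cannot leak across the
fold boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold

from .cohort import ProblemData, oversample_arrays

__all__ = [
    "CVConfig",
    "CVResult",
    "FittedModel",
    "auc",
    "default_grid",
    "default_params",
    "cv_evaluate",
    "cv_importances",
    "fit_final",
    "mdi",
    "mda",
]


def auc(scores, labels) -> float:
    """Rank-based AUC with ties counted 1/2 (normalized Mann-Whitney U)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both label values present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified CV settings; folds x repeats models are fitted."""

    folds: int = 3
    repeats: int = 10
    seed: int = 0
    oversample_inside_folds: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")

    @property
    def n_models(self) -> int:
        return self.folds * self.repeats


@dataclass
class CVResult:
    auc_per_split: np.ndarray
    best_hyperparameters: dict

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_split))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_per_split, ddof=1)) if len(self.auc_per_split) > 1 else 0.0


def default_grid() -> list[dict]:
    """Conventional 3 x 3 x 2 GBM tuning grid (the protocol states tuning
    occurred but not the grid searched)."""
    return list(
        ParameterGrid(
            {
                "n_estimators": [50, 100, 200],
                "max_depth": [2, 3, 4],
                "learning_rate": [0.1, 0.3],
            }
        )
    )


def default_params() -> dict:
    return {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1}


def _make_gbm(params: dict, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(random_state=seed, **params)


def _splits(y: np.ndarray, cv: CVConfig):
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    return list(splitter.split(np.zeros_like(y), y))


def _subset(problem: ProblemData, features) -> np.ndarray:
    missing = [f for f in features if f not in problem.X.columns]
    if missing:
        raise KeyError(f"features not in problem: {missing}")
    return problem.X[list(features)].to_numpy(dtype=float)


def cv_evaluate(
    problem: ProblemData,
    features,
    cv: CVConfig,
    grid: list[dict] | None = None,
) -> CVResult:
    """Repeated-CV AUC of a GBM on a feature subset, with grid search.

    Every grid point is evaluated on the same folds; training folds are
    oversampled to class balance (validation folds untouched); the result
    carries the per-split AUCs of the best grid point and the chosen
    hyperparameters.  With a singleton grid this is plain repeated CV.
    """
    features = list(features)
    if not features:
        raise ValueError("feature subset must be non-empty")
    if grid is None:
        grid = [default_params()]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = _subset(problem, features)
    y = problem.y
    splits = _splits(y, cv)
    rng = np.random.default_rng(cv.seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=len(splits))

    best: CVResult | None = None
    for params in grid:
        aucs = np.empty(len(splits))
        for s, (tr, va) in enumerate(splits):
            X_tr, y_tr = X[tr], y[tr]
            if cv.oversample_inside_folds:
                X_tr, y_tr = oversample_arrays(
                    X_tr, y_tr, np.random.default_rng(fold_seeds[s])
                )
            model = _make_gbm(params, seed=int(fold_seeds[s]))
            model.fit(X_tr, y_tr)
            aucs[s] = auc(model.predict_proba(X[va])[:, 1], y[va])
        candidate = CVResult(auc_per_split=aucs, best_hyperparameters=dict(params))
        if best is None or candidate.mean_auc > best.mean_auc:
            best = candidate
    return best


@dataclass
class FittedModel:
    """A trained GBM bound to its feature list; scores are P(positive)."""

    model: GradientBoostingClassifier
    features: list[str]

    def score(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(X[self.features].to_numpy(dtype=float))[:, 1]


def fit_final(
    problem: ProblemData,
    features,
    params: dict,
    seed: int = 0,
    oversample_train: bool = True,
) -> FittedModel:
    """Fit the final model on the full training data (oversampled once)."""
    features = list(features)
    X = _subset(problem, features)
    y = problem.y
    if oversample_train:
        X, y = oversample_arrays(X, y, np.random.default_rng(seed))
    model = _make_gbm(params, seed=seed)
    model.fit(X, y)
    return FittedModel(model=model, features=features)


def mdi(model: FittedModel) -> pd.Series:
    """Mean-decrease-impurity importance I_I of the fitted ensemble.

    Per feature: the node-sample-weighted Gini impurity decrease summed
    over all splits on that feature, averaged over trees (normalized to
    sum to 1); features never split on score exactly 0.
    """
    return pd.Series(model.model.feature_importances_, index=model.features)


def mda(
    model: FittedModel,
    validation: ProblemData,
    permutations: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean-decrease-AUC (permutation) importance I_A on validation data.

    I_A(f) = baseline AUC minus the mean AUC over ``permutations``
    re-scorings with column f permuted within the validation set; other
    columns are untouched.  May be negative.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    Xv = validation.X[model.features].to_numpy(dtype=float)
    yv = validation.y
    baseline = auc(model.model.predict_proba(Xv)[:, 1], yv)
    out = {}
    for j, f in enumerate(model.features):
        drops = np.empty(permutations)
        Xp = Xv.copy()
        for k in range(permutations):
            Xp[:, j] = rng.permutation(Xv[:, j])
            drops[k] = auc(model.model.predict_proba(Xp)[:, 1], yv)
        out[f] = baseline - float(np.mean(drops))
    return pd.Series(out)


def cv_importances(
    problem: ProblemData,
    cv: CVConfig,
    params: dict,
    features=None,
    permutations: int = 10,
) -> tuple[pd.Series, pd.Series, CVResult]:
    """MDI and MDA averaged over the CV-trained ensemble.

    Fits one GBM per CV split with the given hyperparameters (training
    folds oversampled), accumulates each model's MDI and its MDA measured
    on that split's untouched validation fold, and returns the averages
    together with the per-split AUCs.
    """
    features = list(features) if features is not None else list(problem.X.columns)
    X = _subset(problem, features)
    y = problem.y
    splits = _splits(y, cv)
    rng = np.random.default_rng(cv.seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=len(splits))

    mdi_acc = np.zeros(len(features))
    mda_acc = np.zeros(len(features))
    aucs = np.empty(len(splits))
    for s, (tr, va) in enumerate(splits):
        X_tr, y_tr = X[tr], y[tr]
        if cv.oversample_inside_folds:
            X_tr, y_tr = oversample_arrays(
                X_tr, y_tr, np.random.default_rng(fold_seeds[s])
            )
        gbm = _make_gbm(params, seed=int(fold_seeds[s]))
        gbm.fit(X_tr, y_tr)
        fitted = FittedModel(model=gbm, features=features)
        aucs[s] = auc(gbm.predict_proba(X[va])[:, 1], y[va])
        mdi_acc += gbm.feature_importances_
        va_problem = ProblemData(
            X=pd.DataFrame(X[va], columns=features), y=y[va], spec=problem.spec
        )
        mda_acc += mda(
            fitted, va_problem, permutations=permutations, seed=int(fold_seeds[s])
        ).to_numpy()
    k = len(splits)
    cv_result = CVResult(auc_per_split=aucs, best_hyperparameters=dict(params))
    return (
        pd.Series(mdi_acc / k, index=features),
        pd.Series(mda_acc / k, index=features),
        cv_result,
    )
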