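"""GBM engine: AUC against a pair-counting oracle, repeated-CV shape and
leakage behaviour, grid search, MDI/MDA semantics."""

import numpy as np
import pytest

from conftest import make_problem
from foisel.gbm import (
    CVConfig,
    auc,
    cv_evaluate,
    cv_importances,
    default_grid,
    fit_final,
    mda,
    mdi,
)

FAST = {"n_estimators": 20, "max_depth": 2, "learning_rate": 0.3}


def pair_counting_auc(scores, labels):
    """O(n^2) oracle: fraction of (pos, neg) pairs ranked correctly, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_examples():
    assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auc([0.3] * 10, [1, 0] * 5) == 0.5
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        # discrete scores force plenty of ties
        scores = rng.integers(0, 5, n) / 4.0
        assert auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(12)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    scores = rng.random(50)
    base = auc(scores, labels)
    assert auc(np.exp(3 * scores) - 1, labels) == pytest.approx(base, abs=1e-12)


def _problem(n=60, p=4, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    cols = [rng.integers(0, 2, n) for _ in range(p)]
    if informative:
        cols[0] = np.where(rng.random(n) < 0.9, y, 1 - y)
    return make_problem(np.column_stack(cols), y)


@pytest.mark.parametrize("folds,repeats,expected", [(3, 10, 30), (5, 20, 100)])
def test_cv_model_counts(folds, repeats, expected):
    cv = CVConfig(folds=folds, repeats=repeats, seed=0)
    assert cv.n_models == expected
    res = cv_evaluate(_problem(), ["f0", "f1"], cv=cv, grid=[FAST])
    assert len(res.auc_per_split) == expected
    assert np.all((res.auc_per_split >= 0) & (res.auc_per_split <= 1))
    assert res.mean_auc == pytest.approx(res.auc_per_split.mean())


def test_perfect_feature_gives_auc_one():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    problem = make_problem(y[:, None], y)
    res = cv_evaluate(problem, ["f0"], cv=CVConfig(2, 2, seed=0), grid=[FAST])
    assert res.mean_auc == 1.0


def test_grid_search_returns_grid_member_and_empty_grid_errors():
    grid = default_grid()
    assert len(grid) == 18
    small = [{"n_estimators": 10, "max_depth": 2, "learning_rate": 0.1},
             {"n_estimators": 30, "max_depth": 3, "learning_rate": 0.1}]
    res = cv_evaluate(_problem(), ["f0", "f1"], cv=CVConfig(3, 1, seed=0), grid=small)
    assert res.best_hyperparameters in small
    with pytest.raises(ValueError):
        cv_evaluate(_problem(), ["f0"], cv=CVConfig(3, 1, seed=0), grid=[])


def test_label_permuted_auc_is_chance():
    """Leak canary: with oversampling confined to training folds, CV AUC on
    label-permuted data must sit at 0.5."""
    means = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        problem = _problem(n=120, p=5, seed=seed, informative=True)
        y_perm = rng.permutation(problem.y)
        # imbalance so oversampling actually fires
        y_perm[: len(y_perm) // 3] = 0
        shuffled = make_problem(problem.X.to_numpy(), rng.permutation(y_perm))
        res = cv_evaluate(
            shuffled, list(shuffled.X.columns), cv=CVConfig(3, 3, seed=seed),
            grid=[FAST],
        )
        means.append(res.mean_auc)
    grand = float(np.mean(means))
    se = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    assert abs(grand - 0.5) < max(2 * se, 0.05)


def test_fit_final_deterministic_and_bounded():
    problem = _problem(n=80, p=3, seed=3)
    m1 = fit_final(problem, ["f0", "f1"], FAST, seed=7)
    m2 = fit_final(problem, ["f0", "f1"], FAST, seed=7)
    s1, s2 = m1.score(problem.X), m2.score(problem.X)
    np.testing.assert_array_equal(s1, s2)
    assert np.all((s1 >= 0) & (s1 <= 1))


def test_mdi_semantics():
    problem = _problem(n=100, p=1, seed=4)
    single = mdi(fit_final(problem, ["f0"], FAST, seed=0))
    assert single["f0"] == pytest.approx(1.0)

    problem2 = _problem(n=100, p=3, seed=5)
    scores = mdi(fit_final(problem2, ["f0", "f1", "f2"], FAST, seed=0))
    assert (scores >= 0).all()
    assert scores["f0"] > scores["f1"] and scores["f0"] > scores["f2"]


def test_mdi_duplicated_feature_splits_importance():
    """Two perfect copies of a feature share roughly the MDI the single
    copy earns in a control fit."""
    rng = np.random.default_rng(6)
    n = 200
    y = rng.integers(0, 2, n)
    x = np.where(rng.random(n) < 0.85, y, 1 - y)
    noise = rng.integers(0, 2, n)
    single = mdi(fit_final(make_problem(np.column_stack([x, noise]), y),
                           ["f0", "f1"], FAST, seed=0))
    dup = mdi(fit_final(make_problem(np.column_stack([x, x, noise]), y),
                        ["f0", "f1", "f2"], FAST, seed=0))
    assert dup["f0"] + dup["f1"] == pytest.approx(single["f0"], abs=0.1)


def test_mda_unused_and_informative_features():
    rng = np.random.default_rng(8)
    n = 200
    y = rng.integers(0, 2, n)
    X = np.column_stack([y, rng.integers(0, 2, n)])
    problem = make_problem(X, y)
    model = fit_final(problem, ["f0", "f1"], FAST, seed=0)
    scores = mda(model, problem, permutations=10, seed=1)
    # permuting the label-identical feature destroys the model: drop ~ 0.5
    assert scores["f0"] == pytest.approx(0.5, abs=0.1)
    # the noise feature is unused
    assert abs(scores["f1"]) < 0.02


def test_cv_importances_average_over_models():
    problem = _problem(n=90, p=3, seed=9)
    cv = CVConfig(3, 2, seed=2)
    i_i, i_a, res = cv_importances(problem, cv=cv, params=FAST, permutations=3)
    assert len(res.auc_per_split) == 6
    assert set(i_i.index) == set(i_a.index) == set(problem.X.columns)
    assert (i_i >= 0).all()
    assert i_i["f0"] == max(i_i)
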