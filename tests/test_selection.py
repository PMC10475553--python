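"""Candidate-list construction, multi-list forward selection, and the
transition-point rule."""

import numpy as np
import pytest

from conftest import cohort_to_problem, make_problem, recovery_config
from foisel.gbm import CVConfig, cv_evaluate
from foisel.selection import (
    METRIC_ORDER,
    CandidateLists,
    MetricRanking,
    build_candidate_lists,
    forward_select,
    transition_point,
)
from foisel.synthetic import PlantedInteraction, SyntheticConfig
from foisel.universe import FEATURE_NAMES

FAST = {"n_estimators": 20, "max_depth": 2, "learning_rate": 0.3}
CV = CVConfig(folds=3, repeats=2, seed=0)


@pytest.mark.parametrize(
    "means,expected",
    [
        ([0.60, 0.70, 0.75, 0.755, 0.752, 0.751], 4),  # hand-evaluated rule
        ([0.7, 0.7, 0.7], 1),                           # constant
        ([0.5, 0.6, 0.7, 0.8], 4),                      # strictly increasing
        ([0.9], 1),                                     # single step
        ([0.8, 0.6], 1),                                # immediate decline
        ([0.70, 0.705, 0.703], 2),  # sub-tolerance rise still defers via (b)
    ],
)
def test_transition_point_rule(means, expected):
    assert transition_point(means, tolerance=0.01) == expected


def test_transition_point_needs_steps():
    with pytest.raises(ValueError):
        transition_point([], tolerance=0.01)


def test_candidate_lists_strong_univariate_tops_phi():
    problem = cohort_to_problem(recovery_config(seed=0, n_per_class=150, n_noise=10))
    lists = build_candidate_lists(problem, cv=CV, params=FAST, permutations=3)
    assert lists["phi"].features[0] in {"P1", "M1", "C1"}
    assert set(lists["phi"].features[:3]) == {"P1", "M1", "C1"}
    # entries sorted descending by the importance key
    phi_scores = [abs(s) for _, s in lists["phi"].entries]
    assert phi_scores == sorted(phi_scores, reverse=True)
    for m in ("multisurf", "mdi", "mda"):
        vals = [s for _, s in lists[m].entries]
        assert vals == sorted(vals, reverse=True)
        assert all(v > 0 for v in vals)


def test_candidate_lists_xor_found_by_multisurf_not_phi():
    noise = [f for f in FEATURE_NAMES if f not in ("I1", "V2")][:10]
    zero = tuple(f for f in FEATURE_NAMES if f not in ["I1", "V2"] + noise)
    cfg = SyntheticConfig(
        class_sizes={"A": 150, "B": 150},
        interactions=(PlantedInteraction(("I1", "V2"), {"A": 0.85, "B": 0.15}),),
        zero_features=zero,
        noise_p=0.3,
        seed=2,
    )
    problem = cohort_to_problem(cfg)
    lists = build_candidate_lists(problem, cv=CV, params=FAST, permutations=3)
    assert {"I1", "V2"} <= set(lists["multisurf"].features)
    assert not ({"I1", "V2"} & set(lists["phi"].features))


def test_candidate_lists_all_empty_errors():
    # constant features: no phi p-value, zero relief weight, nothing to split
    X = np.ones((30, 2), dtype=int)
    y = np.array([0, 1] * 15)
    with pytest.raises(ValueError, match="empty"):
        build_candidate_lists(make_problem(X, y), cv=CV, params=FAST, permutations=2)


def _manual_lists(per_metric: dict[str, list[str]]) -> CandidateLists:
    rankings = {
        m: MetricRanking(
            m, [(f, 1.0 - 0.1 * i) for i, f in enumerate(per_metric.get(m, []))], "manual"
        )
        for m in METRIC_ORDER
    }
    return CandidateLists(rankings=rankings, hyperparameters=dict(FAST))


def test_forward_select_dedup_single_candidate():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    X = np.column_stack([y, rng.integers(0, 2, 60)])
    problem = make_problem(X, y)
    lists = _manual_lists({m: ["f0"] for m in METRIC_ORDER})
    trace = forward_select(problem, lists, cv=CV)
    assert len(trace.steps) == 1
    assert len(trace.steps[0].candidates_evaluated) == 1  # all lists agree
    assert trace.steps[0].winner == "f0"


def test_forward_select_informative_wins_and_covers_union():
    problem = cohort_to_problem(recovery_config(seed=4, n_per_class=120, n_noise=6))
    lists = build_candidate_lists(problem, cv=CV, params=FAST, permutations=2)
    trace = forward_select(problem, lists, cv=CV, params=FAST, tolerance=0.01)
    assert trace.steps[0].winner in {"P1", "M1", "C1"}
    seq = trace.selected_features
    assert len(seq) == len(set(seq))             # duplicate-free
    assert set(seq) == set(lists.union)          # exhausts the candidate union
    assert all(len(s.candidates_evaluated) <= 4 for s in trace.steps)
    assert all(s.cumulative_features[-1] == s.winner for s in trace.steps)
    # transition-point AUC within tolerance of the best step
    means = trace.means
    assert means[trace.transition_index - 1] >= max(means) - 0.01


def test_forward_select_holdout_auc_recorded():
    cfg = recovery_config(seed=6, n_per_class=120, n_noise=4)
    problem = cohort_to_problem(cfg)
    from foisel.cohort import split_holdout

    train, holdout = split_holdout(problem, 0.8, seed=1)
    lists = build_candidate_lists(train, cv=CV, params=FAST, permutations=2)
    trace = forward_select(train, lists, cv=CV, params=FAST, holdout=holdout)
    assert all(0.0 <= s.holdout_auc <= 1.0 for s in trace.steps)
    # informative features make the holdout clearly better than chance
    assert trace.steps[trace.transition_index - 1].holdout_auc > 0.6


def test_forward_select_agrees_with_exhaustive_oracle():
    """Greedy multi-list selection reaches the exhaustive-search optimum
    within the transition tolerance on a small feature space."""
    from itertools import combinations

    problem = cohort_to_problem(recovery_config(seed=8, n_per_class=120, n_noise=3))
    features = list(problem.X.columns)
    assert len(features) <= 8
    best = 0.0
    for k in range(1, len(features) + 1):
        for subset in combinations(features, k):
            res = cv_evaluate(problem, list(subset), cv=CV, grid=[FAST])
            best = max(best, res.mean_auc)
    lists = build_candidate_lists(problem, cv=CV, params=FAST, permutations=2)
    trace = forward_select(problem, lists, cv=CV, params=FAST)
    reached = trace.means[trace.transition_index - 1]
    assert reached >= best - 0.01
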