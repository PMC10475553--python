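"""Two-step hybrid feature selection.

Step 1 (:func:`build_candidate_lists`) turns four importance estimates —
phi-coefficient, MultiSURF weight W, mean-decrease-impurity I_I and
mean-decrease-AUC I_A from a CV-trained all-features GBM — into four
ranked *candidate lists*: a feature qualifies for the phi list when its
association with the diagnosis is significant (p < 0.05) and for the other
lists when its weight/importance is positive.

Step 2 (:func:`forward_select`) is a multi-list sequential forward
selection: at each step the best-ranked not-yet-selected feature of each
list supplies at most four distinct candidates; each candidate is
evaluated by repeated-CV AUC of a GBM on the already-selected features
plus the candidate, and the best one is added.  Losing candidates stay
eligible.  The loop continues until the union of all candidate lists is
exhausted, so no potentially useful feature is missed; the *transition
point* (:func:`transition_point`) afterwards marks the step beyond which
additional features stop improving mean CV performance beyond a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import ConstantVectorError, phi
from .cohort import ProblemData
from .gbm import (
    CVConfig,
    CVResult,
    cv_evaluate,
    cv_importances,
    default_params,
    fit_final,
)
from .relief import multisurf

__all__ = [
    "METRIC_ORDER",
    "MetricRanking",
    "CandidateLists",
    "SelectionStep",
    "SelectionTrace",
    "build_candidate_lists",
    "forward_select",
    "transition_point",
]

#: Fixed metric order, also the tie-break order during selection.
METRIC_ORDER: tuple[str, ...] = ("phi", "multisurf", "mdi", "mda")


@dataclass
class MetricRanking:
    """One metric's candidate list: (feature, score) descending."""

    metric: str
    entries: list[tuple[str, float]]
    criterion: str

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CandidateLists:
    """The four per-metric rankings for one problem."""

    rankings: dict[str, MetricRanking]
    hyperparameters: dict = field(default_factory=dict)
    cv_result: CVResult | None = None

    def __post_init__(self) -> None:
        if set(self.rankings) != set(METRIC_ORDER):
            raise ValueError(f"expected rankings for {METRIC_ORDER}")

    def __getitem__(self, metric: str) -> MetricRanking:
        return self.rankings[metric]

    @property
    def union(self) -> list[str]:
        """All candidate features, in first-appearance order over metrics."""
        seen: dict[str, None] = {}
        for m in METRIC_ORDER:
            for f in self.rankings[m].features:
                seen.setdefault(f)
        return list(seen)


def build_candidate_lists(
    problem: ProblemData,
    cv: CVConfig,
    params: dict | None = None,
    permutations: int = 10,
    alpha: float = 0.05,
) -> CandidateLists:
    """Step-1 candidate lists from the four importance metrics.

    ``params`` are the (already tuned) GBM hyperparameters for the
    all-features CV ensemble that supplies MDI and MDA.  Constant columns
    get no phi p-value and weight 0, so they simply never qualify.
    """
    params = dict(params) if params else default_params()
    y = problem.y

    phi_entries = []
    for f in problem.X.columns:
        try:
            res = phi(problem.X[f].to_numpy(dtype=int), y)
        except ConstantVectorError:
            continue
        if res.p_value < alpha:
            phi_entries.append((f, res.r_phi))
    phi_entries.sort(key=lambda t: (-abs(t[1]), t[0]))

    weights = multisurf(problem).W
    ms_entries = sorted(
        ((f, float(w)) for f, w in weights.items() if w > 0),
        key=lambda t: (-t[1], t[0]),
    )

    i_i, i_a, cv_result = cv_importances(
        problem, cv=cv, params=params, permutations=permutations
    )
    mdi_entries = sorted(
        ((f, float(v)) for f, v in i_i.items() if v > 0), key=lambda t: (-t[1], t[0])
    )
    mda_entries = sorted(
        ((f, float(v)) for f, v in i_a.items() if v > 0), key=lambda t: (-t[1], t[0])
    )

    rankings = {
        "phi": MetricRanking("phi", phi_entries, f"p-value < {alpha}, ranked by |r_phi|"),
        "multisurf": MetricRanking("multisurf", ms_entries, "W > 0"),
        "mdi": MetricRanking("mdi", mdi_entries, "I_I > 0"),
        "mda": MetricRanking("mda", mda_entries, "mean I_A > 0"),
    }
    if all(len(r) == 0 for r in rankings.values()):
        raise ValueError("all four candidate lists are empty; nothing selectable")
    return CandidateLists(
        rankings=rankings, hyperparameters=params, cv_result=cv_result
    )


@dataclass
class SelectionStep:
    step_index: int  # 1-based
    candidates_evaluated: list[tuple[str, CVResult]]
    winner: str
    cumulative_features: list[str]
    holdout_auc: float

    @property
    def cv_result(self) -> CVResult:
        for f, res in self.candidates_evaluated:
            if f == self.winner:
                return res
        raise LookupError(self.winner)


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    tolerance: float
    transition_index: int = 0  # 1-based step index = feature count

    @property
    def means(self) -> list[float]:
        return [s.cv_result.mean_auc for s in self.steps]

    @property
    def selected_features(self) -> list[str]:
        return list(self.steps[-1].cumulative_features) if self.steps else []

    @property
    def transition_features(self) -> list[str]:
        return self.selected_features[: self.transition_index]


def transition_point(means, tolerance: float = 0.01) -> int:
    """Smallest step m (1-based) after which performance stops improving.

    Conditions: (a) no later step's mean CV AUC exceeds AUC_m + tolerance,
    and (b) the immediately following step is not better (AUC_{m+1} <=
    AUC_m; vacuous at the last step).  Since one feature is added per
    step, the returned index equals the feature count at the transition.
    """
    if hasattr(means, "means"):
        means = means.means
    means = list(means)
    if not means:
        raise ValueError("need at least one step")
    k = len(means)
    for m in range(k):
        later_ok = all(means[j] <= means[m] + tolerance for j in range(m + 1, k))
        next_ok = m == k - 1 or means[m + 1] <= means[m]
        if later_ok and next_ok:
            return m + 1
    return k  # unreachable: the last step always satisfies both


def _next_candidates(
    lists: CandidateLists, selected: set[str]
) -> list[tuple[str, int]]:
    """Best-ranked unselected feature per list, deduplicated (<= 4)."""
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for li, m in enumerate(METRIC_ORDER):
        for f in lists[m].features:
            if f not in selected:
                if f not in seen:
                    out.append((f, li))
                    seen.add(f)
                break
    return out


def forward_select(
    problem: ProblemData,
    lists: CandidateLists,
    cv: CVConfig,
    params: dict | None = None,
    grid: list[dict] | None = None,
    holdout: ProblemData | None = None,
    tolerance: float = 0.01,
    retune_each_step: bool = False,
    final_seed: int = 0,
) -> SelectionTrace:
    """Multi-list sequential forward selection (step 2).

    Hyperparameters: by default tuned once on the full candidate union via
    ``grid`` (or taken from ``params`` / the step-1 tuning) and reused at
    every step; ``retune_each_step`` re-runs the grid per candidate
    evaluation instead.  Ties on mean CV AUC (within 1e-9) go to the
    candidate supplied by the earlier list in (phi, multisurf, mdi, mda)
    order, then to the lexicographically smaller feature name.

    After every step a final model is fitted on the full (oversampled)
    training data and, when ``holdout`` is given, scored on it.
    """
    if params is None:
        params = lists.hyperparameters or default_params()
    if grid is not None and not retune_each_step:
        tuned = cv_evaluate(problem, lists.union, cv=cv, grid=grid)
        params = tuned.best_hyperparameters

    selected: list[str] = []
    steps: list[SelectionStep] = []
    union = lists.union
    while len(selected) < len(union):
        candidates = _next_candidates(lists, set(selected))
        evaluated: list[tuple[str, CVResult, int]] = []
        for f, list_index in candidates:
            res = cv_evaluate(
                problem,
                selected + [f],
                cv=cv,
                grid=(grid if retune_each_step and grid else [params]),
            )
            evaluated.append((f, res, list_index))
        best = min(evaluated, key=lambda t: (-round(t[1].mean_auc, 9), t[2], t[0]))
        winner = best[0]
        selected = selected + [winner]

        if holdout is not None:
            final = fit_final(problem, selected, best[1].best_hyperparameters,
                              seed=final_seed)
            holdout_auc = _safe_auc(final, holdout)
        else:
            holdout_auc = float("nan")
        steps.append(
            SelectionStep(
                step_index=len(selected),
                candidates_evaluated=[(f, r) for f, r, _ in evaluated],
                winner=winner,
                cumulative_features=list(selected),
                holdout_auc=holdout_auc,
            )
        )
    trace = SelectionTrace(steps=steps, tolerance=tolerance)
    trace.transition_index = transition_point(trace.means, tolerance)
    return trace


def _safe_auc(final, holdout: ProblemData) -> float:
    from .gbm import auc as _auc

    scores = final.score(holdout.X)
    return _auc(scores, holdout.y)
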