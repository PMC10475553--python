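"""Step 2: multi-list sequential forward selection with transition points.

For each problem, runs the greedy multi-list forward selection (at most
four candidates per step, losers stay eligible, continues until the
candidate union is exhausted), fits a final model per step on the full
training data, scores it on the shared holdout, and determines the
transition point at tolerance 0.01.  CV is the reduced 3 x 3 setting.
Writes trace.json / trace.tsv per problem plus the run summary and the
per-problem importance-list table.

Requires 03_rank_features.py to have run.
"""

import json
from pathlib import Path

from foisel.cohort import FeatureTable, build_problems, problem_from_spec
from foisel.gbm import CVConfig, default_params
from foisel.pipeline import (
    _trace_to_dict,
    _trace_to_tsv,
    _write_json,
    lists_from_dict,
    render_reports,
    substream_seed,
)
from foisel.selection import forward_select

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "results" / "run"
SEED = 1
TOLERANCE = 0.01


def main() -> None:
    train = FeatureTable.from_tsv(RUN / "train_table.tsv")
    holdout = FeatureTable.from_tsv(RUN / "holdout_table.tsv")
    cv = CVConfig(folds=3, repeats=3, seed=substream_seed(SEED, "step2"))
    names = []
    for problem in build_problems(train):
        names.append(problem.name)
        pdir = RUN / "problems" / problem.name
        lists = lists_from_dict(json.loads((pdir / "candidates.json").read_text()))
        trace = forward_select(
            problem,
            lists,
            cv=cv,
            params=lists.hyperparameters or default_params(),
            holdout=problem_from_spec(problem.spec, holdout),
            tolerance=TOLERANCE,
            final_seed=substream_seed(SEED, "final"),
        )
        _write_json(pdir / "trace.json", _trace_to_dict(trace))
        _trace_to_tsv(trace, pdir / "trace.tsv")
        t = trace.transition_index
        print(f"{problem.name}: {len(trace.steps)} steps, transition at {t} features "
              f"(mean CV AUC {trace.means[t - 1]:.3f}, holdout "
              f"{trace.steps[t - 1].holdout_auc:.3f})")
        print(f"  importance list: {' '.join(trace.transition_features)}")

    manifest = {"problems": names, "seed": SEED,
                "n_patients": train.n_patients + holdout.n_patients,
                "n_features": len(train.feature_names)}
    (RUN / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print()
    print(render_reports(RUN), end="")


if __name__ == "__main__":
    main()
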