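"""Step 1: per-problem candidate lists from the four importance metrics.

For each of the six OvO/OvR problems, tunes a GBM on all features under
repeated CV, then builds the four candidate lists (phi p < 0.05 ranked by
|r_phi|; MultiSURF W > 0; MDI I_I > 0; MDA I_A > 0).  CV is run at a
reduced 3-fold x 3-repeat setting to keep the desk run short; the
candidate lists are written to results/run/problems/<name>/candidates.json.

Requires 02_preprocess.py to have run (train/holdout tables on disk).
"""

import json
from pathlib import Path

from foisel.cohort import FeatureTable, build_problems
from foisel.gbm import CVConfig, cv_evaluate, default_params
from foisel.pipeline import _lists_to_dict, _write_json, substream_seed
from foisel.selection import METRIC_ORDER, build_candidate_lists

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "results" / "run"
SEED = 1


def main() -> None:
    train = FeatureTable.from_tsv(RUN / "train_table.tsv")
    cv = CVConfig(folds=3, repeats=3, seed=substream_seed(SEED, "step1"))
    grid = [default_params()]
    for problem in build_problems(train):
        tuned = cv_evaluate(problem, problem.X.columns, cv=cv, grid=grid)
        lists = build_candidate_lists(
            problem, cv=cv, params=tuned.best_hyperparameters, permutations=3
        )
        pdir = RUN / "problems" / problem.name
        pdir.mkdir(parents=True, exist_ok=True)
        _write_json(pdir / "candidates.json", _lists_to_dict(lists))
        sizes = {m: len(lists[m]) for m in METRIC_ORDER}
        print(f"{problem.name}: all-features CV AUC "
              f"{tuned.mean_auc:.3f} +/- {tuned.sd_auc:.3f}; list sizes {sizes}")
        for m in METRIC_ORDER:
            top = " ".join(f for f, _ in lists[m].entries[:5])
            print(f"  {m:>9}: {top}")


if __name__ == "__main__":
    main()
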