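"""Preprocess the cohort: fuse hands, encode, filter, split, and screen
collinearity.

Reads results/cohort.csv (or regenerates it), fuses the two hands'
annotations, encodes the 60 binary indicators, drops featureless patients
and never-observed indicators, sets aside the stratified 10% holdout
shared by all problems, and writes the phi/VIF collinearity screen.
Artifacts land in results/run/.
"""

import json
from pathlib import Path

from foisel.pipeline import RunConfig, preprocess
from foisel.synthetic import study_like_config

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "run"
SEED = 1


def main() -> None:
    cohort_csv = ROOT / "results" / "cohort.csv"
    if cohort_csv.exists():
        config = RunConfig(out_dir=str(OUT), input_csv=str(cohort_csv), seed=SEED)
    else:
        config = RunConfig(out_dir=str(OUT), synthetic=study_like_config(), seed=SEED)
    filtered, train, holdout = preprocess(config, OUT)

    drops = json.loads((OUT / "drops.json").read_text())
    coll = json.loads((OUT / "collinearity.json").read_text())
    print(f"patients: {drops['n_patients_before']} -> {drops['n_patients_after']} "
          f"({len(drops['dropped_patients'])} featureless removed)")
    print(f"indicators: 60 -> {len(filtered.feature_names)} "
          f"({len(drops['dropped_features'])} never observed: "
          f"{' '.join(drops['dropped_features'])})")
    print(f"split: {train.n_patients} train / {holdout.n_patients} holdout")
    print(f"max VIF: {coll['max_vif']:.2f} ({coll['max_vif_feature']}) — "
          "no alarming collinearity" if coll["max_vif"] < 5 else "check collinearity")
    print("strongest phi pairs (|phi| >= 0.5):")
    for a, b, r in coll["high_phi_pairs"][:5]:
        print(f"  {a} & {b}: r_phi = {r:.2f}")


if __name__ == "__main__":
    main()
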