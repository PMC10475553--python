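"""Preprocessing: hand fusion, encoding, filtering, problem construction,
holdout splitting, and minority oversampling."""

import numpy as np
import pandas as pd
import pytest

from foisel.cohort import (
    FeatureTable,
    build_problems,
    encode,
    filter_table,
    fuse_hands,
    oversample,
    problem_from_spec,
    read_reading_csv,
    split_holdout,
    split_table,
    write_reading_csv,
)
from foisel.synthetic import SyntheticConfig, generate_cohort
from foisel.universe import FEATURE_NAMES


def reading_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "diagnosis", "hand", "phase", "features"])


def test_fuse_hands_union_and_empty():
    readings = reading_frame(
        [
            ("p1", "RA", "left", 2, "D"),
            ("p1", "RA", "right", 2, "P"),
            ("p2", "OA", "left", 1, "D"),
            ("p2", "OA", "right", 1, "D"),
            ("p3", "CTD", "left", 1, ""),
            ("p3", "CTD", "right", 1, ""),
        ]
    )
    fused = fuse_hands(readings)
    by = fused.set_index(["patient_id", "phase"])["features"]
    assert by[("p1", 2)] == "D;P"
    assert by[("p2", 1)] == "D"
    assert by[("p3", 1)] == ""  # featureless patient retained
    assert "hand" not in fused.columns


def test_fusion_invariant_to_hand_swap():
    cfg = SyntheticConfig(class_sizes={"A": 40, "B": 40}, noise_p=0.2, seed=1)
    readings = generate_cohort(cfg)
    swapped = readings.assign(
        hand=readings["hand"].map({"left": "right", "right": "left"})
    )
    a = encode(fuse_hands(readings))
    b = encode(fuse_hands(swapped))
    pd.testing.assert_frame_equal(a.X, b.X)


def test_encode_shape_and_placement():
    fused = fuse_hands(
        reading_frame(
            [("p1", "RA", "left", 1, "Y"), ("p1", "RA", "right", 2, ""),
             ("p1", "RA", "left", 3, "")]
        )
    )
    table = encode(fused)
    assert table.X.shape == (1, 60)
    row = table.X.iloc[0]
    assert row["Y1"] == 1
    assert row.drop("Y1").sum() == 0


def test_encode_rejects_unknown_acronym():
    fused = reading_frame([("p1", "RA", None, 1, "Q")]).drop(columns=["hand"])
    with pytest.raises(ValueError, match="Q"):
        encode(fused)


def test_encode_empty_table():
    fused = reading_frame([]).drop(columns=["hand"])
    table = encode(fused)
    assert table.X.shape == (0, 60)


def test_filter_table_drops_and_is_idempotent(study_like_encoded, study_like_filtered):
    filtered, dropped_features, dropped_patients = study_like_filtered
    assert len(dropped_features) == 15
    assert len(dropped_patients) == 4
    assert filtered.n_patients == 605
    again, df2, dp2 = filter_table(filtered)
    assert df2 == [] and dp2 == []
    pd.testing.assert_frame_equal(again.X, filtered.X)


def test_filter_table_empty_raises():
    X = pd.DataFrame(np.zeros((3, 4), dtype=int), columns=list("abcd"),
                     index=pd.Index(["p1", "p2", "p3"], name="patient_id"))
    labels = pd.Series(["RA", "OA", "RA"], index=X.index)
    with pytest.raises(ValueError):
        filter_table(FeatureTable(X=X, labels=labels))


def _table(counts: dict[str, int], p: int = 5, seed: int = 0) -> FeatureTable:
    rng = np.random.default_rng(seed)
    labels, ids = [], []
    for cls, n in counts.items():
        labels += [cls] * n
        ids += [f"{cls}{i}" for i in range(n)]
    X = pd.DataFrame(
        rng.integers(0, 2, (len(labels), p)),
        columns=[f"f{i}" for i in range(p)],
        index=pd.Index(ids, name="patient_id"),
    )
    return FeatureTable(X=X, labels=pd.Series(labels, index=X.index))


def test_build_problems_counts_and_sizes():
    table = _table({"RA": 235, "OA": 229, "CTD": 141})
    problems = build_problems(table)
    assert len(problems) == 6  # 3 OvO + 3 OvR
    by_name = {p.name: p for p in problems}
    assert by_name["RA-vs-OA"].n == 464
    assert by_name["RA-vs-Rest"].n == 605
    assert by_name["RA-vs-CTD"].n == 376
    # every row appears in exactly k-1 = 2 OvO problems
    ovo_rows = sum(p.n for p in problems if p.spec.mode == "OvO")
    assert ovo_rows == 2 * 605


def test_build_problems_excludes_problem_constant_columns():
    table = _table({"RA": 30, "OA": 30, "CTD": 30}, p=4, seed=1)
    # column f0 observed only in OA patients: constant (zero) within RA u CTD
    X = table.X.copy()
    X.loc[table.labels != "OA", "f0"] = 0
    X.loc[table.labels == "OA", "f0"] = 1
    table = FeatureTable(X=X, labels=table.labels)
    by_name = {p.name: p for p in build_problems(table)}
    ra_ctd = by_name["RA-vs-CTD"]
    assert "f0" in ra_ctd.spec.excluded_features
    assert "f0" not in ra_ctd.X.columns
    assert "f0" in by_name["RA-vs-OA"].X.columns


def test_build_problems_rejects_tiny_class():
    table = _table({"RA": 10, "OA": 1})
    with pytest.raises(ValueError, match="OA"):
        build_problems(table)


def test_split_table_stratified_and_deterministic():
    table = _table({"RA": 235, "OA": 229}, seed=2)
    train, test = split_table(table, 0.9, seed=11)
    assert train.n_patients in (417, 418)
    assert train.n_patients + test.n_patients == 464
    for part in (train, test):
        assert set(part.labels.unique()) == {"RA", "OA"}
    train2, test2 = split_table(table, 0.9, seed=11)
    assert list(train.X.index) == list(train2.X.index)
    assert list(test.X.index) == list(test2.X.index)
    train3, _ = split_table(table, 0.9, seed=12)
    assert list(train.X.index) != list(train3.X.index)


def test_split_holdout_keeps_both_classes():
    table = _table({"RA": 20, "OA": 20}, seed=3)
    problem = build_problems(table)[0]
    train, test = split_holdout(problem, 0.5, seed=0)
    assert train.n == test.n == 20
    assert set(train.y) == set(test.y) == {0, 1}


def test_problem_from_spec_applies_training_exclusions():
    table = _table({"RA": 30, "OA": 30}, p=3, seed=4)
    problem = build_problems(table)[0]
    spec = problem.spec.__class__(
        mode="OvO", positive_class="RA", negative_classes=("OA",),
        excluded_features=("f1",),
    )
    applied = problem_from_spec(spec, table)
    assert "f1" not in applied.X.columns


@pytest.mark.parametrize("n_pos,n_neg", [(100, 60), (50, 50), (10, 1)])
def test_oversample_balances_and_preserves(n_pos, n_neg):
    from conftest import make_problem

    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, (n_pos + n_neg, 4))
    y = np.array([1] * n_pos + [0] * n_neg)
    problem = make_problem(X, y)
    balanced = oversample(problem, seed=9)
    _, counts = np.unique(balanced.y, return_counts=True)
    assert counts[0] == counts[1] == max(n_pos, n_neg)
    # all original rows retained, majority untouched
    assert (balanced.y[: n_pos + n_neg] == problem.y).all()
    np.testing.assert_array_equal(
        balanced.X.to_numpy()[: n_pos + n_neg], problem.X.to_numpy()
    )
    if n_neg == n_pos:
        assert balanced.n == problem.n
    # duplicates come from the minority support only
    extra = balanced.X.to_numpy()[n_pos + n_neg:]
    minority_rows = problem.X.to_numpy()[problem.y == int(n_pos < n_neg)]
    for row in extra:
        assert any((row == m).all() for m in minority_rows)


def test_reading_csv_roundtrip(tmp_path):
    readings = generate_cohort(
        SyntheticConfig(class_sizes={"A": 10, "B": 10}, noise_p=0.2, seed=6)
    )
    path = tmp_path / "cohort.csv"
    write_reading_csv(readings, path)
    back = read_reading_csv(path)
    pd.testing.assert_frame_equal(
        back.astype({"phase": int}), readings.astype({"phase": int})
    )
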