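"""Reading-table data model and preprocessing.

The raw unit of data is a *reading table*: one row per (patient, hand,
phase) holding the set of image-feature acronyms annotated on that phase
image.  Preprocessing turns it into the binary feature table the selection
pipeline works on:

1. :func:`fuse_hands` — union the two hands' annotations (the diagnosis is
   made per patient, not per hand),
2. :func:`encode` — expand to the 60 acronym-phase indicator columns,
3. :func:`filter_table` — drop featureless patients, then never-observed
   indicators,
4. :func:`split_table` — set aside a stratified holdout,
5. :func:`build_problems` — decompose the multiclass label into all
   One-vs-One and One-vs-Rest binary problems,
6. :func:`oversample` — balance classes by duplicating minority rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .universe import FEATURE_NAMES, HANDS, PHASES, validate_feature_name

__all__ = [
    "FeatureTable",
    "ProblemSpec",
    "ProblemData",
    "fuse_hands",
    "encode",
    "filter_table",
    "build_problems",
    "problem_from_spec",
    "split_table",
    "split_holdout",
    "oversample",
    "oversample_arrays",
    "read_reading_csv",
    "write_reading_csv",
]

READING_COLUMNS = ["patient_id", "diagnosis", "hand", "phase", "features"]


@dataclass
class FeatureTable:
    """Binary patient x indicator matrix with diagnosis labels.

    ``X`` is indexed by patient_id with one 0/1 column per feature-phase
    name; ``labels`` is the diagnosis Series on the same index.
    """

    X: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.labels.index):
            raise ValueError("X and labels must share the same patient index")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")

    @property
    def n_patients(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def to_tsv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "diagnosis", self.labels)
        out.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        return cls(X=df.drop(columns=["diagnosis"]), labels=df["diagnosis"])


@dataclass(frozen=True)
class ProblemSpec:
    """Recipe for one binary classification problem.

    ``mode`` is ``"OvO"`` (one diagnosis vs another, third dropped) or
    ``"OvR"`` (one diagnosis vs the union of the rest).
    ``excluded_features`` are indicator columns constant within the
    problem's training observations, e.g. features never present for
    either diagnosis of the pair.
    """

    mode: str
    positive_class: str
    negative_classes: tuple[str, ...]
    excluded_classes: tuple[str, ...] = ()
    excluded_features: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        if self.mode == "OvR":
            return f"{self.positive_class}-vs-Rest"
        return f"{self.positive_class}-vs-{self.negative_classes[0]}"


@dataclass
class ProblemData:
    """Feature matrix and binary target for one problem instance."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = positive class
    spec: ProblemSpec

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n(self) -> int:
        return len(self.y)


def _parse_features(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [a for a in str(cell).split(";") if a]


def fuse_hands(readings: pd.DataFrame) -> pd.DataFrame:
    """Union the per-hand annotations, dropping the hand column.

    Output has one row per (patient, phase); patients with empty readings
    are retained (they are removed later by :func:`filter_table`).
    """
    df = readings.copy()
    df["_set"] = df["features"].map(lambda c: set(_parse_features(c)))
    fused = (
        df.groupby(["patient_id", "diagnosis", "phase"], sort=False)["_set"]
        .agg(lambda sets: set().union(*sets))
        .reset_index()
    )
    fused["features"] = fused["_set"].map(lambda s: ";".join(sorted(s)))
    return fused[["patient_id", "diagnosis", "phase", "features"]]


def encode(fused: pd.DataFrame) -> FeatureTable:
    """Expand a hand-fused reading table into the 60 binary indicators.

    Cell (patient, acronym+phase) is 1 iff the acronym was annotated in
    that phase on either hand.  Unknown acronyms raise a ValueError naming
    the offender.
    """
    if "hand" in fused.columns:
        raise ValueError("encode expects a hand-fused table (no 'hand' column)")
    patient_ids = list(dict.fromkeys(fused["patient_id"]))
    labels = fused.drop_duplicates("patient_id").set_index("patient_id")["diagnosis"]
    matrix = pd.DataFrame(
        np.zeros((len(patient_ids), len(FEATURE_NAMES)), dtype=np.int8),
        index=pd.Index(patient_ids, name="patient_id"),
        columns=list(FEATURE_NAMES),
    )
    for row in fused.itertuples(index=False):
        phase = int(row.phase)
        if phase not in PHASES:
            raise ValueError(f"phase {phase} outside 1-3")
        for acronym in _parse_features(row.features):
            name = f"{acronym}{phase}"
            validate_feature_name(name)
            matrix.at[row.patient_id, name] = 1
    return FeatureTable(X=matrix, labels=labels.loc[patient_ids])


def filter_table(
    table: FeatureTable,
) -> tuple[FeatureTable, list[str], list[str]]:
    """Drop featureless patients, then never-observed indicator columns.

    Returns the filtered table plus the dropped column and patient id
    lists for logging.  Raises if nothing remains.
    """
    row_mask = table.X.to_numpy().any(axis=1)
    dropped_patients = list(table.X.index[~row_mask])
    X = table.X.loc[row_mask]
    labels = table.labels.loc[row_mask]
    col_mask = X.to_numpy().any(axis=0) if len(X) else np.zeros(X.shape[1], bool)
    dropped_features = list(X.columns[~col_mask])
    X = X.loc[:, col_mask]
    if X.empty:
        raise ValueError("feature table empty after filtering")
    return FeatureTable(X=X, labels=labels), dropped_features, dropped_patients


def _class_order(labels: pd.Series) -> list[str]:
    return list(dict.fromkeys(labels))


def _make_problem(
    table: FeatureTable,
    mode: str,
    positive: str,
    negatives: tuple[str, ...],
    excluded_classes: tuple[str, ...],
) -> ProblemData:
    included = table.labels.isin([positive, *negatives])
    X = table.X.loc[included]
    y = (table.labels.loc[included] == positive).to_numpy(dtype=int)
    # columns constant within this problem's observations carry no signal
    arr = X.to_numpy()
    constant = arr.min(axis=0) == arr.max(axis=0)
    excluded_features = tuple(X.columns[constant])
    spec = ProblemSpec(
        mode=mode,
        positive_class=positive,
        negative_classes=negatives,
        excluded_classes=excluded_classes,
        excluded_features=excluded_features,
    )
    return ProblemData(X=X.loc[:, ~constant], y=y, spec=spec)


def build_problems(table: FeatureTable) -> list[ProblemData]:
    """All k(k-1)/2 One-vs-One and k One-vs-Rest problems of a table.

    OvO drops the left-out class's rows; per problem, columns constant
    within the included rows are excluded and recorded on the spec.
    """
    classes = _class_order(table.labels)
    if len(classes) < 2:
        raise ValueError("need at least two diagnosis classes")
    counts = table.labels.value_counts()
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 observations: {small}")
    problems: list[ProblemData] = []
    for i, pos in enumerate(classes):
        for neg in classes[i + 1 :]:
            excluded = tuple(c for c in classes if c not in (pos, neg))
            problems.append(_make_problem(table, "OvO", pos, (neg,), excluded))
    for pos in classes:
        rest = tuple(c for c in classes if c != pos)
        problems.append(_make_problem(table, "OvR", pos, rest, ()))
    return problems


def problem_from_spec(spec: ProblemSpec, table: FeatureTable) -> ProblemData:
    """Instantiate a problem on another table (e.g. the holdout) using a
    spec derived from training data, so feature exclusions do not leak."""
    included = table.labels.isin([spec.positive_class, *spec.negative_classes])
    X = table.X.loc[included].drop(columns=list(spec.excluded_features), errors="ignore")
    y = (table.labels.loc[included] == spec.positive_class).to_numpy(dtype=int)
    return ProblemData(X=X, y=y, spec=spec)


def split_table(
    table: FeatureTable, train_fraction: float = 0.9, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/holdout split of the multiclass table.

    Performed once, before problem construction, so all binary problems
    share the same holdout patients.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    idx_train, idx_test = train_test_split(
        table.X.index,
        train_size=train_fraction,
        stratify=table.labels,
        random_state=seed,
    )
    train = FeatureTable(X=table.X.loc[idx_train], labels=table.labels.loc[idx_train])
    test = FeatureTable(X=table.X.loc[idx_test], labels=table.labels.loc[idx_test])
    for part, which in ((train, "train"), (test, "holdout")):
        missing = set(table.labels.unique()) - set(part.labels.unique())
        if missing:
            raise ValueError(f"classes {sorted(missing)} absent from {which} split")
    return train, test


def split_holdout(
    problem: ProblemData, train_fraction: float = 0.9, seed: int = 0
) -> tuple[ProblemData, ProblemData]:
    """Per-problem stratified split (alternative to the shared split)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    idx = np.arange(problem.n)
    tr, te = train_test_split(
        idx, train_size=train_fraction, stratify=problem.y, random_state=seed
    )
    out = []
    for part in (tr, te):
        y = problem.y[part]
        if len(np.unique(y)) < 2:
            raise ValueError("a class is absent from one side of the split")
        out.append(ProblemData(X=problem.X.iloc[part], y=y, spec=problem.spec))
    return out[0], out[1]


def oversample_arrays(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random minority oversampling on plain arrays (used inside CV folds).

    Minority rows are duplicated uniformly at random with replacement until
    both classes are equally frequent; all original rows are retained and
    the majority class is untouched.
    """
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2 or counts[0] == counts[1]:
        return X, y
    minority = values[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    order = np.concatenate([np.arange(len(y)), extra])
    return X[order], y[order]


def oversample(train: ProblemData, seed: int = 0) -> ProblemData:
    """Random minority oversampling of a training problem."""
    rng = np.random.default_rng(seed)
    Xb, yb = oversample_arrays(train.X.to_numpy(), train.y, rng)
    X = pd.DataFrame(Xb, columns=train.X.columns)
    return ProblemData(X=X, y=yb, spec=train.spec)


def write_reading_csv(readings: pd.DataFrame, path) -> None:
    readings.to_csv(path, index=False, columns=READING_COLUMNS)


def read_reading_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(READING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reading CSV missing columns: {sorted(missing)}")
    df["features"] = df["features"].fillna("").astype(str)
    bad_hands = set(df["hand"]) - set(HANDS)
    if bad_hands:
        raise ValueError(f"unknown hand labels: {sorted(bad_hands)}")
    return df[READING_COLUMNS]
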