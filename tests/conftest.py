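import numpy as np
import pandas as pd
import pytest

from foisel.cohort import ProblemData, ProblemSpec, encode, filter_table, fuse_hands
from foisel.synthetic import (
    PlantedEffect,
    SyntheticConfig,
    generate_cohort,
    study_like_config,
)
from foisel.universe import FEATURE_NAMES


def make_problem(X: np.ndarray, y, columns=None) -> ProblemData:
    """Wrap plain arrays as a binary ProblemData for unit tests."""
    X = np.asarray(X)
    columns = columns or [f"f{i}" for i in range(X.shape[1])]
    spec = ProblemSpec(mode="OvO", positive_class="A", negative_classes=("B",))
    return ProblemData(X=pd.DataFrame(X, columns=columns), y=np.asarray(y), spec=spec)


def recovery_config(seed: int, n_per_class: int = 200, n_noise: int = 20,
                    p_pos: float = 0.8, p_neg: float = 0.2) -> SyntheticConfig:
    """Binary cohort with 3 planted univariate effects among noise features.

    Planted prevalences give an analytic single-feature AUC of
    p_pos(1-p_neg) + (p_pos p_neg + (1-p_pos)(1-p_neg))/2 = 0.8 at the
    defaults.
    """
    planted = ["P1", "M1", "C1"]
    noise = [f for f in FEATURE_NAMES if f not in planted][:n_noise]
    zero = tuple(f for f in FEATURE_NAMES if f not in planted + noise)
    return SyntheticConfig(
        class_sizes={"A": n_per_class, "B": n_per_class},
        effects=tuple(PlantedEffect(f, {"A": p_pos, "B": p_neg}) for f in planted),
        zero_features=zero,
        noise_p=0.3,
        seed=seed,
    )


def cohort_to_problem(config: SyntheticConfig) -> ProblemData:
    """Generate, preprocess, and return the single OvO problem of a
    two-class synthetic cohort."""
    from foisel.cohort import build_problems

    table, _, _ = filter_table(encode(fuse_hands(generate_cohort(config))))
    return next(p for p in build_problems(table) if p.spec.mode == "OvO")


@pytest.fixture(scope="session")
def study_like_readings() -> pd.DataFrame:
    return generate_cohort(study_like_config(seed=0))


@pytest.fixture(scope="session")
def study_like_encoded(study_like_readings):
    return encode(fuse_hands(study_like_readings))


@pytest.fixture(scope="session")
def study_like_filtered(study_like_encoded):
    return filter_table(study_like_encoded)
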