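"""Synthetic FOI reading cohorts with planted statistical structure.

Real FOI reading data are per-patient, per-hand, per-phase sets of binary
image-feature annotations together with a diagnosis label.  No such data set
is publicly deposited, so this module generates cohorts that reproduce the
*statistical shape* the downstream pipeline assumes:

* 20 feature acronyms x 3 phases = 60 binary indicators,
* three diagnosis classes with configurable sizes,
* indicators that are never observed (all-zero columns),
* a small number of patients with no annotations at all,
* moderate correlation between phase copies of the same feature,
* planted univariate class effects with known prevalence per class, and
* planted 2-/3-way XOR-parity interactions that are univariately invisible
  but jointly informative.

Because every planted effect has a known generating law, parameter-recovery
tests can compare what the selection pipeline finds against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .universe import (
    ACRONYMS,
    COHORT_SIZES,
    FEATURE_NAMES,
    NEVER_OBSERVED,
    PHASES,
    validate_feature_name,
)

__all__ = [
    "PlantedEffect",
    "PlantedInteraction",
    "SyntheticConfig",
    "generate_cohort",
    "expected_univariate_auc",
    "study_like_config",
    "config_from_yaml",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A univariate class effect: one indicator with class-specific prevalence.

    ``p_given_class`` maps each diagnosis label to the Bernoulli probability
    of the indicator being annotated for patients of that class.
    """

    feature_id: str
    p_given_class: dict[str, float]

    def validate(self) -> None:
        validate_feature_name(self.feature_id)
        for cls, p in self.p_given_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"effect {self.feature_id}: p({cls}) = {p} outside [0, 1]"
                )


@dataclass(frozen=True)
class PlantedInteraction:
    """An XOR-parity interaction between 2 or 3 indicators.

    Each involved indicator has marginal probability exactly 0.5 in every
    class (so its univariate association with the diagnosis is zero in
    expectation), while the XOR parity of the group equals 1 with a
    class-specific probability.  This is the canonical structure that
    relief-family algorithms detect and univariate filters cannot.
    """

    feature_ids: tuple[str, ...]
    parity_p_given_class: dict[str, float]

    def validate(self) -> None:
        if len(self.feature_ids) not in (2, 3):
            raise ValueError("interactions must involve 2 or 3 features")
        for fid in self.feature_ids:
            validate_feature_name(fid)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("interaction features must be distinct")
        for cls, p in self.parity_p_given_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"interaction: parity p({cls}) = {p} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort.

    The seed fully determines the output; regenerating with the same config
    is bit-identical.

    Parameters
    ----------
    class_sizes
        Patients per diagnosis label.
    effects, interactions
        Planted structure (see :class:`PlantedEffect`,
        :class:`PlantedInteraction`).
    phase_correlation
        Target phi between consecutive phase copies of each acronym listed
        in ``correlated_acronyms``.  Induced by copy-with-noise: the later
        phase copies the earlier one with probability ``phase_correlation``
        and otherwise redraws from its own law, which preserves marginals
        and hits the target phi exactly whenever consecutive phases share
        the same generating probability (phases with differing laws are
        drawn independently).
    zero_features
        Indicators forced all-zero, emulating never-observed features.
    featureless_rate
        Fraction of patients with no annotations on either hand; realised
        as a seeded quota of ``round(rate * n)`` patients so cohort shape
        is deterministic.  All other patients are guaranteed at least one
        annotation.
    noise_p
        Background annotation probability for every unplanted indicator.
    """

    class_sizes: dict[str, int]
    effects: tuple[PlantedEffect, ...] = ()
    interactions: tuple[PlantedInteraction, ...] = ()
    phase_correlation: float = 0.0
    correlated_acronyms: tuple[str, ...] = ()
    zero_features: tuple[str, ...] = ()
    featureless_rate: float = 0.0
    noise_p: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for cls, n in self.class_sizes.items():
            if n < 0:
                raise ValueError(f"class size for {cls} is negative")
        if not 0.0 <= self.phase_correlation < 1.0:
            raise ValueError("phase_correlation must be in [0, 1)")
        if not 0.0 <= self.noise_p <= 1.0:
            raise ValueError("noise_p must be in [0, 1]")
        if not 0.0 <= self.featureless_rate <= 1.0:
            raise ValueError("featureless_rate must be in [0, 1]")
        for fid in self.zero_features:
            validate_feature_name(fid)
        for eff in self.effects:
            eff.validate()
        for inter in self.interactions:
            inter.validate()
        for a in self.correlated_acronyms:
            if a not in ACRONYMS:
                raise ValueError(f"unknown feature acronym: {a!r}")
        planted = {e.feature_id for e in self.effects}
        interacting = {f for i in self.interactions for f in i.feature_ids}
        if planted & interacting:
            raise ValueError(
                "features cannot carry both a univariate effect and an "
                f"interaction: {sorted(planted & interacting)}"
            )
        clash = set(self.zero_features) & (planted | interacting)
        if clash:
            raise ValueError(
                f"zero_features overlap planted features: {sorted(clash)}"
            )


def expected_univariate_auc(effect: PlantedEffect, pos: str, neg: str) -> float:
    """Analytic single-feature AUC of a planted effect for a class pair.

    For independent Bernoulli draws X_pos ~ Bern(p), X_neg ~ Bern(q) the
    rank-based AUC is P(X_pos > X_neg) + 0.5 P(X_pos = X_neg)
    = p(1-q) + 0.5 (pq + (1-p)(1-q)).
    """
    for cls in (pos, neg):
        if cls not in effect.p_given_class:
            raise KeyError(f"class {cls!r} not in effect {effect.feature_id}")
    p = effect.p_given_class[pos]
    q = effect.p_given_class[neg]
    return p * (1.0 - q) + 0.5 * (p * q + (1.0 - p) * (1.0 - q))


def _class_probabilities(config: SyntheticConfig, cls: str) -> np.ndarray:
    """Per-indicator Bernoulli probability vector for one class."""
    p = np.full(len(FEATURE_NAMES), config.noise_p)
    idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
    for fid in config.zero_features:
        p[idx[fid]] = 0.0
    for eff in config.effects:
        p[idx[eff.feature_id]] = eff.p_given_class.get(cls, config.noise_p)
    # interaction features are drawn by the parity mechanism below
    for inter in config.interactions:
        for fid in inter.feature_ids:
            p[idx[fid]] = 0.5
    return p


def _draw_row(
    rng: np.random.Generator, config: SyntheticConfig, cls: str, p: np.ndarray
) -> np.ndarray:
    """One patient's fused 60-indicator vector."""
    idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
    x = np.zeros(len(FEATURE_NAMES), dtype=np.int8)
    correlated = set(config.correlated_acronyms)
    rho = config.phase_correlation
    for a in ACRONYMS:
        prev_i = None
        for ph in PHASES:
            i = idx[f"{a}{ph}"]
            chain = (
                a in correlated
                and prev_i is not None
                and p[i] == p[prev_i]
                and rho > 0.0
            )
            if chain and rng.random() < rho:
                x[i] = x[prev_i]
            else:
                x[i] = rng.random() < p[i]
            prev_i = i
    for inter in config.interactions:
        parity = int(rng.random() < inter.parity_p_given_class.get(cls, 0.5))
        ids = [idx[f] for f in inter.feature_ids]
        vals = [int(rng.random() < 0.5) for _ in ids[:-1]]
        last = parity
        for v in vals:
            last ^= v
        for i, v in zip(ids, vals + [last]):
            x[i] = v
    return x


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a per-hand, per-phase reading table.

    Returns a tidy DataFrame with columns ``patient_id, diagnosis, hand,
    phase, features`` (one row per patient x hand x phase; ``features`` is a
    semicolon-joined acronym list, possibly empty).  Each annotated
    indicator is placed on the left hand, the right hand, or both with
    equal probability, so downstream hand fusion is a non-trivial union.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    patients: list[tuple[str, str]] = []
    for cls in sorted(config.class_sizes):
        for k in range(config.class_sizes[cls]):
            patients.append((f"{cls}-{k + 1:04d}", cls))
    n = len(patients)

    probs = {cls: _class_probabilities(config, cls) for cls in config.class_sizes}
    can_be_nonzero = {cls: bool((probs[cls] > 0).any()) or bool(config.interactions)
                      for cls in config.class_sizes}

    n_featureless = int(round(config.featureless_rate * n))
    featureless = set(rng.choice(n, size=n_featureless, replace=False)) if n_featureless else set()

    matrix = np.zeros((n, len(FEATURE_NAMES)), dtype=np.int8)
    for row, (pid, cls) in enumerate(patients):
        if row in featureless:
            continue
        x = _draw_row(rng, config, cls, probs[cls])
        tries = 0
        while not x.any() and can_be_nonzero[cls] and tries < 1000:
            x = _draw_row(rng, config, cls, probs[cls])
            tries += 1
        matrix[row] = x

    # distribute each annotation over hands: 0 = left, 1 = right, 2 = both
    records = []
    for row, (pid, cls) in enumerate(patients):
        sets: dict[tuple[str, int], list[str]] = {
            (hand, ph): [] for hand in ("left", "right") for ph in PHASES
        }
        for j, name in enumerate(FEATURE_NAMES):
            if matrix[row, j]:
                acronym, ph = name[:-1], int(name[-1])
                side = rng.integers(0, 3)
                if side in (0, 2):
                    sets[("left", ph)].append(acronym)
                if side in (1, 2):
                    sets[("right", ph)].append(acronym)
        for hand in ("left", "right"):
            for ph in PHASES:
                records.append(
                    {
                        "patient_id": pid,
                        "diagnosis": cls,
                        "hand": hand,
                        "phase": ph,
                        "features": ";".join(sets[(hand, ph)]),
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["patient_id", "diagnosis", "hand", "phase", "features"]
    )


def study_like_config(seed: int = 0) -> SyntheticConfig:
    """Default cohort mirroring the study's shape.

    Cohort sizes 237/231/141 (RA/OA/CTD), the 15 never-observed indicators,
    4/609 featureless patients, background prevalence 0.1, inter-phase
    correlation 0.7 for acronyms D and P, a handful of moderate univariate
    effects on indicators the study found informative (Y1, P2/P3, M3, C3),
    and one 2-way interaction (I1 x V2) that only a multivariate filter can
    see.  Effect strengths are conventions chosen to give single-feature
    AUCs around 0.6-0.7; the study reports no per-class prevalences.
    """
    effects = (
        PlantedEffect("Y1", {"RA": 0.55, "OA": 0.25, "CTD": 0.30}),
        PlantedEffect("P2", {"RA": 0.50, "OA": 0.20, "CTD": 0.55}),
        PlantedEffect("P3", {"RA": 0.50, "OA": 0.20, "CTD": 0.55}),
        PlantedEffect("M3", {"RA": 0.45, "OA": 0.20, "CTD": 0.25}),
        PlantedEffect("C3", {"RA": 0.25, "OA": 0.15, "CTD": 0.45}),
    )
    interactions = (
        PlantedInteraction(("I1", "V2"), {"RA": 0.5, "OA": 0.5, "CTD": 0.7}),
    )
    return SyntheticConfig(
        class_sizes=dict(COHORT_SIZES),
        effects=effects,
        interactions=interactions,
        phase_correlation=0.7,
        correlated_acronyms=("D", "P"),
        zero_features=NEVER_OBSERVED,
        featureless_rate=4 / 609,
        noise_p=0.1,
        seed=seed,
    )


def config_from_yaml(path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("study_like"):
        base = study_like_config(seed=int(raw.get("seed", 0)))
        known = {"study_like", "seed"}
        overrides = {k: v for k, v in raw.items() if k not in known}
        return replace(base, **_coerce(overrides)) if overrides else base
    return SyntheticConfig(**_coerce(raw))


def _coerce(raw: dict) -> dict:
    out = dict(raw)
    if "effects" in out:
        out["effects"] = tuple(
            PlantedEffect(e["feature_id"], dict(e["p_given_class"]))
            for e in out["effects"]
        )
    if "interactions" in out:
        out["interactions"] = tuple(
            PlantedInteraction(tuple(i["feature_ids"]), dict(i["parity_p_given_class"]))
            for i in out["interactions"]
        )
    for key in ("zero_features", "correlated_acronyms"):
        if key in out:
            out[key] = tuple(out[key])
    return out
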