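"""End-to-end workflow: fuse -> encode -> filter -> split -> collinearity
-> candidate lists -> forward selection -> transition point, per problem.

All artifacts are written under a run directory with a JSON manifest; a
rerun with the same configuration and seed is bit-identical (no
timestamps are recorded).  Every source of randomness draws its seed from
one root seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assoc import collinearity
from .cohort import (
    FeatureTable,
    ProblemData,
    build_problems,
    encode,
    filter_table,
    fuse_hands,
    problem_from_spec,
    read_reading_csv,
    split_holdout,
    split_table,
    write_reading_csv,
)
from .gbm import CVConfig, cv_evaluate, default_grid
from .selection import (
    METRIC_ORDER,
    CandidateLists,
    SelectionTrace,
    build_candidate_lists,
    forward_select,
)
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "render_reports", "substream_seed"]

_SUBSTREAMS = ("synthesis", "split", "tuning", "step1", "step2", "final")


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named child seed of a root seed (below 2**31)."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {_SUBSTREAMS}")
    ss = np.random.SeedSequence([root_seed, _SUBSTREAMS.index(name)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Pipeline configuration.

    Defaults reproduce the study protocol: 90/10 stratified holdout shared
    across problems, 3-fold x 10-repeat CV (30 models) in step 1, 5-fold x
    20-repeat CV (100 models) in step 2, grid-search tuning, transition
    tolerance 0.01, at most four candidates per selection step.  When a
    synthetic cohort is requested its generator seed is derived from
    ``seed`` (overriding the SyntheticConfig's own seed) so one root seed
    governs the entire run.
    """

    out_dir: str
    synthetic: SyntheticConfig | None = None
    input_csv: str | None = None
    train_fraction: float = 0.9
    step1_folds: int = 3
    step1_repeats: int = 10
    step2_folds: int = 5
    step2_repeats: int = 20
    grid: list = field(default_factory=default_grid)
    tolerance: float = 0.01
    seed: int = 0
    problems: tuple[str, ...] | None = None
    shared_split: bool = True
    retune_each_step: bool = False
    permutations: int = 10
    phi_report_threshold: float = 0.5

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_csv is None):
            raise ValueError("provide exactly one of synthetic / input_csv")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # location, not content
        blob = json.dumps(_jsonable(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _lists_to_dict(lists: CandidateLists) -> dict:
    return {
        "hyperparameters": lists.hyperparameters,
        "step1_cv_mean_auc": lists.cv_result.mean_auc if lists.cv_result else None,
        "step1_cv_sd_auc": lists.cv_result.sd_auc if lists.cv_result else None,
        "rankings": {
            m: {
                "criterion": lists[m].criterion,
                "entries": [[f, s] for f, s in lists[m].entries],
            }
            for m in METRIC_ORDER
        },
    }


def lists_from_dict(d: dict) -> CandidateLists:
    """Rebuild CandidateLists from the candidates.json payload."""
    from .selection import MetricRanking

    rankings = {
        m: MetricRanking(
            metric=m,
            entries=[(f, float(s)) for f, s in d["rankings"][m]["entries"]],
            criterion=d["rankings"][m]["criterion"],
        )
        for m in METRIC_ORDER
    }
    return CandidateLists(rankings=rankings, hyperparameters=d.get("hyperparameters", {}))


def _trace_to_dict(trace: SelectionTrace) -> dict:
    return {
        "tolerance": trace.tolerance,
        "transition_index": trace.transition_index,
        "transition_features": trace.transition_features,
        "selected_features": trace.selected_features,
        "steps": [
            {
                "step": s.step_index,
                "winner": s.winner,
                "mean_cv_auc": s.cv_result.mean_auc,
                "sd_cv_auc": s.cv_result.sd_auc,
                "holdout_auc": s.holdout_auc,
                "candidates": {
                    f: r.mean_auc for f, r in s.candidates_evaluated
                },
            }
            for s in trace.steps
        ],
    }


def _split_aucs_to_tsv(trace: SelectionTrace, path: Path) -> None:
    """Per-step, per-CV-split AUCs of the winning candidate (box-plot data)."""
    lines = ["step\twinner\tsplit\tauc"]
    for s in trace.steps:
        for k, a in enumerate(s.cv_result.auc_per_split, start=1):
            lines.append(f"{s.step_index}\t{s.winner}\t{k}\t{a:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _trace_to_tsv(trace: SelectionTrace, path: Path) -> None:
    lines = ["step\twinner\tmean_cv_auc\tsd_cv_auc\tholdout_auc\tphase"]
    for s in trace.steps:
        phase = "pre" if s.step_index <= trace.transition_index else "post"
        lines.append(
            f"{s.step_index}\t{s.winner}\t{s.cv_result.mean_auc:.6f}"
            f"\t{s.cv_result.sd_auc:.6f}\t{s.holdout_auc:.6f}\t{phase}"
        )
    path.write_text("\n".join(lines) + "\n")


def preprocess(config: RunConfig, out: Path) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Stages up to and including the holdout split; writes the cohort CSV,
    the filtered feature table, the drop report, and the collinearity
    screen.  Returns (filtered table, train, holdout)."""
    out.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        synth = dataclasses.replace(
            config.synthetic, seed=substream_seed(config.seed, "synthesis")
        )
        readings = generate_cohort(synth)
        write_reading_csv(readings, out / "cohort.csv")
    else:
        readings = read_reading_csv(config.input_csv)
    fused = fuse_hands(readings)
    table = encode(fused)
    filtered, dropped_features, dropped_patients = filter_table(table)
    _write_json(
        out / "drops.json",
        {
            "dropped_features": dropped_features,
            "dropped_patients": dropped_patients,
            "n_patients_before": table.n_patients,
            "n_patients_after": filtered.n_patients,
        },
    )
    filtered.to_tsv(out / "feature_table.tsv")

    report = collinearity(filtered)
    report.phi_matrix.to_csv(out / "phi_matrix.tsv", sep="\t")
    report.p_value_matrix.to_csv(out / "phi_pvalues.tsv", sep="\t")
    vif = report.vif
    _write_json(
        out / "collinearity.json",
        {
            "max_vif": None if not np.isfinite(vif).any() else float(vif[np.isfinite(vif)].max()),
            "max_vif_feature": str(vif[np.isfinite(vif)].idxmax()) if np.isfinite(vif).any() else None,
            "vif": {k: (None if not np.isfinite(v) else float(v)) for k, v in vif.items()},
            "infinite_vif": report.flagged,
            "high_phi_pairs": [
                [a, b, r] for a, b, r in report.high_pairs(config.phi_report_threshold)
            ],
        },
    )

    train, holdout = split_table(
        filtered, config.train_fraction, seed=substream_seed(config.seed, "split")
    )
    train.to_tsv(out / "train_table.tsv")
    holdout.to_tsv(out / "holdout_table.tsv")
    return filtered, train, holdout


def _problem_pairs(
    config: RunConfig, filtered: FeatureTable, train: FeatureTable, holdout: FeatureTable
) -> list[tuple[ProblemData, ProblemData]]:
    if config.shared_split:
        pairs = [
            (p, problem_from_spec(p.spec, holdout)) for p in build_problems(train)
        ]
    else:
        pairs = [
            split_holdout(p, config.train_fraction, seed=substream_seed(config.seed, "split"))
            for p in build_problems(filtered)
        ]
    if config.problems is not None:
        wanted = set(config.problems)
        pairs = [pp for pp in pairs if pp[0].name in wanted]
        if not pairs:
            raise ValueError(f"no problems match filter {sorted(wanted)}")
    return pairs


def run_problem(
    config: RunConfig, train_problem: ProblemData, holdout_problem: ProblemData, pdir: Path
) -> SelectionTrace:
    """Step 1 + step 2 for one binary problem; writes its artifacts."""
    pdir.mkdir(parents=True, exist_ok=True)
    step1_cv = CVConfig(
        folds=config.step1_folds,
        repeats=config.step1_repeats,
        seed=substream_seed(config.seed, "step1"),
    )
    step2_cv = CVConfig(
        folds=config.step2_folds,
        repeats=config.step2_repeats,
        seed=substream_seed(config.seed, "step2"),
    )
    tuned = cv_evaluate(
        train_problem, train_problem.X.columns, cv=step1_cv, grid=config.grid
    )
    lists = build_candidate_lists(
        train_problem,
        cv=step1_cv,
        params=tuned.best_hyperparameters,
        permutations=config.permutations,
    )
    _write_json(pdir / "candidates.json", _lists_to_dict(lists))
    trace = forward_select(
        train_problem,
        lists,
        cv=step2_cv,
        params=tuned.best_hyperparameters,
        grid=config.grid if config.retune_each_step else None,
        holdout=holdout_problem,
        tolerance=config.tolerance,
        retune_each_step=config.retune_each_step,
        final_seed=substream_seed(config.seed, "final"),
    )
    _write_json(pdir / "trace.json", _trace_to_dict(trace))
    _trace_to_tsv(trace, pdir / "trace.tsv")
    _split_aucs_to_tsv(trace, pdir / "step_auc_splits.tsv")
    return trace


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest (also written)."""
    out = Path(config.out_dir)
    filtered, train, holdout = preprocess(config, out)
    pairs = _problem_pairs(config, filtered, train, holdout)
    problem_names = []
    for train_problem, holdout_problem in pairs:
        name = train_problem.name
        problem_names.append(name)
        run_problem(config, train_problem, holdout_problem, out / "problems" / name)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": _jsonable(
            {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
        ),
        "problems": problem_names,
        "n_patients": filtered.n_patients,
        "n_features": len(filtered.feature_names),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def render_reports(run_dir) -> str:
    """Human-readable summary of a completed run.

    Writes ``importance_lists.tsv`` (one row per problem: the winners up
    to the transition point, in selection order) and ``summary.md``;
    returns the summary text.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# Feature-selection run summary",
        "",
        f"patients: {manifest['n_patients']}, features: {manifest['n_features']},"
        f" seed: {manifest['seed']}",
        "",
    ]
    coll_path = run_dir / "collinearity.json"
    if coll_path.exists():
        coll = json.loads(coll_path.read_text())
        lines += [
            f"max VIF: {coll['max_vif']:.2f} ({coll['max_vif_feature']})"
            if coll["max_vif"] is not None
            else "max VIF: n/a",
            f"|phi| pairs above threshold: {len(coll['high_phi_pairs'])}",
            "",
        ]
    table_rows = ["problem\ttransition_features\tfeature_importance_list"]
    for name in manifest["problems"]:
        trace_path = run_dir / "problems" / name / "trace.json"
        if not trace_path.exists():
            raise FileNotFoundError(trace_path)
        trace = json.loads(trace_path.read_text())
        feats = trace["transition_features"]
        if feats:
            best = trace["steps"][trace["transition_index"] - 1]
            lines.append(
                f"- **{name}**: {len(feats)} features to peak "
                f"(mean CV AUC {best['mean_cv_auc']:.3f}, holdout "
                f"{_fmt(best['holdout_auc'])}): {' '.join(feats)}"
            )
        else:
            lines.append(f"- **{name}**: no candidates")
        table_rows.append(f"{name}\t{len(feats)}\t{' '.join(feats)}")
    summary = "\n".join(lines) + "\n"
    (run_dir / "summary.md").write_text(summary)
    (run_dir / "importance_lists.tsv").write_text("\n".join(table_rows) + "\n")
    return summary


def _fmt(x) -> str:
    return "n/a" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.3f}"
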