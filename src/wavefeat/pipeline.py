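"""End-to-end orchestration of the waveform feature-selection pipeline.

``run_pipeline`` executes, for one reference limb: data loading or
synthesis -> per-variable weighted-correlation PCA -> parallel analysis ->
Welch-t screening -> repeated sequential naive-Bayes selection -> final
inference and associated features -> interpretation (quartile curves,
influence windows, modes of variation) -> descriptive pointwise
comparison.  All stochastic stages are driven by a single top-level seed,
and the machine-readable results bundle is byte-reproducible given the
same configuration: tables, figures and reports are derived views of that
bundle and never recompute statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import inference, interpret
from .datasets import (
    ConfigError,
    GROUPS,
    N_SAMPLES,
    VARIABLES,
    WaveformDataset,
    read_dataset,
)
from .pca import ScoreTable, VariablePCModel, build_score_table, fit_variable_pca
from .selection import (
    FeatureId,
    SelectionResult,
    parallel_analysis,
    parallel_reference,
    screen_features,
    sequential_selection,
)
from .synthetic import CohortConfig, generate_cohort, planted_feature_check

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their standard defaults.

    Defaults: 101 samples per waveform, screening threshold |t| >= 2.0,
    10-fold CV, 1000 selection iterations, at most 10 main features, final
    inference at alpha = 0.001, association bands 0.5/0.7 at alpha = 0.05,
    Bonferroni-corrected pointwise alpha = 0.05/16 = 0.003125.
    """

    cohort: CohortConfig | None = None
    data_path: str | None = None
    data_config: Mapping | str | None = None
    reference_limb: str = "pivot"
    weighting: str = "equal_participant"
    parallel_reps: int = 100
    screening_threshold: float = 2.0
    max_features: int = 10
    n_iterations: int = 1000
    n_folds: int = 10
    alpha: float = 0.001
    association_moderate: float = 0.5
    association_strong: float = 0.7
    association_alpha: float = 0.05
    pointwise_alpha: float = 0.003125
    influence_fraction: float = 0.5
    quartile_mode: str = "representative_trial"
    inference_unit: str = "trial"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.screening_threshold <= 0 or self.influence_fraction <= 0:
            raise ConfigError("thresholds must be positive")
        if self.cohort is not None and not isinstance(self.cohort, CohortConfig):
            self.cohort = CohortConfig.from_dict(self.cohort)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text) or {}
        else:
            payload = json.loads(text)
        return cls.from_dict(payload)


@dataclass
class PipelineResult:
    """Rich in-memory pipeline outcome plus the serializable bundle."""

    dataset: WaveformDataset
    models: dict[str, VariablePCModel]
    score_table: ScoreTable
    selection: SelectionResult
    final_table: "object"
    associations: "object"
    results: dict

    def to_json(self) -> str:
        return json.dumps(self.results, sort_keys=True, indent=2)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage_counts(models, retained, screened, main_features):
    rows = []
    for v in VARIABLES:
        scr_v = screened[(screened["variable"] == v) & screened["retained"]]
        rows.append({
            "variable": v,
            "candidate_pcs": models[v].n_pcs if v in models else 0,
            "retained_parallel": len(retained.get(v, [])),
            "retained_screening": int(len(scr_v)),
            "main_features": sum(f.variable == v for f in main_features),
        })
    rows.append({
        "variable": "total",
        "candidate_pcs": sum(r["candidate_pcs"] for r in rows),
        "retained_parallel": sum(r["retained_parallel"] for r in rows),
        "retained_screening": sum(r["retained_screening"] for r in rows),
        "main_features": sum(r["main_features"] for r in rows),
    })
    return rows


def run_pipeline(
    config: PipelineConfig,
    dataset: WaveformDataset | None = None,
    truth=None,
) -> PipelineResult:
    """Execute the full pipeline and return the results bundle.

    If no ``dataset`` is passed, either ``config.data_path`` is read or a
    synthetic cohort is generated from ``config.cohort``.  When a truth
    table of planted effects is available (passed in or generated), the
    bundle includes a planted-effect recovery report.
    """
    if dataset is None:
        if config.data_path is not None:
            dataset = read_dataset(config.data_path, config.data_config)
        elif config.cohort is not None:
            dataset, truth = generate_cohort(config.cohort)
        else:
            raise ConfigError("config needs a data_path or a cohort")
    logger.info("pipeline start: %d trials, reference limb %s",
                dataset.n_trials, config.reference_limb)

    ss = np.random.SeedSequence(config.seed)
    rng_parallel, rng_selection, rng_perm = (
        np.random.default_rng(child) for child in ss.spawn(3))

    digest = dataset.weights_digest()
    models = {
        v: fit_variable_pca(dataset.variable_matrix(v), dataset.weights,
                            variable=v, weights_digest=digest)
        for v in VARIABLES
    }

    reference = parallel_reference(
        dataset.n_trials, dataset.weights, n_reps=config.parallel_reps,
        seed=rng_parallel)
    retained = {
        v: parallel_analysis(models[v].eigenvalues, dataset.n_trials,
                             dataset.weights, reference=reference)
        for v in VARIABLES
    }
    logger.info("parallel analysis retained %d PCs",
                sum(len(v) for v in retained.values()))

    score_table = build_score_table(dataset, models, retained)
    post_parallel = [FeatureId(*k) for k in score_table.feature_keys()]
    screened = screen_features(score_table, config.screening_threshold)
    n_screened = int(screened["retained"].sum())
    logger.info("screening retained %d features at |t| >= %g",
                n_screened, config.screening_threshold)

    if n_screened == 0:
        logger.warning("no feature passed screening; main set is empty")
        selection = SelectionResult(
            retained_after_parallel=post_parallel,
            screened=screened[screened["retained"]].reset_index(drop=True),
            selection_frequency={}, main_features=[],
            seed=config.seed, n_iterations=config.n_iterations)
    else:
        selection = sequential_selection(
            score_table, screened,
            retained_after_parallel=post_parallel,
            max_features=config.max_features,
            n_iterations=config.n_iterations,
            n_folds=config.n_folds,
            seed=rng_selection)
        selection.seed = config.seed
    logger.info("main features: %s",
                ", ".join(f.label for f in selection.main_features) or "(none)")

    final_table = inference.final_feature_table(
        score_table, selection.main_features, alpha=config.alpha,
        unit=config.inference_unit)
    associations = inference.associated_features(
        selection.main_features, post_parallel, score_table,
        alpha=config.association_alpha)

    boundaries = (config.cohort.phase_boundaries if config.cohort is not None
                  else interpret.DEFAULT_PHASE_BOUNDARIES)
    w = score_table.weights
    interpretation_rows = []
    feature_curves = {}
    for fid in selection.main_features:
        model = models[fid.variable]
        qw = interpret.quartile_waveforms(
            model, score_table, fid, dataset=dataset,
            mode=config.quartile_mode)
        scores = score_table.feature(fid)
        is_sym = score_table.groups == GROUPS[0]
        group_means = {
            GROUPS[0]: float((w[is_sym] * scores[is_sym]).sum() / w[is_sym].sum()),
            GROUPS[1]: float((w[~is_sym] * scores[~is_sym]).sum() / w[~is_sym].sum()),
        }
        quartile_map = interpret.assign_group_quartile(group_means)
        windows = interpret.influence_windows(
            model, fid.pc, fraction=config.influence_fraction,
            phase_boundaries=boundaries)
        fit_win = max(windows, default=None,
                      key=lambda win: (win.end - win.start, -win.start))
        if fit_win is not None and fit_win.end - fit_win.start >= 5:
            mode_window = (fit_win.start, fit_win.end)
        else:
            mode_window = (0, N_SAMPLES - 1)
        mode_label = interpret.fit_variation_mode(
            qw.upper, qw.lower, mode_window, feature=fid)
        interpretation_rows.append({
            "feature": fid.label,
            "explained_variance_pct":
                float(100 * models[fid.variable].explained_fraction[fid.pc - 1]),
            "q_upper": qw.q_upper, "q_lower": qw.q_lower,
            "group_quartile": quartile_map,
            "group_mean_scores": group_means,
            "influence_windows": [[win.start, win.end] for win in windows],
            "influence_phases": sorted(
                {p for win in windows for p in win.phases}),
            "mode_A": mode_label.A, "mode_B": mode_label.B,
            "mode_C": mode_label.C, "dominant_mode": mode_label.dominant_mode,
            "mode_residual": mode_label.residual,
            "mode_window": list(mode_label.window),
        })
        feature_curves[fid.label] = {
            "upper": qw.upper, "lower": qw.lower, "mu": model.mu,
            "coefficient": model.coefficient(fid.pc),
            "r2": model.squared_correlation(fid.pc),
        }

    pointwise = inference.pointwise_group_comparison(
        dataset, alpha=config.pointwise_alpha)
    pointwise_summary = {
        v: {
            "n_significant_samples": int(pc.mask.sum()),
            "max_abs_t": float(np.nanmax(np.abs(pc.t))),
        } for v, pc in pointwise.items()
    }

    planted = None
    if truth is not None:
        planted = planted_feature_check(
            selection, truth, models, influence_fraction=config.influence_fraction)

    screened_t = {FeatureId(v, int(p)): float(t) for v, p, t in zip(
        screened["variable"], screened["pc"], screened["t"])}
    selection_rows = [{
        "feature": f.label,
        "screening_t": screened_t.get(f),
        "selection_frequency": selection.selection_frequency.get(f, 0),
        "main_feature": f in selection.main_features,
    } for f in selection.screened_features()]

    results = _jsonify({
        "config": config.to_dict(),
        "reference_limb": config.reference_limb,
        "n_trials": dataset.n_trials,
        "n_trials_symptomatic": int((dataset.groups == GROUPS[0]).sum()),
        "n_trials_control": int((dataset.groups == GROUPS[1]).sum()),
        "stage_counts": _stage_counts(models, retained, screened,
                                      selection.main_features),
        "parallel_retained": {v: retained[v] for v in VARIABLES},
        "screening": screened.to_dict(orient="records"),
        "selection_frequency": {f.label: c for f, c in sorted(
            selection.selection_frequency.items())},
        "selection": selection_rows,
        "main_features": [f.label for f in selection.main_features],
        "final_features": final_table.to_dict(orient="records"),
        "associations": associations.to_dict(orient="records"),
        "interpretation": interpretation_rows,
        "pointwise": pointwise_summary,
        "pointwise_alpha": config.pointwise_alpha,
        "phase_boundaries": list(boundaries),
        "planted_report": planted,
        "curves": {"features": feature_curves},
        "events": list(dataset.events[0]) if dataset.events else [],
        "seed": config.seed,
    })

    result = PipelineResult(
        dataset=dataset, models=models, score_table=score_table,
        selection=selection, final_table=final_table,
        associations=associations, results=results)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "results.json", "w") as fh:
            fh.write(result.to_json())
        _write_run_log(outdir / "run.log", config, dataset, selection)
        interpret.render_report(results, outdir / "report")
        logger.info("results written to %s", outdir)
    return result


def _write_run_log(path, config, dataset, selection) -> None:
    """Plain-text run log with timestamps, seeds and library versions."""
    import datetime

    from . import __version__

    lines = [
        f"{datetime.datetime.now().isoformat()} wavefeat {__version__} "
        f"(numpy {np.__version__})",
        f"seed: {config.seed}",
        f"reference limb: {config.reference_limb}",
        f"trials: {dataset.n_trials} ({len(dataset.participants)} participants)",
        f"iterations: {config.n_iterations}, folds: {config.n_folds}, "
        f"parallel reps: {config.parallel_reps}",
        f"main features: {', '.join(f.label for f in selection.main_features) or '(none)'}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
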