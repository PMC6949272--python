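"""Config-driven orchestration of the full forecasting study.

Stage order (fixed): simulate/ingest → hourly aggregation → architecture
search on the single-lag four-variable table → per-variable input-window
search → feature combination (A, ART, ARTP, RT, RTP) → permutation
feature importance + correlation pruning on the weather-only set
(FSL0 / CORR70 / CORR80) → report.

Every stage consumes seeds derived from the single global seed, records
its raw per-replicate RMSE vectors (so any statistical claim can be
re-derived), and writes JSON/CSV artifacts plus a provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic, timeseries
from .errors import ConfigError, InsufficientDataError
from .rnn import CANONICAL_GRID, NetworkTopology, TrainingConfig
from .seeds import derive_seed
from .selection import (
    ComparisonReport,
    ReplicateResult,
    correlation_matrix,
    permutation_feature_importance,
    prune_features,
    run_replicates,
    select_best,
    welch_compare,
)
from .timeseries import CANONICAL_WINDOWS, build_windowed_dataset, window_spec

__all__ = [
    "PipelineConfig",
    "default_config",
    "load_config",
    "load_panel",
    "architecture_order",
    "run_architecture_search",
    "run_window_search",
    "run_combination_stage",
    "run_feature_selection_stage",
    "run_all",
]

#: Named predictor combinations at each variable's selected window.
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "A": ("activity",),
    "ART": ("activity", "irradiance", "temperature"),
    "ARTP": ("activity", "irradiance", "temperature", "pressure"),
    "RT": ("irradiance", "temperature"),
    "RTP": ("irradiance", "temperature", "pressure"),
}

#: Simplest-first order for the combination stage (fewer channels first).
COMBINATION_ORDER = ("A", "RT", "ART", "RTP", "ARTP")

WINDOW_ORDER = tuple(CANONICAL_WINDOWS)  # w1 simplest, w60 largest


def architecture_order() -> list[str]:
    """Simplest-first labels: fewer total units, then fewer layers."""
    return [
        t.label
        for t in sorted(
            CANONICAL_GRID,
            key=lambda t: (t.n_layers * t.units, t.n_layers, t.cell_type),
        )
    ]


@dataclass
class PipelineConfig:
    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    events_csv: str | None = None     # ingest instead of simulate when set
    weather_csv: str | None = None
    population: int | None = None     # tagged bees per day for ingested logs
    replicates: int = 30
    training: TrainingConfig = field(default_factory=TrainingConfig)
    window_names: tuple[str, ...] = WINDOW_ORDER
    score_threshold: float = 0.0
    corr_thresholds: tuple[float, ...] = (0.7, 0.8)
    pfi_repeats: int = 1
    train_fraction: float = 2 / 3
    contiguous_split: bool = False
    seed: int = 0
    out_dir: str = "beecast_out"

    def validate(self) -> None:
        self.simulation.validate()
        for thr in self.corr_thresholds:
            if not 0 < thr <= 1:
                raise ConfigError(f"correlation threshold must be in (0, 1]; got {thr}")
        unknown = [w for w in self.window_names if w not in CANONICAL_WINDOWS]
        if unknown:
            raise ConfigError(f"unknown window names: {unknown}")
        if (self.events_csv is None) != (self.weather_csv is None):
            raise ConfigError("events_csv and weather_csv must be given together")
        if self.events_csv is not None and self.population is None:
            raise ConfigError("population required when ingesting CSV event logs")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_names"] = list(self.window_names)
        d["corr_thresholds"] = list(self.corr_thresholds)
        return d


def default_config(seed: int = 0) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed)
    cfg.simulation = synthetic.SimulationConfig(seed=derive_seed(seed, "simulation"))
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline config; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = synthetic.SimulationConfig(**raw.pop("simulation", {}))
    training = TrainingConfig(**raw.pop("training", {}))
    for key in ("window_names", "corr_thresholds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = PipelineConfig.__dataclass_fields__
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    cfg = PipelineConfig(simulation=sim, training=training, **raw)
    cfg.validate()
    return cfg


def load_panel(config: PipelineConfig):
    """Materialize the hourly panel (and ground truth when simulating)."""
    config.validate()
    if config.events_csv is not None:
        events = synthetic.read_event_log(config.events_csv)
        weather = synthetic.read_weather(config.weather_csv)
        grid = weather.index
        truth = None
        population = config.population
    else:
        weather = synthetic.simulate_weather(config.simulation)
        events, truth = synthetic.simulate_events(config.simulation, weather)
        grid = weather.index
        population = config.simulation.n_bees
    activity = timeseries.compute_activity_level(events, population, grid)
    panel = timeseries.build_panel(activity, weather)
    return panel, truth


def run_architecture_search(
    config: PipelineConfig, panel: pd.DataFrame
) -> tuple[ComparisonReport, dict[str, ReplicateResult]]:
    """Evaluate the eight-model grid on the single-lag four-variable table."""
    w1 = window_spec("w1")
    dataset = build_windowed_dataset(panel, {v: w1 for v in timeseries.VARIABLES})
    results: dict[str, ReplicateResult] = {}
    base = derive_seed(config.seed, "arch")
    for topo in CANONICAL_GRID:
        results[topo.label] = run_replicates(
            dataset,
            topo,
            n_replicates=config.replicates,
            base_seed=base,  # shared across architectures: paired splits
            training=config.training,
            train_fraction=config.train_fraction,
            contiguous_split=config.contiguous_split,
        )
    report = select_best(list(results.values()), architecture_order())
    return report, results


def run_window_search(
    config: PipelineConfig, panel: pd.DataFrame, topology: NetworkTopology
) -> dict[str, tuple[ComparisonReport, dict[str, ReplicateResult]]]:
    """Per-variable single-predictor window search with the chosen topology."""
    out: dict[str, tuple[ComparisonReport, dict[str, ReplicateResult]]] = {}
    for var in timeseries.VARIABLES:
        results: dict[str, ReplicateResult] = {}
        for wname in config.window_names:
            spec = window_spec(wname)
            if len(panel) <= spec.max_lag + 1:
                import warnings

                warnings.warn(
                    f"panel of {len(panel)} h too short for {wname} "
                    f"(needs > {spec.max_lag + 1}); skipping",
                    stacklevel=2,
                )
                continue
            dataset = build_windowed_dataset(panel, {var: spec})
            results[wname] = run_replicates(
                dataset,
                topology,
                n_replicates=config.replicates,
                base_seed=derive_seed(config.seed, "window", var),
                training=config.training,
                train_fraction=config.train_fraction,
                contiguous_split=config.contiguous_split,
                label=wname,
            )
        report = select_best(list(results.values()), list(WINDOW_ORDER))
        out[var] = (report, results)
    return out


def run_combination_stage(
    config: PipelineConfig,
    panel: pd.DataFrame,
    topology: NetworkTopology,
    best_windows: dict[str, str],
) -> tuple[ComparisonReport, dict[str, ReplicateResult]]:
    """Evaluate the named predictor combinations at their best windows."""
    results: dict[str, ReplicateResult] = {}
    for name, variables in COMBINATIONS.items():
        specs = {v: window_spec(best_windows[v]) for v in variables}
        dataset = build_windowed_dataset(panel, specs)
        results[name] = run_replicates(
            dataset,
            topology,
            n_replicates=config.replicates,
            base_seed=derive_seed(config.seed, "combine", name),
            training=config.training,
            train_fraction=config.train_fraction,
            contiguous_split=config.contiguous_split,
            label=name,
        )
    report = select_best(list(results.values()), list(COMBINATION_ORDER))
    return report, results


def run_feature_selection_stage(
    config: PipelineConfig,
    panel: pd.DataFrame,
    topology: NetworkTopology,
    best_windows: dict[str, str],
) -> dict:
    """PFI + correlation pruning of the weather-only set, then re-evaluation.

    The designated PFI model is the lowest-RMSE replicate of the combined
    weather (RTP) evaluation; pruned datasets FSL0 and CORR<thr> are
    rebuilt from the surviving (variable, lag) pairs and re-scored with
    fresh replicates.
    """
    weather_vars = ("irradiance", "temperature", "pressure")
    specs = {v: window_spec(best_windows[v]) for v in weather_vars}
    dataset = build_windowed_dataset(panel, specs)

    baseline = run_replicates(
        dataset,
        topology,
        n_replicates=config.replicates,
        base_seed=derive_seed(config.seed, "fsl", "baseline"),
        training=config.training,
        train_fraction=config.train_fraction,
        contiguous_split=config.contiguous_split,
        label="RTP",
        keep_models=True,
    )
    best_i = baseline.best_replicate()
    model = baseline.models[best_i]
    test_set = baseline.test_sets[best_i]

    scores = permutation_feature_importance(
        model, test_set, n_repeats=config.pfi_repeats,
        seed=derive_seed(config.seed, "fsl", "pfi"),
    )
    corr = correlation_matrix(dataset)

    selections = {"FSL0": prune_features(scores, None, config.score_threshold)}
    for thr in config.corr_thresholds:
        name = f"CORR{int(round(thr * 100))}"
        selections[name] = prune_features(
            scores, corr, config.score_threshold, corr_threshold=thr
        )

    results: dict[str, ReplicateResult] = {"RTP": baseline}
    for name, feats in selections.items():
        if not feats:
            raise ConfigError(f"feature selection {name} removed every feature")
        per_var: dict[str, list[int]] = {}
        for f in feats:
            var, lag = timeseries.parse_feature_name(f)
            per_var.setdefault(var, []).append(lag)
        sub = build_windowed_dataset(panel, per_var)
        results[name] = run_replicates(
            sub,
            topology,
            n_replicates=config.replicates,
            base_seed=derive_seed(config.seed, "fsl", name),
            training=config.training,
            train_fraction=config.train_fraction,
            contiguous_split=config.contiguous_split,
            label=name,
        )

    labels = list(results)
    pairwise: dict[str, float | None] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            try:
                pairwise[f"{a}|{b}"] = welch_compare(
                    results[a].rmse_values, results[b].rmse_values
                )
            except ConfigError:
                pairwise[f"{a}|{b}"] = None  # single replicate: not testable
    medians = {l: results[l].median for l in labels}
    best = min(labels, key=lambda l: medians[l])
    return {
        "scores": scores,
        "correlation": corr,
        "selections": selections,
        "results": results,
        "medians": medians,
        "pairwise_welch_p": pairwise,
        "best": best,
    }


# ---------------------------------------------------------------------------
# end-to-end run


def _result_block(results: dict[str, ReplicateResult]) -> dict:
    return {
        label: {"rmse": r.rmse_values, "seeds": r.seeds, "median": r.median}
        for label, r in results.items()
    }


def _provenance(config: PipelineConfig) -> dict:
    from . import __version__

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "beecast_version": __version__,
    }


def run_all(config: PipelineConfig, write: bool = True) -> dict:
    """Run every stage in order; returns (and optionally writes) the report."""
    config.validate()
    out_dir = Path(config.out_dir)
    panel, truth = load_panel(config)

    arch_report, arch_results = run_architecture_search(config, panel)
    topology = next(t for t in CANONICAL_GRID if t.label == arch_report.selected)

    window_out = run_window_search(config, panel, topology)
    best_windows = {var: rep.selected for var, (rep, _) in window_out.items()}

    combo_report, combo_results = run_combination_stage(
        config, panel, topology, best_windows
    )
    fsl = run_feature_selection_stage(config, panel, topology, best_windows)

    report = {
        "provenance": _provenance(config),
        "architecture": {
            "report": arch_report.to_dict(),
            "results": _result_block(arch_results),
        },
        "windows": {
            var: {"report": rep.to_dict(), "results": _result_block(res)}
            for var, (rep, res) in window_out.items()
        },
        "best_windows": best_windows,
        "combinations": {
            "report": combo_report.to_dict(),
            "results": _result_block(combo_results),
        },
        "feature_selection": {
            "pfi": fsl["scores"].to_dict(),
            "selections": fsl["selections"],
            "results": _result_block(fsl["results"]),
            "medians": fsl["medians"],
            "pairwise_welch_p": fsl["pairwise_welch_p"],
            "best": fsl["best"],
        },
    }
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        timeseries.write_panel(panel, out_dir / "panel.csv")
        if truth is not None:
            truth.to_json(out_dir / "ground_truth.json")
        fsl["correlation"].to_csv(out_dir / "correlation_matrix.csv")
        fsl["scores"].to_frame().to_csv(out_dir / "pfi_scores.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
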