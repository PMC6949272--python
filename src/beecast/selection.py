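"""Replicate evaluation, statistical model selection, and feature pruning.

Because the forecasters are randomly initialized and the hold-out split is
randomized, a single train/test run is an unreliable estimate of a model's
error. The protocol here trains each candidate 30 times (configurable),
records the test RMSE distribution, checks each distribution for normality
with Shapiro–Wilk (p > 0.05 → treated as Gaussian; non-normal sets are
flagged but still compared), and uses the two-sided Welch unequal-variance
t-test to compare every candidate against the lowest-median one. Among the
candidates statistically equivalent to the best (p > 0.05) the *simplest*
is selected — fewer lags or fewer units win when the errors are
indistinguishable at 95% confidence.

Predictor selection uses Permutation Feature Importance: with a trained
model and an intact test set Dt, the baseline error is Eo; shuffling one
feature column of Dt gives Dt′ and error Ed, and the feature's score is
Ed − Eo. Features with score ≤ 0 are dropped (FSL0), and surviving pairs
with |Pearson r| above a threshold (0.70 / 0.80) lose their lower-scored
member (CORR70 / CORR80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, TrainingError
from .rnn import (
    NetworkTopology,
    TrainedModel,
    TrainingConfig,
    init_network,
    rmse,
    train,
)
from .seeds import derive_seed
from .timeseries import WindowedDataset, normalize, parse_feature_name, split_holdout

__all__ = [
    "ReplicateResult",
    "ComparisonReport",
    "FeatureScoreTable",
    "CorrelationMatrix",
    "run_replicates",
    "test_normality",
    "welch_compare",
    "select_best",
    "permutation_feature_importance",
    "correlation_matrix",
    "prune_features",
]

ALPHA = 0.05  # 95% confidence throughout


@dataclass
class ReplicateResult:
    """Test-RMSE distribution of one candidate over seeded replicates."""

    label: str
    rmse_values: list[float]
    seeds: list[int]
    models: list[TrainedModel] | None = None
    test_sets: list[WindowedDataset] | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.rmse_values):
            raise ConfigError("RMSE values must be non-negative")

    @property
    def median(self) -> float:
        return float(np.median(self.rmse_values))

    def best_replicate(self) -> int:
        return int(np.argmin(self.rmse_values))


@dataclass
class ComparisonReport:
    """Outcome of the lowest-median + Welch-equivalence selection rule."""

    medians: dict[str, float]
    shapiro_p: dict[str, float | None]
    non_normal: list[str]
    welch_p: dict[str, float | None]  # vs. the lowest-median set; None if not testable
    lowest_median: str
    equivalent: list[str]            # p > alpha, excluding the lowest itself
    selected: str
    rationale: str

    def to_dict(self) -> dict:
        return {
            "medians": self.medians,
            "shapiro_p": self.shapiro_p,
            "non_normal": self.non_normal,
            "welch_p_vs_lowest": self.welch_p,
            "lowest_median": self.lowest_median,
            "equivalent": self.equivalent,
            "selected": self.selected,
            "rationale": self.rationale,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, med in self.medians.items():
            rows.append(
                {
                    "set": label,
                    "median_rmse": med,
                    "shapiro_p": self.shapiro_p.get(label),
                    "welch_p_vs_lowest": self.welch_p.get(label),
                    "selected": label == self.selected,
                }
            )
        return pd.DataFrame(rows)


def run_replicates(
    dataset: WindowedDataset,
    topology: NetworkTopology,
    n_replicates: int = 30,
    base_seed: int = 0,
    training: TrainingConfig | None = None,
    train_fraction: float = 2 / 3,
    label: str | None = None,
    contiguous_split: bool = False,
    keep_models: bool = False,
) -> ReplicateResult:
    """Train/evaluate ``topology`` on ``dataset`` over fresh seeded hold-outs.

    Each replicate draws its own 2/3–1/3 split and weight initialization
    from a seed derived from ``base_seed``; the scaler is fitted on that
    replicate's training rows only, and the test RMSE is computed on the
    raw activity scale. A replicate failure aborts the run with the
    partial results attached to the raised :class:`TrainingError`.
    """
    training = training or TrainingConfig()
    label = label or topology.label
    values: list[float] = []
    seeds: list[int] = []
    models: list[TrainedModel] = []
    tests: list[WindowedDataset] = []
    for i in range(n_replicates):
        rep_seed = derive_seed(base_seed, "replicate", i)
        seeds.append(rep_seed)
        try:
            tr, te = split_holdout(
                dataset, train_fraction, seed=derive_seed(rep_seed, "split"),
                contiguous=contiguous_split,
            )
            tr_n, scaler = normalize(tr, np.arange(tr.n_samples))
            te_n = te.subset(np.arange(te.n_samples))
            te_n.X = _apply_scaler(te, scaler)
            te_n.y = scaler.transform_y(te.y_raw)
            te_n.scaler = scaler
            params = init_network(
                topology, 2 * len(dataset.variables), seed=derive_seed(rep_seed, "init")
            )
            cfg = TrainingConfig(
                epochs=training.epochs,
                learning_rate=training.learning_rate,
                batch_size=training.batch_size,
                optimizer=training.optimizer,
                clip_norm=training.clip_norm,
                seed=derive_seed(rep_seed, "train"),
            )
            model = train(params, tr_n.model_inputs(), tr_n.y, cfg)
            pred_raw = scaler.inverse_y(model.predict_dataset(te_n))
            values.append(rmse(te.y_raw, pred_raw))
            if keep_models:
                models.append(model)
                tests.append(te_n)
        except Exception as exc:  # record partial results, then abort
            partial = ReplicateResult(
                label=label, rmse_values=values, seeds=seeds,
                models=models or None, test_sets=tests or None,
            )
            raise TrainingError(
                f"replicate {i} of {label} failed: {exc}", partial=partial
            ) from exc
    return ReplicateResult(
        label=label, rmse_values=values, seeds=seeds,
        models=models or None, test_sets=tests or None,
    )


def _apply_scaler(dataset: WindowedDataset, scaler) -> np.ndarray:
    X = dataset.X.copy()
    for v, var in enumerate(dataset.variables):
        present = dataset.mask[:, v]
        lo, hi = scaler.channel_min[var], scaler.channel_max[var]
        X[:, present, v] = (dataset.X[:, present, v] - lo) / (hi - lo)
    return X


def test_normality(rmse_values: Sequence[float]) -> float:
    """Shapiro–Wilk p-value; p > 0.05 is read as 'accept Gaussian'."""
    x = np.asarray(rmse_values, dtype=float)
    if x.size < 3:
        raise ConfigError(f"Shapiro-Wilk needs >= 3 values; got {x.size}")
    if np.ptp(x) == 0:
        raise ConfigError("Shapiro-Wilk undefined for identical values (zero variance)")
    return float(stats.shapiro(x).pvalue)


def welch_compare(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch unequal-variance t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("Welch test needs >= 2 values per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ConfigError("Welch test undefined: both samples have zero variance")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def select_best(
    results: Sequence[ReplicateResult],
    complexity_order: Sequence[str],
    alpha: float = ALPHA,
) -> ComparisonReport:
    """Lowest median wins unless a simpler set is statistically equivalent.

    Every other set is Welch-compared against the lowest-median one; among
    the equivalents (p > alpha) plus the lowest-median set itself, the one
    earliest in ``complexity_order`` (simplest first) is selected. Sets
    failing the Shapiro–Wilk gate are flagged, not excluded.
    """
    if not results:
        raise ConfigError("no result sets to compare")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate result labels")
    missing = [l for l in labels if l not in complexity_order]
    if missing:
        raise ConfigError(f"complexity order does not cover: {missing}")
    by_label = {r.label: r for r in results}

    medians = {l: by_label[l].median for l in labels}
    shapiro_p: dict[str, float | None] = {}
    non_normal: list[str] = []
    for l in labels:
        try:
            p = test_normality(by_label[l].rmse_values)
        except ConfigError:
            p = None
        shapiro_p[l] = p
        if p is not None and p <= alpha:
            non_normal.append(l)

    lowest = min(labels, key=lambda l: (medians[l], complexity_order.index(l)))
    welch_p: dict[str, float | None] = {}
    equivalent: list[str] = []
    if len(results) > 1:
        for l in labels:
            if l == lowest:
                continue
            try:
                p = welch_compare(by_label[l].rmse_values, by_label[lowest].rmse_values)
            except ConfigError:
                p = None  # too few replicates / degenerate variance: not comparable
            welch_p[l] = p
            if p is not None and p > alpha:
                equivalent.append(l)

    candidates = [lowest] + equivalent
    selected = min(candidates, key=complexity_order.index)
    if len(results) == 1:
        rationale = f"only candidate {selected}"
    elif selected == lowest and not equivalent:
        rationale = (
            f"{lowest} has the lowest median RMSE ({medians[lowest]:.4g}) and no "
            f"other set is statistically equivalent (all Welch p <= {alpha})"
        )
    elif selected == lowest:
        rationale = (
            f"{lowest} has the lowest median RMSE ({medians[lowest]:.4g}) and is "
            f"the simplest among the equivalent sets {sorted(candidates, key=complexity_order.index)}"
        )
    else:
        rationale = (
            f"{selected} is statistically equivalent to the lowest-median set "
            f"{lowest} (Welch p = {welch_p[selected]:.2g} > {alpha}) and simpler"
        )
    return ComparisonReport(
        medians=medians,
        shapiro_p=shapiro_p,
        non_normal=non_normal,
        welch_p=welch_p,
        lowest_median=lowest,
        equivalent=equivalent,
        selected=selected,
        rationale=rationale,
    )


@dataclass
class FeatureScoreTable:
    """Permutation importance scores Ed − Eo per (variable, lag) feature."""

    eo: float
    ed: dict[str, float]
    scores: dict[str, float]
    n_repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.scores),
                "ed": [self.ed[f] for f in self.scores],
                "score": [self.scores[f] for f in self.scores],
            }
        ).assign(eo=self.eo)

    def to_dict(self) -> dict:
        return {
            "eo": self.eo,
            "ed": self.ed,
            "scores": self.scores,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }


def permutation_feature_importance(
    model: TrainedModel | Callable[[WindowedDataset], np.ndarray],
    test_set: WindowedDataset,
    n_repeats: int = 1,
    seed: int = 0,
) -> FeatureScoreTable:
    """Score each feature by the RMSE increase after shuffling its column.

    ``model`` is a :class:`TrainedModel` or any callable mapping a
    :class:`WindowedDataset` to predictions (useful for oracle models in
    tests). The test set is never mutated; each repeat draws a fresh
    seeded permutation per feature.
    """
    if test_set.n_samples < 2:
        raise ConfigError("PFI needs >= 2 test samples (permutation is vacuous)")
    predict = model.predict_dataset if isinstance(model, TrainedModel) else model
    y = test_set.y
    eo = rmse(y, np.asarray(predict(test_set), dtype=float))
    ed: dict[str, float] = {}
    scores: dict[str, float] = {}
    for name in test_set.feature_names:
        j, v = test_set.feature_position(name)
        ed_vals = []
        for rep in range(n_repeats):
            rng = np.random.default_rng(derive_seed(seed, "pfi", name, rep))
            shuffled = test_set.subset(np.arange(test_set.n_samples))
            col = shuffled.X[:, j, v].copy()
            shuffled.X = test_set.X.copy()
            shuffled.X[:, j, v] = col[rng.permutation(test_set.n_samples)]
            ed_vals.append(rmse(y, np.asarray(predict(shuffled), dtype=float)))
        ed[name] = float(np.mean(ed_vals))
        scores[name] = ed[name] - eo
    return FeatureScoreTable(eo=eo, ed=ed, scores=scores, n_repeats=n_repeats, seed=seed)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r over feature columns, feature names as index."""

    values: pd.DataFrame
    excluded: list[str] = field(default_factory=list)  # zero-variance columns

    def r(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def correlation_matrix(dataset: WindowedDataset) -> CorrelationMatrix:
    """Pearson correlations of the flattened (variable, lag) columns."""
    if dataset.n_samples < 2:
        raise ConfigError("correlation needs >= 2 samples")
    X = dataset.feature_matrix()
    names = list(dataset.feature_names)
    sd = X.std(axis=0)
    keep = sd > 0
    excluded = [n for n, k in zip(names, keep) if not k]
    if excluded:
        warnings.warn(
            f"excluding zero-variance features from correlation: {excluded}",
            stacklevel=2,
        )
    if not keep.any():
        raise ConfigError("all feature columns are constant")
    kept = [n for n, k in zip(names, keep) if k]
    r = np.corrcoef(X[:, keep].T)
    r = np.atleast_2d(r)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(r, index=kept, columns=kept), excluded=excluded
    )


def prune_features(
    scores: FeatureScoreTable,
    corr: CorrelationMatrix | None = None,
    score_threshold: float = 0.0,
    corr_threshold: float | None = None,
) -> list[str]:
    """Two-stage pruning: importance gate, then correlation de-duplication.

    Stage 1 keeps features with score strictly above ``score_threshold``.
    Stage 2 (when ``corr_threshold`` is given) visits surviving pairs with
    |r| above the threshold in descending |r| order and drops the
    lower-scored member of each (ties: drop the larger lag, then the
    lexicographically later name). Deterministic by construction.
    """
    survivors = [f for f, s in scores.scores.items() if s > score_threshold]
    if corr_threshold is None:
        return survivors
    if corr is None:
        raise ConfigError("corr_threshold given without a correlation matrix")
    known = set(corr.values.index) | set(corr.excluded)
    unknown = [f for f in survivors if f not in known]
    if unknown:
        raise ConfigError(f"features missing from correlation matrix: {unknown}")

    present = [f for f in survivors if f in corr.values.index]
    pairs = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            r = abs(corr.r(a, b))
            if r > corr_threshold:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = set(survivors)
    for _, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        alive.remove(_pruning_loser(a, b, scores.scores))
    return [f for f in survivors if f in alive]


def _pruning_loser(a: str, b: str, scores: dict[str, float]) -> str:
    if scores[a] != scores[b]:
        return a if scores[a] < scores[b] else b
    try:
        lag_a, lag_b = parse_feature_name(a)[1], parse_feature_name(b)[1]
    except ConfigError:
        lag_a = lag_b = 0  # free-form names: fall through to lexicographic
    if lag_a != lag_b:
        return a if lag_a > lag_b else b
    return max(a, b)
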