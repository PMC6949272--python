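"""Hourly panel construction and canonical lag-window datasets.

The observable the whole package forecasts is the *activity level*: the
hourly count of RFID-detected bee passages divided by the number of tagged
bees that day (movements·bee⁻¹·h⁻¹, observed range roughly 0–2). This
module aggregates raw event logs onto an hour grid, aligns them with the
weather channels into an :class:`HourlyPanel` (a plain pandas DataFrame),
and builds the supervised lag-window datasets used by the forecasters.

Lag conventions: ``t0`` is the hour immediately before the forecast target,
and a lag offset ``L`` means ``t0 − L`` hours, so the canonical window
``w12`` = {0, 2, 5, 11} spans the 12 hours preceding the target. The eight
canonical windows are nested and the largest, ``w60``, carries 8 lags.
The forecast horizon is fixed at +1 hour.

Heterogeneous per-variable windows are encoded as a masked sequence over
the union of lags, oldest timestep first: each timestep carries one value
channel per variable plus an availability flag, with unavailable entries
zero-filled after normalization. This preserves temporal order for the
recurrent cells instead of flattening to a vector.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateScaleError,
    GapError,
    InsufficientDataError,
)

__all__ = [
    "VARIABLES",
    "CANONICAL_WINDOWS",
    "WindowSpec",
    "window_spec",
    "WindowedDataset",
    "Scaler",
    "compute_activity_level",
    "build_panel",
    "build_windowed_dataset",
    "normalize",
    "dataset_from_frame",
    "split_holdout",
    "feature_name",
    "parse_feature_name",
    "write_panel",
    "read_panel",
]

VARIABLES = ("activity", "temperature", "pressure", "irradiance")

PANEL_CSV_COLUMNS = {
    "activity": "activity",
    "temperature": "temperature_c",
    "pressure": "pressure_hpa",
    "irradiance": "irradiance_kj_m2",
}

# Canonical nested lag sets: wN covers the N hours preceding the target.
CANONICAL_WINDOWS: dict[str, tuple[int, ...]] = {
    "w1": (0,),
    "w3": (0, 2),
    "w6": (0, 2, 5),
    "w12": (0, 2, 5, 11),
    "w24": (0, 2, 5, 11, 23),
    "w36": (0, 2, 5, 11, 23, 35),
    "w48": (0, 2, 5, 11, 23, 35, 47),
    "w60": (0, 2, 5, 11, 23, 35, 47, 59),
}


@dataclass(frozen=True)
class WindowSpec:
    """A named set of hourly lag offsets feeding a +1 h forecast."""

    name: str
    lags: tuple[int, ...]
    horizon: int = 1

    def __post_init__(self):
        if not self.lags:
            raise ConfigError(f"window {self.name!r} has no lags")
        if list(self.lags) != sorted(set(self.lags)):
            raise ConfigError(f"lags of {self.name!r} must be ascending and unique")
        if any(l < 0 for l in self.lags):
            raise ConfigError("lag offsets must be non-negative")

    @property
    def max_lag(self) -> int:
        return self.lags[-1]


def window_spec(name: str) -> WindowSpec:
    """Return one of the eight canonical window specs (w1 ... w60)."""
    try:
        return WindowSpec(name=name, lags=CANONICAL_WINDOWS[name])
    except KeyError:
        raise ConfigError(
            f"unknown window {name!r}; canonical names are {sorted(CANONICAL_WINDOWS)}"
        ) from None


def feature_name(variable: str, lag: int) -> str:
    return f"{variable}_t0" if lag == 0 else f"{variable}_t-{lag}"


_FEATURE_RE = re.compile(r"^(?P<var>.+)_t(?:0|-(?P<lag>\d+))$")


def parse_feature_name(name: str) -> tuple[str, int]:
    m = _FEATURE_RE.match(name)
    if m is None:
        raise ConfigError(f"not a feature name: {name!r}")
    return m.group("var"), int(m.group("lag") or 0)


# ---------------------------------------------------------------------------
# aggregation and alignment


def compute_activity_level(
    events: pd.DataFrame,
    population: int | Mapping | pd.Series,
    hour_grid: pd.DatetimeIndex,
) -> pd.Series:
    """Hourly activity level: passage count / tagged-bee count of the day.

    ``population`` is either a constant count or a per-day mapping
    (date → tagged bees). Hours with no events get level 0. Events outside
    ``hour_grid`` or non-positive population counts raise.
    """
    if len(hour_grid) == 0:
        raise AlignmentError("empty hour grid")
    days = pd.DatetimeIndex(hour_grid).normalize().unique()
    if isinstance(population, (int, np.integer)):
        pop_by_day = pd.Series(int(population), index=days, dtype=float)
    else:
        pop = pd.Series(population, dtype=float)
        pop.index = pd.DatetimeIndex(pop.index).normalize()
        missing = days.difference(pop.index)
        if len(missing):
            raise ConfigError(f"population count missing for days: {list(missing.date)}")
        pop_by_day = pop.reindex(days)
    if (pop_by_day <= 0).any():
        bad = pop_by_day.index[pop_by_day <= 0][0].date()
        raise ConfigError(f"population count must be positive; day {bad} is not")

    if len(events):
        stamps = pd.DatetimeIndex(pd.to_datetime(events["timestamp"]))
        floored = stamps.floor("h")
        inside = floored.isin(hour_grid)
        if not inside.all():
            first = stamps[~inside][0]
            raise AlignmentError(f"event at {first} falls outside the hour grid")
        counts = pd.Series(1, index=floored).groupby(level=0).sum()
    else:
        counts = pd.Series(dtype=float)
    counts = counts.reindex(hour_grid, fill_value=0).astype(float)
    denom = pop_by_day.reindex(pd.DatetimeIndex(hour_grid).normalize()).to_numpy()
    level = counts.to_numpy() / denom
    return pd.Series(level, index=hour_grid, name="activity")


def build_panel(
    activity: pd.Series, weather: pd.DataFrame, max_gap_hours: int = 3
) -> pd.DataFrame:
    """Align activity and weather on the intersection of their hour ranges.

    Interior weather gaps of at most ``max_gap_hours`` missing hours are
    filled by linear interpolation; longer gaps (or missing activity
    hours) raise. Columns: activity, temperature, pressure, irradiance.
    """
    start = max(activity.index[0], weather.index[0])
    end = min(activity.index[-1], weather.index[-1])
    if start > end:
        raise AlignmentError("activity and weather hour ranges do not overlap")
    grid = pd.date_range(start, end, freq="h")

    act = activity.reindex(grid)
    if act.isna().any():
        raise GapError("activity series has missing hours inside the overlap")

    met = weather.reindex(grid)
    for col in ("temperature", "pressure", "irradiance"):
        isna = met[col].isna().to_numpy()
        if isna.any():
            run = _longest_nan_run(isna)
            if isna[0] or isna[-1] or run > max_gap_hours:
                raise GapError(
                    f"weather channel {col!r} has a gap of {run} h "
                    f"(max interpolatable: {max_gap_hours} h)"
                )
            met[col] = met[col].interpolate(method="linear")

    panel = pd.DataFrame(
        {
            "activity": act,
            "temperature": met["temperature"],
            "pressure": met["pressure"],
            "irradiance": met["irradiance"],
        },
        index=grid,
    )
    return panel


def _longest_nan_run(isna: np.ndarray) -> int:
    best = cur = 0
    for flag in isna:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# windowed supervised datasets


@dataclass
class Scaler:
    """Per-variable min-max parameters plus the target's own range."""

    channel_min: dict[str, float]
    channel_max: dict[str, float]
    y_min: float
    y_max: float

    def inverse_y(self, y_norm: np.ndarray) -> np.ndarray:
        return np.asarray(y_norm) * (self.y_max - self.y_min) + self.y_min

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) - self.y_min) / (self.y_max - self.y_min)


@dataclass
class WindowedDataset:
    """Supervised tensors for the +1 h forecast over a masked lag sequence.

    ``X`` has shape [n_samples, n_timesteps, n_variables] with timesteps
    ordered oldest → newest (descending lag); ``mask`` marks which
    (timestep, variable) cells the per-variable specs actually provide.
    ``y`` is the activity level one hour after each sample's t0 hour.
    """

    X: np.ndarray
    mask: np.ndarray            # [n_timesteps, n_variables] bool
    y: np.ndarray
    y_raw: np.ndarray           # target on the original activity scale
    timesteps: tuple[int, ...]  # lag offsets, descending (oldest first)
    variables: tuple[str, ...]
    feature_names: tuple[str, ...]
    t0_hours: pd.DatetimeIndex
    scaler: Scaler | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature_position(self, name: str) -> tuple[int, int]:
        """(timestep index, variable index) of a named (variable, lag) cell."""
        var, lag = parse_feature_name(name)
        j = self.timesteps.index(lag)
        v = self.variables.index(var)
        if not self.mask[j, v]:
            raise ConfigError(f"feature {name!r} not present in this dataset")
        return j, v

    def feature_matrix(self) -> np.ndarray:
        """[n_samples, n_features] view in ``feature_names`` order."""
        cols = []
        for name in self.feature_names:
            j, v = self.feature_position(name)
            cols.append(self.X[:, j, v])
        return np.column_stack(cols)

    def model_inputs(self) -> np.ndarray:
        """Value channels with the availability mask appended as channels."""
        n = self.n_samples
        m = np.broadcast_to(self.mask.astype(float), (n, *self.mask.shape))
        return np.concatenate([self.X, m], axis=2)

    def subset(self, rows: np.ndarray) -> "WindowedDataset":
        rows = np.asarray(rows)
        return replace(
            self,
            X=self.X[rows],
            y=self.y[rows],
            y_raw=self.y_raw[rows],
            t0_hours=self.t0_hours[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide export: one column per (variable, lag) plus ``target``."""
        df = pd.DataFrame(self.feature_matrix(), columns=list(self.feature_names))
        df["target"] = self.y
        df.index = self.t0_hours
        df.index.name = "t0"
        return df


def build_windowed_dataset(
    panel: pd.DataFrame,
    specs: Mapping[str, WindowSpec | Sequence[int]],
    target: str = "activity",
) -> WindowedDataset:
    """One supervised sample per valid t0 from per-variable lag windows."""
    norm_specs: dict[str, tuple[int, ...]] = {}
    for var, spec in specs.items():
        if var not in panel.columns:
            raise ConfigError(f"variable {var!r} not in panel columns {list(panel.columns)}")
        lags = tuple(spec.lags) if isinstance(spec, WindowSpec) else tuple(sorted(set(spec)))
        if not lags:
            raise ConfigError(f"empty lag set for {var!r}")
        norm_specs[var] = lags
    if not norm_specs:
        raise ConfigError("no variables given")

    # deterministic variable order: canonical first, then extras alphabetically
    variables = tuple(
        sorted(norm_specs, key=lambda v: (VARIABLES.index(v) if v in VARIABLES else len(VARIABLES), v))
    )
    timesteps = tuple(sorted({l for lags in norm_specs.values() for l in lags}, reverse=True))
    max_lag = timesteps[0]
    n = len(panel) - max_lag - 1
    if n < 1:
        raise InsufficientDataError(
            f"panel of {len(panel)} h cannot host max lag {max_lag} plus a +1 h target"
        )

    t0 = np.arange(max_lag, max_lag + n)  # positions in the panel
    X = np.zeros((n, len(timesteps), len(variables)))
    mask = np.zeros((len(timesteps), len(variables)), dtype=bool)
    for v, var in enumerate(variables):
        col = panel[var].to_numpy()
        for j, lag in enumerate(timesteps):
            if lag in norm_specs[var]:
                mask[j, v] = True
                X[:, j, v] = col[t0 - lag]

    y = panel[target].to_numpy()[t0 + 1].astype(float)
    names = tuple(
        feature_name(var, lag) for var in variables for lag in norm_specs[var]
    )
    return WindowedDataset(
        X=X,
        mask=mask,
        y=y.copy(),
        y_raw=y.copy(),
        timesteps=timesteps,
        variables=variables,
        feature_names=names,
        t0_hours=panel.index[t0],
    )


def normalize(
    dataset: WindowedDataset, fit_rows: np.ndarray | Sequence[int]
) -> tuple[WindowedDataset, Scaler]:
    """Min-max map each variable channel (and the target) onto [0, 1].

    Parameters are estimated only from ``fit_rows``; values outside the
    fitted range map outside [0, 1] and are left unclipped. Masked cells
    stay exactly zero. Raises on constant channels.
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ConfigError("fit_rows is empty")
    cmin: dict[str, float] = {}
    cmax: dict[str, float] = {}
    Xn = dataset.X.copy()
    for v, var in enumerate(dataset.variables):
        present = dataset.mask[:, v]
        vals = dataset.X[fit_rows][:, present, v]
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise DegenerateScaleError(
                f"channel {var!r} is constant ({lo}) on the fitted rows; "
                "min-max scaling undefined"
            )
        cmin[var], cmax[var] = lo, hi
        Xn[:, present, v] = (dataset.X[:, present, v] - lo) / (hi - lo)

    y_fit = dataset.y_raw[fit_rows]
    y_lo, y_hi = float(y_fit.min()), float(y_fit.max())
    if y_hi <= y_lo:
        # constant target: map to 0 with unit span so the inverse is exact
        # (a bias-only fit is still well defined; channels must still vary)
        y_hi = y_lo + 1.0
    scaler = Scaler(channel_min=cmin, channel_max=cmax, y_min=y_lo, y_max=y_hi)
    out = replace(dataset, X=Xn, y=scaler.transform_y(dataset.y_raw), scaler=scaler)
    return out, scaler


def dataset_from_frame(df: pd.DataFrame) -> WindowedDataset:
    """Rebuild a :class:`WindowedDataset` from its wide export.

    Inverse of :meth:`WindowedDataset.to_frame` (and of reading that frame
    back from CSV with ``index_col=0, parse_dates=True``).
    """
    if "target" not in df.columns:
        raise ConfigError("wide frame must carry a 'target' column")
    feature_cols = [c for c in df.columns if c != "target"]
    parsed = [parse_feature_name(c) for c in feature_cols]
    per_var: dict[str, list[int]] = {}
    for var, lag in parsed:
        per_var.setdefault(var, []).append(lag)
    variables = tuple(
        sorted(per_var, key=lambda v: (VARIABLES.index(v) if v in VARIABLES else len(VARIABLES), v))
    )
    timesteps = tuple(sorted({l for lags in per_var.values() for l in lags}, reverse=True))
    n = len(df)
    X = np.zeros((n, len(timesteps), len(variables)))
    mask = np.zeros((len(timesteps), len(variables)), dtype=bool)
    for col, (var, lag) in zip(feature_cols, parsed):
        j, v = timesteps.index(lag), variables.index(var)
        mask[j, v] = True
        X[:, j, v] = df[col].to_numpy(dtype=float)
    y = df["target"].to_numpy(dtype=float)
    names = tuple(feature_name(var, lag) for var in variables for lag in sorted(per_var[var]))
    return WindowedDataset(
        X=X,
        mask=mask,
        y=y.copy(),
        y_raw=y.copy(),
        timesteps=timesteps,
        variables=variables,
        feature_names=names,
        t0_hours=pd.DatetimeIndex(df.index),
    )


def split_holdout(
    dataset: WindowedDataset,
    train_fraction: float = 2 / 3,
    seed: int = 0,
    contiguous: bool = False,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Randomized hold-out: ⌈f·n⌉ training rows, the rest for testing.

    The default shuffled split reproduces the study protocol (overlapping
    windows may straddle the split); ``contiguous=True`` gives a leading
    block train / trailing block test alternative for leakage-sensitivity
    checks.
    """
    n = dataset.n_samples
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples to split; have {n}")
    n_train = math.ceil(train_fraction * n)
    if contiguous:
        order = np.arange(n)
    else:
        order = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    if test_idx.size == 0:
        raise InsufficientDataError("train_fraction leaves no test rows")
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# panel I/O


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.rename(columns=PANEL_CSV_COLUMNS).copy()
    out.insert(0, "timestamp", panel.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    idx = pd.DatetimeIndex(pd.to_datetime(df.pop("timestamp")))
    inverse = {v: k for k, v in PANEL_CSV_COLUMNS.items()}
    df = df.rename(columns=inverse)
    df.index = idx
    return df
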