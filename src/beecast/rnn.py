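"""Small stacked gated recurrent forecasters, implemented in numpy.

The forecasting model is the standard recurrence h(t) = f(h(t−1), x(t); θ)
with gated cells — GRU (update/reset gates) or LSTM (input/forget/output
gates plus a cell state) — stacked in 2 or 5 layers of 2 or 5 units and
read out through a single linear unit from the last timestep's top hidden
state. The canonical model grid is {GRU, LSTM} × {2x2, 2x5, 5x2, 5x5}.

Cells, backpropagation through time and the Adam optimizer are written
in-repo on purpose: the networks are at most 5×5 units, and owning the
arithmetic buys exact analytic/finite-difference gradient checking, full
determinism from a seed, and zero heavyweight dependencies.

GRU update (per layer, per timestep; σ = logistic):

    z = σ(W_z x + U_z h + b_z)
    r = σ(W_r x + U_r h + b_r)
    c = tanh(W_c x + U_c (r∘h) + b_c)
    h' = (1 − z)∘h + z∘c

LSTM update:

    i, f, o = σ(W x + U h + b)   (three separate gate parameter sets)
    g = tanh(W_g x + U_g h + b_g)
    c' = f∘c + i∘g,   h' = o∘tanh(c')

Model quality is measured throughout by RMSE = sqrt(mean((y − ŷ)²)).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ConfigError, TrainingError
from .timeseries import WindowedDataset

__all__ = [
    "NetworkTopology",
    "CANONICAL_GRID",
    "TrainingConfig",
    "ModelParams",
    "TrainedModel",
    "init_network",
    "forward",
    "train",
    "rmse",
    "gradient_check",
    "persistence_rmse",
    "model_to_json",
    "model_from_json",
]

_GATES = {"gru": ("z", "r", "c"), "lstm": ("i", "f", "o", "g")}


@dataclass(frozen=True)
class NetworkTopology:
    """Cell type plus a layers × units stack description (e.g. GRU 2x2)."""

    cell_type: str
    n_layers: int
    units: int

    def __post_init__(self):
        if self.cell_type not in _GATES:
            raise ConfigError(f"cell_type must be 'gru' or 'lstm'; got {self.cell_type!r}")
        if self.n_layers < 1 or self.units < 1:
            raise ConfigError(
                f"topology needs at least one layer and one unit; "
                f"got {self.n_layers}x{self.units}"
            )

    @property
    def label(self) -> str:
        return f"{self.cell_type.upper()}{self.n_layers}x{self.units}"


#: The eight evaluated models: both cell types over 2x2, 2x5, 5x2, 5x5.
CANONICAL_GRID: tuple[NetworkTopology, ...] = tuple(
    NetworkTopology(cell, layers, units)
    for cell in ("gru", "lstm")
    for layers, units in ((2, 2), (2, 5), (5, 2), (5, 5))
)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 200
    learning_rate: float = 0.01
    batch_size: int = 32
    optimizer: str = "adam"
    clip_norm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ConfigError("learning rate must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class ModelParams:
    """Shared parameter set θ: gate matrices per layer plus linear readout."""

    topology: NetworkTopology
    n_channels: int
    layers: list[dict[str, np.ndarray]]
    readout_w: np.ndarray  # [units]
    readout_b: np.ndarray  # [1]

    def iter_arrays(self) -> Iterator[tuple[str, np.ndarray]]:
        for li, layer in enumerate(self.layers):
            for key in sorted(layer):
                yield f"layer{li}.{key}", layer[key]
        yield "readout_w", self.readout_w
        yield "readout_b", self.readout_b

    @property
    def n_params(self) -> int:
        return sum(arr.size for _, arr in self.iter_arrays())

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


def init_network(topology: NetworkTopology, n_channels: int, seed: int = 0) -> ModelParams:
    """Seeded small-scale initialization: uniform ±1/√fan_in, zero biases."""
    if n_channels < 1:
        raise ConfigError(f"n_channels must be >= 1; got {n_channels}")
    rng = np.random.default_rng(seed)
    H = topology.units
    layers = []
    in_dim = n_channels
    for _ in range(topology.n_layers):
        layer: dict[str, np.ndarray] = {}
        for gate in _GATES[topology.cell_type]:
            layer[f"W{gate}"] = rng.uniform(-1, 1, (in_dim, H)) / math.sqrt(in_dim)
            layer[f"U{gate}"] = rng.uniform(-1, 1, (H, H)) / math.sqrt(H)
            layer[f"b{gate}"] = np.zeros(H)
        layers.append(layer)
        in_dim = H
    readout_w = rng.uniform(-1, 1, H) / math.sqrt(H)
    return ModelParams(
        topology=topology,
        n_channels=n_channels,
        layers=layers,
        readout_w=readout_w,
        readout_b=np.zeros(1),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gru_layer_forward(p, X):
    B, T, _ = X.shape
    H = p["Uz"].shape[0]
    h = np.zeros((B, H), dtype=X.dtype)
    outs = np.empty((B, T, H), dtype=X.dtype)
    cache = []
    for t in range(T):
        x = X[:, t]
        z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
        c = np.tanh(x @ p["Wc"] + (r * h) @ p["Uc"] + p["bc"])
        h_new = (1 - z) * h + z * c
        cache.append((x, h, z, r, c))
        h = h_new
        outs[:, t] = h
    return outs, cache


def _gru_layer_backward(p, cache, dOut):
    B, T, H = dOut.shape
    g = {k: np.zeros_like(v) for k, v in p.items()}
    dX = np.empty((B, T, cache[0][0].shape[1]))
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, z, r, c = cache[t]
        dh = dOut[:, t] + dh_next
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1 - z)
        dc_pre = dc * (1 - c * c)
        g["Wc"] += x.T @ dc_pre
        g["Uc"] += (r * h_prev).T @ dc_pre
        g["bc"] += dc_pre.sum(0)
        dhr = dc_pre @ p["Uc"].T
        dr = dhr * h_prev
        dh_prev += dhr * r
        dz_pre = dz * z * (1 - z)
        dr_pre = dr * r * (1 - r)
        g["Wz"] += x.T @ dz_pre
        g["Uz"] += h_prev.T @ dz_pre
        g["bz"] += dz_pre.sum(0)
        g["Wr"] += x.T @ dr_pre
        g["Ur"] += h_prev.T @ dr_pre
        g["br"] += dr_pre.sum(0)
        dh_prev += dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        dX[:, t] = dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T + dc_pre @ p["Wc"].T
        dh_next = dh_prev
    return g, dX


def _lstm_layer_forward(p, X):
    B, T, _ = X.shape
    H = p["Ui"].shape[0]
    h = np.zeros((B, H), dtype=X.dtype)
    c = np.zeros((B, H), dtype=X.dtype)
    outs = np.empty((B, T, H), dtype=X.dtype)
    cache = []
    for t in range(T):
        x = X[:, t]
        i = _sigmoid(x @ p["Wi"] + h @ p["Ui"] + p["bi"])
        f = _sigmoid(x @ p["Wf"] + h @ p["Uf"] + p["bf"])
        o = _sigmoid(x @ p["Wo"] + h @ p["Uo"] + p["bo"])
        gg = np.tanh(x @ p["Wg"] + h @ p["Ug"] + p["bg"])
        c_new = f * c + i * gg
        h_new = o * np.tanh(c_new)
        cache.append((x, h, c, i, f, o, gg, c_new))
        h, c = h_new, c_new
        outs[:, t] = h
    return outs, cache


def _lstm_layer_backward(p, cache, dOut):
    B, T, H = dOut.shape
    g = {k: np.zeros_like(v) for k, v in p.items()}
    dX = np.empty((B, T, cache[0][0].shape[1]))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, o, gg, c_new = cache[t]
        dh = dOut[:, t] + dh_next
        tc = np.tanh(c_new)
        do = dh * tc
        dc = dc_next + dh * o * (1 - tc * tc)
        di = dc * gg
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        di_pre = di * i * (1 - i)
        df_pre = df * f * (1 - f)
        do_pre = do * o * (1 - o)
        dg_pre = dg * (1 - gg * gg)
        dh_prev = np.zeros((B, H))
        dx = np.zeros_like(dX[:, t])
        for gate, dpre in (("i", di_pre), ("f", df_pre), ("o", do_pre), ("g", dg_pre)):
            g[f"W{gate}"] += x.T @ dpre
            g[f"U{gate}"] += h_prev.T @ dpre
            g[f"b{gate}"] += dpre.sum(0)
            dh_prev += dpre @ p[f"U{gate}"].T
            dx += dpre @ p[f"W{gate}"].T
        dX[:, t] = dx
        dh_next = dh_prev
    return g, dX


_LAYER_FWD = {"gru": _gru_layer_forward, "lstm": _lstm_layer_forward}
_LAYER_BWD = {"gru": _gru_layer_backward, "lstm": _lstm_layer_backward}


def _forward_cached(params: ModelParams, inputs: np.ndarray):
    fwd = _LAYER_FWD[params.topology.cell_type]
    seq = inputs
    caches = []
    for layer in params.layers:
        seq, cache = fwd(layer, seq)
        caches.append(cache)
    pred = seq[:, -1] @ params.readout_w + params.readout_b[0]
    return pred, seq, caches


def _check_inputs(params: ModelParams, inputs: np.ndarray) -> np.ndarray:
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 2:
        inputs = inputs[None]
    if inputs.ndim != 3:
        raise ConfigError(f"inputs must be [batch, timesteps, channels]; got shape {inputs.shape}")
    if inputs.shape[1] == 0:
        raise ConfigError("zero-length input sequence")
    if inputs.shape[2] != params.n_channels:
        raise ConfigError(
            f"input has {inputs.shape[2]} channels but network expects {params.n_channels}"
        )
    return inputs


def forward(params: ModelParams, inputs: np.ndarray) -> np.ndarray:
    """Predictions for a batch [B, T, C] (or one sample [T, C] → scalar)."""
    squeeze = np.asarray(inputs).ndim == 2
    inputs = _check_inputs(params, inputs)
    pred, _, _ = _forward_cached(params, inputs)
    return float(pred[0]) if squeeze else pred


def _loss_and_grads(params: ModelParams, inputs: np.ndarray, y: np.ndarray):
    """Mean squared error and its gradients w.r.t. every parameter."""
    pred, top_seq, caches = _forward_cached(params, inputs)
    err = pred - y
    loss = float(np.mean(err**2))
    B, T, H = top_seq.shape
    dpred = 2.0 * err / len(y)

    grads = {
        "layers": [],
        "readout_w": top_seq[:, -1].T @ dpred,
        "readout_b": np.array([dpred.sum()]),
    }
    dOut = np.zeros((B, T, H))
    dOut[:, -1] = np.outer(dpred, params.readout_w)
    bwd = _LAYER_BWD[params.topology.cell_type]
    layer_grads: list[dict] = [None] * len(params.layers)
    for li in range(len(params.layers) - 1, -1, -1):
        g, dOut = bwd(params.layers[li], caches[li], dOut)
        layer_grads[li] = g
    grads["layers"] = layer_grads
    return loss, grads


def _grad_arrays(params: ModelParams, grads) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    for li, layer in enumerate(params.layers):
        for key in sorted(layer):
            yield layer[key], grads["layers"][li][key]
    yield params.readout_w, grads["readout_w"]
    yield params.readout_b, grads["readout_b"]


@dataclass
class TrainedModel:
    """Final parameters plus the full per-epoch loss trace."""

    params: ModelParams
    loss_history: list[float]
    config: TrainingConfig

    @property
    def topology(self) -> NetworkTopology:
        return self.params.topology

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return forward(self.params, inputs)

    def predict_dataset(self, dataset: WindowedDataset) -> np.ndarray:
        return forward(self.params, dataset.model_inputs())


def train(
    params: ModelParams, inputs: np.ndarray, y: np.ndarray, config: TrainingConfig
) -> TrainedModel:
    """Minimize MSE by backpropagation through time; seeded and restartable.

    Returns a new :class:`TrainedModel`; ``params`` is not modified. A
    non-finite loss aborts with a :class:`TrainingError` naming the epoch.
    """
    inputs = _check_inputs(params, inputs)
    y = np.asarray(y, dtype=float)
    if len(y) == 0 or len(y) != inputs.shape[0]:
        raise ConfigError("training targets empty or misaligned with inputs")

    p = params.copy()
    rng = np.random.default_rng(config.seed)
    adam_m = adam_v = None
    if config.optimizer == "adam":
        adam_m = [np.zeros_like(a) for _, a in p.iter_arrays()]
        adam_v = [np.zeros_like(a) for _, a in p.iter_arrays()]
    step = 0
    history: list[float] = []
    n = inputs.shape[0]
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, grads = _loss_and_grads(p, inputs[idx], y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")
            pairs = list(_grad_arrays(p, grads))
            if config.clip_norm is not None:
                norm = math.sqrt(sum(float(np.sum(g * g)) for _, g in pairs))
                if norm > config.clip_norm:
                    scale = config.clip_norm / norm
                    pairs = [(a, g * scale) for a, g in pairs]
            step += 1
            if config.optimizer == "adam":
                b1, b2, eps = 0.9, 0.999, 1e-8
                for k, (arr, grad) in enumerate(pairs):
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * grad
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * grad**2
                    mhat = adam_m[k] / (1 - b1**step)
                    vhat = adam_v[k] / (1 - b2**step)
                    arr -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            else:
                for arr, grad in pairs:
                    arr -= config.learning_rate * grad
        # epoch loss on the full training set with the updated parameters
        epoch_loss = float(_loss_only(p, inputs, y))
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")
        history.append(epoch_loss)
    return TrainedModel(params=p, loss_history=history, config=config)


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean square error sqrt(mean((y − ŷ)²)); zero iff identical."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ConfigError(
            f"length mismatch: observed {observed.shape} vs predicted {predicted.shape}"
        )
    if observed.size == 0:
        raise ConfigError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def _loss_only(params: ModelParams, inputs: np.ndarray, y: np.ndarray) -> float:
    """Forward-only MSE; follows the dtype of ``inputs`` (extended precision ok)."""
    fwd = _LAYER_FWD[params.topology.cell_type]
    seq = inputs
    for layer in params.layers:
        seq, _ = fwd(layer, seq)
    pred = seq[:, -1] @ params.readout_w + params.readout_b[0]
    return np.mean((pred - y) ** 2)  # dtype preserved; do not cast to float64


def gradient_check(
    params: ModelParams, inputs: np.ndarray, y: np.ndarray, eps: float = 1e-6
) -> float:
    """Max relative deviation of analytic BPTT gradients vs central differences.

    The finite-difference oracle evaluates the loss in extended precision
    so that subtractive cancellation does not mask genuinely small
    gradients in deep stacks; the analytic path stays in float64.
    """
    inputs = _check_inputs(params, inputs)
    y = np.asarray(y, dtype=float)
    _, grads = _loss_and_grads(params, inputs, y)

    ld = np.longdouble
    p_ld = params.copy()
    p_ld.layers = [{k: v.astype(ld) for k, v in layer.items()} for layer in params.layers]
    p_ld.readout_w = params.readout_w.astype(ld)
    p_ld.readout_b = params.readout_b.astype(ld)
    x_ld = inputs.astype(ld)
    y_ld = y.astype(ld)

    worst = 0.0
    for (_, grad), (_, arr_ld) in zip(_grad_arrays(params, grads), p_ld.iter_arrays()):
        flat = arr_ld.ravel()
        gflat = grad.ravel() if isinstance(grad, np.ndarray) else np.ravel(grad)
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            lp = _loss_only(p_ld, x_ld, y_ld)
            flat[k] = orig - eps
            lm = _loss_only(p_ld, x_ld, y_ld)
            flat[k] = orig
            numeric = (lp - lm) / (2 * eps)
            denom = max(abs(gflat[k]) + abs(numeric), 1e-8)
            worst = max(worst, abs(gflat[k] - numeric) / denom)
    return float(worst)


def persistence_rmse(dataset: WindowedDataset) -> float:
    """RMSE of the naive forecast ŷ(t+1) = activity(t0), on the raw scale."""
    j, v = dataset.feature_position("activity_t0")
    x = dataset.X[:, j, v]
    if dataset.scaler is not None:
        lo = dataset.scaler.channel_min["activity"]
        hi = dataset.scaler.channel_max["activity"]
        x = x * (hi - lo) + lo
    return rmse(dataset.y_raw, x)


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: TrainedModel, path: str | Path | None = None) -> str:
    payload = {
        "topology": asdict(model.params.topology),
        "n_channels": model.params.n_channels,
        "config": asdict(model.config),
        "weights": {name: arr.tolist() for name, arr in model.params.iter_arrays()},
        "loss_history": model.loss_history,
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> TrainedModel:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
        text = Path(source).read_text()
    else:
        text = str(source)
    payload = json.loads(text)
    topo = NetworkTopology(**payload["topology"])
    params = init_network(topo, payload["n_channels"], seed=0)
    weights = payload["weights"]
    for name, arr in params.iter_arrays():
        arr[...] = np.asarray(weights[name])
    return TrainedModel(
        params=params,
        loss_history=list(payload["loss_history"]),
        config=TrainingConfig(**payload["config"]),
    )
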