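"""One-dimensional convolutional IC50 regressor, implemented in NumPy.

The architecture maps a selected-descriptor vector, read as a length-n
single-channel sequence, through

    Conv1D(k=3, ReLU) -> MaxPool1D(2) -> Conv1D(k=3, ReLU) -> MaxPool1D(2)
    -> Flatten -> Dense(64, ReLU) -> Dense(1)

and is trained with Adam on mean-squared error against min-max-scaled
targets.  Convolutions are valid (no padding); pooling truncates odd
remainders.  Everything — initialization, the 80/20 validation split and
per-epoch shuffling — is driven by one seed, so training histories are
bit-reproducible.

The evaluation metrics are the usual regression pair

    MSE = Σ (y_k − ŷ_k)² / m        MAE = Σ |y_k − ŷ_k| / m
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chem_io import DescriptorTable

__all__ = [
    "RegressorConfig",
    "CNNRegressor",
    "TrainedRegressor",
    "build_regressor",
    "train",
    "predict",
    "evaluate",
    "mse",
    "mae",
    "minimum_features",
    "save_checkpoint",
    "load_checkpoint",
    "metrics_report_to_csv",
]


@dataclass(frozen=True)
class RegressorConfig:
    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 64
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    target_scaling: str = "minmax"  # or "none"
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ValueError("kernel_size and pool_size must be >= 1")
        if min(self.conv_filters) < 1 or self.dense_units < 1:
            raise ValueError("layer widths must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if self.target_scaling not in ("minmax", "none"):
            raise ValueError("target_scaling must be 'minmax' or 'none'")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


def _stage_lengths(n_features: int, k: int, p: int) -> tuple[int, int, int, int]:
    l1 = n_features - k + 1
    p1 = l1 // p
    l2 = p1 - k + 1
    p2 = l2 // p
    return l1, p1, l2, p2


def minimum_features(k: int = 3, p: int = 2) -> int:
    """Smallest input length that leaves >= 1 position after both stages."""
    n = k
    while True:
        l1, p1, l2, p2 = _stage_lengths(n, k, p)
        if l1 >= 1 and p1 >= 1 and l2 >= 1 and p2 >= 1:
            return n
        n += 1


class CNNRegressor:
    """Untrained network: seeded parameters plus forward/backward passes."""

    #: ordered computational stages of the architecture
    STAGES = ("conv1", "pool1", "conv2", "pool2", "flatten", "dense1", "dense2")

    def __init__(self, n_features: int, config: RegressorConfig):
        k, p = config.kernel_size, config.pool_size
        l1, p1, l2, p2 = _stage_lengths(n_features, k, p)
        if min(l1, p1, l2, p2) < 1:
            raise ValueError(
                f"n_features={n_features} too small for two (conv k={k}, pool {p}) stages; "
                f"minimum is {minimum_features(k, p)}"
            )
        self.n_features = n_features
        self.config = config
        f1, f2 = config.conv_filters
        d = config.dense_units
        flat = p2 * f2
        rng = np.random.default_rng(config.seed)

        def glorot(shape, fan_in, fan_out):
            # Glorot-uniform, the standard initializer for conv/dense stacks
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        self.params: dict[str, np.ndarray] = {
            "W1": glorot((k, 1, f1), k, k * f1),
            "b1": np.zeros(f1),
            "W2": glorot((k, f1, f2), k * f1, k * f2),
            "b2": np.zeros(f2),
            "W3": glorot((flat, d), flat, d),
            "b3": np.zeros(d),
            "W4": glorot((d, 1), d, 1),
            "b4": np.zeros(1),
        }

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _conv(a: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # a: (B, L, C_in), w: (K, C_in, C_out) -> (B, L-K+1, C_out), valid
        k = w.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(a, k, axis=1)  # (B, L', C_in, K)
        return np.einsum("blck,kco->blo", win, w) + b

    def _pool(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.config.pool_size
        b, l, c = a.shape
        lt = (l // p) * p
        blocks = a[:, :lt].reshape(b, l // p, p, c)
        arg = blocks.argmax(axis=2)
        return blocks.max(axis=2), arg

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (B, n_features) -> predictions (B,) on the scaled-target scale."""
        x = np.asarray(x, dtype=float)
        a0 = x[:, :, None]
        z1 = self._conv(a0, self.params["W1"], self.params["b1"])
        a1 = np.maximum(z1, 0.0)
        m1, arg1 = self._pool(a1)
        z2 = self._conv(m1, self.params["W2"], self.params["b2"])
        a2 = np.maximum(z2, 0.0)
        m2, arg2 = self._pool(a2)
        flat = m2.reshape(m2.shape[0], -1)
        z3 = flat @ self.params["W3"] + self.params["b3"]
        a3 = np.maximum(z3, 0.0)
        out = (a3 @ self.params["W4"] + self.params["b4"])[:, 0]
        if not keep_cache:
            return out
        cache = dict(a0=a0, z1=z1, a1=a1, m1=m1, arg1=arg1, z2=z2, a2=a2,
                     m2=m2, arg2=arg2, flat=flat, z3=z3, a3=a3)
        return out, cache

    # -- backward -----------------------------------------------------------

    def _conv_backward(self, a_in, w, dz):
        k = w.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(a_in, k, axis=1)
        dw = np.einsum("blck,blo->kco", win, dz)
        db = dz.sum(axis=(0, 1))
        da = np.zeros_like(a_in)
        for kk in range(k):
            da[:, kk : kk + dz.shape[1], :] += np.einsum("blo,co->blc", dz, w[kk])
        return dw, db, da

    def _pool_backward(self, a_shape, arg, dm):
        p = self.config.pool_size
        b, l, c = a_shape
        da = np.zeros((b, l, c))
        npool = dm.shape[1]
        bi = np.arange(b)[:, None, None]
        li = np.arange(npool)[None, :, None] * p + arg
        ci = np.arange(c)[None, None, :]
        np.add.at(da, (bi, li, ci), dm)
        return da

    def gradients(self, x: np.ndarray, y: np.ndarray):
        """MSE loss gradients for one batch; returns (loss, grads dict)."""
        pred, c = self.forward(x, keep_cache=True)
        b = x.shape[0]
        err = pred - y
        loss = float(np.mean(err**2))
        dout = (2.0 / b) * err[:, None]
        g: dict[str, np.ndarray] = {}
        g["W4"] = c["a3"].T @ dout
        g["b4"] = dout.sum(axis=0)
        da3 = dout @ self.params["W4"].T
        dz3 = da3 * (c["z3"] > 0)
        g["W3"] = c["flat"].T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ self.params["W3"].T
        dm2 = dflat.reshape(c["m2"].shape)
        da2 = self._pool_backward(c["a2"].shape, c["arg2"], dm2)
        dz2 = da2 * (c["z2"] > 0)
        g["W2"], g["b2"], dm1 = self._conv_backward(c["m1"], self.params["W2"], dz2)
        da1 = self._pool_backward(c["a1"].shape, c["arg1"], dm1)
        dz1 = da1 * (c["z1"] > 0)
        g["W1"], g["b1"], _ = self._conv_backward(c["a0"], self.params["W1"], dz1)
        return loss, g


@dataclass
class TrainedRegressor:
    """Fitted network plus everything needed to reproduce its predictions."""

    model: CNNRegressor
    config: RegressorConfig
    feature_names: list[str]
    y_min: float
    y_max: float
    history: list[dict] = field(default_factory=list)  # per-epoch train/val MSE
    norm_params: dict[str, tuple[float, float]] | None = None  # feature scaling

    def predict(self, table: DescriptorTable) -> np.ndarray:
        if table.feature_names != self.feature_names:
            missing = sorted(set(self.feature_names) - set(table.feature_names))
            extra = sorted(set(table.feature_names) - set(self.feature_names))
            raise ValueError(
                "feature mismatch between table and trained model; "
                f"missing: {missing or 'none'}; unexpected: {extra or 'none'}; "
                f"order must match training order"
            )
        if table.n_compounds == 0:
            return np.empty(0)
        scaled = self.model.forward(table.values)
        return scaled * (self.y_max - self.y_min) + self.y_min


def build_regressor(n_features: int, config: RegressorConfig | None = None) -> CNNRegressor:
    """Seeded, untrained network for descriptor vectors of length ``n_features``."""
    return CNNRegressor(n_features, config or RegressorConfig())


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: CNNRegressor,
    table: DescriptorTable,
    targets: np.ndarray,
    config: RegressorConfig | None = None,
) -> TrainedRegressor:
    """Fit the network on a (normalized) descriptor table and IC50 targets.

    Targets are min-max scaled to [0, 1] (unless ``target_scaling='none'``),
    split 80/20 into train/validation by the config seed, and optimized with
    Adam; the per-epoch train/validation MSE history (scaled-target scale)
    is recorded.  Fully reproducible for a fixed config.
    """
    config = config or model.config
    y = np.asarray(targets, dtype=float)
    n = table.n_compounds
    if n < 10:
        raise ValueError(f"insufficient data: need >= 10 rows, got {n}")
    if y.shape != (n,):
        raise ValueError("targets must align with table rows")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    if table.n_features != model.n_features:
        raise ValueError(
            f"table has {table.n_features} features, model expects {model.n_features}"
        )

    if config.target_scaling == "minmax":
        y_min, y_max = float(y.min()), float(y.max())
        if y_max == y_min:
            y_max = y_min + 1.0
        ys = (y - y_min) / (y_max - y_min)
    else:
        y_min, y_max = 0.0, 1.0
        ys = y.copy()

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xtr, ytr = table.values[train_idx], ys[train_idx]
    xva, yva = table.values[val_idx], ys[val_idx]

    opt = _Adam(model.params, config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            _, grads = model.gradients(xtr[batch], ytr[batch])
            opt.step(model.params, grads)
        history.append(
            {
                "epoch": epoch,
                "train_mse": mse(ytr, model.forward(xtr)),
                "val_mse": mse(yva, model.forward(xva)),
            }
        )
    return TrainedRegressor(
        model=model,
        config=config,
        feature_names=list(table.feature_names),
        y_min=y_min,
        y_max=y_max,
        history=history,
        norm_params=table.norm_params,
    )


def predict(trained: TrainedRegressor, table: DescriptorTable) -> np.ndarray:
    """Predicted IC50 per row, inverse-scaled to original µg/mL units."""
    return trained.predict(table)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("metrics need at least one observation")
    return y, yhat


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error Σ(y_k − ŷ_k)² / m."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error Σ|y_k − ŷ_k| / m."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def evaluate(trained, table: DescriptorTable, targets: np.ndarray) -> dict[str, float]:
    """{mse, mae} of the model's predictions against measured IC50s."""
    yhat = trained.predict(table)
    return {"mse": mse(targets, yhat), "mae": mae(targets, yhat)}


def metrics_report_to_csv(reports: Mapping[str, Mapping[str, float]], path: str | Path) -> Path:
    """Write per-context metric rows with columns CellLine, MSE, MAE."""
    rows = [
        {"CellLine": name, "MSE": rep["mse"], "MAE": rep["mae"]}
        for name, rep in reports.items()
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["CellLine", "MSE", "MAE"]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(trained: TrainedRegressor, path: str | Path) -> Path:
    payload = {
        "config": asdict(trained.config),
        "n_features": trained.model.n_features,
        "feature_names": trained.feature_names,
        "y_min": trained.y_min,
        "y_max": trained.y_max,
        "history": trained.history,
        "norm_params": (
            {k: list(v) for k, v in trained.norm_params.items()}
            if trained.norm_params is not None else None
        ),
        "params": {k: v.tolist() for k, v in trained.model.params.items()},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def load_checkpoint(path: str | Path) -> TrainedRegressor:
    payload = json.loads(Path(path).read_text())
    cfg_d = payload["config"]
    cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
    config = RegressorConfig(**cfg_d)
    model = CNNRegressor(payload["n_features"], config)
    model.params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    return TrainedRegressor(
        model=model,
        config=config,
        feature_names=list(payload["feature_names"]),
        y_min=payload["y_min"],
        y_max=payload["y_max"],
        history=payload["history"],
        norm_params=(
            {k: (v[0], v[1]) for k, v in payload["norm_params"].items()}
            if payload.get("norm_params") else None
        ),
    )
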