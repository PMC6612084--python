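"""Feed-forward back-propagation network with momentum (delta rule).

A deliberately small, from-scratch implementation: one hidden layer of
logistic-sigmoid units, a sigmoid output, online (pattern-by-pattern) weight
updates

    dw(t) = -eta * dE/dw + alpha * dw(t-1)

with learning rate eta and momentum alpha, and per-epoch mean-squared-error
tracking

    MSE = (1/Q) * sum_q (T_q - A_q)^2

on the train / validation / test splits.  The network is used to verify that
the defect signal of the designed experiment is learnable and converges
stably — not as a production classifier.

Analytic gradients are validated against central finite differences
(:func:`gradient_check`), which is the module's correctness oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EncodingError,
    StructuralError,
    TrainingError,
)
from .experiment_design import ExperimentPlan

__all__ = [
    "HIDDEN_UNIT_PRESETS",
    "NetworkConfig",
    "TrainingRecord",
    "Network",
    "ConvergenceReport",
    "encode_records",
    "split_data",
    "train",
    "gradient_check",
]

#: Hidden-unit sizing heuristics for a net with 4 inputs and 1 output:
#: average (in+out)/2, summation in+out, doubling 2*(in+out).
HIDDEN_UNIT_PRESETS = {"average": 3, "summation": 5, "doubling": 10}


@dataclass(frozen=True)
class NetworkConfig:
    """Training configuration.

    Defaults mirror the reference verification run: 4 inputs, one hidden
    layer of 5 units (the "summation" sizing rule), 1 output, learning rate
    0.1, momentum 0.1, 500 epochs, 80/10/10 split.
    """

    n_inputs: int = 4
    hidden_units: int = HIDDEN_UNIT_PRESETS["summation"]
    n_outputs: int = 1
    learning_rate: float = 0.1
    momentum: float = 0.1
    epochs: int = 500
    seed: int = 0
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    early_stopping: bool = False
    convergence_tol: float = 1e-4
    convergence_patience: int = 10

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.split), 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"split fractions must sum to 1, got {self.split}")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if min(self.n_inputs, self.hidden_units, self.n_outputs) < 1:
            raise ConfigurationError("layer sizes must be >= 1")


@dataclass(frozen=True)
class TrainingRecord:
    """One encoded run: normalized inputs, target, and its condition id."""

    inputs: tuple[float, ...]
    target: float
    condition_id: int

    def __post_init__(self) -> None:
        if any(not 0.0 <= x <= 1.0 for x in self.inputs):
            raise EncodingError(f"encoded inputs must lie in [0, 1], got {self.inputs}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class Network:
    """A 1-hidden-layer sigmoid network with plain numpy weights.

    Weights are initialized uniformly in [-0.5, 0.5] from the supplied
    generator; ``w1`` has shape (n_inputs, hidden), ``w2`` (hidden,
    n_outputs), with separate bias vectors.
    """

    def __init__(
        self,
        n_inputs: int,
        hidden_units: int,
        n_outputs: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.n_inputs = n_inputs
        self.hidden_units = hidden_units
        self.n_outputs = n_outputs
        self.w1 = rng.uniform(-0.5, 0.5, size=(n_inputs, hidden_units))
        self.b1 = rng.uniform(-0.5, 0.5, size=hidden_units)
        self.w2 = rng.uniform(-0.5, 0.5, size=(hidden_units, n_outputs))
        self.b2 = rng.uniform(-0.5, 0.5, size=n_outputs)

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Forward pass for one pattern; returns (output, hidden activation)."""
        a1 = _sigmoid(x @ self.w1 + self.b1)
        y = _sigmoid(a1 @ self.w2 + self.b2)
        return y, a1

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorized forward pass over a (n, n_inputs) matrix."""
        A1 = _sigmoid(X @ self.w1 + self.b1)
        return _sigmoid(A1 @ self.w2 + self.b2)

    def mse(self, X: np.ndarray, t: np.ndarray) -> float:
        """Mean squared error (1/Q) sum (T_q - A_q)^2 over a set."""
        y = self.predict(X)[:, 0]
        return float(np.mean((y - t) ** 2))

    # -- gradients -------------------------------------------------------

    def gradients(
        self, x: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Analytic gradients of E = 0.5 * (y - t)^2 for one pattern."""
        y, a1 = self.forward(x)
        d2 = (y - t) * y * (1.0 - y)                      # (out,)
        gw2 = np.outer(a1, d2)
        gb2 = d2
        d1 = (self.w2 @ d2) * a1 * (1.0 - a1)             # (hidden,)
        gw1 = np.outer(x, d1)
        gb1 = d1
        return gw1, gb1, gw2, gb2

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path, config: NetworkConfig | None = None) -> None:
        payload = {
            "layer_sizes": [self.n_inputs, self.hidden_units, self.n_outputs],
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
        }
        if config is not None:
            payload["config"] = {
                "learning_rate": config.learning_rate,
                "momentum": config.momentum,
                "epochs": config.epochs,
                "seed": config.seed,
                "split": list(config.split),
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Network":
        payload = json.loads(Path(path).read_text())
        n_in, n_hid, n_out = payload["layer_sizes"]
        net = cls.__new__(cls)
        net.n_inputs, net.hidden_units, net.n_outputs = n_in, n_hid, n_out
        net.w1 = np.asarray(payload["w1"], dtype=float)
        net.b1 = np.asarray(payload["b1"], dtype=float)
        net.w2 = np.asarray(payload["w2"], dtype=float)
        net.b2 = np.asarray(payload["b2"], dtype=float)
        return net


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-epoch MSE curves plus a convergence flag.

    ``convergence_epoch`` is the first epoch (1-based) opening a window of
    ``patience`` consecutive epochs during which the monitored MSE's running
    minimum improves by no more than ``tol`` (a plateau detector: upward
    jitter from online updates does not reset the window, only a real
    improvement does).  The monitored series is the validation curve when a
    validation set exists, otherwise the training curve.
    """

    train_mse: tuple[float, ...]
    val_mse: tuple[float, ...] = ()
    test_mse: tuple[float, ...] = ()
    convergence_epoch: int | None = None
    converged: bool = False

    @property
    def final_train_mse(self) -> float:
        return self.train_mse[-1]

    @property
    def epochs(self) -> int:
        return len(self.train_mse)

    def to_frame(self) -> pd.DataFrame:
        data = {"epoch": np.arange(1, self.epochs + 1), "train_mse": self.train_mse}
        if self.val_mse:
            data["val_mse"] = self.val_mse
        if self.test_mse:
            data["test_mse"] = self.test_mse
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# encoding and splitting


def encode_records(
    runs: pd.DataFrame,
    plan: ExperimentPlan,
    encoding: Literal["proportion", "binary"] = "proportion",
    access_encoding: Literal["ordinal", "onehot"] = "ordinal",
) -> list[TrainingRecord]:
    """Encode per-run records into normalized network inputs and targets.

    Numeric factors are min-max scaled to [0, 1] using their level values;
    categorical factors are ordinal-encoded as level/3 by default, or one-hot
    (three extra columns, changing the input width).  Targets: ``binary``
    maps defective -> 1, good -> 0; ``proportion`` assigns every run of a
    condition that condition's empirical defect rate.
    """
    if encoding not in ("proportion", "binary"):
        raise EncodingError(f"unknown target encoding {encoding!r}")
    if access_encoding not in ("ordinal", "onehot"):
        raise EncodingError(f"unknown access encoding {access_encoding!r}")
    names = list(plan.factor_names)
    if not set(names).issubset(runs.columns) or "outcome" not in runs.columns:
        raise StructuralError(f"per-run table needs columns {names + ['outcome']}")

    cond_rate: dict[int, float] = {}
    if encoding == "proportion":
        for cond, group in runs.groupby("condition"):
            cond_rate[int(cond)] = float((group["outcome"] == "defective").mean())

    scalers = {}
    for factor in plan.factors:
        if factor.is_numeric:
            vals = [float(lv.value) for lv in factor.levels]
            lo, hi = min(vals), max(vals)
            scalers[factor.name] = ("numeric", lo, hi, vals)
        else:
            scalers[factor.name] = ("categorical", None, None, None)

    records: list[TrainingRecord] = []
    for _, row in runs.iterrows():
        xs: list[float] = []
        for factor in plan.factors:
            level = int(row[factor.name])
            if not 1 <= level <= 3:
                raise EncodingError(f"unknown level {level} for factor {factor.name}")
            kind, lo, hi, vals = scalers[factor.name]
            if kind == "numeric":
                xs.append((vals[level - 1] - lo) / (hi - lo))
            elif access_encoding == "ordinal":
                xs.append(level / 3.0)
            else:
                xs.extend(1.0 if level == k else 0.0 for k in (1, 2, 3))
        cond = int(row["condition"])
        if encoding == "binary":
            target = 1.0 if row["outcome"] == "defective" else 0.0
        else:
            target = cond_rate[cond]
        records.append(TrainingRecord(inputs=tuple(xs), target=target, condition_id=cond))
    return records


def split_data(
    records: Sequence[TrainingRecord],
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[TrainingRecord], list[TrainingRecord], list[TrainingRecord]]:
    """Seeded shuffle into train/validation/test with floor-based sizes.

    Validation and test receive floor(n * fraction) records each, the
    remainder goes to train (270 -> 216/27/27).  The split is stratified in
    the weak sense that every condition present in the data ends up with at
    least one training record (repaired by swapping if the shuffle leaves a
    condition out of train).
    """
    n = len(records)
    if n < 10:
        raise StructuralError(f"need at least 10 records to split, got {n}")
    if not math.isclose(sum(split), 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"split fractions must sum to 1, got {split}")
    n_val = int(n * split[1])
    n_test = int(n * split[2])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = list(order[:n_val])
    test_idx = list(order[n_val : n_val + n_test])
    train_idx = list(order[n_val + n_test :])

    # repair stratification: every condition must appear in train
    train_conds = {records[i].condition_id for i in train_idx}
    for pool in (val_idx, test_idx):
        for pos, i in enumerate(pool):
            cond = records[i].condition_id
            if cond not in train_conds:
                # swap with a train record whose condition is redundantly covered
                counts: dict[int, int] = {}
                for j in train_idx:
                    counts[records[j].condition_id] = counts.get(records[j].condition_id, 0) + 1
                donor_pos = max(
                    range(len(train_idx)), key=lambda k: counts[records[train_idx[k]].condition_id]
                )
                pool[pos], train_idx[donor_pos] = train_idx[donor_pos], i
                train_conds = {records[j].condition_id for j in train_idx}

    pick = lambda idx: [records[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


# ---------------------------------------------------------------------------
# training


def _as_arrays(records: Sequence[TrainingRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([r.inputs for r in records], dtype=float)
    t = np.array([r.target for r in records], dtype=float)
    return X, t


def train(
    config: NetworkConfig,
    train_records: Sequence[TrainingRecord],
    val_records: Sequence[TrainingRecord] = (),
    test_records: Sequence[TrainingRecord] = (),
) -> tuple[Network, ConvergenceReport]:
    """Train by online delta rule with momentum; returns net + MSE curves.

    One generator seeded from ``config.seed`` drives first the weight
    initialization and then the per-epoch pattern shuffles, so training is
    bit-reproducible given (seed, config, data order).  A non-finite loss
    aborts with :class:`TrainingError` naming the epoch.
    """
    if not train_records:
        raise StructuralError("training set is empty")
    width = len(train_records[0].inputs)
    if width != config.n_inputs:
        config = replace(config, n_inputs=width)

    rng = np.random.default_rng(config.seed)
    net = Network(config.n_inputs, config.hidden_units, config.n_outputs, rng=rng)

    Xtr, ttr = _as_arrays(train_records)
    sets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(val_records):
        sets["val"] = _as_arrays(val_records)
    if len(test_records):
        sets["test"] = _as_arrays(test_records)

    eta, alpha = config.learning_rate, config.momentum
    vw1 = np.zeros_like(net.w1)
    vb1 = np.zeros_like(net.b1)
    vw2 = np.zeros_like(net.w2)
    vb2 = np.zeros_like(net.b2)

    curves: dict[str, list[float]] = {"train": [], "val": [], "test": []}
    monitor_name = "val" if "val" in sets else "train"
    run_min = math.inf
    stable = 0
    convergence_epoch: int | None = None

    n = len(train_records)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for i in order:
            x = Xtr[i]
            gw1, gb1, gw2, gb2 = net.gradients(x, ttr[i])
            vw1 = -eta * gw1 + alpha * vw1
            vb1 = -eta * gb1 + alpha * vb1
            vw2 = -eta * gw2 + alpha * vw2
            vb2 = -eta * gb2 + alpha * vb2
            net.w1 += vw1
            net.b1 += vb1
            net.w2 += vw2
            net.b2 += vb2

        train_mse = net.mse(Xtr, ttr)
        if not math.isfinite(train_mse):
            raise TrainingError(f"training diverged at epoch {epoch}", epoch=epoch)
        curves["train"].append(train_mse)
        for name, (X, t) in sets.items():
            curves[name].append(net.mse(X, t))

        monitored = curves[monitor_name][-1]
        if monitored < run_min - config.convergence_tol:
            run_min = monitored
            stable = 0
        else:
            run_min = min(run_min, monitored)
            stable += 1
            if stable >= config.convergence_patience and convergence_epoch is None:
                convergence_epoch = epoch - config.convergence_patience + 1
                if config.early_stopping:
                    break

    report = ConvergenceReport(
        train_mse=tuple(curves["train"]),
        val_mse=tuple(curves["val"]),
        test_mse=tuple(curves["test"]),
        convergence_epoch=convergence_epoch,
        converged=convergence_epoch is not None,
    )
    return net, report


def gradient_check(
    network: Network,
    inputs: Sequence[float] | np.ndarray,
    target: float,
    epsilon: float = 1e-5,
) -> float:
    """Max deviation between analytic and central finite-difference gradients.

    The deviation per weight is relative (|a - f| / max(|a|, |f|)) where
    either gradient is appreciably non-zero, and absolute where both vanish,
    so zero-gradient configurations remain well-defined.
    """
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    x = np.asarray(inputs, dtype=float)

    def loss() -> float:
        y, _ = network.forward(x)
        return float(0.5 * np.sum((y - target) ** 2))

    analytic = network.gradients(x, target)
    params = (network.w1, network.b1, network.w2, network.b2)
    worst = 0.0
    for arr, grad in zip(params, analytic):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + epsilon
            up = loss()
            arr[idx] = orig - epsilon
            down = loss()
            arr[idx] = orig
            fd = (up - down) / (2.0 * epsilon)
            a = float(grad[idx])
            denom = max(abs(a), abs(fd))
            dev = abs(a - fd) / denom if denom > 1e-10 else abs(a - fd)
            worst = max(worst, dev)
    return worst
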