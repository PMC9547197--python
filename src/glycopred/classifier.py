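"""Feed-forward binary classifier for lectin-high vs lectin-low cells.

The network has four hidden layers (128, 64, 16, 8 units). The first three
are each followed by a leaky rectifier (negative slope 0.01), dropout
(0.4, 0.4, 0.2) and batch normalization; the fourth feeds a 1-unit output
layer with a sigmoid, yielding the probability of the lectin-high class.
Training minimizes binary cross-entropy with Adam, mini-batches of 128 and a
cosine-annealed learning rate starting at 1e-4; the checkpoint with the best
validation loss is returned. Everything is implemented on numpy so the
attribution module can read per-layer pre-activations and folded batch-norm
parameters directly.

Two ensemble baselines (a 500-tree depth-2 random forest and a 300-round
AdaBoost with learning rate 0.1) are trained through scikit-learn on the same
splits for comparison.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "MLPSpec",
    "TrainConfig",
    "Metrics",
    "MLPClassifier",
    "TrainingDivergenceError",
    "build_mlp",
    "train_mlp",
    "predict_proba",
    "bce_loss",
    "evaluate",
    "train_baselines",
]

_EPS_PROB = 1e-7  # probability clip inside the cross-entropy
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class TrainingDivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of the classifier."""

    input_dim: int
    hidden_sizes: tuple[int, ...] = (128, 64, 16, 8)
    dropout_probs: tuple[float, ...] = (0.4, 0.4, 0.2)
    negative_slope: float = 0.01

    def validate(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if len(self.hidden_sizes) != 4:
            raise ValueError("exactly 4 hidden layers required")
        if len(self.dropout_probs) != 3:
            raise ValueError("dropout applies after hidden layers 1-3 only")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    initial_learning_rate: float = 1e-4
    max_epochs: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class Metrics:
    """Per-split performance. Accuracies are class-conditional recalls."""

    accuracy_high: float
    accuracy_low: float
    mean_bce_loss: float
    roc_auc: float | None
    f1_positive: float

    def to_dict(self) -> dict:
        return {
            "accuracy_high": self.accuracy_high,
            "accuracy_low": self.accuracy_low,
            "mean_bce_loss": self.mean_bce_loss,
            "roc_auc": self.roc_auc,
            "f1_positive": self.f1_positive,
        }


def _leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPClassifier:
    """Numpy multilayer perceptron with dropout and batch normalization.

    Linear layers: input -> 128 -> 64 -> 16 -> 8 -> 1. Blocks 1-3 apply
    leaky ReLU, dropout and batch norm after the linear map; block 4 is
    linear only; the output layer is linear followed by a sigmoid.
    """

    def __init__(self, spec: MLPSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = [spec.input_dim, *spec.hidden_sizes, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)  # fan-in-scaled uniform init
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))
        # batch-norm state for blocks 1-3
        self.bn_dims = spec.hidden_sizes[:3]
        self.gamma = [np.ones(d) for d in self.bn_dims]
        self.beta = [np.zeros(d) for d in self.bn_dims]
        self.running_mean = [np.zeros(d) for d in self.bn_dims]
        self.running_var = [np.ones(d) for d in self.bn_dims]

    # ---- parameter bookkeeping -------------------------------------------------

    @property
    def n_dense_hidden_parameters(self) -> int:
        """Weights + biases of the four hidden layers (no output layer)."""
        return int(sum(w.size + v.size for w, v in zip(self.W[:4], self.b[:4])))

    @property
    def n_batchnorm_parameters(self) -> int:
        return int(2 * sum(self.bn_dims))

    @property
    def n_parameters(self) -> int:
        dense = sum(w.size + v.size for w, v in zip(self.W, self.b))
        return int(dense + self.n_batchnorm_parameters)

    def state_dict(self) -> dict:
        return {
            "W": [w.copy() for w in self.W],
            "b": [v.copy() for v in self.b],
            "gamma": [g.copy() for g in self.gamma],
            "beta": [v.copy() for v in self.beta],
            "running_mean": [m.copy() for m in self.running_mean],
            "running_var": [v.copy() for v in self.running_var],
        }

    def load_state_dict(self, state: dict) -> None:
        self.W = [w.copy() for w in state["W"]]
        self.b = [v.copy() for v in state["b"]]
        self.gamma = [g.copy() for g in state["gamma"]]
        self.beta = [v.copy() for v in state["beta"]]
        self.running_mean = [m.copy() for m in state["running_mean"]]
        self.running_var = [v.copy() for v in state["running_var"]]

    def save(self, path) -> None:
        """Self-describing checkpoint: spec + parameters + buffers."""
        arrays = {}
        for key, vals in self.state_dict().items():
            for i, a in enumerate(vals):
                arrays[f"{key}__{i}"] = a
        np.savez(
            path,
            __input_dim=np.asarray(self.spec.input_dim),
            __seed=np.asarray(self.seed),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "MLPClassifier":
        with np.load(path) as data:
            spec = MLPSpec(input_dim=int(data["__input_dim"]))
            model = cls(spec, seed=int(data["__seed"]))
            state = {k: [] for k in ("W", "b", "gamma", "beta", "running_mean", "running_var")}
            for key in state:
                i = 0
                while f"{key}__{i}" in data:
                    state[key].append(data[f"{key}__{i}"])
                    i += 1
            model.load_state_dict(state)
        return model

    # ---- forward / backward ----------------------------------------------------

    def _check_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"feature matrix has shape {X.shape}, expected (*, {self.spec.input_dim})"
            )
        return X

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ):
        """Return (probabilities, cache). Training mode uses batch statistics,
        inverted dropout, and updates the running batch-norm buffers."""
        X = self._check_features(X)
        slope = self.spec.negative_slope
        cache = {"X": X, "z": [], "a": [], "mask": [], "bn": []}
        h = X
        for i in range(3):
            z = h @ self.W[i] + self.b[i]
            a = _leaky_relu(z, slope)
            cache["z"].append(z)
            cache["a"].append(a)
            if training:
                p = self.spec.dropout_probs[i]
                if p > 0:
                    mask = (rng.random(a.shape) >= p) / (1.0 - p)
                    a = a * mask
                else:
                    mask = None
                cache["mask"].append(mask)
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                self.running_mean[i] = (1 - _BN_MOMENTUM) * self.running_mean[i] + _BN_MOMENTUM * mu
                n = max(a.shape[0], 2)
                unbiased = var * n / (n - 1)
                self.running_var[i] = (
                    (1 - _BN_MOMENTUM) * self.running_var[i] + _BN_MOMENTUM * unbiased
                )
            else:
                cache["mask"].append(None)
                mu = self.running_mean[i]
                var = self.running_var[i]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (a - mu) * inv_std
            cache["bn"].append({"x": a, "xhat": xhat, "inv_std": inv_std, "mu": mu})
            h = self.gamma[i] * xhat + self.beta[i]
        z4 = h @ self.W[3] + self.b[3]
        z5 = z4 @ self.W[4] + self.b[4]
        cache["h3"] = h
        cache["z4"] = z4
        p = _sigmoid(z5[:, 0])
        cache["p"] = p
        return p, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities (dropout off, running BN statistics);
        each row is scored independently of batch composition."""
        p, _ = self.forward(X, training=False)
        return p

    def first_layer_preactivation(self, X: np.ndarray) -> np.ndarray:
        return self._check_features(X) @ self.W[0] + self.b[0]

    def predict_proba_from_z1(self, z1: np.ndarray) -> np.ndarray:
        """Inference from a precomputed first-layer pre-activation.

        Used by permutation importance: permuting one input column only
        shifts z1 by an outer product, so the first (and largest) matrix
        product need not be recomputed per permutation.
        """
        slope = self.spec.negative_slope
        h = _leaky_relu(z1, slope)
        h = self.gamma[0] * (h - self.running_mean[0]) / np.sqrt(
            self.running_var[0] + _BN_EPS
        ) + self.beta[0]
        for i in (1, 2):
            z = h @ self.W[i] + self.b[i]
            a = _leaky_relu(z, slope)
            h = self.gamma[i] * (a - self.running_mean[i]) / np.sqrt(
                self.running_var[i] + _BN_EPS
            ) + self.beta[i]
        z5 = (h @ self.W[3] + self.b[3]) @ self.W[4] + self.b[4]
        return _sigmoid(z5[:, 0])

    def _backward(self, cache: dict, y: np.ndarray) -> dict:
        """Gradients of mean BCE w.r.t. all parameters (training mode)."""
        X = cache["X"]
        n = X.shape[0]
        slope = self.spec.negative_slope
        grads = {"W": [None] * 5, "b": [None] * 5, "gamma": [None] * 3, "beta": [None] * 3}

        dz5 = ((cache["p"] - y) / n)[:, None]
        grads["W"][4] = cache["z4"].T @ dz5
        grads["b"][4] = dz5.sum(axis=0)
        dz4 = dz5 @ self.W[4].T
        grads["W"][3] = cache["h3"].T @ dz4
        grads["b"][3] = dz4.sum(axis=0)
        dh = dz4 @ self.W[3].T

        for i in (2, 1, 0):
            bn = cache["bn"][i]
            xhat, inv_std = bn["xhat"], bn["inv_std"]
            grads["gamma"][i] = (dh * xhat).sum(axis=0)
            grads["beta"][i] = dh.sum(axis=0)
            dxhat = dh * self.gamma[i]
            m = xhat.shape[0]
            dx = (
                inv_std
                / m
                * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
            )
            mask = cache["mask"][i]
            if mask is not None:
                dx = dx * mask
            da = dx
            dz = da * np.where(cache["z"][i] >= 0, 1.0, slope)
            prev = X if i == 0 else self.gamma[i - 1] * cache["bn"][i - 1]["xhat"] + self.beta[i - 1]
            grads["W"][i] = prev.T @ dz
            grads["b"][i] = dz.sum(axis=0)
            dh = dz @ self.W[i].T
        return grads


def build_mlp(spec: MLPSpec, seed: int = 0) -> MLPClassifier:
    """Construct an untrained classifier with deterministic initialization."""
    return MLPClassifier(spec, seed=seed)


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy in nats, probabilities clipped away from 0/1."""
    p = np.clip(np.asarray(p, dtype=float), _EPS_PROB, 1.0 - _EPS_PROB)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "validation_loss": self.validation_loss,
            "learning_rate": self.learning_rate,
            "best_epoch": self.best_epoch,
        }


class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train_mlp(
    model: MLPClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[MLPClassifier, TrainingHistory]:
    """Train with Adam + cosine-annealed learning rate; keep the best
    validation-loss checkpoint.

    Dropout and batch-norm run in training mode only during optimization;
    all evaluation (including the per-epoch validation loss) is done in
    inference mode.
    """
    config.validate()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(config.seed)
    params = model.W + model.b + model.gamma + model.beta
    optimizer = _Adam([p.shape for p in params])
    history = TrainingHistory()
    best_state = model.state_dict()
    best_loss = np.inf

    n = X_train.shape[0]
    for epoch in range(config.max_epochs):
        lr = config.initial_learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * epoch / config.max_epochs)
        )
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            if idx.shape[0] < 2:
                continue  # batch norm needs >= 2 rows
            p, cache = model.forward(X_train[idx], training=True, rng=rng)
            loss = bce_loss(p, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            epoch_losses.append(loss)
            grads = model._backward(cache, y_train[idx])
            flat_grads = grads["W"] + grads["b"] + grads["gamma"] + grads["beta"]
            optimizer.step(params, flat_grads, lr)
        val_loss = bce_loss(model.predict_proba(X_val), y_val)
        if not np.isfinite(val_loss):
            raise TrainingDivergenceError(epoch)
        history.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        history.validation_loss.append(val_loss)
        history.learning_rate.append(float(lr))
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
    model.load_state_dict(best_state)
    return model, history


def predict_proba(model: MLPClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def evaluate(probabilities, labels, threshold: float = 0.5) -> Metrics:
    """Class-conditional accuracies, mean BCE, ROC AUC and positive-class F1.

    With a single-class label vector the AUC is undefined and reported as
    ``None``; all other metrics are still returned.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")

    pred = (p >= threshold).astype(int)
    high = y == 1
    low = y == 0
    acc_high = float(pred[high].mean()) if high.any() else float("nan")
    acc_low = float((1 - pred[low]).mean()) if low.any() else float("nan")
    auc = float(roc_auc_score(y, p)) if high.any() and low.any() else None
    f1 = float(f1_score(y, pred, pos_label=1, zero_division=0))
    return Metrics(
        accuracy_high=acc_high,
        accuracy_low=acc_low,
        mean_bce_loss=bce_loss(p, y),
        roc_auc=auc,
        f1_positive=f1,
    )


def train_baselines(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> dict[str, Metrics]:
    """Random forest (500 trees, depth 2) and AdaBoost (300 rounds, lr 0.1)."""
    forest = RandomForestClassifier(n_estimators=500, max_depth=2, random_state=seed, n_jobs=1)
    boost = AdaBoostClassifier(n_estimators=300, learning_rate=0.1, random_state=seed)
    out = {}
    for name, clf in (("random_forest", forest), ("adaboost", boost)):
        clf.fit(X_train, y_train)
        p = clf.predict_proba(X_test)[:, 1]
        out[name] = evaluate(p, y_test)
    return out
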