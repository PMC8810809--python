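"""Shallow dense neural network: forward pass, backprop, mini-batch training.

The regression head is deliberately small — input of 9 fields (3 NIR bands +
6 medical features), two sigmoid hidden layers of 50 and 30 nodes, and a
single rectified-linear output node predicting glucose scaled by the upper
detection limit (400 mg/dL).  Everything is plain numpy so that gradients can
be verified against finite differences and training is deterministic under a
seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkParameters",
    "TrainingConfig",
    "FeatureScaler",
    "init_params",
    "forward",
    "forward_activations",
    "loss_and_gradients",
    "train",
]

DEFAULT_LAYER_SIZES = (9, 50, 30, 1)


def _sigmoid(z):
    # stable: never exponentiates a large positive argument
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NetworkParameters:
    """Weights and biases of the dense network.

    ``weights[i]`` has shape (fan_in, fan_out); hidden activations are sigmoid
    and the output activation is a rectifier (or a sigmoid for the optional
    binary head).
    """

    weights: list
    biases: list
    output_activation: str = "relu"

    def __post_init__(self):
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float).ravel() for b in self.biases]
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up layer by layer")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or w.shape[1] != b.shape[0]:
                raise ValueError(f"layer {i}: weight {w.shape} incompatible with bias {b.shape}")
            if i > 0 and self.weights[i - 1].shape[1] != w.shape[0]:
                raise ValueError(f"layer {i}: fan-in mismatch")
        if not all(np.all(np.isfinite(w)) for w in self.weights) or not all(
            np.all(np.isfinite(b)) for b in self.biases
        ):
            raise ValueError("parameters must be finite")
        if self.output_activation not in ("relu", "sigmoid"):
            raise ValueError("output_activation must be 'relu' or 'sigmoid'")

    @property
    def layer_sizes(self) -> tuple:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.output_activation,
        )

    # -- flat-vector view used by the finite-difference checks -------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights] + [b for b in self.biases])

    def from_vector(self, vec: np.ndarray) -> "NetworkParameters":
        vec = np.asarray(vec, dtype=float)
        ws, bs, k = [], [], 0
        for w in self.weights:
            ws.append(vec[k : k + w.size].reshape(w.shape))
            k += w.size
        for b in self.biases:
            bs.append(vec[k : k + b.size])
            k += b.size
        if k != vec.size:
            raise ValueError("vector length mismatch")
        return NetworkParameters(ws, bs, self.output_activation)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the mini-batch gradient-descent fit.

    The loss is mean-squared error on glucose divided by ``target_scaling``
    (the 400 mg/dL upper detection limit), which keeps targets in roughly
    [0.15, 1] where the sigmoid hidden layers have healthy gradients.  A
    fraction ``validation_fraction`` of the training set — stratified on
    glucose quartiles so the sparse high-glucose tail is represented — is held
    out; early stopping and the choice among restarts select the parameters
    with the lowest mean relative error on that split, the scale on which
    glucometer accuracy is judged.
    """

    learning_rate: float = 0.05
    epochs: int = 3000
    batch_size: int = 32
    seed: int = 0
    init_scale: float = 0.5
    momentum: float = 0.9
    #: cap on the global gradient norm per batch; guards the rectified output
    #: node against a single catastrophic step into its dead region
    grad_clip: float = 1.0
    #: final learning rate as a fraction of learning_rate (cosine schedule
    #: over the epoch budget); 1.0 disables the decay
    lr_decay: float = 0.1
    target_scaling: float = 400.0
    validation_fraction: float = 0.1
    early_stop_patience: int = 250
    eval_every: int = 10
    #: independent seeded restarts; the run with the best validation loss wins
    n_restarts: int = 3
    #: "mse" or "relative_mse" (squared error weighted by 1/target**2)
    loss: str = "mse"
    hidden_sizes: tuple = (50, 30)
    output_activation: str = "relu"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.target_scaling <= 0:
            raise ValueError("target_scaling must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.loss not in ("mse", "relative_mse"):
            raise ValueError("loss must be 'mse' or 'relative_mse'")

    def replace(self, **kwargs) -> "TrainingConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        degenerate = sd == 0
        if np.any(degenerate):
            warnings.warn(
                f"{int(degenerate.sum())} feature(s) have zero variance; scaling with sd=1",
                stacklevel=2,
            )
            sd = np.where(degenerate, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def init_params(
    n_inputs: int,
    config: TrainingConfig,
    rng=None,
) -> NetworkParameters:
    """Randomized initialization: layer weights uniform in
    [-init_scale/sqrt(fan_in), +init_scale/sqrt(fan_in)].

    The fan-in scaling keeps every pre-activation of order one regardless of
    layer width; the output bias starts at 0.5 (mid-range of the scaled
    target) so the rectified output node begins in its active region instead
    of dead at zero.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    sizes = (n_inputs,) + tuple(config.hidden_sizes) + (1,)
    weights = [
        rng.uniform(-config.init_scale, config.init_scale, size=(sizes[i], sizes[i + 1]))
        / np.sqrt(sizes[i])
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    biases[-1][:] = 0.5
    return NetworkParameters(weights, biases, config.output_activation)


def forward_activations(X: np.ndarray, params: NetworkParameters):
    """Forward pass returning (pre-activations, activations) per layer.

    ``X`` is (n, d) of already-scaled features; output is on the scaled target
    scale (divide-by-400 convention handled by the caller).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.weights[0].shape[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    zs, activations = [], [X]
    a = X
    n_layers = len(params.weights)
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        zs.append(z)
        if i < n_layers - 1:
            a = _sigmoid(z)
        elif params.output_activation == "relu":
            a = np.maximum(z, 0.0)
        else:
            a = _sigmoid(z)
        activations.append(a)
    return zs, activations


def forward(X: np.ndarray, params: NetworkParameters) -> np.ndarray:
    """Network output for scaled inputs; shape (n,), always >= 0."""
    _, activations = forward_activations(X, params)
    return activations[-1][:, 0]


def loss_and_gradients(params: NetworkParameters, X: np.ndarray, t: np.ndarray,
                       sample_weight=None):
    """(Weighted) mean-squared error on the scaled target and its analytic
    gradients.

    Returns ``(loss, grad_weights, grad_biases)`` for
    ``loss = mean(w_i * (y_i - t_i)**2)`` with unit weights by default.  The
    rectifier derivative at exactly zero is taken as 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n = X.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float).ravel()
    zs, activations = forward_activations(X, params)
    y = activations[-1][:, 0]
    resid = y - t
    loss = float(np.mean(w * resid**2))

    # output-layer delta
    if params.output_activation == "relu":
        dact = (zs[-1][:, 0] > 0).astype(float)
    else:
        s = activations[-1][:, 0]
        dact = s * (1.0 - s)
    delta = (2.0 / n) * w * resid * dact  # (n,)
    delta = delta[:, None]

    grad_w = [None] * len(params.weights)
    grad_b = [None] * len(params.biases)
    for i in range(len(params.weights) - 1, -1, -1):
        grad_w[i] = activations[i].T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            a = activations[i]  # sigmoid layer output
            delta = (delta @ params.weights[i].T) * a * (1.0 - a)
    return loss, grad_w, grad_b


def train(
    X: np.ndarray,
    glucose: np.ndarray,
    config: TrainingConfig | None = None,
    scaler: FeatureScaler | None = None,
    rng=None,
):
    """Fit the network by mini-batch gradient descent with momentum.

    ``X`` is the raw (n, d) feature matrix and ``glucose`` the reference values
    in mg/dL.  Features are standardized with ``scaler`` (fitted here on the
    training rows if not supplied); the target is divided by
    ``config.target_scaling``.  A validation split drives early stopping; the
    parameters achieving the best validation loss are returned.

    Returns ``(params, scaler, history)`` where ``history`` is a dict with
    ``train_loss`` / ``val_loss`` checkpoint arrays.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(glucose, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("training set must be nonempty")
    if X.shape[0] != g.shape[0]:
        raise ValueError("feature matrix and targets must have equal length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(g))):
        raise ValueError("training data must be finite")

    rng = np.random.default_rng(config.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    n = X.shape[0]
    # stratify the early-stopping split on glucose quartiles so the sparse
    # high-glucose tail is represented in the validation set
    val_parts, tr_parts = [], []
    for q in np.array_split(np.argsort(g, kind="stable"), min(4, n)):
        q = q[rng.permutation(q.size)]
        k = int(round(config.validation_fraction * q.size))
        val_parts.append(q[:k])
        tr_parts.append(q[k:])
    val_idx = np.concatenate(val_parts)
    tr_idx = np.concatenate(tr_parts)
    if tr_idx.size == 0:
        val_idx, tr_idx = val_idx[:-1], val_idx[-1:]

    if scaler is None:
        scaler = FeatureScaler.fit(X[tr_idx])
    Xs = scaler.transform(X)
    t = g / config.target_scaling
    Xtr, ttr = Xs[tr_idx], t[tr_idx]
    Xval, tval = Xs[val_idx], t[val_idx]

    best_params, best_hist, best_val = None, None, np.inf
    for _ in range(max(config.n_restarts, 1)):
        params, history, val_loss = _train_once(Xtr, ttr, Xval, tval, config, rng)
        if val_loss < best_val:
            best_params, best_hist, best_val = params, history, val_loss
    return best_params, scaler, best_hist


def _val_metric(y, t):
    """Model-selection criterion: mean relative error on the validation split.

    Relative (rather than squared) error mirrors how glucometer accuracy is
    judged clinically, where tolerances above 100 mg/dL are percentages of the
    reference; selecting on it keeps the sparse high-glucose tail from being
    ignored.  The training loss itself remains plain MSE.
    """
    return float(np.mean(np.abs(y - t) / np.maximum(t, 1e-6)))


def _train_once(Xtr, ttr, Xval, tval, config: TrainingConfig, rng):
    """One seeded training run; returns (params, history, best validation metric)."""
    if config.loss == "relative_mse":
        wtr = 1.0 / np.maximum(ttr, 1e-3) ** 2
        wtr = wtr / wtr.mean()
    else:
        wtr = np.ones_like(ttr)
    params = init_params(Xtr.shape[1], config, rng)
    vel_w = [np.zeros_like(w) for w in params.weights]
    vel_b = [np.zeros_like(b) for b in params.biases]

    best = params.copy()
    best_val = np.inf
    since_best = 0
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    n_tr = Xtr.shape[0]
    n_val = Xval.shape[0]

    for epoch in range(config.epochs):
        # cosine learning-rate decay from lr to lr * lr_decay
        frac = epoch / max(config.epochs - 1, 1)
        lr = config.learning_rate * (
            config.lr_decay + (1.0 - config.lr_decay) * 0.5 * (1.0 + np.cos(np.pi * frac))
        )
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, gw, gb = loss_and_gradients(params, Xtr[idx], ttr[idx], wtr[idx])
            if config.grad_clip > 0:
                gnorm = np.sqrt(
                    sum(float(np.sum(g_**2)) for g_ in gw)
                    + sum(float(np.sum(g_**2)) for g_ in gb)
                )
                if gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    gw = [g_ * scale for g_ in gw]
                    gb = [g_ * scale for g_ in gb]
            for i in range(len(params.weights)):
                vel_w[i] = config.momentum * vel_w[i] - lr * gw[i]
                vel_b[i] = config.momentum * vel_b[i] - lr * gb[i]
                params.weights[i] += vel_w[i]
                params.biases[i] += vel_b[i]

        if epoch % config.eval_every == 0 or epoch == config.epochs - 1:
            if params.output_activation == "relu" and np.all(forward(Xtr, params) == 0.0):
                # output rectifier is dead on the whole training split, which
                # is an absorbing state under gradient descent: restart from a
                # fresh (still seeded) initialization
                params = init_params(Xtr.shape[1], config, rng)
                vel_w = [np.zeros_like(w) for w in params.weights]
                vel_b = [np.zeros_like(b) for b in params.biases]
            ytr = forward(Xtr, params)
            tr_loss = float(np.mean((ytr - ttr) ** 2))
            if n_val > 0:
                val_loss = _val_metric(forward(Xval, params), tval)
            else:
                val_loss = _val_metric(ytr, ttr)
            history["epoch"].append(epoch)
            history["train_loss"].append(tr_loss)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best = params.copy()
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break

    history = {k: np.asarray(v) for k, v in history.items()}
    return best, history, best_val


# ---------------------------------------------------------------------------
# plain-text serialization

def params_to_dict(params: NetworkParameters, scaler: FeatureScaler, config: TrainingConfig,
                   feature_names=None) -> dict:
    return {
        "layer_sizes": list(params.layer_sizes),
        "output_activation": params.output_activation,
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
        "feature_mean": scaler.mean.tolist(),
        "feature_sd": scaler.sd.tolist(),
        "target_scaling": config.target_scaling,
        "feature_names": list(feature_names) if feature_names is not None else None,
    }


def save_params(path, params: NetworkParameters, scaler: FeatureScaler,
                config: TrainingConfig, feature_names=None) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(params, scaler, config, feature_names), fh, indent=1)


def load_params(path):
    """Load a serialized model: returns (params, scaler, target_scaling, feature_names)."""
    with open(path) as fh:
        d = json.load(fh)
    params = NetworkParameters(
        [np.asarray(w) for w in d["weights"]],
        [np.asarray(b) for b in d["biases"]],
        d.get("output_activation", "relu"),
    )
    scaler = FeatureScaler(np.asarray(d["feature_mean"]), np.asarray(d["feature_sd"]))
    return params, scaler, float(d["target_scaling"]), d.get("feature_names")
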