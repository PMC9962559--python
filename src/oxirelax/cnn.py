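"""1-D dilated convolutional network for oxidation-class prediction.

The classifier maps a raw (preprocessed) CPMG relaxation curve directly
to one of three ordinal oxidation classes, skipping the inverse Laplace
transform entirely.  Architecture: four dilated 1-D convolution layers
(ReLU after each), a global max-pool over the feature length, one hidden
fully connected layer (ReLU) and a softmax output over the three
classes.  Dilations (1, 2, 4, 8 by default) widen the receptive field
geometrically at constant parameter count, and the global max-pool makes
the network indifferent to the raw input length — curves of any echo
count are first block-mean pooled to a fixed working length.

Training minimizes categorical cross-entropy with the Adam optimizer
(adaptive moment estimation).  The whole network — forward pass,
backpropagation and optimizer — is implemented directly on numpy
arrays, which keeps desk-scale training (hundreds of curves, a few
hundred epochs) to a couple of CPU-minutes and makes runs exactly
reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .curves import RelaxationCurve
from .errors import ConfigurationError, DegenerateInputError, InvalidInputError
from .labels import CLASS_ORDER


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the dilated-CNN classifier.

    The architecture family (4 dilated convolution layers, ReLU,
    max-pooling, dense classifier head, 3-way softmax) is fixed; filter
    counts, kernel size, dilation rates, dense width, learning rate and
    batch size are free and default to values sized for CPU training.
    """

    n_conv_layers: int = 4
    filters_per_layer: tuple = (16, 16, 32, 32)
    kernel_size: int = 9
    dilation_rates: tuple = (1, 2, 4, 8)
    dense_units: int = 64
    n_classes: int = 3
    target_len: int = 512
    learning_rate: float = 1e-3
    epochs: int = 210
    batch_size: int = 32
    val_fraction: float = 0.15   # used only when train() must split internally
    class_weights: tuple | None = None  # optional per-class loss weights
    seed: int = 0

    def __post_init__(self):
        if not (self.n_conv_layers == len(self.filters_per_layer) == len(self.dilation_rates)):
            raise ConfigurationError(
                "n_conv_layers, filters_per_layer and dilation_rates must agree")
        if self.n_classes != 3:
            raise ConfigurationError("the classifier is a fixed 3-class model")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd and positive")
        if self.receptive_field > self.target_len:
            raise ConfigurationError(
                f"receptive field {self.receptive_field} exceeds target_len {self.target_len}")

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel_size - 1) * int(np.sum(self.dilation_rates))


def preprocess(curve, target_len: int = 512) -> np.ndarray:
    """Normalize a raw curve for the network: resample, then min-max scale.

    Curves longer than ``target_len`` are mean-pooled over near-equal
    blocks (exactly equal when the length divides evenly); shorter curves
    are linearly interpolated up.  The output is scaled to [0, 1] so the
    network never sees the instrument's amplitude units.
    """
    if target_len < 16:
        raise InvalidInputError("target_len must be >= 16")
    a = curve.amplitudes if isinstance(curve, RelaxationCurve) else np.asarray(curve, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise InvalidInputError("curve must be a 1-D array with at least 2 points")
    n = a.size
    if n > target_len:
        if n % target_len == 0:
            a = a.reshape(target_len, n // target_len).mean(axis=1)
        else:
            a = np.array([blk.mean() for blk in np.array_split(a, target_len)])
    elif n < target_len:
        a = np.interp(np.linspace(0, n - 1, target_len), np.arange(n), a)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        raise DegenerateInputError("curve is constant; nothing to normalize")
    return ((a - lo) / (hi - lo)).astype(np.float32)


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


@dataclass
class TrainedModel:
    """Weights plus everything needed to reproduce and apply a training run."""

    config: ModelConfig
    weights: dict
    class_order: tuple = CLASS_ORDER
    training_history: dict = field(default_factory=dict)
    n_parameters: int = 0

    # -- persistence ----------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["class_weights"] = list(cfg["class_weights"]) if cfg["class_weights"] else None
        (out_dir / "config.json").write_text(json.dumps(
            {"config": cfg, "class_order": list(self.class_order),
             "n_parameters": self.n_parameters}, indent=1))
        np.savez(out_dir / "weights.npz", **self.weights)
        if self.training_history:
            hist = self.training_history
            rows = ["epoch,train_acc,train_loss,val_acc,val_loss"]
            for i in range(len(hist["train_loss"])):
                rows.append(f"{i + 1},{hist['train_acc'][i]:.6f},{hist['train_loss'][i]:.6f},"
                            f"{hist['val_acc'][i]:.6f},{hist['val_loss'][i]:.6f}")
            (out_dir / "history.csv").write_text("\n".join(rows) + "\n")
        return out_dir

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "config.json").read_text())
        cfg = meta["config"]
        for key in ("filters_per_layer", "dilation_rates"):
            cfg[key] = tuple(cfg[key])
        cfg["class_weights"] = tuple(cfg["class_weights"]) if cfg["class_weights"] else None
        with np.load(model_dir / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        return cls(config=ModelConfig(**cfg), weights=weights,
                   class_order=tuple(meta["class_order"]),
                   n_parameters=meta.get("n_parameters", 0))


def build_model(config: ModelConfig) -> TrainedModel:
    """Initialize an untrained network (He init for the ReLU layers)."""
    rng = np.random.default_rng(config.seed)
    weights: dict[str, np.ndarray] = {}
    c_in = 1
    k = config.kernel_size
    for i, c_out in enumerate(config.filters_per_layer):
        weights[f"conv{i}_W"] = _he_init(rng, (k * c_in, c_out), k * c_in)
        weights[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
        c_in = c_out
    weights["dense_W"] = _he_init(rng, (c_in, config.dense_units), c_in)
    weights["dense_b"] = np.zeros(config.dense_units, dtype=np.float32)
    # small-variance init for the linear softmax layer
    weights["out_W"] = (rng.standard_normal((config.dense_units, config.n_classes))
                        * np.sqrt(1.0 / config.dense_units)).astype(np.float32)
    weights["out_b"] = np.zeros(config.n_classes, dtype=np.float32)
    n_params = int(sum(w.size for w in weights.values()))
    return TrainedModel(config=config, weights=weights, n_parameters=n_params)


# -- forward / backward -------------------------------------------------
#
# The dilated convolution is computed as a sum over kernel taps,
#   y[:, l, :] = sum_j x_padded[:, l + j*dilation, :] @ W_j + b,
# which works on strided views of the padded input and never
# materializes an im2col patch tensor (it is memory-bound otherwise).


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int, dilation: int):
    """Same-padded dilated 1-D convolution.  x: (B, L, C_in) -> (B, L, C_out)."""
    B, L, _ = x.shape
    pad = (k - 1) * dilation // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    Wr = W.reshape(k, -1, W.shape[1])
    out = np.broadcast_to(b, (B, L, W.shape[1])).copy()
    for j in range(k):
        out += xp[:, j * dilation:j * dilation + L, :] @ Wr[j]
    return out, xp


def _forward(model: TrainedModel, X: np.ndarray, want_cache: bool = False):
    """X: (B, L) in [0,1].  Returns class probabilities (B, 3) [+ cache]."""
    cfg = model.config
    W = model.weights
    a = X[:, :, None].astype(np.float32)  # (B, L, 1)
    cache = {"padded": [], "pre": []}
    for i, dil in enumerate(cfg.dilation_rates):
        z, xp = _conv_forward(a, W[f"conv{i}_W"], W[f"conv{i}_b"], cfg.kernel_size, dil)
        if want_cache:
            cache["padded"].append(xp)
            cache["pre"].append(z)
        a = np.maximum(z, 0.0)
    pooled = a.max(axis=1)                       # global max over length
    argmax = a.argmax(axis=1)                    # (B, C) positions for backprop
    h_pre = pooled @ W["dense_W"] + W["dense_b"]
    h = np.maximum(h_pre, 0.0)
    logits = h @ W["out_W"] + W["out_b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    probs = expz / expz.sum(axis=1, keepdims=True)
    if not want_cache:
        return probs
    cache.update({"conv_out": a, "pool_argmax": argmax, "pooled": pooled,
                  "h_pre": h_pre, "h": h})
    return probs, cache


def _backward(model: TrainedModel, cache, probs, Y_onehot, sample_weight):
    cfg = model.config
    W = model.weights
    B = probs.shape[0]
    grads: dict[str, np.ndarray] = {}
    dlogits = (probs - Y_onehot) * sample_weight[:, None] / B
    grads["out_W"] = cache["h"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dh = dlogits @ W["out_W"].T
    dh_pre = dh * (cache["h_pre"] > 0)
    grads["dense_W"] = cache["pooled"].T @ dh_pre
    grads["dense_b"] = dh_pre.sum(axis=0)
    dpooled = dh_pre @ W["dense_W"].T          # (B, C_last)

    # route the pooled gradient back to each channel's argmax position
    a = cache["conv_out"]
    da = np.zeros_like(a)
    bidx = np.arange(B)[:, None]
    cidx = np.arange(a.shape[2])[None, :]
    da[bidx, cache["pool_argmax"], cidx] = dpooled

    k = cfg.kernel_size
    for i in reversed(range(cfg.n_conv_layers)):
        dz = da * (cache["pre"][i] > 0)        # (B, L, C_out)
        xp = cache["padded"][i]                # (B, L + 2*pad, C_in)
        Bn, L, _ = dz.shape
        c_in = xp.shape[2]
        dil = cfg.dilation_rates[i]
        Wr = W[f"conv{i}_W"].reshape(k, c_in, -1)
        dW = np.empty((k, c_in, dz.shape[2]), dtype=np.float32)
        dxp = np.zeros_like(xp) if i > 0 else None
        for j in range(k):
            sl = xp[:, j * dil:j * dil + L, :]
            dW[j] = np.tensordot(sl, dz, axes=([0, 1], [0, 1]))
            if dxp is not None:
                dxp[:, j * dil:j * dil + L, :] += dz @ Wr[j].T
        grads[f"conv{i}_W"] = dW.reshape(k * c_in, -1)
        grads[f"conv{i}_b"] = dz.sum(axis=(0, 1))
        if i > 0:
            pad = (k - 1) * dil // 2
            da = dxp[:, pad:pad + L, :]
    return grads


def _batched_probs(model: TrainedModel, X: np.ndarray, chunk: int = 256) -> np.ndarray:
    out = [_forward(model, X[i:i + chunk]) for i in range(0, X.shape[0], chunk)]
    return np.concatenate(out, axis=0)


def _xent(probs, y, eps=1e-12):
    return float(-np.mean(np.log(probs[np.arange(y.size), y] + eps)))


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Train the dilated CNN on preprocessed curves.

    ``X`` is (n, target_len) with rows already through :func:`preprocess`;
    ``y`` holds integer class indices into :data:`CLASS_ORDER`.  When no
    validation set is given, a stratified ``val_fraction`` share of the
    training data is held out for the per-epoch history.  Runs are exactly
    reproducible from ``config.seed`` (single-threaded).
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidInputError("X must be (n_samples, length) matching y")
    if np.unique(y).size < 2:
        raise InvalidInputError("training data must contain at least 2 classes")
    if X.shape[1] != config.target_len:
        raise InvalidInputError(
            f"X length {X.shape[1]} != config.target_len {config.target_len}; "
            "run preprocess() first")

    if validation is None:
        from sklearn.model_selection import train_test_split
        X, X_val, y, y_val = train_test_split(
            X, y, test_size=config.val_fraction, stratify=y,
            random_state=int(config.seed) % (2**32))
    else:
        X_val = np.asarray(validation[0], dtype=np.float32)
        y_val = np.asarray(validation[1], dtype=np.int64)

    model = build_model(config)
    W = model.weights
    n = X.shape[0]
    onehot = np.eye(config.n_classes, dtype=np.float32)[y]
    if config.class_weights is not None:
        cw = np.asarray(config.class_weights, dtype=np.float32)
        sample_weight = cw[y]
    else:
        sample_weight = np.ones(n, dtype=np.float32)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in W.items()}
    v = {k: np.zeros_like(v_) for k, v_ in W.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step = 0
    rng = np.random.default_rng(config.seed + 1)
    history = {"train_acc": [], "train_loss": [], "val_acc": [], "val_loss": []}

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        # train metrics are running (pre-update) batch statistics, the usual
        # convention for per-epoch training curves
        loss_sum, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            probs, cache = _forward(model, X[sel], want_cache=True)
            loss_sum += _xent(probs, y[sel]) * sel.size
            correct += int(np.sum(probs.argmax(axis=1) == y[sel]))
            grads = _backward(model, cache, probs, onehot[sel], sample_weight[sel])
            step += 1
            bc1 = 1.0 - beta1 ** step
            bc2 = 1.0 - beta2 ** step
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                W[key] -= lr * (m[key] / bc1) / (np.sqrt(v[key] / bc2) + eps)
        p_va = _batched_probs(model, X_val)
        history["train_loss"].append(loss_sum / n)
        history["train_acc"].append(correct / n)
        history["val_loss"].append(_xent(p_va, y_val))
        history["val_acc"].append(float(np.mean(p_va.argmax(axis=1) == y_val)))

    model.training_history = history
    return model


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of preprocessed curves."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 1:
        X = X[None, :]
    return _batched_probs(model, X)


def predict(model: TrainedModel, curve) -> tuple[str, float]:
    """Classify one raw curve; returns ``(class_label, probability)``.

    The curve may be a :class:`RelaxationCurve` or a raw amplitude vector
    of any length; it is preprocessed to the model's working length.
    Exact probability ties resolve to the earliest class in
    ``model.class_order`` (argmax convention).
    """
    x = preprocess(curve, model.config.target_len)
    probs = predict_proba(model, x)[0]
    idx = int(np.argmax(probs))
    return model.class_order[idx], float(probs[idx])
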