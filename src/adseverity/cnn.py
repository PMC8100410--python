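"""A small 1-D convolutional network for severity classification.

The architecture maps a length-167 feature vector (one patient) through
one convolutional layer (16 filters of length 5, stride 1, zero "same"
padding), a rectifier, a stack of fully connected layers (384, 384, 384
by default) with rectifiers, a final fully connected layer to the 4
severity classes, and a softmax.  Training minimises the multiclass
cross-entropy with plain mini-batch stochastic gradient descent.

The network is implemented directly on NumPy arrays with hand-written
backpropagation, which keeps it dependency-free and makes the gradients
available for finite-difference verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CnnArchitecture",
    "TrainingConfig",
    "CnnModel",
    "softmax",
    "crossentropy_loss",
    "build",
    "init_params",
    "forward",
    "loss_and_grads",
    "train_cnn",
    "predict_cnn",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class CnnArchitecture:
    input_length: int = 167
    n_filters: int = 16
    filter_length: int = 5
    fc_sizes: tuple[int, ...] = (384, 384, 384)  # hidden widths before the output layer
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.input_length < self.filter_length:
            raise ValueError("input_length must be >= filter_length")
        if self.filter_length % 2 != 1:
            raise ValueError("filter_length must be odd for symmetric same-padding")
        if any(w <= 0 for w in self.fc_sizes) or self.n_classes <= 0:
            raise ValueError("layer widths must be positive")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """Input widths of the fully connected stack (conv output flattened first)."""
        return (self.n_filters * self.input_length, *self.fc_sizes, self.n_classes)

    @property
    def n_parameters(self) -> int:
        n = self.n_filters * self.filter_length + self.n_filters
        widths = self.layer_widths
        for w_in, w_out in zip(widths[:-1], widths[1:]):
            n += w_in * w_out + w_out
        return n


@dataclass(frozen=True)
class TrainingConfig:
    iterations: int = 420          # optimizer steps, not epochs
    batch_size: int = 32
    learning_rate: float = 1e-3
    momentum: float = 0.9
    standardize: bool = True       # z-score inputs using training-set statistics
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class CnnModel:
    arch: CnnArchitecture
    params: dict
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None


def softmax(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis (max-subtraction)."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _as_onehot(labels, n_classes: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.ndim == 2:
        return y.astype(float)
    y = y.astype(int).ravel()
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError(f"label index out of range [0, {n_classes})")
    oh = np.zeros((y.size, n_classes))
    oh[np.arange(y.size), y] = 1.0
    return oh


def crossentropy_loss(probabilities: np.ndarray, labels) -> float:
    """Mean over the batch of -log p(true class), with a 1e-12 probability floor."""
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    oh = _as_onehot(labels, p.shape[1])
    if oh.shape != p.shape:
        raise ValueError("probabilities and labels misaligned")
    p_true = (p * oh).sum(axis=1)
    return float(-np.mean(np.log(np.maximum(p_true, _PROB_FLOOR))))


def build(n_features: int, n_classes: int = 4, **overrides) -> CnnArchitecture:
    """Architecture for a given input length; ``overrides`` adjust any field.

    ``fc_sizes=(384, 384)`` reproduces the three-fully-connected-layer
    variant (384, 384, output) of the reference architecture table.
    """
    return CnnArchitecture(input_length=int(n_features), n_classes=int(n_classes),
                           **overrides)


def init_params(arch: CnnArchitecture, seed: int = 0) -> dict:
    """He-style small-variance symmetric initialization; biases zero."""
    rng = np.random.default_rng(seed)
    params = {
        "Wc": rng.normal(0.0, np.sqrt(2.0 / arch.filter_length),
                         (arch.n_filters, arch.filter_length)),
        "bc": np.zeros(arch.n_filters),
    }
    widths = arch.layer_widths
    for li, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
        params[f"W{li}"] = rng.normal(0.0, np.sqrt(2.0 / w_in), (w_out, w_in))
        params[f"b{li}"] = np.zeros(w_out)
    return params


def _conv_windows(X: np.ndarray, k: int) -> np.ndarray:
    """(B, L) -> (B, L, k) sliding windows after symmetric zero 'same' padding."""
    pad = k // 2
    Xp = np.pad(X, ((0, 0), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(Xp, k, axis=1)


def forward(params: dict, X: np.ndarray, arch: CnnArchitecture,
            return_cache: bool = False):
    """Logits for a batch (rows = patients); optionally the backprop cache."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != arch.input_length:
        raise ValueError(f"feature length {X.shape[1]} != input_length {arch.input_length}")
    win = _conv_windows(X, arch.filter_length)                      # B x L x k
    zc = np.einsum("blk,fk->blf", win, params["Wc"]) + params["bc"]  # B x L x F
    ac = np.maximum(zc, 0.0)
    acts = [ac.reshape(X.shape[0], -1)]
    zs = []
    n_fc = len(arch.fc_sizes) + 1
    for li in range(n_fc):
        z = acts[-1] @ params[f"W{li}"].T + params[f"b{li}"]
        zs.append(z)
        if li < n_fc - 1:
            acts.append(np.maximum(z, 0.0))
    logits = zs[-1]
    if return_cache:
        return logits, {"win": win, "zc": zc, "acts": acts, "zs": zs}
    return logits


def loss_and_grads(params: dict, X: np.ndarray, labels, arch: CnnArchitecture
                   ) -> tuple[float, dict]:
    """Cross-entropy of softmax(forward(X)) and its gradient in every parameter."""
    logits, cache = forward(params, X, arch, return_cache=True)
    probs = softmax(logits)
    oh = _as_onehot(labels, arch.n_classes)
    B = probs.shape[0]
    loss = crossentropy_loss(probs, oh)
    grads = {}
    delta = (probs - oh) / B                                        # d loss / d logits
    n_fc = len(arch.fc_sizes) + 1
    for li in range(n_fc - 1, -1, -1):
        a_in = cache["acts"][li]
        grads[f"W{li}"] = delta.T @ a_in
        grads[f"b{li}"] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ params[f"W{li}"]) * (cache["zs"][li - 1] > 0)
    d_flat = delta @ params["W0"]                                   # into the flattened conv output
    d_ac = d_flat.reshape(cache["zc"].shape)
    d_zc = d_ac * (cache["zc"] > 0)
    grads["Wc"] = np.einsum("blf,blk->fk", d_zc, cache["win"])
    grads["bc"] = d_zc.sum(axis=(0, 1))
    return loss, grads


def train_cnn(arch: CnnArchitecture, train_features: np.ndarray, train_labels,
              config: TrainingConfig | None = None) -> tuple[CnnModel, dict]:
    """Mini-batch SGD for ``config.iterations`` steps.

    Returns the model and a trace dict with per-iteration training loss
    and batch accuracy.  Batching and initialization are fully seeded,
    so retraining reproduces the model exactly.
    """
    if config is None:
        config = TrainingConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int).ravel()
    if np.any((y < 0) | (y >= arch.n_classes)):
        raise ValueError(f"labels must lie in [0, {arch.n_classes})")
    mean = sd = None
    if config.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mean) / sd
    rng = np.random.default_rng(config.seed)
    params = init_params(arch, seed=config.seed)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    n = X.shape[0]
    losses, accs = [], []
    for it in range(config.iterations):
        batch = rng.choice(n, size=min(config.batch_size, n), replace=False)
        loss, grads = loss_and_grads(params, X[batch], y[batch], arch)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        for k in params:
            velocity[k] = config.momentum * velocity[k] - config.learning_rate * grads[k]
            params[k] = params[k] + velocity[k]
        losses.append(loss)
        pred = forward(params, X[batch], arch).argmax(axis=1)
        accs.append(float(np.mean(pred == y[batch])))
    model = CnnModel(arch, params, mean, sd)
    return model, {"loss": np.asarray(losses), "accuracy": np.asarray(accs)}


def predict_cnn(model: CnnModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels and softmax class probabilities for a batch."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.arch.input_length:
        raise ValueError(f"feature length {X.shape[1]} != input_length "
                         f"{model.arch.input_length}")
    if model.input_mean is not None:
        X = (X - model.input_mean) / model.input_sd
    probs = softmax(forward(model.params, X, model.arch))
    return probs.argmax(axis=1), probs
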