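"""Graph-convolutional classifier over feature-similarity graphs.

Each frame is a vector of F audio features.  A graph convolution layer
maps a per-feature signal (F x C_in) to (F x C_out): for every feature
the layer gathers the signal at the feature's receptive field (the
feature itself plus its most-correlated neighbors, ordered by
similarity rank) and applies a learned kernel shared across features,

    out[f, o] = bias[o] + sum_{c, k} signal[rf(f)[k], c] * kernel[c, k, o]

where tap k of the kernel is bound to similarity rank k (center first).
This mirrors grid convolution in image CNNs with the pixel neighborhood
replaced by the correlation neighborhood.  A stack of such layers is
followed by flattening and fully connected layers, softmax output,
cross-entropy loss, and Adam optimization with early stopping on
validation loss.

The implementation is pure NumPy: forward, analytic backpropagation and
the optimizer are written out explicitly, which keeps the model
dependency-light and lets finite-difference tests verify every
gradient.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import FeatureMatrix
from .simgraph import NeighborhoodGraph

__all__ = [
    "GCNNConfig",
    "GCNNParams",
    "TrainHistory",
    "desk_profile",
    "init_model",
    "graph_convolve",
    "forward",
    "loss_and_grads",
    "train",
    "predict",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GCNNConfig:
    """Architecture and training hyperparameters.

    Defaults follow the full reference architecture (receptive field 9,
    conv channels 64/128/256/512, fully connected 4096/1024/256): with
    65 retained features the flattened width is 65 x 512 = 33,280.  That
    profile is compute-heavy on a laptop-class CPU; use
    :func:`desk_profile` for a reduced model with the same topology.
    """

    m: int = 9
    conv_channels: tuple[int, ...] = (64, 128, 256, 512)
    fc_sizes: tuple[int, ...] = (4096, 1024, 256)
    n_classes: int = 2
    dropout_rate: float = 0.1
    conv_dropout: bool = False  # reference architecture applies dropout to FC layers only
    learning_rate: float = 0.001
    batch_size: int = 1024
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_classes < 2:
            raise ValueError("m must be >= 1 and n_classes >= 2")
        if any(c <= 0 for c in self.conv_channels) or any(s <= 0 for s in self.fc_sizes):
            raise ValueError("layer sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def desk_profile(**overrides) -> GCNNConfig:
    """Reduced configuration (conv 8/16, FC 64/32) for CPU-scale runs."""
    cfg = GCNNConfig(conv_channels=(8, 16), fc_sizes=(64, 32), max_epochs=20, patience=3)
    return replace(cfg, **overrides)


@dataclass
class GCNNParams:
    """Learned weights: one kernel+bias per conv layer, weight+bias per FC layer."""

    conv_kernels: list[np.ndarray]  # each (C_in, width, C_out)
    conv_biases: list[np.ndarray]   # each (C_out,)
    fc_weights: list[np.ndarray]    # each (n_in, n_out)
    fc_biases: list[np.ndarray]     # each (n_out,)
    n_features: int
    feature_names: list[str] = field(default_factory=list)

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for k, b in zip(self.conv_kernels, self.conv_biases):
            out += [k, b]
        for w, b in zip(self.fc_weights, self.fc_biases):
            out += [w, b]
        return out

    def copy(self) -> "GCNNParams":
        return GCNNParams(
            [k.copy() for k in self.conv_kernels],
            [b.copy() for b in self.conv_biases],
            [w.copy() for w in self.fc_weights],
            [b.copy() for b in self.fc_biases],
            self.n_features,
            list(self.feature_names),
        )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        ).to_csv(path, index=False)


def init_model(cfg: GCNNConfig, g: NeighborhoodGraph, seed: int | None = None) -> GCNNParams:
    """He-initialized weights, zero biases, reproducible for a given seed."""
    if g.width != cfg.m:
        raise ValueError(
            f"graph receptive-field width {g.width} incompatible with cfg.m={cfg.m}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    F = g.n_features
    conv_kernels, conv_biases = [], []
    c_in = 1
    for c_out in cfg.conv_channels:
        fan_in = c_in * cfg.m
        conv_kernels.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, cfg.m, c_out)))
        conv_biases.append(np.zeros(c_out))
        c_in = c_out
    fc_weights, fc_biases = [], []
    n_in = F * c_in
    for n_out in tuple(cfg.fc_sizes) + (cfg.n_classes,):
        fc_weights.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        fc_biases.append(np.zeros(n_out))
        n_in = n_out
    return GCNNParams(conv_kernels, conv_biases, fc_weights, fc_biases, F, list(g.feature_names))


def _conv_batch(
    signal: np.ndarray, rf: np.ndarray, kernel: np.ndarray, bias: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched graph convolution.

    signal: (B, F, C_in); rf: (F, W); kernel: (C_in, W, C_out).
    Returns (output (B, F, C_out), gathered (B*F, W*C_in) cache).
    """
    B, F, c_in = signal.shape
    W = rf.shape[1]
    gathered = signal[:, rf, :]                     # (B, F, W, C_in)
    gmat = gathered.reshape(B * F, W * c_in)
    kmat = kernel.transpose(1, 0, 2).reshape(W * c_in, -1)
    out = (gmat @ kmat).reshape(B, F, -1) + bias
    return out, gmat


def graph_convolve(
    signal: np.ndarray,
    g: NeighborhoodGraph,
    kernel: np.ndarray,
    bias: np.ndarray,
) -> np.ndarray:
    """Single-frame graph convolution: (F, C_in) -> (F, C_out).

    Tap ``k`` of the kernel reads the signal at similarity rank ``k`` of
    each feature's receptive field (center first, then neighbors in
    descending similarity).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2 or signal.shape[0] != g.n_features:
        raise ValueError("signal must be (n_features, in_channels)")
    c_in, W, _ = kernel.shape
    if W != g.width or c_in != signal.shape[1]:
        raise ValueError(
            f"kernel shape {kernel.shape} incompatible with signal "
            f"{signal.shape} and graph width {g.width}"
        )
    out, _ = _conv_batch(signal[None], g.receptive_fields, kernel, np.asarray(bias))
    return out[0]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_full(
    params: GCNNParams,
    cfg: GCNNConfig,
    g: NeighborhoodGraph,
    X: np.ndarray,
    train_mode: bool,
    rng: np.random.Generator | None,
):
    """Forward pass keeping per-layer caches for backpropagation."""
    B = X.shape[0]
    rf = g.receptive_fields
    h = X[:, :, None]  # (B, F, 1)
    conv_caches = []
    for kernel, bias in zip(params.conv_kernels, params.conv_biases):
        out, gmat = _conv_batch(h, rf, kernel, bias)
        mask = out > 0
        h = out * mask
        drop = None
        if train_mode and cfg.conv_dropout and cfg.dropout_rate > 0:
            drop = (rng.random(h.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
            h = h * drop
        conv_caches.append((gmat, mask, drop, h.shape))
    flat = h.reshape(B, -1)
    fc_caches = []
    a = flat
    n_fc = len(params.fc_weights)
    for li, (w, b) in enumerate(zip(params.fc_weights, params.fc_biases)):
        z = a @ w + b
        last = li == n_fc - 1
        if last:
            fc_caches.append((a, None, None))
            probs = _softmax(z)
        else:
            mask = z > 0
            out = z * mask
            drop = None
            if train_mode and cfg.dropout_rate > 0:
                drop = (rng.random(out.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
                out = out * drop
            fc_caches.append((a, mask, drop))
            a = out
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite activations in forward pass")
    return probs, (conv_caches, fc_caches, flat.shape)


def forward(
    params: GCNNParams,
    cfg: GCNNConfig,
    g: NeighborhoodGraph,
    batch: np.ndarray,
) -> np.ndarray:
    """Inference-mode class probabilities for a batch of frames (B, F)."""
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if batch.shape[1] != params.n_features:
        raise ValueError(
            f"input width {batch.shape[1]} != model n_features {params.n_features}"
        )
    probs, _ = _forward_full(params, cfg, g, batch, train_mode=False, rng=None)
    return probs


def _cross_entropy(probs: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-300, None)
    if w is None:
        return float(-np.log(p).mean())
    sw = w[y]
    return float(-(sw * np.log(p)).sum() / sw.sum())


def loss_and_grads(
    params: GCNNParams,
    cfg: GCNNConfig,
    g: NeighborhoodGraph,
    X: np.ndarray,
    y: np.ndarray,
    train_mode: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, GCNNParams]:
    """Mean cross-entropy and its analytic gradients w.r.t. every parameter.

    Returned gradients are packaged in a ``GCNNParams`` with the same
    shapes as ``params``.
    """
    B, F = X.shape
    rf = g.receptive_fields
    W = rf.shape[1]
    probs, (conv_caches, fc_caches, flat_shape) = _forward_full(
        params, cfg, g, X, train_mode, rng
    )
    cw = np.asarray(cfg.class_weights, dtype=np.float64) if cfg.class_weights else None
    loss = _cross_entropy(probs, y, cw)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")

    # softmax + cross-entropy gradient
    dz = probs.copy()
    dz[np.arange(B), y] -= 1.0
    if cw is None:
        dz /= B
    else:
        sw = cw[y]
        dz *= sw[:, None] / sw.sum()

    d_fc_w, d_fc_b = [], []
    n_fc = len(params.fc_weights)
    for li in range(n_fc - 1, -1, -1):
        a, mask, drop = fc_caches[li]
        d_fc_w.append(a.T @ dz)
        d_fc_b.append(dz.sum(axis=0))
        if li > 0:
            da = dz @ params.fc_weights[li].T
            _, pmask, pdrop = fc_caches[li - 1]
            if pdrop is not None:
                da = da * pdrop
            dz = da * pmask
        else:
            dflat = dz @ params.fc_weights[0].T
    d_fc_w.reverse()
    d_fc_b.reverse()

    dh = dflat.reshape(flat_shape[0], F, -1)
    d_conv_k, d_conv_b = [], []
    # precompute dense scatter matrix mapping (F*W) gathered slots back to features
    scatter = np.zeros((F * W, F))
    scatter[np.arange(F * W), rf.ravel()] = 1.0
    for li in range(len(params.conv_kernels) - 1, -1, -1):
        gmat, mask, drop, out_shape = conv_caches[li]
        if drop is not None:
            dh = dh * drop
        dout = (dh * mask).reshape(-1, out_shape[-1])        # (B*F, C_out)
        kernel = params.conv_kernels[li]
        c_in = kernel.shape[0]
        kmat = kernel.transpose(1, 0, 2).reshape(W * c_in, -1)
        dkmat = gmat.T @ dout                                 # (W*C_in, C_out)
        d_conv_k.append(dkmat.reshape(W, c_in, -1).transpose(1, 0, 2))
        d_conv_b.append(dout.sum(axis=0))
        if li > 0:
            dgmat = dout @ kmat.T                             # (B*F, W*C_in)
            dg = dgmat.reshape(B, F * W, c_in)
            dsig = np.einsum("bkc,kj->bjc", dg, scatter, optimize=True)
            dh = dsig
    d_conv_k.reverse()
    d_conv_b.reverse()
    grads = GCNNParams(d_conv_k, d_conv_b, d_fc_w, d_fc_b, params.n_features)
    return loss, grads


def _evaluate(params, cfg, g, X, y, batch_size) -> tuple[float, float]:
    """Inference-mode mean cross-entropy and accuracy."""
    losses, correct, n = [], 0, 0
    cw = np.asarray(cfg.class_weights, dtype=np.float64) if cfg.class_weights else None
    for start in range(0, len(X), batch_size):
        xb = X[start : start + batch_size]
        yb = y[start : start + batch_size]
        probs, _ = _forward_full(params, cfg, g, xb, train_mode=False, rng=None)
        losses.append(_cross_entropy(probs, yb, cw) * len(yb))
        correct += int((probs.argmax(axis=1) == yb).sum())
        n += len(yb)
    return float(np.sum(losses) / n), correct / n


def train(
    params: GCNNParams,
    cfg: GCNNConfig,
    g: NeighborhoodGraph,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
) -> tuple[GCNNParams, TrainHistory]:
    """Minimize cross-entropy with Adam; early-stop on validation loss.

    Returns the parameters of the best validation epoch and the
    per-epoch history.  Fully deterministic for a fixed ``cfg.seed``,
    data and initial parameters.
    """
    X_tr, y_tr = train_set
    X_val, y_val = val_set
    if len(X_tr) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if y_tr.min() < 0 or y_tr.max() >= cfg.n_classes:
        raise ValueError("labels must be in 0..n_classes-1")
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    if cfg.max_epochs == 0:
        return params, history

    tensors = params.flat()
    m_state = [np.zeros_like(t) for t in tensors]
    v_state = [np.zeros_like(t) for t in tensors]
    t_step = 0
    best_val = np.inf
    best_params = params.copy()
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_tr))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(X_tr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = loss_and_grads(
                params, cfg, g, X_tr[idx], y_tr[idx], train_mode=True, rng=rng
            )
            epoch_loss += loss * len(idx)
            seen += len(idx)
            t_step += 1
            b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
            for t, gt, ms, vs in zip(tensors, grads.flat(), m_state, v_state):
                ms *= b1
                ms += (1 - b1) * gt
                vs *= b2
                vs += (1 - b2) * gt * gt
                mhat = ms / (1 - b1**t_step)
                vhat = vs / (1 - b2**t_step)
                t -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        val_loss, val_acc = _evaluate(params, cfg, g, X_val, y_val, cfg.batch_size)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    return best_params, history


def predict_proba(
    params: GCNNParams,
    cfg: GCNNConfig,
    g: NeighborhoodGraph,
    X: np.ndarray,
    batch_size: int | None = None,
) -> np.ndarray:
    """Class probabilities for raw (already scaled) frame vectors."""
    bs = batch_size or cfg.batch_size
    out = [forward(params, cfg, g, X[s : s + bs]) for s in range(0, len(X), bs)]
    return np.vstack(out)


def predict(
    params: GCNNParams,
    cfg: GCNNConfig,
    g: NeighborhoodGraph,
    fm: FeatureMatrix | np.ndarray,
) -> np.ndarray:
    """Per-frame class labels: argmax probability, ties to the lowest index."""
    if isinstance(fm, FeatureMatrix):
        if params.feature_names and list(fm.feature_names) != list(params.feature_names):
            raise ValueError("feature names/order differ from the training features")
        X = fm.values
    else:
        X = np.asarray(fm, dtype=np.float64)
    return predict_proba(params, cfg, g, X).argmax(axis=1)


def save_checkpoint(path: str | Path, params: GCNNParams, cfg: GCNNConfig) -> None:
    """Persist config + parameters to one ``.npz`` archive."""
    import json

    arrays = {}
    for i, (k, b) in enumerate(zip(params.conv_kernels, params.conv_biases)):
        arrays[f"conv_k{i}"] = k
        arrays[f"conv_b{i}"] = b
    for i, (w, b) in enumerate(zip(params.fc_weights, params.fc_biases)):
        arrays[f"fc_w{i}"] = w
        arrays[f"fc_b{i}"] = b
    cfg_d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()}
    meta = {
        "config": cfg_d,
        "n_features": params.n_features,
        "feature_names": params.feature_names,
        "n_conv": len(params.conv_kernels),
        "n_fc": len(params.fc_weights),
    }
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[GCNNParams, GCNNConfig]:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        cfg_d = meta["config"]
        for key in ("conv_channels", "fc_sizes", "class_weights"):
            if cfg_d.get(key) is not None:
                cfg_d[key] = tuple(cfg_d[key])
        cfg = GCNNConfig(**cfg_d)
        params = GCNNParams(
            [z[f"conv_k{i}"] for i in range(meta["n_conv"])],
            [z[f"conv_b{i}"] for i in range(meta["n_conv"])],
            [z[f"fc_w{i}"] for i in range(meta["n_fc"])],
            [z[f"fc_b{i}"] for i in range(meta["n_fc"])],
            meta["n_features"],
            meta["feature_names"],
        )
    return params, cfg
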