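"""Feed-forward emotion classifier with in-network batch or stratified
normalization.

The architecture is three dense hidden layers of 64 units, each followed
by ReLU, a (non-learnable) normalization step and — for the first two
hidden layers — dropout, then a final dense layer with log-softmax
output. The normalization step after each hidden layer is either

* *batch*: mean-variance normalization over the whole training batch
  (frozen statistics at inference), or
* *stratified*: mean-variance normalization within each (participant,
  session) stratum, recomputed from whichever rows are in the current
  pass.

Training is full batch: all trials form one batch, optimized with Adam
under negative log-likelihood for 100 epochs, learning rate 0.005 for
the first 40 epochs and 0.001 thereafter.

The network is small enough that forward and backward passes are written
directly in NumPy; the only non-textbook gradient is the one through the
normalization statistics, which for a group R of m rows with
y = (a − μ_R)/√(σ²_R + ε) is

    ∂L/∂a = (g − mean_R(g) − y ⊙ mean_R(g ⊙ y)) / √(σ²_R + ε)

applied per feature column, with g the upstream gradient. Gradients flow
through μ and σ² exactly as in standard batch normalization (without the
learnable affine step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .normalization import GlobalMeanVarStats, NormConfig

__all__ = [
    "ModelParams",
    "TrainConfig",
    "ActivationTrace",
    "init_model",
    "forward",
    "train_model",
    "predict",
    "save_model",
    "load_model",
]

HIDDEN_WIDTH = 64
N_HIDDEN = 3

#: Probe points, in network order.
TRACE_LAYERS = ("input", "h1", "h2", "h3", "output")


@dataclass
class TrainConfig:
    epochs: int = 100
    lr_high: float = 0.005
    lr_low: float = 0.001
    lr_switch_epoch: int = 40  # epochs 1..40 use lr_high, 41.. use lr_low
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    dropout_rate: float = 0.25
    seed: int = 0


@dataclass
class ModelParams:
    weights: list[np.ndarray]  # 4 matrices: in->64, 64->64, 64->64, 64->out
    biases: list[np.ndarray]
    norm: NormConfig
    dropout_rate: float = 0.25
    # Frozen per-layer statistics for batch-mode inference (set after training).
    frozen_stats: list[GlobalMeanVarStats] | None = None

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]


@dataclass
class ActivationTrace:
    """Post-normalization activations at the five probe points."""

    input: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    output: np.ndarray  # softmax probabilities, rows sum to 1

    def layer(self, name: str) -> np.ndarray:
        if name not in TRACE_LAYERS:
            raise KeyError(f"unknown probe layer {name!r}")
        return getattr(self, name)


def init_model(
    n_features: int,
    n_classes: int,
    norm: NormConfig,
    seed: int = 0,
    dropout_rate: float = 0.25,
) -> ModelParams:
    """Fan-in-scaled uniform initialization, deterministic given ``seed``."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    rng = np.random.default_rng(seed)
    sizes = [n_features, HIDDEN_WIDTH, HIDDEN_WIDTH, HIDDEN_WIDTH, n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return ModelParams(
        weights=weights, biases=biases, norm=norm, dropout_rate=dropout_rate
    )


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _norm_forward(a, params, layer_idx, strata, phase):
    """Normalize activations; returns (output, cache-for-backward).

    The cache holds the normalized output y, the stratum ids (None for
    batch mode) and the per-row inverse scale 1/sqrt(var + eps) needed by
    the backward pass.
    """
    eps = params.norm.eps
    if params.norm.mode == "stratified":
        if strata is None:
            raise ValueError("stratified normalization requires stratum ids")
        strata = np.asarray(strata)
        out = np.empty_like(a)
        inv = np.empty_like(a)
        for s in np.unique(strata):
            rows = np.flatnonzero(strata == s)
            if len(rows) < 2:
                raise ValueError("singleton stratum in normalization layer")
            block = a[rows]
            inv_s = 1.0 / np.sqrt(block.var(axis=0) + eps)
            out[rows] = (block - block.mean(axis=0)) * inv_s
            inv[rows] = inv_s
        return out, ("strat", out, strata, inv)
    if phase == "eval":
        if params.frozen_stats is None:
            raise ValueError(
                "batch-mode inference requires frozen statistics; train first"
            )
        st = params.frozen_stats[layer_idx]
        inv = 1.0 / np.sqrt(st.var + eps)
        return (a - st.mean) * inv, ("frozen", None, None, inv)
    mean = a.mean(axis=0)
    var = a.var(axis=0)
    inv = 1.0 / np.sqrt(var + eps)
    out = (a - mean) * inv
    return out, ("batch", out, None, inv)


def _group_norm_backward(g, y, strata):
    """Gradient through mean-variance normalization, per group of rows."""
    out = np.empty_like(g)
    if strata is None:
        groups = [slice(None)]
    else:
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for rows in groups:
        gb, yb = g[rows], y[rows]
        out[rows] = gb - gb.mean(axis=0) - yb * (gb * yb).mean(axis=0)
    return out


def forward(
    params: ModelParams,
    X: np.ndarray,
    strata: np.ndarray | None = None,
    phase: str = "eval",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ActivationTrace]:
    """Run the network; returns (log-probabilities, activation trace).

    ``X`` must already be min-max normalized according to the model's
    normalization mode. In ``train`` phase dropout is active after hidden
    layers 1–2 and batch-mode statistics come from the current batch; in
    ``eval`` phase there is no dropout and batch mode uses frozen
    statistics.
    """
    logp, trace, _ = _forward_full(params, X, strata, phase, rng)
    return logp, trace


def _forward_full(params, X, strata, phase, rng):
    if phase not in ("train", "eval"):
        raise ValueError("phase must be 'train' or 'eval'")
    if phase == "train" and params.dropout_rate > 0 and rng is None:
        raise ValueError("train phase with dropout needs an rng")
    X = np.asarray(X, dtype=np.float64)
    cache = {"X": X, "layers": []}
    hidden = []
    a = X
    for layer in range(N_HIDDEN):
        z = a @ params.weights[layer] + params.biases[layer]
        relu_mask = z > 0
        h = z * relu_mask
        n, norm_cache = _norm_forward(h, params, layer, strata, phase)
        hidden.append(n)
        if layer < 2 and phase == "train" and params.dropout_rate > 0:
            keep = 1.0 - params.dropout_rate
            drop_mask = (rng.random(n.shape) < keep) / keep
            out = n * drop_mask
        else:
            drop_mask = None
            out = n
        cache["layers"].append(
            {"a_in": a, "relu_mask": relu_mask, "norm": norm_cache, "drop": drop_mask}
        )
        a = out
    z_out = a @ params.weights[-1] + params.biases[-1]
    logp = _log_softmax(z_out)
    cache["a_last"] = a
    trace = ActivationTrace(
        input=X, h1=hidden[0], h2=hidden[1], h3=hidden[2], output=np.exp(logp)
    )
    return logp, trace, cache


def _backward(params, cache, logp, y):
    """Gradients of mean NLL w.r.t. all weights and biases."""
    n = logp.shape[0]
    dz = np.exp(logp)
    dz[np.arange(n), y] -= 1.0
    dz /= n
    grads_w = [None] * 4
    grads_b = [None] * 4
    grads_w[3] = cache["a_last"].T @ dz
    grads_b[3] = dz.sum(axis=0)
    g = dz @ params.weights[3].T
    for layer in reversed(range(N_HIDDEN)):
        lc = cache["layers"][layer]
        if lc["drop"] is not None:
            g = g * lc["drop"]
        kind, y_norm, strata, inv = lc["norm"]
        if kind == "frozen":  # pragma: no cover - eval never backprops
            g = g * inv
        else:
            g = _group_norm_backward(g, y_norm, strata) * inv
        g = g * lc["relu_mask"]
        grads_w[layer] = lc["a_in"].T @ g
        grads_b[layer] = g.sum(axis=0)
        g = g @ params.weights[layer].T
    return grads_w, grads_b


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray | None,
    cfg: TrainConfig,
    norm: NormConfig,
) -> tuple[ModelParams, np.ndarray]:
    """Full-batch Adam training; returns the model and per-epoch NLL.

    Deterministic given ``cfg.seed``. After the last epoch, batch-mode
    statistics are collected from one dropout-free pass over the
    training batch and frozen into the model for inference.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if y.min() < 0 or y.max() > 2:
        raise ValueError("labels must be coded 0/1(/2)")
    n_classes = 3 if int(y.max()) > 1 else 2
    params = init_model(
        X.shape[1], n_classes, norm, seed=cfg.seed, dropout_rate=cfg.dropout_rate
    )
    rng = np.random.default_rng(cfg.seed + 1)
    theta = params.weights + params.biases
    m = [np.zeros_like(p) for p in theta]
    v = [np.zeros_like(p) for p in theta]
    losses = np.empty(cfg.epochs)
    step = 0
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr_high if epoch <= cfg.lr_switch_epoch else cfg.lr_low
        logp, _, cache = _forward_full(params, X, strata, "train", rng)
        loss = -logp[np.arange(len(y)), y].mean()
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}"
            )
        losses[epoch - 1] = loss
        grads_w, grads_b = _backward(params, cache, logp, y)
        grads = grads_w + grads_b
        step += 1
        for i, (p, gr) in enumerate(zip(theta, grads)):
            m[i] = cfg.beta1 * m[i] + (1 - cfg.beta1) * gr
            v[i] = cfg.beta2 * v[i] + (1 - cfg.beta2) * gr**2
            m_hat = m[i] / (1 - cfg.beta1**step)
            v_hat = v[i] / (1 - cfg.beta2**step)
            p -= lr * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)
    # Freeze batch statistics from a dropout-free pass for inference.
    if norm.mode == "batch":
        frozen = []
        a = X
        for layer in range(N_HIDDEN):
            h = np.maximum(a @ params.weights[layer] + params.biases[layer], 0.0)
            st = GlobalMeanVarStats(mean=h.mean(axis=0), var=h.var(axis=0))
            frozen.append(st)
            a = (h - st.mean) / np.sqrt(st.var + norm.eps)
        params.frozen_stats = frozen
    return params, losses


def predict(
    params: ModelParams, X: np.ndarray, strata: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eval-phase argmax prediction; ties break to the lowest class index."""
    logp, _ = forward(params, X, strata, phase="eval")
    return logp.argmax(axis=1), logp


_FORMAT_VERSION = 1


def save_model(params: ModelParams, path) -> None:
    obj = {
        "version": _FORMAT_VERSION,
        "norm": {"mode": params.norm.mode, "eps": params.norm.eps},
        "dropout_rate": params.dropout_rate,
        "shapes": [list(w.shape) for w in params.weights],
        "weights": [w.ravel().tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
        "frozen_stats": None
        if params.frozen_stats is None
        else [
            {"mean": s.mean.tolist(), "var": s.var.tolist()}
            for s in params.frozen_stats
        ],
    }
    with open(path, "w") as f:
        json.dump(obj, f)


def load_model(path) -> ModelParams:
    with open(path) as f:
        obj = json.load(f)
    if obj.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {obj.get('version')}")
    weights = [
        np.asarray(w, dtype=np.float64).reshape(shape)
        for w, shape in zip(obj["weights"], obj["shapes"])
    ]
    biases = [np.asarray(b, dtype=np.float64) for b in obj["biases"]]
    frozen = obj["frozen_stats"]
    return ModelParams(
        weights=weights,
        biases=biases,
        norm=NormConfig(mode=obj["norm"]["mode"], eps=obj["norm"]["eps"]),
        dropout_rate=obj["dropout_rate"],
        frozen_stats=None
        if frozen is None
        else [
            GlobalMeanVarStats(
                mean=np.asarray(s["mean"]), var=np.asarray(s["var"])
            )
            for s in frozen
        ],
    )
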