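"""The paratope-epitope image classifier.

A pair of H x W RGB images (paratope + epitope) is stacked into an H x W x 6
tensor and passed through two residual blocks of 3x3 convolutions (32 kernels
each, leaky-ReLU activations, zero "same" padding).  The first block's skip
connection projects the 6 input channels to 32 with a 1x1 convolution; the
second block's skip is the identity.  The block stack is followed by parallel
max- and average-pooling with window s=4, concatenated channelwise to an
(H/4) x (W/4) x 64 tensor, flattened, passed through dropout (rate 0.75,
training only) and a single dense unit, and squashed by a sigmoid into a
binding score in (0, 1).

Training minimises binary cross-entropy with Adam, Kaiming-normal initial
convolution weights, Xavier-normal dense weights, plateau-based learning-rate
reduction and early stopping on the validation loss.  Ten stratified
cross-validation folds yield ten parameter sets; the deployed score is the
mean of the ten sigmoid outputs.

Everything is plain NumPy.  The layer primitives (`conv2d`, `pool`) operate
on single H x W x C arrays and preserve the input dtype; the training path
uses batched float32 internals for speed.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from sklearn.metrics import (average_precision_score, balanced_accuracy_score,
                             matthews_corrcoef, roc_auc_score)

from .config import TrainConfig

LRELU_SLOPE = 0.1


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def lrelu(x):
    """Leaky ReLU: x for x > 0, else 0.1 x."""
    x = np.asarray(x)
    return np.where(x > 0, x, LRELU_SLOPE * x)


def _dlrelu(x):
    return np.where(x > 0, 1.0, LRELU_SLOPE).astype(x.dtype)


@dataclasses.dataclass
class ConvLayerParams:
    """Weights of one convolutional layer: kernels (2k+1, 2k+1, Cin, Cout) + bias."""
    kernels: np.ndarray
    bias: np.ndarray


def _conv_batch(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero-padded 'same' convolution on a (B, H, W, Cin) batch."""
    B, H, Wd, Cin = x.shape
    kh, kw, cin, Cout = W.shape
    if cin != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {cin}")
    k = kh // 2
    dtype = np.result_type(x.dtype, W.dtype)
    xp = np.zeros((B, H + 2 * k, Wd + 2 * k, Cin), dtype=dtype)
    xp[:, k:H + k, k:Wd + k] = x
    out = np.zeros((B, H, Wd, Cout), dtype=dtype)
    out += b.astype(dtype)
    acc = out.reshape(-1, Cout)
    for t in range(kh):
        for s in range(kw):
            acc += xp[:, t:t + H, s:s + Wd, :].reshape(-1, Cin) @ W[t, s].astype(dtype)
    return out


def _conv_batch_backward(x, W, gout, need_gx=True):
    B, H, Wd, Cin = x.shape
    kh, kw, _, Cout = W.shape
    k = kh // 2
    gb = gout.sum(axis=(0, 1, 2))
    gW = np.zeros_like(W)
    xp = np.zeros((B, H + 2 * k, Wd + 2 * k, Cin), dtype=x.dtype)
    xp[:, k:H + k, k:Wd + k] = x
    gxp = np.zeros_like(xp) if need_gx else None
    go = gout.reshape(-1, Cout)
    for t in range(kh):
        for s in range(kw):
            xs = xp[:, t:t + H, s:s + Wd, :].reshape(-1, Cin)
            gW[t, s] = xs.T @ go
            if need_gx:
                gxp[:, t:t + H, s:s + Wd, :] += (go @ W[t, s].T).reshape(B, H, Wd, Cin)
    gx = gxp[:, k:H + k, k:Wd + k] if need_gx else None
    return gx, gW, gb


def conv2d(x: np.ndarray, layer: ConvLayerParams) -> np.ndarray:
    """'Same'-padded convolution of one H x W x C tensor."""
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError("conv2d expects an H x W x C tensor")
    return _conv_batch(x[None], layer.kernels, layer.bias)[0]


def _pool_windows(x: np.ndarray, s: int) -> np.ndarray:
    B, H, Wd, C = x.shape
    if H % s or Wd % s:
        raise ValueError(f"spatial shape ({H}, {Wd}) not divisible by window {s}")
    xr = x.reshape(B, H // s, s, Wd // s, s, C)
    return xr.transpose(0, 1, 3, 5, 2, 4).reshape(B, H // s, Wd // s, C, s * s)


def _maxpool_batch(x, s):
    win = _pool_windows(x, s)
    idx = win.argmax(axis=-1)
    return win.max(axis=-1), idx


def _avgpool_batch(x, s):
    return _pool_windows(x, s).mean(axis=-1)


def _max_unpool_batch(p, idx, s):
    """Place each pooled value at its recorded argmax position (zeros elsewhere)."""
    B, Hp, Wp, C = p.shape
    win = np.zeros((B, Hp, Wp, C, s * s), dtype=p.dtype)
    np.put_along_axis(win, idx[..., None], p[..., None], axis=-1)
    return _unwindow(win, s)


def _avg_unpool_batch(p, s):
    """Spread each pooled value uniformly over its window (value / s^2 per cell)."""
    B, Hp, Wp, C = p.shape
    win = np.broadcast_to((p / (s * s))[..., None], (B, Hp, Wp, C, s * s)).copy()
    return _unwindow(win, s)


def _unwindow(win, s):
    B, Hp, Wp, C, _ = win.shape
    return (win.reshape(B, Hp, Wp, C, s, s)
               .transpose(0, 1, 4, 2, 5, 3)
               .reshape(B, Hp * s, Wp * s, C))


def pool(x: np.ndarray, s: int = 4, mode: str = "max"):
    """Window pooling of one H x W x C tensor.

    Max mode returns ``(pooled, argmax_indices)`` where the indices address
    positions inside each flattened s x s window (needed for unpooling);
    avg mode returns the pooled tensor alone.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError("pool expects an H x W x C tensor")
    if mode == "max":
        p, idx = _maxpool_batch(x[None], s)
        return p[0], idx[0]
    if mode == "avg":
        return _avgpool_batch(x[None], s)[0]
    raise ValueError(f"unknown pooling mode {mode!r}")


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(scores, labels, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with score clipping for numerical safety."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    s = np.clip(scores, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


# ---------------------------------------------------------------------------
# parameters and forward pass
# ---------------------------------------------------------------------------

def init_params(size: int, seed: int, in_channels: int = 6,
                n_kernels: int = 32, pool_window: int = 4,
                dtype=np.float32) -> dict[str, np.ndarray]:
    """Kaiming-normal convolution weights, Xavier-normal dense weights."""
    rng = np.random.default_rng(seed)
    nk = n_kernels

    def kaiming(shape):
        fan_in = shape[0] * shape[1] * shape[2]
        std = np.sqrt(2.0 / ((1.0 + LRELU_SLOPE ** 2) * fan_in))
        return (rng.standard_normal(shape) * std).astype(dtype)

    feat = (size // pool_window) ** 2 * 2 * nk
    xavier_std = np.sqrt(2.0 / (feat + 1))
    return {
        "w1a": kaiming((3, 3, in_channels, nk)), "b1a": np.zeros(nk, dtype),
        "w1b": kaiming((3, 3, nk, nk)), "b1b": np.zeros(nk, dtype),
        "wp": kaiming((1, 1, in_channels, nk))[0, 0], "bp": np.zeros(nk, dtype),
        "w2a": kaiming((3, 3, nk, nk)), "b2a": np.zeros(nk, dtype),
        "w2b": kaiming((3, 3, nk, nk)), "b2b": np.zeros(nk, dtype),
        "wd": (rng.standard_normal(feat) * xavier_std).astype(dtype),
        "bd": np.zeros((), dtype),
    }


def _forward_batch(X, params, s: int = 4, train_mode: bool = False,
                   dropout: float = 0.75, rng: np.random.Generator | None = None):
    """Forward pass on a (B, H, W, 6) batch; returns (scores, cache)."""
    c1 = _conv_batch(X, params["w1a"], params["b1a"])
    a1 = lrelu(c1)
    c2 = _conv_batch(a1, params["w1b"], params["b1b"])
    B, H, Wd, Cin = X.shape
    sp = (X.reshape(-1, Cin) @ params["wp"] + params["bp"]).reshape(B, H, Wd, -1)
    z1 = c2 + sp
    r1 = lrelu(z1)
    c3 = _conv_batch(r1, params["w2a"], params["b2a"])
    a3 = lrelu(c3)
    c4 = _conv_batch(a3, params["w2b"], params["b2b"])
    z2 = c4 + r1
    r2 = lrelu(z2)
    pmax, idx = _maxpool_batch(r2, s)
    pavg = _avgpool_batch(r2, s)
    pooled = np.concatenate([pmax, pavg], axis=-1)
    f = pooled.reshape(B, -1)
    if train_mode and dropout > 0:
        if rng is None:
            raise ValueError("train-mode forward needs an rng for dropout")
        keep = 1.0 - dropout
        mask = (rng.random(f.shape) < keep).astype(f.dtype)
        fd = f * mask / keep
    else:
        mask = None
        fd = f
    logit = fd @ params["wd"] + params["bd"]
    score = sigmoid(logit)
    cache = {"X": X, "c1": c1, "a1": a1, "c2": c2, "z1": z1, "r1": r1,
             "c3": c3, "a3": a3, "c4": c4, "z2": z2, "r2": r2,
             "pool_idx": idx, "pooled": pooled, "f": f, "fd": fd,
             "mask": mask, "logit": logit, "s": s}
    return score, cache


def forward(pair: np.ndarray, params: dict, train_mode: bool = False,
            pool_window: int = 4, dropout: float = 0.75,
            rng: np.random.Generator | None = None):
    """Score one H x W x 6 pair tensor; returns (score, cache).

    The cache retains every activation and the max-pool argmax indices needed
    for feature-map backprojection.
    """
    pair = np.asarray(pair)
    if pair.ndim != 3 or pair.shape[-1] != params["w1a"].shape[2]:
        raise ValueError("input must be H x W x C with C matching the model")
    scores, cache = _forward_batch(pair[None], params, s=pool_window,
                                   train_mode=train_mode, dropout=dropout, rng=rng)
    cache = {k: (v[0] if isinstance(v, np.ndarray) and v.ndim > 0
                 and k not in ("s",) else v)
             for k, v in cache.items()}
    return float(scores[0]), cache


def _backward_batch(params, cache, dlogit, dropout=0.75):
    """Gradients of the mean BCE loss given dJ/dlogit per sample."""
    g = {}
    fd = cache["fd"]
    dlogit = dlogit.astype(fd.dtype)
    g["wd"] = fd.T @ dlogit
    g["bd"] = dlogit.sum()
    gfd = np.outer(dlogit, params["wd"])
    if cache["mask"] is not None:
        gf = gfd * cache["mask"] / (1.0 - dropout)
    else:
        gf = gfd
    B = fd.shape[0]
    s = cache["s"]
    pooled = cache["pooled"]
    gpooled = gf.reshape(pooled.shape)
    C = pooled.shape[-1] // 2
    gr2 = (_max_unpool_batch(gpooled[..., :C], cache["pool_idx"], s)
           + _avg_unpool_batch(gpooled[..., C:], s))
    gz2 = gr2 * _dlrelu(cache["z2"])
    ga3, g["w2b"], g["b2b"] = _conv_batch_backward(cache["a3"], params["w2b"], gz2)
    gc3 = ga3 * _dlrelu(cache["c3"])
    gr1_conv, g["w2a"], g["b2a"] = _conv_batch_backward(cache["r1"], params["w2a"], gc3)
    gr1 = gz2 + gr1_conv
    gz1 = gr1 * _dlrelu(cache["z1"])
    ga1, g["w1b"], g["b1b"] = _conv_batch_backward(cache["a1"], params["w1b"], gz1)
    X = cache["X"]
    Cin = X.shape[-1]
    g["wp"] = X.reshape(-1, Cin).T @ gz1.reshape(-1, gz1.shape[-1])
    g["bp"] = gz1.sum(axis=(0, 1, 2))
    gc1 = ga1 * _dlrelu(cache["c1"])
    _, g["w1a"], g["b1a"] = _conv_batch_backward(X, params["w1a"], gc1, need_gx=False)
    return g


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            gk = grads[k].astype(params[k].dtype, copy=False)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _eval_loss(X, y, params, cfg: TrainConfig, batch: int = 64) -> tuple[float, np.ndarray]:
    scores = np.empty(len(X), dtype=np.float64)
    for i in range(0, len(X), batch):
        sc, _ = _forward_batch(X[i:i + batch], params, s=cfg.pool_window,
                               train_mode=False)
        scores[i:i + batch] = sc
    return bce_loss(scores, y, cfg.eps_clip), scores


def train_fold(X_sub, y_sub, X_val, y_val, cfg: TrainConfig, seed: int):
    """Train one model on a subtrain/validation pair.

    Returns ``(params, history)`` where ``history`` is a list of per-epoch
    dicts (subtrain loss, validation loss, learning rate).  Fully
    deterministic for a given seed.
    """
    if len(X_sub) == 0 or len(X_val) == 0:
        raise ValueError("subtrain and validation sets must be non-empty")
    X_sub = np.asarray(X_sub, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    y_sub = np.asarray(y_sub, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    size = X_sub.shape[1]
    params = init_params(size, seed, in_channels=X_sub.shape[-1],
                         n_kernels=cfg.n_kernels, pool_window=cfg.pool_window)
    rng = np.random.default_rng(seed + 1)
    opt = _Adam(params, cfg.lr)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stall = plateau = 0
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_sub))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            bidx = order[i:i + cfg.batch_size]
            Xb, yb = X_sub[bidx], y_sub[bidx]
            scores, cache = _forward_batch(Xb, params, s=cfg.pool_window,
                                           train_mode=True, dropout=cfg.dropout,
                                           rng=rng)
            loss = bce_loss(scores, yb, cfg.eps_clip)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            epoch_losses.append(loss)
            dlogit = (scores - yb) / len(yb)
            grads = _backward_batch(params, cache, dlogit, dropout=cfg.dropout)
            opt.step(params, grads)
        val_loss, _ = _eval_loss(X_val, y_val, params, cfg)
        history.append({"epoch": epoch, "subtrain_loss": float(np.mean(epoch_losses)),
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            stall = plateau = 0
            if cfg.val_loss_floor and val_loss < cfg.val_loss_floor:
                break   # converged
        else:
            stall += 1
            plateau += 1
            if plateau >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                plateau = 0
            if stall >= cfg.early_stop_patience:
                break
    return best_params, history


@dataclasses.dataclass
class ModelEnsemble:
    """Cross-validation models; the deployed score is their mean sigmoid output."""

    members: list[dict]
    pool_window: int = 4
    histories: list[list[dict]] | None = None   # per-fold training logs

    def member_scores(self, X) -> np.ndarray:
        """Per-member scores, shape (n_members, n_samples).

        Samples are scored one at a time so that a pair's score is bit-exactly
        independent of whatever batch it happens to be evaluated in (BLAS
        kernels vary with batch size).
        """
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        out = np.empty((len(self.members), len(X)), dtype=np.float64)
        for i, params in enumerate(self.members):
            for j in range(len(X)):
                sc, _ = _forward_batch(X[j:j + 1], params, s=self.pool_window,
                                       train_mode=False)
                out[i, j] = sc[0]
        return out

    def score(self, X) -> np.ndarray:
        """Mean of the member sigmoid outputs; shape (n_samples,)."""
        return self.member_scores(X).mean(axis=0)

    def save(self, directory: str) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        files = []
        for i, params in enumerate(self.members):
            fn = f"fold_{i:02d}.npz"
            np.savez(d / fn, **params)
            files.append(fn)
        (d / "ensemble.json").write_text(json.dumps(
            {"folds": files, "pool_window": self.pool_window}, indent=2))

    @classmethod
    def load(cls, directory: str) -> "ModelEnsemble":
        d = pathlib.Path(directory)
        desc = json.loads((d / "ensemble.json").read_text())
        members = []
        for fn in desc["folds"]:
            with np.load(d / fn) as z:
                members.append({k: z[k] for k in z.files})
        return cls(members, pool_window=desc.get("pool_window", 4))


def train_cv(X, y, folds, cfg: TrainConfig, seed: int) -> ModelEnsemble:
    """Train one model per (subtrain_idx, validation_idx) fold pair."""
    members, histories = [], []
    for k, (sub_idx, val_idx) in enumerate(folds):
        params, hist = train_fold(X[sub_idx], y[sub_idx], X[val_idx], y[val_idx],
                                  cfg, seed + k)
        members.append(params)
        histories.append(hist)
    return ModelEnsemble(members, pool_window=cfg.pool_window,
                         histories=histories)


def write_training_log(ensemble: ModelEnsemble, path: str) -> None:
    """TSV log: fold, epoch, subtrain loss, validation loss, learning rate."""
    import pandas as pd
    rows = []
    for k, hist in enumerate(ensemble.histories or []):
        for h in hist:
            rows.append({"fold": k, **h})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Balanced accuracy, MCC, AUROC and AUPRC of binding scores."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to evaluate")
    pred = (scores >= threshold).astype(int)
    return {
        "BAC": float(balanced_accuracy_score(labels, pred)),
        "MCC": float(matthews_corrcoef(labels, pred)),
        "AUROC": float(roc_auc_score(labels, scores)),
        "AUPRC": float(average_precision_score(labels, scores)),
    }
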