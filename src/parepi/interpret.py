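"""Backprojection of the dense head onto the image plane.

The dense unit computes logit = w . f + b with f the flattened pooled
activations.  Since a dot product equals a Hadamard product followed by a
total sum, the elementwise product h = w * f decomposes the logit into
per-feature contributions.  Reshaped to (H/s, W/s, 64) and split into its
max-pool and average-pool halves, each half is unpooled back to pixel
resolution — max-unpooling places each contribution at the recorded argmax
position of its window, average-unpooling spreads it uniformly (value / s^2
per cell), both of which conserve the total contribution.  Averaging each
unpooled tensor over its 32 channels and summing the two maps yields a single
signed H x W contribution image: positive cells push the score toward
binding, negative cells away from it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cnn import _avg_unpool_batch, _max_unpool_batch, forward, sigmoid


@dataclasses.dataclass
class FeatureMap:
    map: np.ndarray        # H x W signed contributions
    logit: float
    bias: float
    score: float


def feature_map(pair: np.ndarray, params: dict, pool_window: int = 4,
                combine: str = "sum") -> FeatureMap:
    """Signed per-pixel contribution map of one fold for one image pair.

    ``combine`` chooses how the unpooled max and avg maps merge: ``"sum"``
    (conserves the total contribution; default) or ``"mean"``.
    """
    score, cache = forward(pair, params, train_mode=False, pool_window=pool_window)
    f = cache["f"].astype(np.float64)
    w = np.asarray(params["wd"], dtype=np.float64)
    b = float(params["bd"])
    h = w * f
    logit = float(h.sum() + b)
    s = pool_window
    pooled_shape = cache["pooled"].shape       # (Hp, Wp, 64)
    hp = h.reshape(pooled_shape)
    C = pooled_shape[-1] // 2
    max_half, avg_half = hp[..., :C], hp[..., C:]
    idx = cache["pool_idx"][None]
    max_up = _max_unpool_batch(max_half[None], idx, s)[0]
    avg_up = _avg_unpool_batch(avg_half[None], s)[0]
    max_map = max_up.mean(axis=-1)
    avg_map = avg_up.mean(axis=-1)
    if combine == "sum":
        m = max_map + avg_map
    elif combine == "mean":
        m = 0.5 * (max_map + avg_map)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    return FeatureMap(map=m, logit=logit, bias=b, score=float(sigmoid(logit)))


def ensemble_feature_map(pair: np.ndarray, ensemble, combine: str = "sum") -> np.ndarray:
    """Average of the per-fold contribution maps."""
    maps = [feature_map(pair, p, ensemble.pool_window, combine).map
            for p in ensemble.members]
    return np.mean(maps, axis=0)


def save_overlay_png(fmap: np.ndarray, path: str) -> None:
    """Write the signed map as a diverging-palette PNG (red +, blue -)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    lim = float(np.abs(fmap).max()) or 1.0
    fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
    ax.imshow(fmap, cmap="bwr", vmin=-lim, vmax=lim)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
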