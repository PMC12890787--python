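"""Training losses: soft Dice, boundary (signed-distance) loss, hybrid.

The boundary loss is the L1 distance between the pre-SoftMax logits and
the negated ground-truth signed distance map, so logits are driven
positive inside a structure and negative outside. The hybrid loss is
``alpha * dice + (1 - alpha) * boundary``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import autograd as ag
from .autograd import Tensor

DICE_EPS = 1e-5


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Channel-first one-hot encoding (V, D, H, W) of an integer map."""
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for v in range(n_classes):
        out[v] = labels == v
    return out


def dice_loss(
    probs: Tensor,
    onehot: np.ndarray,
    eps: float = DICE_EPS,
    include_background: bool = False,
) -> Tensor:
    """1 - mean over foreground labels of the soft Dice coefficient.

    ``probs`` are channel-first SoftMax probabilities (V, D, H, W);
    ``onehot`` the matching ground-truth encoding. Labels absent from
    the truth still enter the mean (their Dice is eps-regularized), so a
    model that hallucinates absent structures is penalized.

    ``include_background`` adds the background term to the mean; the
    training recipe uses this because a loss blind to background lets
    the background channel collapse on out-of-suite inputs (foreground
    labels then flood the volume).
    """
    g = np.asarray(onehot, dtype=np.float32)
    V = g.shape[0]
    sel = np.ones(V, dtype=np.float32)
    if not include_background:
        sel[0] = 0.0

    inter = ag.tsum(ag.mul(probs, Tensor(g)), axis=(1, 2, 3), keepdims=False)
    psum = ag.tsum(probs, axis=(1, 2, 3))
    gsum = g.sum(axis=(1, 2, 3))
    num = 2.0 * inter + eps
    den = psum + Tensor(gsum + eps)
    dice = ag.div(num, den)                       # (V,)
    mean_sel = ag.tsum(ag.mul(dice, Tensor(sel))) * (1.0 / sel.sum())
    return 1.0 - mean_sel


def signed_distance_map(
    labels: np.ndarray, v: int, sampling: float = 1.0
) -> np.ndarray:
    """Signed Euclidean distance to the boundary of label ``v``.

    Boundary voxels (label voxels with a face-connected background
    neighbor) are zero, outside is positive, inside negative. An absent
    label yields a constant ``+max_dist`` field (the grid diagonal).
    """
    mask = np.asarray(labels) == v
    if not mask.any():
        max_dist = float(np.linalg.norm(np.array(mask.shape) * sampling))
        return np.full(mask.shape, max_dist, dtype=np.float64)
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    dist = ndimage.distance_transform_edt(~boundary, sampling=sampling)
    return np.where(mask, -dist, dist)


def sdm_stack(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-foreground-label SDMs, channel-first (V-1, D, H, W)."""
    return np.stack(
        [signed_distance_map(labels, v) for v in range(1, n_classes)], axis=0
    ).astype(np.float32)


def boundary_loss(logits: Tensor, sdms: np.ndarray) -> Tensor:
    """Mean L1 distance between foreground logits and -SDM."""
    fg_logits_target = Tensor(-np.asarray(sdms, dtype=np.float32))
    V = logits.data.shape[0]
    fg_logits = _select_channels(logits, np.arange(1, V))
    return ag.tmean(ag.tabs(fg_logits - fg_logits_target))


def _select_channels(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[idx] = g
        x._accum(gx)

    return ag._node(x.data[idx], (x,), bw)


def hybrid_loss(
    logits: Tensor,
    probs: Tensor,
    onehot: np.ndarray,
    sdms: np.ndarray,
    alpha: float = 0.5,
) -> Tensor:
    return alpha * dice_loss(probs, onehot) + (1.0 - alpha) * boundary_loss(
        logits, sdms
    )
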