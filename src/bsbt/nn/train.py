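"""Mini-batch training with on-the-fly augmentation.

Augmentation emulates acquisition variability: random affine (rotations
up to +-10 degrees, scaling +-10%), a smooth elastic deformation,
per-channel intensity jitter (+-10%) and Rician noise injection. The
spatial transforms are applied identically to the channels (trilinear)
and the label map (nearest-neighbor). Everything is driven by a single
generator so runs are reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autograd as ag
from .autograd import Adam, Tensor
from .losses import boundary_loss, dice_loss, one_hot, sdm_stack
from .unet import AttentionUNet3D


@dataclass
class AugmentParams:
    rotate_deg: float = 10.0
    scale_frac: float = 0.10
    elastic_sigma_vox: float = 4.0
    elastic_amp_vox: float = 1.0
    intensity_jitter: float = 0.10
    rician_sigma: float = 0.01
    enabled: bool = True


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def best_val_dice(self) -> float:
        return max(self.val_dice) if self.val_dice else float("nan")


def _random_affine_matrix(rng: np.random.Generator, p: AugmentParams) -> np.ndarray:
    angles = np.deg2rad(rng.uniform(-p.rotate_deg, p.rotate_deg, size=3))
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = rng.uniform(1 - p.scale_frac, 1 + p.scale_frac, size=3)
    return (Rx @ Ry @ Rz) * scale


def augment_sample(
    stack: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    p: AugmentParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment a channel-last stack (D,H,W,C) and its label map."""
    if not p.enabled:
        return stack, labels
    shape = np.array(labels.shape, dtype=float)
    center = (shape - 1) / 2.0
    A = _random_affine_matrix(rng, p)
    # coordinates of the output grid mapped back into the input
    grid = np.stack(
        np.meshgrid(*(np.arange(int(s)) for s in shape), indexing="ij"), axis=0
    ).astype(float)
    coords = np.tensordot(np.linalg.inv(A), grid - center[:, None, None, None], axes=1)
    coords += center[:, None, None, None]
    # smooth random displacement field
    for ax in range(3):
        d = rng.standard_normal(labels.shape)
        d = ndimage.gaussian_filter(d, p.elastic_sigma_vox)
        mx = np.abs(d).max()
        if mx > 0:
            d *= p.elastic_amp_vox / mx
        coords[ax] += d

    out_stack = np.empty_like(stack)
    for c in range(stack.shape[-1]):
        out_stack[..., c] = ndimage.map_coordinates(
            stack[..., c], coords, order=1, mode="constant", cval=0.0
        )
    out_labels = ndimage.map_coordinates(
        labels.astype(np.int16), coords, order=0, mode="constant", cval=0
    )
    # intensity jitter then Rician noise per channel
    gains = 1.0 + rng.uniform(
        -p.intensity_jitter, p.intensity_jitter, size=stack.shape[-1]
    )
    out_stack = out_stack * gains
    if p.rician_sigma > 0:
        n1 = rng.standard_normal(out_stack.shape) * p.rician_sigma
        n2 = rng.standard_normal(out_stack.shape) * p.rician_sigma
        out_stack = np.sqrt((out_stack + n1) ** 2 + n2**2)
    return out_stack.astype(np.float32), out_labels


def _foreground_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    """Mean Dice over foreground labels present in the truth."""
    scores = []
    for v in range(1, n_classes):
        t = truth == v
        if not t.any():
            continue
        p_ = pred == v
        denom = p_.sum() + t.sum()
        scores.append(2.0 * np.logical_and(p_, t).sum() / denom if denom else 1.0)
    return float(np.mean(scores)) if scores else float("nan")


def train(
    model: AttentionUNet3D,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    loss_kind: str = "dice",
    epochs: int = 50,
    lr: float = 1e-3,
    val_fraction: float = 0.2,
    augment: AugmentParams | None = None,
    hybrid_alpha: float = 0.5,
    rng_seed: int = 0,
    verbose: bool = False,
    dice_include_background: bool = False,
) -> TrainHistory:
    """Train in place; returns the loss/validation history.

    ``dataset`` is a list of (channel-last stack, integer label map)
    pairs; an 80/20 train-validation split (by ``val_fraction``) is
    drawn deterministically from ``rng_seed``.
    """
    if loss_kind not in ("dice", "boundary", "hybrid"):
        raise ValueError(f"unknown loss {loss_kind!r}")
    if len(dataset) < 2:
        raise ValueError("training needs at least two labeled examples")
    rng = np.random.default_rng(rng_seed)
    n_val = max(1, int(round(val_fraction * len(dataset))))
    if n_val >= len(dataset):
        raise ValueError("validation split leaves no training data")
    perm = rng.permutation(len(dataset))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    augment = augment if augment is not None else AugmentParams()

    V = model.spec.n_classes
    opt = Adam(model.params(), lr=lr)
    history = TrainHistory()

    need_sdm = loss_kind in ("boundary", "hybrid")
    sdm_cache: dict[int, np.ndarray] = {}

    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        ep_loss = 0.0
        for i in order:
            stack, labels = dataset[i]
            stack_a, labels_a = augment_sample(stack, labels, rng, augment)
            x = Tensor(np.moveaxis(stack_a, -1, 0))
            logits = model.forward_logits(x)
            probs = ag.softmax_channels(logits)
            if loss_kind == "dice":
                loss = dice_loss(
                    probs,
                    one_hot(labels_a, V),
                    include_background=dice_include_background,
                )
            else:
                if augment.enabled or i not in sdm_cache:
                    sdms = sdm_stack(labels_a, V)
                else:
                    sdms = sdm_cache.setdefault(i, sdm_stack(labels_a, V))
                if loss_kind == "boundary":
                    loss = boundary_loss(logits, sdms)
                else:
                    loss = hybrid_alpha * dice_loss(
                        probs, one_hot(labels_a, V)
                    ) + (1.0 - hybrid_alpha) * boundary_loss(logits, sdms)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
        history.train_loss.append(ep_loss / max(1, len(order)))

        vd, vl = [], []
        for i in val_idx:
            stack, labels = dataset[i]
            S = model.predict_softmax(stack)
            pred = S.argmax(axis=-1)
            vd.append(_foreground_dice(pred, labels, V))
            vl.append(
                float(
                    dice_loss(
                        Tensor(np.moveaxis(S, -1, 0)), one_hot(labels, V)
                    ).data
                )
            )
        history.val_dice.append(float(np.nanmean(vd)))
        history.val_loss.append(float(np.mean(vl)))
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  train loss {history.train_loss[-1]:.4f}"
                f"  val dice {history.val_dice[-1]:.3f}"
            )
    return history
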