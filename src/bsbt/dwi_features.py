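"""Diffusion-tensor channels and the pons-centered network frame.

The single diffusion tensor is fit by ordinary least squares in
log-signal space (signal model ``S_g = S0 * exp(-b g^T D g)``), and the
derived scalar channels (low-b, FA, MD, AD, RD) plus the principal
eigenvector V1 feed the probabilistic fiber mapping and the network
input stack: a 64x64x64 grid at 1 mm isotropic resolution centered on
the pons, with channel order (low-b, FA, PFM1, PFM2, PFM3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import DWIVolume, ValidationError

CROP_SHAPE = (64, 64, 64)
CROP_RES_MM = 1.0

#: relative signal floor applied before the log-linear fit
SIGNAL_FLOOR_REL = 1e-6


class CapabilityError(RuntimeError):
    """The acquisition cannot support the requested model fit."""


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor as 6 unique coefficients.

    Coefficient order: ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` in mm^2/s.
    ``valid`` flags voxels where the fit succeeded; invalid voxels carry
    zero tensors but remain identifiable.
    """

    coeffs: np.ndarray      # (..., 6)
    valid: np.ndarray       # (...,) bool
    s0: np.ndarray | None = None

    def as_matrices(self) -> np.ndarray:
        """Expand to full (..., 3, 3) symmetric matrices."""
        c = self.coeffs
        D = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
        D[..., 0, 0] = c[..., 0]
        D[..., 1, 1] = c[..., 1]
        D[..., 2, 2] = c[..., 2]
        D[..., 0, 1] = D[..., 1, 0] = c[..., 3]
        D[..., 0, 2] = D[..., 2, 0] = c[..., 4]
        D[..., 1, 2] = D[..., 2, 1] = c[..., 5]
        return D

    def eigenvalues(self, clamp: bool = True) -> np.ndarray:
        """Sorted eigenvalues, descending (lambda1 >= lambda2 >= lambda3)."""
        w = np.linalg.eigvalsh(self.as_matrices())[..., ::-1]
        if clamp:
            w = np.clip(w, 0.0, None)
        return w


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map (log S0, D6) -> log signal: [1, -b*gx^2, -b*gy^2, ...]."""
    b = np.asarray(bvals, float)
    g = np.asarray(bvecs, float)
    cols = np.stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    return cols


def _count_usable_directions(dwi: DWIVolume) -> int:
    dirs = dwi.bvecs[~dwi.b0_mask]
    if len(dirs) == 0:
        return 0
    # distinct up to antipodal symmetry
    canon = dirs * np.sign(dirs[:, [0]] + 1e-12)
    uniq = np.unique(np.round(canon, 6), axis=0)
    return len(uniq)


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Ordinary log-linear least-squares tensor fit per masked voxel.

    Non-positive signals are floored at ``SIGNAL_FLOOR_REL * S0`` before
    the log; all-zero voxels inside the mask are flagged invalid.
    """
    if _count_usable_directions(dwi) < 6:
        raise CapabilityError(
            "tensor fit needs >= 6 distinct non-collinear b>0 directions"
        )
    data = np.asarray(dwi.data, dtype=np.float64)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    X = design_matrix(dwi.bvals, dwi.bvecs)          # (g, 7)
    pinv = np.linalg.pinv(X)                          # (7, g)

    sig = data[mask]                                  # (n, g)
    s0 = sig[:, dwi.b0_mask].mean(axis=1)
    bad = s0 <= 0
    floor = np.where(bad, 1.0, s0)[:, None] * SIGNAL_FLOOR_REL
    logsig = np.log(np.maximum(sig, floor))
    beta = logsig @ pinv.T                            # (n, 7)

    coeffs = np.zeros(data.shape[:3] + (6,), dtype=np.float64)
    valid = np.zeros(data.shape[:3], dtype=bool)
    s0_vol = np.zeros(data.shape[:3], dtype=np.float64)

    vox_coeffs = beta[:, 1:]
    vox_coeffs[bad] = 0.0
    full = np.zeros((mask.sum(), 6))
    full[:] = vox_coeffs
    coeffs[mask] = full
    valid[mask] = ~bad
    s0_vol[mask] = np.exp(np.clip(beta[:, 0], -700, 700)) * (~bad)
    return TensorField(coeffs=coeffs, valid=valid, s0=s0_vol)


def tensor_scalars(tf: TensorField, which: str) -> np.ndarray:
    """Scalar maps from sorted, clamped eigenvalues.

    FA = sqrt(3/2)*||lam - mean||/||lam||; MD = mean; AD = lam1;
    RD = (lam2+lam3)/2. Invalid voxels propagate as 0.
    """
    which = which.upper()
    w = tf.eigenvalues(clamp=True)
    if which == "MD":
        out = w.mean(axis=-1)
    elif which == "AD":
        out = w[..., 0]
    elif which == "RD":
        out = 0.5 * (w[..., 1] + w[..., 2])
    elif which == "FA":
        mean = w.mean(axis=-1, keepdims=True)
        num = np.linalg.norm(w - mean, axis=-1)
        den = np.linalg.norm(w, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
        out = np.clip(out, 0.0, 1.0)
    else:
        raise ValueError(f"unknown scalar {which!r}; expected FA/MD/AD/RD")
    return np.where(tf.valid, out, 0.0)


def principal_direction(
    tf: TensorField, degeneracy_rtol: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel principal eigenvector V1, sign-canonicalized.

    Returns ``(v1, reliable)``. The sign is fixed so the first nonzero
    component is >= 0. Voxels with lambda1 ~ lambda2 (relative gap below
    ``degeneracy_rtol``) are flagged unreliable.
    """
    D = tf.as_matrices()
    w, v = np.linalg.eigh(D)
    v1 = v[..., :, -1]                     # eigenvector of largest eigenvalue
    lam1, lam2 = w[..., -1], w[..., -2]
    scale = np.maximum(np.abs(lam1), 1e-30)
    reliable = tf.valid & ((lam1 - lam2) / scale > degeneracy_rtol)
    # canonical sign: first component with |.| > tol decides
    sign = np.where(
        np.abs(v1[..., 0]) > 1e-12,
        np.sign(v1[..., 0]),
        np.where(
            np.abs(v1[..., 1]) > 1e-12,
            np.sign(v1[..., 1]),
            np.where(v1[..., 2] >= 0, 1.0, -1.0),
        ),
    )
    v1 = v1 * sign[..., None]
    v1 = np.where(tf.valid[..., None], v1, 0.0)
    return v1, reliable


def extract_lowb(dwi: DWIVolume) -> np.ndarray:
    """Voxelwise mean over all b~0 volumes."""
    return np.asarray(dwi.data, dtype=np.float64)[..., dwi.b0_mask].mean(axis=-1)


def center_of_mass_mm(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World-mm center of mass of a binary mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("cannot take center of mass of an empty mask")
    com_vox = np.array(ndimage.center_of_mass(mask))
    return (affine[:3, :3] @ com_vox + affine[:3, 3])


def crop_affine(pons_center_mm: np.ndarray, shape=CROP_SHAPE) -> np.ndarray:
    """Affine of the 1 mm isotropic crop frame centered at the pons."""
    A = np.eye(4)
    A[:3, :3] *= CROP_RES_MM
    center_vox = (np.array(shape) - 1) / 2.0
    A[:3, 3] = np.asarray(pons_center_mm, float) - CROP_RES_MM * center_vox
    return A


def resample_to_crop(
    volume: np.ndarray,
    source_affine: np.ndarray,
    pons_center_mm: np.ndarray,
    order: int = 1,
    shape=CROP_SHAPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one channel onto the pons-centered crop grid.

    Trilinear (``order=1``) for intensity channels, nearest-neighbor
    (``order=0``) for label maps. Out-of-field voxels are zero-filled; a
    warning is issued when the crop window extends more than 50% beyond
    the source field of view.
    """
    volume = np.asarray(volume, dtype=np.float64)
    target_aff = crop_affine(pons_center_mm, shape)
    # voxel coords in source frame for each target voxel
    M = np.linalg.inv(source_affine) @ target_aff
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    tgt = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (M @ tgt)[:3]

    frac_outside = np.mean(
        (src < -0.5).any(axis=0)
        | (src > (np.array(volume.shape)[:, None] - 0.5)).any(axis=0)
    )
    if frac_outside > 0.5:
        warnings.warn(
            f"crop window exceeds source field of view for "
            f"{100 * frac_outside:.0f}% of voxels; zero-filling",
            stacklevel=2,
        )
    out = ndimage.map_coordinates(
        volume, src, order=order, mode="constant", cval=0.0, prefilter=False
    ).reshape(shape)
    return out, target_aff


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def resample_crop(
    lowb: np.ndarray,
    fa: np.ndarray,
    pfm: np.ndarray,
    source_affine: np.ndarray,
    pons_center_mm: np.ndarray,
    shape=CROP_SHAPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 5-channel network input stack in the crop frame.

    Low-b and each PFM channel are min-max normalized to [0,1] inside
    the crop; FA is left as-is (already in [0,1]).

    Returns ``(stack (64,64,64,5), crop affine)``.
    """
    chans = []
    lowb_c, aff = resample_to_crop(lowb, source_affine, pons_center_mm, 1, shape)
    chans.append(_minmax01(lowb_c))
    fa_c, _ = resample_to_crop(fa, source_affine, pons_center_mm, 1, shape)
    chans.append(np.clip(fa_c, 0.0, 1.0))
    pfm = np.asarray(pfm)
    for c in range(3):
        p, _ = resample_to_crop(pfm[..., c], source_affine, pons_center_mm, 1, shape)
        chans.append(_minmax01(np.clip(p, 0.0, 1.0)))
    stack = np.stack(chans, axis=-1)
    if np.isnan(stack).any():
        raise ValidationError("NaNs in assembled channel stack")
    return stack, aff
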