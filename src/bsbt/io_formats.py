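"""On-disk formats and shared conventions.

All volumes travel as NIfTI-1 with RAS-millimetre world coordinates and
0-based voxel indexing; gradient tables use the FSL bval/bvec text dialect
(bvec in 3-row layout). The integer label scheme used throughout the
package is fixed here: eight bilateral brainstem bundles, odd = left,
even = right, 0 = background.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("bsbt")

#: Bundle ordering; label = 2*index+1 (left) or 2*index+2 (right).
BUNDLE_NAMES = ("MLc", "SCP", "LFB", "MHB", "Bic", "MLr", "MLF", "CTG")

#: b-values at or below this threshold (s/mm^2) are treated as b=0.
B0_THRESHOLD = 50.0

N_LABELS = 17  # 16 bundle labels + background


def label_scheme() -> dict[int, tuple[str, str]]:
    """Bijection {1..16} -> (bundle name, side)."""
    scheme = {}
    for k, name in enumerate(BUNDLE_NAMES):
        scheme[2 * k + 1] = (name, "left")
        scheme[2 * k + 2] = (name, "right")
    return scheme


def label_of(bundle: str, side: str) -> int:
    """Inverse of :func:`label_scheme`."""
    k = BUNDLE_NAMES.index(bundle)
    return 2 * k + (1 if side == "left" else 2)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a domain invariant."""


@dataclass
class DWIVolume:
    """A 4D diffusion acquisition with its gradient table.

    ``bvecs`` are stored in the world (scanner) frame, rows = gradients.
    """

    data: np.ndarray          # (x, y, z, g)
    affine: np.ndarray        # 4x4 voxel->world (RAS mm)
    bvals: np.ndarray         # (g,)
    bvecs: np.ndarray         # (g, 3), unit norm where b > 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"DWI data must be 4D, got {self.data.ndim}D")
        g = self.data.shape[3]
        if self.bvals.shape[0] != g or self.bvecs.shape != (g, 3):
            raise FormatError(
                f"gradient table ({self.bvals.shape[0]} bvals, "
                f"{self.bvecs.shape} bvecs) does not match {g} volumes"
            )
        dwi = self.bvals > B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValidationError("b>0 gradient directions must be unit norm")
        if not (~dwi).any():
            raise ValidationError(
                f"no b<= {B0_THRESHOLD:g} s/mm^2 volume present"
            )

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def n_gradients(self) -> int:
        return int(self.data.shape[3])


@dataclass
class LabelMap:
    """Integer-coded segmentation: 0 background, 1..16 bundle labels."""

    data: np.ndarray
    affine: np.ndarray
    scheme: Mapping[int, tuple[str, str]] = field(default_factory=label_scheme)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int16)
            else:
                raise ValidationError("label map grid must be integer-valued")
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi > 16:
            raise ValidationError(
                f"label values must lie in 0..16, found range [{lo}, {hi}]"
            )

    def volumes_mm3(self) -> dict[int, float]:
        """Per-label volume in mm^3 (voxel count x voxel volume)."""
        voxvol = float(abs(np.linalg.det(self.affine[:3, :3])))
        labels, counts = np.unique(self.data, return_counts=True)
        return {
            int(v): float(c) * voxvol for v, c in zip(labels, counts) if v != 0
        }


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D NIfTI plus FSL-dialect bval/bvec gradient table.

    bvecs are given in the image voxel frame (FSL convention) and are
    reoriented to the world frame with the rotation part of the affine.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # 3-row FSL layout -> rows=gradients
    elif bvecs.shape == (3, 3):
        pass  # ambiguous; FSL files are row-major per axis, keep as-is
    if bvecs.shape != (bvals.size, 3):
        raise FormatError(
            f"bvec shape {bvecs.shape} does not match {bvals.size} bvals"
        )
    # rotate voxel-frame directions into world frame
    R = np.asarray(img.affine)[:3, :3].copy()
    scales = np.linalg.norm(R, axis=0)
    scales[scales == 0] = 1.0
    R = R / scales
    world_bvecs = bvecs @ R.T
    nz = np.linalg.norm(world_bvecs, axis=1) > 0
    world_bvecs[nz] /= np.linalg.norm(world_bvecs[nz], axis=1, keepdims=True)
    return DWIVolume(data=data, affine=img.affine, bvals=bvals, bvecs=world_bvecs)


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a label map as integer NIfTI; round-trip is bit-exact."""
    if int(np.count_nonzero(labelmap.data)) == 0:
        warnings.warn("writing an empty (all-background) label map", stacklevel=2)
        logger.warning("writing empty label map to %s", path)
    img = nib.Nifti1Image(labelmap.data.astype(np.int16), labelmap.affine)
    nib.save(img, str(path))


def read_labelmap(path) -> LabelMap:
    img = nib.load(str(path))
    return LabelMap(data=np.asarray(img.dataobj).astype(np.int16), affine=img.affine)


def write_volume(data: np.ndarray, affine: np.ndarray, path, description: str = "") -> None:
    """Write a float scalar/vector volume as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), np.asarray(img.affine)


# --------------------------------------------------------------------------
# Run configuration

#: Flat default configuration for every tunable in the pipeline.
DEFAULT_CONFIG: dict[str, object] = {
    # tractography
    "track.step_mm": 0.5,
    "track.max_angle_deg": 45.0,
    "track.kappa": 30.0,
    "track.seeds_per_voxel": 5,
    "track.max_len_mm": 120.0,
    "track.fa_threshold": 0.10,
    "pfm.clip_pct": 99.0,
    # CRF
    "crf.wu": 1.0,
    "crf.lam": 0.1,
    "crf.sigma_b": 1.0,
    "crf.sigma_k": 5.0,
    "crf.nbhd": 3,
    "crf.iters": 5,
    # U-Net
    "unet.levels": 5,
    "unet.base_features": 24,
    "unet.in_channels": 5,
    "unet.n_classes": 17,
    "unet.attention": True,
    # training
    "train.lr": 1e-3,
    "train.epochs": 50,
    "train.loss": "dice",
    "train.hybrid_alpha": 0.5,
    "train.val_fraction": 0.2,
    "train.augment": True,
    # seeds
    "seed": 0,
}


@dataclass
class RunConfig:
    """Flat key/value configuration; unknown keys are rejected."""

    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULT_CONFIG)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        return cls(values=loaded)

    def digest(self) -> str:
        import hashlib

        blob = json.dumps(self.values, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
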