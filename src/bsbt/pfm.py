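"""Probabilistic fiber map (PFM) construction.

Streamlines are propagated through the diffusion-tensor principal
direction field with a von Mises-Fisher orientation model, seeded from
both regions of each anchor-ROI pair, filtered by pairwise connectivity,
rasterized to per-streamline-unique visitation counts, and
histogram-normalized. The three channels encode connectivity between
thalamus <-> medulla (1), cerebellar gray matter <-> ventral
diencephalon (2), and ventral diencephalon <-> medulla (3).

All tracking happens in the 1 mm isotropic crop frame, so voxel units
and millimetres coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dwi_features import TensorField, principal_direction, tensor_scalars

ROI_NAMES = ("thalamus", "medulla", "cerebellum", "vdc")

#: (channel index, ROI pair) in fixed order
PFM_PAIRS = (
    ("thalamus", "medulla"),
    ("cerebellum", "vdc"),
    ("vdc", "medulla"),
)


@dataclass
class ROISet:
    """Binary anchor masks in the cropped frame."""

    thalamus: np.ndarray
    medulla: np.ndarray
    cerebellum: np.ndarray
    vdc: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def validate(self) -> None:
        masks = [np.asarray(self[n], bool) for n in ROI_NAMES]
        for n, m in zip(ROI_NAMES, masks):
            if m.ndim != 3:
                raise ValueError(f"ROI {n} must be a 3D mask")
        for a in range(len(masks)):
            for b in range(a + 1, len(masks)):
                if (masks[a] & masks[b]).any():
                    raise ValueError(
                        f"ROIs {ROI_NAMES[a]} and {ROI_NAMES[b]} overlap"
                    )

    def union(self) -> np.ndarray:
        out = np.zeros_like(np.asarray(self.thalamus, bool))
        for n in ROI_NAMES:
            out |= np.asarray(self[n], bool)
        return out


@dataclass
class TrackingParams:
    step_mm: float = 0.5
    max_angle_deg: float = 45.0
    kappa: float = 30.0            # vMF concentration; inf = deterministic
    seeds_per_voxel: int = 5
    max_len_mm: float = 120.0
    fa_threshold: float = 0.10


@dataclass
class StreamlineSet:
    """Polyline trajectories in voxel coordinates with provenance."""

    points: list = field(default_factory=list)     # list of (k,3) arrays
    seed_roi: list = field(default_factory=list)   # per-streamline ROI name
    termination: list = field(default_factory=list)  # (reason_bwd, reason_fwd)
    step_mm: float = 0.5

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, idx) -> "StreamlineSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return StreamlineSet(
            points=[self.points[i] for i in idx],
            seed_roi=[self.seed_roi[i] for i in idx],
            termination=[self.termination[i] for i in idx],
            step_mm=self.step_mm,
        )


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one unit vector per row of ``mu`` from vMF(mu, kappa) on S^2."""
    n = mu.shape[0]
    if np.isinf(kappa):
        return mu.copy()
    u = rng.random(n)
    # inverse-CDF for the cosine w of the polar angle (Fisher distribution)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.random(n) * 2.0 * np.pi
    # orthonormal tangent basis at each mu
    ref = np.where(np.abs(mu[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    t1 = np.cross(mu, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(mu, t1)
    s = np.sqrt(np.maximum(0.0, 1.0 - w**2))
    return (
        w[:, None] * mu
        + s[:, None] * (np.cos(phi)[:, None] * t1 + np.sin(phi)[:, None] * t2)
    )


def _in_mask(pos: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mask membership of continuous voxel positions (nearest voxel)."""
    vox = np.round(pos).astype(int)
    shape = np.array(mask.shape)
    inside = ((vox >= 0) & (vox < shape)).all(axis=1)
    out = np.zeros(len(pos), dtype=bool)
    iv = vox[inside]
    out[inside] = mask[iv[:, 0], iv[:, 1], iv[:, 2]]
    return out


def _v1_at(pos: np.ndarray, v1: np.ndarray) -> np.ndarray:
    vox = np.clip(
        np.round(pos).astype(int), 0, np.array(v1.shape[:3]) - 1
    )
    return v1[vox[:, 0], vox[:, 1], vox[:, 2]]


def _track_one_way(
    seeds: np.ndarray,
    init_dirs: np.ndarray,
    v1: np.ndarray,
    mask: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate all seeds simultaneously in one direction.

    Returns ``(paths (n, max_steps+1, 3), lengths (n,), reasons (n,))``
    where lengths count valid points and reasons are termination codes.
    """
    n = len(seeds)
    max_steps = int(np.floor(params.max_len_mm / params.step_mm))
    cos_max = np.cos(np.deg2rad(params.max_angle_deg))
    paths = np.zeros((n, max_steps + 1, 3))
    paths[:, 0] = seeds
    lengths = np.ones(n, dtype=int)
    reasons = np.full(n, "max_len", dtype=object)

    pos = seeds.copy()
    prev = init_dirs.copy()
    active = _in_mask(pos, mask)
    reasons[~active] = "mask_exit"

    for _ in range(max_steps):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        mu = _v1_at(pos[ai], v1)
        # sign-align local V1 with the incoming direction
        flip = np.einsum("ij,ij->i", mu, prev[ai]) < 0
        mu[flip] *= -1
        norms = np.linalg.norm(mu, axis=1)
        dead = norms < 1e-12
        mu[~dead] /= norms[~dead, None]
        step_dir = _sample_vmf(mu, params.kappa, rng)

        cosang = np.einsum("ij,ij->i", step_dir, prev[ai])
        bad_angle = (cosang < cos_max) | dead
        reasons[ai[bad_angle]] = "angle"
        active[ai[bad_angle]] = False

        ok = ai[~bad_angle]
        if len(ok) == 0:
            continue
        newpos = pos[ok] + params.step_mm * step_dir[~bad_angle]
        inside = _in_mask(newpos, mask)
        exited = ok[~inside]
        reasons[exited] = "mask_exit"
        active[exited] = False

        moved = ok[inside]
        pos[moved] = newpos[inside]
        prev[moved] = step_dir[~bad_angle][inside]
        paths[moved, lengths[moved]] = pos[moved]
        lengths[moved] += 1
    return paths, lengths, reasons


def track_probabilistic(
    tf: TensorField,
    seeds: np.ndarray,
    params: TrackingParams,
    mask: np.ndarray,
    rng_seed: int,
    seed_roi: list | None = None,
) -> StreamlineSet:
    """Bidirectional probabilistic tracking from continuous seed points.

    Each step direction is drawn from a von Mises-Fisher distribution
    centered on the sign-aligned local V1 with concentration
    ``params.kappa``, and the streamline terminates on mask exit, an
    angular deviation beyond ``max_angle_deg``, or the length cap.
    Fully reproducible given ``rng_seed``.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    out = StreamlineSet(step_mm=params.step_mm)
    if len(seeds) == 0:
        warnings.warn("empty seed set: no streamlines generated", stacklevel=2)
        return out
    v1, _ = principal_direction(tf)
    rng = np.random.default_rng(rng_seed)

    init = _v1_at(seeds, v1)
    norms = np.linalg.norm(init, axis=1)
    fallback = norms < 1e-12
    init[fallback] = (0.0, 0.0, 1.0)
    init[~fallback] /= norms[~fallback, None]

    fwd_paths, fwd_len, fwd_r = _track_one_way(seeds, init, v1, mask, params, rng)
    bwd_paths, bwd_len, bwd_r = _track_one_way(seeds, -init, v1, mask, params, rng)

    for i in range(len(seeds)):
        back = bwd_paths[i, 1 : bwd_len[i]][::-1]
        fore = fwd_paths[i, : fwd_len[i]]
        out.points.append(np.concatenate([back, fore], axis=0))
        out.seed_roi.append(seed_roi[i] if seed_roi is not None else "")
        out.termination.append((str(bwd_r[i]), str(fwd_r[i])))
    return out


def connectivity_filter(
    s: StreamlineSet, roiA: np.ndarray, roiB: np.ndarray
) -> StreamlineSet:
    """Retain streamlines with at least one point in each ROI."""
    roiA = np.asarray(roiA, bool)
    roiB = np.asarray(roiB, bool)
    keep = []
    for i, pts in enumerate(s.points):
        if len(pts) == 0:
            continue
        inA = _in_mask(pts, roiA).any()
        inB = inA and _in_mask(pts, roiB).any()
        if inB:
            keep.append(i)
    return s.subset(keep)


def visitation_map(s: StreamlineSet, grid_shape) -> np.ndarray:
    """Count distinct streamlines visiting each voxel.

    A streamline increments a voxel at most once regardless of how many
    of its points fall inside it.
    """
    counts = np.zeros(grid_shape, dtype=np.int64)
    shape = np.array(grid_shape)
    for pts in s.points:
        if len(pts) == 0:
            continue
        vox = np.round(pts).astype(int)
        ok = ((vox >= 0) & (vox < shape)).all(axis=1)
        vox = np.unique(vox[ok], axis=0)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return counts


def histogram_normalize(v: np.ndarray, clip_pct: float = 99.0) -> np.ndarray:
    """Clip at the ``clip_pct``-th percentile of nonzero counts, scale to [0,1]."""
    v = np.asarray(v, dtype=np.float64)
    nz = v[v > 0]
    if nz.size == 0:
        return np.zeros_like(v)
    clip = np.percentile(nz, clip_pct)
    if clip <= 0:
        return np.zeros_like(v)
    return np.clip(v, 0.0, clip) / clip


def _seed_points(
    roi: np.ndarray, seeds_per_voxel: int, rng: np.random.Generator
) -> np.ndarray:
    vox = np.argwhere(np.asarray(roi, bool))
    if len(vox) == 0:
        return np.zeros((0, 3))
    rep = np.repeat(vox, seeds_per_voxel, axis=0).astype(float)
    jitter = rng.random(rep.shape) - 0.5  # uniform within the voxel
    return rep + jitter


def build_pfm(
    tf: TensorField,
    rois: ROISet,
    params: TrackingParams,
    rng_seed: int = 0,
    clip_pct: float = 99.0,
) -> np.ndarray:
    """Build the 3-channel PFM volume (shape ``grid + (3,)``).

    For each anchor pair: seed in both ROIs, track, keep pair-connecting
    streamlines, accumulate per-streamline-unique visitation counts, and
    histogram-normalize. A pair with no retained streamlines yields a
    zero channel with a warning.
    """
    rois.validate()
    fa = tensor_scalars(tf, "FA")
    track_mask = (fa > params.fa_threshold) | rois.union()
    shape = fa.shape
    out = np.zeros(shape + (3,), dtype=np.float64)
    root = np.random.SeedSequence(rng_seed)
    child_seeds = root.generate_state(2 * len(PFM_PAIRS))

    for c, (name_a, name_b) in enumerate(PFM_PAIRS):
        roiA = np.asarray(rois[name_a], bool)
        roiB = np.asarray(rois[name_b], bool)
        seed_rng = np.random.default_rng(int(child_seeds[2 * c]))
        seeds = np.concatenate(
            [
                _seed_points(roiA, params.seeds_per_voxel, seed_rng),
                _seed_points(roiB, params.seeds_per_voxel, seed_rng),
            ],
            axis=0,
        )
        roi_tags = [name_a] * (len(seeds) - 0)
        if len(seeds) == 0:
            warnings.warn(
                f"PFM channel {c + 1} ({name_a}<->{name_b}): no seeds; "
                "channel left zero",
                stacklevel=2,
            )
            continue
        sl = track_probabilistic(
            tf,
            seeds,
            params,
            track_mask,
            rng_seed=int(child_seeds[2 * c + 1]),
            seed_roi=roi_tags,
        )
        kept = connectivity_filter(sl, roiA, roiB)
        if len(kept) == 0:
            warnings.warn(
                f"PFM channel {c + 1} ({name_a}<->{name_b}): no streamline "
                "connects the pair; channel left zero",
                stacklevel=2,
            )
            continue
        counts = visitation_map(kept, shape)
        out[..., c] = histogram_normalize(counts, clip_pct)
    return out
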