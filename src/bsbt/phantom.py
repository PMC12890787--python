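"""Synthetic bundle phantoms with ground truth.

Each phantom is a cube of tissue holding up to eight bilateral tubular
bundles (mirror-symmetric about the mid-sagittal plane), four anchor
ROIs (thalamus and ventral diencephalon as rostral slabs, medulla and
cerebellar gray matter as caudal slabs), and a diffusion acquisition
synthesized from an axially symmetric tensor field: inside a tube the
tensor is aligned with the local centerline tangent with eigenvalues
chosen in closed form to hit the bundle's FA target; the background is
nearly isotropic (FA ~ 0.05). The acquisition is a 30-direction
b=1000 s/mm^2 shell plus two b=0 volumes with Rician noise.

Crucially, bundle identity is only fully determined by connectivity:
tubes with matched FA/low-b contrast can connect different anchor
pairs, which is exactly the information the probabilistic fiber map
contributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from scipy import ndimage

from .io_formats import DWIVolume, LabelMap, label_of
from .pfm import ROISet

MD_MM2_S = 0.7e-3          # mean diffusivity everywhere (mm^2/s)
BACKGROUND_FA = 0.05
BACKGROUND_S0 = 1.0
B_SHELL = 1000.0
N_DIRECTIONS = 30

#: ROI slabs in unit-cube fractions: (x0, x1, y0, y1, z0, z1)
ROI_BOXES = {
    "medulla": (0.08, 0.92, 0.31, 0.67, 0.03, 0.12),
    "cerebellum": (0.08, 0.92, 0.72, 0.91, 0.03, 0.12),
    "thalamus": (0.08, 0.92, 0.22, 0.45, 0.88, 0.97),
    "vdc": (0.08, 0.92, 0.53, 0.77, 0.88, 0.97),
}

TUBE_Z0, TUBE_Z1 = 0.07, 0.92   # tube endpoints sit inside the caudal/rostral ROIs


@dataclass
class BundleSpec:
    """One bilateral bundle: geometry in unit-cube fractions."""

    name: str
    pair: tuple[str, str]       # (caudal ROI, rostral ROI)
    x_frac: float               # left tube x; right tube mirrored
    y_bot_frac: float
    y_top_frac: float
    radius_frac: float
    fa_target: float
    lowb_target: float
    #: "linear" drifts in y along the whole tube; "terminal" stays at
    #: y_bot until the rostral quarter, then bends into the target ROI
    y_profile: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.fa_target < 1:
            raise ValueError(f"FA target must be in (0,1), got {self.fa_target}")


#: Default eight-bundle layout. Caudal ROI first; rostral second.
DEFAULT_BUNDLES = (
    BundleSpec("MLc", ("medulla", "thalamus"), 0.38, 0.45, 0.33, 0.040, 0.75, 0.65),
    BundleSpec("SCP", ("cerebellum", "vdc"), 0.30, 0.80, 0.62, 0.052, 0.80, 0.60),
    BundleSpec("LFB", ("medulla", "vdc"), 0.22, 0.48, 0.64, 0.044, 0.70, 0.70),
    BundleSpec("MHB", ("medulla", "vdc"), 0.155, 0.60, 0.74, 0.022, 0.60, 0.72),
    BundleSpec("Bic", ("cerebellum", "vdc"), 0.10, 0.80, 0.53, 0.034, 0.65, 0.68),
    BundleSpec("MLr", ("medulla", "thalamus"), 0.45, 0.36, 0.26, 0.038, 0.72, 0.66),
    BundleSpec("MLF", ("medulla", "thalamus"), 0.47, 0.62, 0.46, 0.026, 0.68, 0.64),
    BundleSpec("CTG", ("medulla", "thalamus"), 0.31, 0.52, 0.36, 0.030, 0.66, 0.67),
)


@dataclass
class LesionSpec:
    center_frac: tuple[float, float, float] = (0.5, 0.5, 0.55)
    radius_frac: float = 0.12          # hemorrhagic core radius
    sigma_frac: float = 0.18           # Gaussian falloff of the displacement
    amplitude_frac: float = 0.08       # peak displacement


@dataclass
class PhantomSpec:
    shape: int = 64
    bundles: tuple = DEFAULT_BUNDLES
    noise_sigma: float = 0.03          # Rician sigma as a fraction of S0
    lesion: LesionSpec | None = None
    rng_seed: int = 0

    def frame_mm(self) -> np.ndarray:
        return np.eye(4)    # 1 mm isotropic, origin at voxel (0,0,0)


@dataclass
class Phantom:
    dwi: DWIVolume
    rois: ROISet
    labels: LabelMap
    fa_true: np.ndarray
    lowb_true: np.ndarray
    v1_true: np.ndarray
    spec: PhantomSpec = None


def fibonacci_directions(n: int = N_DIRECTIONS) -> np.ndarray:
    """Deterministic, nearly uniform unit directions on the hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n                    # upper hemisphere; antipodal symmetry of DWI
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def eigenvalues_for_fa(fa: float, md: float = MD_MM2_S) -> tuple[float, float]:
    """Axially symmetric eigenvalues (lam_par, lam_perp) hitting FA and MD.

    For lam = (l1, l2, l2): FA = (l1 - l2)/sqrt(l1^2 + 2 l2^2); inverting
    gives a quadratic in the ratio r = l2/l1 with one root in (0, 1].
    """
    if not 0 <= fa < 1:
        raise ValueError(f"infeasible FA target {fa}")
    if fa == 0:
        return md, md
    a = 2 * fa**2 - 1
    disc = 4 - 4 * a * (fa**2 - 1)
    roots = []
    for s in (+1, -1):
        if abs(a) > 1e-12:
            roots.append((-2 + s * np.sqrt(disc)) / (2 * a))
        else:
            roots.append((fa**2 - 1) / -2.0)
    r = next(r for r in roots if 0 <= r <= 1)
    lam1 = 3 * md / (1 + 2 * r)
    return lam1, r * lam1


def _roi_mask(box, shape: int) -> np.ndarray:
    m = np.zeros((shape,) * 3, dtype=bool)
    x0, x1, y0, y1, z0, z1 = (int(round(f * (shape - 1))) for f in box)
    m[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
    return m


def make_rois(shape: int) -> ROISet:
    return ROISet(**{k: _roi_mask(v, shape) for k, v in ROI_BOXES.items()})


def _tube_samples(
    b: BundleSpec, side: str, shape: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled centerline points and unit tangents for one tube."""
    n = shape - 1
    x = b.x_frac if side == "left" else 1.0 - b.x_frac
    z_ctrl = np.array([TUBE_Z0, 0.35, 0.65, TUBE_Z1])
    t = (z_ctrl - TUBE_Z0) / (TUBE_Z1 - TUBE_Z0)
    if b.y_profile == "terminal":
        y_ctrl = np.array(
            [b.y_bot_frac, b.y_bot_frac, b.y_bot_frac, b.y_top_frac]
        )
    else:
        y_ctrl = b.y_bot_frac + (b.y_top_frac - b.y_bot_frac) * t
    # gentle lateral bowing so tangents are not exactly axial
    bow = 0.02 * np.sin(np.pi * t) * (1 if side == "left" else -1)
    x_ctrl = np.full(4, x) + bow
    cs_x = CubicSpline(z_ctrl, x_ctrl * n)
    cs_y = CubicSpline(z_ctrl, y_ctrl * n)
    zs = np.linspace(TUBE_Z0, TUBE_Z1, 4 * shape)
    pts = np.stack([cs_x(zs), cs_y(zs), zs * n], axis=1)
    tangents = np.stack([cs_x(zs, 1), cs_y(zs, 1), np.full_like(zs, n)], axis=1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return pts, tangents


def _tensor_from_axis(axis: np.ndarray, lam_par: float, lam_perp: float) -> np.ndarray:
    """Axially symmetric tensor(s) with principal axis ``axis`` (..., 3)."""
    outer = axis[..., :, None] * axis[..., None, :]
    eye = np.eye(3)
    return lam_perp * eye + (lam_par - lam_perp) * outer


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Synthesize one fully ground-truthed phantom (deterministic per seed)."""
    N = spec.shape
    rng = np.random.default_rng(spec.rng_seed)

    # rasterize tubes: nearest centerline wins inside its radius
    all_pts, all_tan, all_label, all_radius = [], [], [], []
    tube_info = []
    for b in spec.bundles:
        for side in ("left", "right"):
            pts, tan = _tube_samples(b, side, N)
            all_pts.append(pts)
            all_tan.append(tan)
            lab = label_of(b.name, side)
            all_label.append(np.full(len(pts), lab))
            all_radius.append(np.full(len(pts), b.radius_frac * N))
            tube_info.append((lab, b))
    pts = np.concatenate(all_pts)
    tan = np.concatenate(all_tan)
    lab_of_pt = np.concatenate(all_label)
    rad_of_pt = np.concatenate(all_radius)

    tree = cKDTree(pts)
    grid = np.stack(
        np.meshgrid(*(np.arange(N),) * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    dist, idx = tree.query(grid, k=1)
    inside = dist <= rad_of_pt[idx]
    labels = np.zeros(N**3, dtype=np.int16)
    labels[inside] = lab_of_pt[idx[inside]]
    labels = labels.reshape(N, N, N)

    # per-voxel tensor and S0
    fa_map = np.full((N, N, N), BACKGROUND_FA)
    s0_map = np.full((N, N, N), BACKGROUND_S0)
    axis = np.zeros((N, N, N, 3))
    axis[..., 2] = 1.0   # background principal axis (nearly isotropic anyway)
    vox_axis = tan[idx[inside]]
    flat_axis = axis.reshape(-1, 3)
    flat_axis[inside] = vox_axis
    axis = flat_axis.reshape(N, N, N, 3)
    by_label = {label_of(b.name, s): b for b in spec.bundles for s in ("left", "right")}
    for lab, b in by_label.items():
        sel = labels == lab
        fa_map[sel] = b.fa_target
        s0_map[sel] = b.lowb_target

    # closed-form eigenvalues per distinct FA
    lam_par = np.empty_like(fa_map)
    lam_perp = np.empty_like(fa_map)
    for fa in np.unique(fa_map):
        lp, lq = eigenvalues_for_fa(float(fa))
        lam_par[fa_map == fa] = lp
        lam_perp[fa_map == fa] = lq

    D = _tensor_from_axis(axis, lam_par[..., None, None], lam_perp[..., None, None])

    dirs = fibonacci_directions()
    bvals = np.concatenate([[0.0, 0.0], np.full(N_DIRECTIONS, B_SHELL)])
    bvecs = np.concatenate([np.zeros((2, 3)), dirs], axis=0)
    # S_g = S0 exp(-b g^T D g)
    quad = np.einsum("gi,...ij,gj->...g", dirs, D, dirs)
    signal = np.empty((N, N, N, len(bvals)))
    signal[..., :2] = s0_map[..., None]
    signal[..., 2:] = s0_map[..., None] * np.exp(-B_SHELL * quad)

    if spec.noise_sigma > 0:
        sig = spec.noise_sigma * BACKGROUND_S0
        n1 = rng.standard_normal(signal.shape) * sig
        n2 = rng.standard_normal(signal.shape) * sig
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    affine = spec.frame_mm()
    dwi = DWIVolume(data=signal, affine=affine, bvals=bvals, bvecs=bvecs)
    rois = make_rois(N)
    labelmap = LabelMap(data=labels, affine=affine)
    phantom = Phantom(
        dwi=dwi,
        rois=rois,
        labels=labelmap,
        fa_true=fa_map,
        lowb_true=s0_map,
        v1_true=axis,
        spec=spec,
    )
    if spec.lesion is not None:
        phantom = apply_lesion(phantom, spec.lesion)
    return phantom


def perturb(
    spec: PhantomSpec,
    rng: np.random.Generator,
    pos_jitter: float = 0.02,
    radius_jitter: float = 0.15,
    fa_jitter: float = 0.04,
) -> PhantomSpec:
    """Random per-subject variation of bundle geometry and contrast."""
    new_bundles = []
    for b in spec.bundles:
        new_bundles.append(
            replace(
                b,
                x_frac=float(
                    np.clip(b.x_frac + rng.uniform(-pos_jitter, pos_jitter), 0.06, 0.48)
                ),
                y_bot_frac=float(b.y_bot_frac + rng.uniform(-pos_jitter, pos_jitter)),
                y_top_frac=float(b.y_top_frac + rng.uniform(-pos_jitter, pos_jitter)),
                radius_frac=float(
                    b.radius_frac * rng.uniform(1 - radius_jitter, 1 + radius_jitter)
                ),
                fa_target=float(
                    np.clip(b.fa_target + rng.uniform(-fa_jitter, fa_jitter), 0.2, 0.95)
                ),
            )
        )
    return replace(spec, bundles=tuple(new_bundles))


def make_ambiguous_pair(
    shape: int = 64,
    noise_sigma: float = 0.03,
    rng_seed: int = 0,
    fa: float = 0.72,
    lowb: float = 0.66,
    radius_frac: float = 0.045,
) -> Phantom:
    """Two tubes with identical scalar contrast but different connectivity.

    Tube A connects thalamus <-> medulla (labeled MLc), tube B connects
    ventral diencephalon <-> medulla (labeled LFB). Both run nearly
    parallel at mid-frame y, their rostral endpoints just inside the
    adjacent borders of the thalamus and VDC masks, so tube geometry is
    almost identical and scalar contrast exactly so: only which anchor
    the streamlines reach — the fiber-map channel — robustly separates
    the two. Which x slot each tube occupies is randomized so lateral
    position carries no identity information across a suite.
    """
    rng = np.random.default_rng(rng_seed)
    slots = [float(rng.uniform(0.16, 0.25)), float(rng.uniform(0.36, 0.45))]
    if rng.integers(2):
        slots.reverse()
    tube_a = BundleSpec(
        "MLc", ("medulla", "thalamus"), slots[0], 0.50, 0.44, radius_frac,
        fa, lowb, y_profile="terminal",
    )
    tube_b = BundleSpec(
        "LFB", ("medulla", "vdc"), slots[1], 0.50, 0.56, radius_frac,
        fa, lowb, y_profile="terminal",
    )
    spec = PhantomSpec(
        shape=shape,
        bundles=(tube_a, tube_b),
        noise_sigma=noise_sigma,
        rng_seed=int(rng.integers(2**31)),
    )
    return generate_phantom(spec)


def displacement_field(
    shape: int, lesion: LesionSpec
) -> np.ndarray:
    """Analytic radial displacement (vox): u(x) = A * exp(-d^2/(2 s^2)) * d_hat."""
    N = shape
    center = np.array(lesion.center_frac) * (N - 1)
    sigma = lesion.sigma_frac * N
    amp = lesion.amplitude_frac * N
    grid = np.stack(np.meshgrid(*(np.arange(N),) * 3, indexing="ij"), axis=-1).astype(
        float
    )
    delta = grid - center
    d = np.linalg.norm(delta, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirn = np.where(d[..., None] > 0, delta / np.maximum(d, 1e-12)[..., None], 0.0)
    mag = amp * np.exp(-(d**2) / (2 * sigma**2))
    return mag[..., None] * dirn


def apply_lesion(ph: Phantom, lesion: LesionSpec) -> Phantom:
    """Mass-effect deformation plus a hemorrhage-like core.

    Tissue is pushed radially away from the lesion center with Gaussian
    falloff, consistently across all channels, ROIs and labels (backward
    warp with the negated field; accurate for the small amplitudes
    used). Core voxels become near-isotropic, dark, and background.
    """
    N = ph.labels.data.shape[0]
    u = displacement_field(N, lesion)
    grid = np.stack(np.meshgrid(*(np.arange(N),) * 3, indexing="ij"), axis=0).astype(
        float
    )
    coords = grid - np.moveaxis(u, -1, 0)   # backward warp

    def warp(vol, order):
        return ndimage.map_coordinates(
            vol, coords, order=order, mode="constant", cval=0.0
        )

    data = np.stack(
        [warp(ph.dwi.data[..., g], 1) for g in range(ph.dwi.data.shape[-1])], axis=-1
    )
    labels = warp(ph.labels.data.astype(np.int16), 0).astype(np.int16)
    rois = ROISet(
        **{
            n: warp(getattr(ph.rois, n).astype(np.uint8), 0).astype(bool)
            for n in ("thalamus", "medulla", "cerebellum", "vdc")
        }
    )
    fa = warp(ph.fa_true, 1)
    lowb = warp(ph.lowb_true, 1)
    v1 = np.stack([warp(ph.v1_true[..., c], 1) for c in range(3)], axis=-1)

    center = np.array(lesion.center_frac) * (N - 1)
    grid_pts = np.moveaxis(grid, 0, -1)
    core = np.linalg.norm(grid_pts - center, axis=-1) <= lesion.radius_frac * N
    lam_iso = MD_MM2_S
    core_s0 = 0.15  # hemorrhage: strongly attenuated signal
    data[core] = core_s0 * np.exp(
        -np.concatenate([[0.0, 0.0], np.full(N_DIRECTIONS, B_SHELL * lam_iso)])
    )
    labels[core] = 0
    fa[core] = BACKGROUND_FA
    lowb[core] = core_s0

    return Phantom(
        dwi=DWIVolume(
            data=data, affine=ph.dwi.affine, bvals=ph.dwi.bvals, bvecs=ph.dwi.bvecs
        ),
        rois=rois,
        labels=LabelMap(data=labels, affine=ph.labels.affine),
        fa_true=fa,
        lowb_true=lowb,
        v1_true=v1,
        spec=ph.spec,
    )
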