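"""End-to-end segmentation: channels -> PFM -> U-Net -> CRF -> labels.

The full route mirrors the method's deployment path: fit the diffusion
tensor in native space, derive low-b/FA/V1, resample everything into
the pons-centered isotropic crop, run probabilistic tractography
between the anchor ROIs to build the PFM, stack the five channels,
infer SoftMax probabilities with the attention-gated U-Net, refine with
the semidense CRF, and map the argmax labels back to native space.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .crf import CRFParams, crf_argmax, mean_field_refine
from .dwi_features import (
    TensorField,
    _minmax01,
    center_of_mass_mm,
    crop_affine,
    extract_lowb,
    fit_tensor,
    principal_direction,
    resample_to_crop,
    tensor_scalars,
)
from .io_formats import DWIVolume, LabelMap, label_of
from .metrics import ICCResult, icc_two_way
from .nn.unet import AttentionUNet3D
from .pfm import ROISet, TrackingParams, build_pfm
from .phantom import Phantom, PhantomSpec, generate_phantom, perturb


@dataclass
class SegmentationResult:
    labels: LabelMap               # native space
    labels_crop: np.ndarray        # crop space, pre-inverse-mapping
    softmax: np.ndarray            # refined probabilities, crop space
    softmax_raw: np.ndarray        # network output before CRF
    pfm: np.ndarray                # crop space (D,H,W,3)
    stack: np.ndarray              # network input (D,H,W,5)
    timings: dict = field(default_factory=dict)


def assemble_stack(
    lowb_c: np.ndarray, fa_c: np.ndarray, pfm_c: np.ndarray
) -> np.ndarray:
    """Normalize and stack crop-frame channels in the fixed order."""
    chans = [_minmax01(lowb_c), np.clip(fa_c, 0.0, 1.0)]
    for c in range(3):
        chans.append(np.clip(pfm_c[..., c], 0.0, 1.0))
    return np.stack(chans, axis=-1).astype(np.float32)


def prepare_input(
    dwi: DWIVolume,
    rois_native: ROISet,
    pons_center_mm: np.ndarray | None = None,
    crop_shape: int = 64,
    track_params: TrackingParams | None = None,
    rng_seed: int = 0,
    scalar: str = "FA",
) -> tuple[np.ndarray, TensorField, ROISet, np.ndarray]:
    """Native DWI + ROIs -> (5-channel stack, crop tensor field, crop ROIs,
    crop affine)."""
    track_params = track_params or TrackingParams()
    shape3 = (crop_shape,) * 3
    tf = fit_tensor(dwi)
    lowb = extract_lowb(dwi)
    if pons_center_mm is None:
        # default: center of the union of anchor ROIs (the brainstem frame)
        pons_center_mm = center_of_mass_mm(rois_native.union(), dwi.affine)

    # resample tensor coefficients into the crop so tracking sees the
    # crop-frame orientation field
    coeffs_c = np.stack(
        [
            resample_to_crop(
                tf.coeffs[..., c], dwi.affine, pons_center_mm, 1, shape3
            )[0]
            for c in range(6)
        ],
        axis=-1,
    )
    valid_c = (
        resample_to_crop(
            tf.valid.astype(np.float64), dwi.affine, pons_center_mm, 0, shape3
        )[0]
        > 0.5
    )
    tf_c = TensorField(coeffs=coeffs_c, valid=valid_c)
    rois_c = ROISet(
        **{
            n: resample_to_crop(
                np.asarray(getattr(rois_native, n), np.float64),
                dwi.affine,
                pons_center_mm,
                0,
                shape3,
            )[0]
            > 0.5
            for n in ("thalamus", "medulla", "cerebellum", "vdc")
        }
    )
    pfm_c = build_pfm(tf_c, rois_c, track_params, rng_seed=rng_seed)
    lowb_c, aff = resample_to_crop(lowb, dwi.affine, pons_center_mm, 1, shape3)
    scalar_c = resample_to_crop(
        tensor_scalars(tf, scalar), dwi.affine, pons_center_mm, 1, shape3
    )[0]
    stack = assemble_stack(lowb_c, scalar_c, pfm_c)
    return stack, tf_c, rois_c, aff


def segment(
    dwi: DWIVolume,
    rois_native: ROISet,
    model: AttentionUNet3D,
    pons_center_mm: np.ndarray | None = None,
    crf_params: CRFParams | None = None,
    crf_on: bool = True,
    track_params: TrackingParams | None = None,
    ablate_pfm: str = "none",
    rng_seed: int = 0,
    scalar: str = "FA",
) -> SegmentationResult:
    """Run the full pipeline on one scan; deterministic given ``rng_seed``."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    stack, tf_c, rois_c, aff = prepare_input(
        dwi,
        rois_native,
        pons_center_mm,
        crop_shape=model.spec.input_size,
        track_params=track_params,
        rng_seed=rng_seed,
        scalar=scalar,
    )
    timings["prepare_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    v1 = None
    if ablate_pfm == "v1":
        v1 = principal_direction(tf_c)[0]
    S_raw = model.predict_softmax(stack, ablate_pfm=ablate_pfm, v1=v1)
    timings["cnn_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if crf_on:
        S = mean_field_refine(S_raw, crf_params or CRFParams())
    else:
        S = S_raw
    labels_crop = crf_argmax(S)
    timings["crf_s"] = time.perf_counter() - t0

    # inverse of the crop resampling: native voxel -> crop voxel, NN
    shape_native = dwi.data.shape[:3]
    M = np.linalg.inv(aff) @ dwi.affine
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape_native), indexing="ij")
    native = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (M @ native)[:3]
    labels_native = ndimage.map_coordinates(
        labels_crop.astype(np.int16), src, order=0, mode="constant", cval=0
    ).reshape(shape_native)

    return SegmentationResult(
        labels=LabelMap(data=labels_native, affine=dwi.affine),
        labels_crop=labels_crop,
        softmax=S,
        softmax_raw=S_raw,
        pfm=stack[..., 2:5].astype(np.float64),
        stack=stack,
        timings=timings,
    )


def testretest_harness(
    model: AttentionUNet3D,
    base_spec: PhantomSpec,
    n_subjects: int = 20,
    noise_sigma: float | None = None,
    seed: int = 0,
    crf_params: CRFParams | None = None,
    track_params: TrackingParams | None = None,
    spec_transform=None,
) -> dict:
    """Synthetic test-retest reliability of per-bundle volumes.

    Each synthetic subject is a random perturbation of ``base_spec``,
    scanned twice with independent noise; both sessions are segmented
    and per-bundle volumes collected, then ICC(A,1) is computed per
    bundle across subjects. Returns bundle -> (ICCResult, volume table).
    """
    rng = np.random.default_rng(seed)
    present = sorted(
        label_of(b.name, s) for b in base_spec.bundles for s in ("left", "right")
    )
    vols = {lab: np.zeros((n_subjects, 2)) for lab in present}
    for subj in range(n_subjects):
        spec_s = perturb(base_spec, rng)
        if spec_transform is not None:
            spec_s = spec_transform(spec_s)
        for sess in range(2):
            spec_scan = PhantomSpec(
                shape=spec_s.shape,
                bundles=spec_s.bundles,
                noise_sigma=(
                    noise_sigma if noise_sigma is not None else spec_s.noise_sigma
                ),
                rng_seed=int(rng.integers(2**31)),
            )
            ph = generate_phantom(spec_scan)
            res = segment(
                ph.dwi,
                ph.rois,
                model,
                crf_params=crf_params,
                track_params=track_params,
                rng_seed=int(rng.integers(2**31)),
            )
            volumes = res.labels.volumes_mm3()
            for lab in present:
                vols[lab][subj, sess] = volumes.get(lab, 0.0)
    iccs: dict[int, ICCResult] = {}
    for lab in present:
        iccs[lab] = icc_two_way(vols[lab])
    return {"icc": iccs, "volumes": vols}
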