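"""Reproducible desk-scale experiment recipes.

These functions bundle the pipeline into the standard experiments run
by the test-suite and the results script: building a training suite of
phantoms, training the reduced ("tiny") model and its zero-PFM
counterpart, and evaluating held-out accuracy, connectivity-ambiguity
resolution, and test-retest reliability.

Problem sizes are deliberately desk-scale: 32-cube phantoms, reduced
feature widths and a bounded epoch budget, chosen so the full study
runs on a single CPU in minutes while exercising every component at
full fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crf import CRFParams
from .dwi_features import fit_tensor
from .io_formats import label_of
from .nn.train import AugmentParams, TrainHistory, train
from .nn.unet import AttentionUNet3D, UNetSpec
from .pfm import TrackingParams, build_pfm
from .phantom import (
    BundleSpec,
    Phantom,
    PhantomSpec,
    generate_phantom,
    make_ambiguous_pair,
    perturb,
)
from .pipeline import assemble_stack, segment, testretest_harness

TINY_SHAPE = 32
TINY_BASE_FEATURES = 6
TINY_EPOCHS = 28
TINY_LR = 3e-3

#: minimum tube radius in voxels for reduced frames. Real bundles are
#: several voxels thick at native resolution; shrinking the frame while
#: keeping radius fractions fixed would make the thinnest bundles
#: sub-voxel, which misrepresents the conditions being scaled down.
MIN_RADIUS_VOX = 1.6

#: Desk-scale bundle layout: four bilateral bundles covering all three
#: fiber-map channels, placed so that every tube keeps >= ~2 voxels of
#: clearance from every other tube (and its own mirror twin) across the
#: whole 32-cube frame under the per-subject jitter used below. The full
#: eight-bundle layout cannot be packed resolvably at this frame size:
#: each lateral slot can host only one thalamus-ending and one
#: VDC-ending tube, because all rostral endpoints crowd those two bands.
TINY_BUNDLES = (
    BundleSpec("MLc", ("medulla", "thalamus"), 0.345, 0.41, 0.38, 0.069, 0.75, 0.65),
    BundleSpec("SCP", ("cerebellum", "vdc"), 0.105, 0.86, 0.74, 0.072, 0.80, 0.60),
    BundleSpec("LFB", ("medulla", "vdc"), 0.345, 0.65, 0.66, 0.072, 0.70, 0.70),
    BundleSpec("MLr", ("medulla", "thalamus"), 0.105, 0.33, 0.25, 0.063, 0.72, 0.66),
)
TINY_N_STANDARD = 10
TINY_N_AMBIGUOUS = 10
TINY_N_HELDOUT = 4

#: tracking defaults reused everywhere a tiny-frame PFM is built
TINY_TRACK = TrackingParams()


def tiny_spec() -> UNetSpec:
    return UNetSpec(
        levels=5,
        base_features=TINY_BASE_FEATURES,
        in_channels=5,
        n_classes=17,
        input_size=TINY_SHAPE,
    )


def phantom_stack(ph: Phantom, rng_seed: int) -> np.ndarray:
    """Front half of the pipeline: phantom -> 5-channel network input."""
    tf = fit_tensor(ph.dwi)
    from .dwi_features import extract_lowb, tensor_scalars

    pfm = build_pfm(tf, ph.rois, TINY_TRACK, rng_seed=rng_seed)
    return assemble_stack(
        extract_lowb(ph.dwi), tensor_scalars(tf, "FA"), pfm
    )


@dataclass
class Suite:
    """Training/evaluation material: (stack, labels) pairs plus phantoms."""

    stacks: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    phantoms: list = field(default_factory=list)
    kinds: list = field(default_factory=list)    # "standard" | "ambiguous"

    def dataset(self, zero_pfm: bool = False):
        out = []
        for s, l in zip(self.stacks, self.labels):
            if zero_pfm:
                s = s.copy()
                s[..., 2:5] = 0.0
            out.append((s, l))
        return out

    def __len__(self):
        return len(self.stacks)


def build_suite(
    n_standard: int = TINY_N_STANDARD,
    n_ambiguous: int = TINY_N_AMBIGUOUS,
    shape: int = TINY_SHAPE,
    noise_sigma: float = 0.03,
    seed: int = 0,
) -> Suite:
    """Mixed suite of perturbed full-layout and connectivity-ambiguous
    phantoms, with PFMs already computed."""
    rng = np.random.default_rng(seed)
    bundles = TINY_BUNDLES if shape < 64 else None
    base = PhantomSpec(shape=shape, noise_sigma=noise_sigma)
    if bundles is not None:
        from dataclasses import replace

        base = replace(base, bundles=bundles)
    base = resolvable_spec(base)
    suite = Suite()
    for _ in range(n_standard):
        spec = resolvable_spec(perturb(base, rng))
        spec = PhantomSpec(
            shape=shape,
            bundles=spec.bundles,
            noise_sigma=noise_sigma,
            rng_seed=int(rng.integers(2**31)),
        )
        ph = generate_phantom(spec)
        suite.phantoms.append(ph)
        suite.stacks.append(phantom_stack(ph, int(rng.integers(2**31))))
        suite.labels.append(ph.labels.data)
        suite.kinds.append("standard")
    for _ in range(n_ambiguous):
        ph = make_ambiguous_pair(
            shape=shape,
            noise_sigma=noise_sigma,
            rng_seed=int(rng.integers(2**31)),
            radius_frac=max(0.045, MIN_RADIUS_VOX / shape),
        )
        suite.phantoms.append(ph)
        suite.stacks.append(phantom_stack(ph, int(rng.integers(2**31))))
        suite.labels.append(ph.labels.data)
        suite.kinds.append("ambiguous")
    return suite


@dataclass
class TrainedModels:
    full: AttentionUNet3D
    zero_pfm: AttentionUNet3D
    history_full: TrainHistory
    history_zero: TrainHistory
    train_suite: Suite
    heldout: Suite


def train_tiny_models(
    seed: int = 0,
    epochs: int = TINY_EPOCHS,
    train_zero_pfm: bool = True,
    verbose: bool = False,
) -> TrainedModels:
    """Train the reduced model (and its zero-PFM ablation) on a fresh suite.

    The zero-PFM model sees the same stacks with fiber-map channels
    zeroed, isolating the contribution of connectivity contrast.
    """
    rng = np.random.default_rng(seed)
    suite = build_suite(seed=int(rng.integers(2**31)))
    heldout = build_suite(
        n_standard=TINY_N_HELDOUT,
        n_ambiguous=4,
        seed=int(rng.integers(2**31)),
    )
    aug = AugmentParams(
        elastic_amp_vox=0.5, rotate_deg=5.0, scale_frac=0.05, rician_sigma=0.01
    )
    model_seed = int(rng.integers(2**31))
    train_seed = int(rng.integers(2**31))

    full = AttentionUNet3D(tiny_spec(), rng_seed=model_seed)
    hist_full = train(
        full,
        suite.dataset(),
        loss_kind="dice",
        epochs=epochs,
        lr=TINY_LR,
        augment=aug,
        rng_seed=train_seed,
        verbose=verbose,
        dice_include_background=True,
    )
    if train_zero_pfm:
        zero = AttentionUNet3D(tiny_spec(), rng_seed=model_seed)
        hist_zero = train(
            zero,
            suite.dataset(zero_pfm=True),
            loss_kind="dice",
            epochs=epochs,
            lr=TINY_LR,
            augment=aug,
            rng_seed=train_seed,
            verbose=verbose,
            dice_include_background=True,
        )
    else:
        zero, hist_zero = None, None
    return TrainedModels(
        full=full,
        zero_pfm=zero,
        history_full=hist_full,
        history_zero=hist_zero,
        train_suite=suite,
        heldout=heldout,
    )


def heldout_mean_dice(model: AttentionUNet3D, suite: Suite, zero_pfm=False) -> float:
    """Mean foreground Dice over held-out phantoms (labels present in truth)."""
    from .nn.train import _foreground_dice

    scores = []
    for s, l in zip(suite.stacks, suite.labels):
        S = model.predict_softmax(s, ablate_pfm="zero" if zero_pfm else "none")
        scores.append(_foreground_dice(S.argmax(axis=-1), l, model.spec.n_classes))
    return float(np.nanmean(scores))


#: anchor-pair family of every label: which PFM channel its bundle rides
PAIR_OF_LABEL = {}
for _b in (
    ("MLc", 0), ("SCP", 1), ("LFB", 2), ("MHB", 2),
    ("Bic", 1), ("MLr", 0), ("MLF", 0), ("CTG", 0),
):
    PAIR_OF_LABEL[label_of(_b[0], "left")] = _b[1]
    PAIR_OF_LABEL[label_of(_b[0], "right")] = _b[1]


def _pair_mask(labels: np.ndarray, pair: int) -> np.ndarray:
    out = np.zeros(labels.shape, bool)
    for lab, p in PAIR_OF_LABEL.items():
        if p == pair:
            out |= labels == lab
    return out


def ambiguity_dice(
    model: AttentionUNet3D, suite: Suite, zero_pfm: bool = False
) -> float:
    """Mean per-pair Dice on the connectivity-ambiguous phantoms.

    Labels are grouped by their anchor-pair family (the connectivity the
    PFM channel encodes) and scored within the phantom's true foreground
    voxels: the score asks whether the model tells thalamus-medulla
    tissue from VDC-medulla tissue on the tubes themselves — exactly
    the information scalar contrast cannot supply. Individual bundle
    identity within a family is positional, and background errors are
    the business of the overall accuracy score, so neither contaminates
    this comparison.
    """
    from .metrics import dice as _dice

    scores = []
    for s, l, kind in zip(suite.stacks, suite.labels, suite.kinds):
        if kind != "ambiguous":
            continue
        fg = l > 0
        S = model.predict_softmax(s, ablate_pfm="zero" if zero_pfm else "none")
        pred = S.argmax(axis=-1)
        for pair in (0, 2):          # Thal-Med and VDC-Med families
            t = _pair_mask(l, pair) & fg
            if t.any():
                scores.append(_dice(_pair_mask(pred, pair) & fg, t))
    return float(np.mean(scores))


def resolvable_spec(spec: PhantomSpec) -> PhantomSpec:
    """Keep tubes resolvable in a reduced frame.

    Radii are clamped to at least MIN_RADIUS_VOX voxels, and tube
    centers are kept at least radius + 1 voxel away from the
    mid-sagittal plane so a bundle and its mirror twin never merge —
    at full scale both properties hold by construction.
    """
    from dataclasses import replace

    floor = MIN_RADIUS_VOX / spec.shape
    bundles = []
    for b in spec.bundles:
        r = max(b.radius_frac, floor)
        x_max = 0.5 - r - 1.0 / spec.shape
        bundles.append(replace(b, radius_frac=r, x_frac=min(b.x_frac, x_max)))
    return replace(spec, bundles=tuple(bundles))


def tiny_crf_params() -> CRFParams:
    """CRF defaults scaled to the 32-cube frame (kernel ~ bundle radius)."""
    return CRFParams(sigma_k=2.0, nbhd=3, iters=5)


def run_testretest(model: AttentionUNet3D, n_subjects: int = 20, seed: int = 0):
    base = resolvable_spec(
        PhantomSpec(shape=TINY_SHAPE, bundles=TINY_BUNDLES, noise_sigma=0.03)
    )
    return testretest_harness(
        model,
        base,
        n_subjects=n_subjects,
        seed=seed,
        crf_params=tiny_crf_params(),
        track_params=TINY_TRACK,
        spec_transform=resolvable_spec,
    )
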