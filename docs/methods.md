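# Methods

`bsbt` segments the eight bilateral white-matter bundles of the human
brainstem (MLc, SCP, LFB, MHB, Bic, MLr, MLF, CTG; left/right coded as
odd/even integer labels 1–16, 0 = background) directly from diffusion
MRI. The pipeline has three stages: a connectivity prior (the
probabilistic fiber map), a convolutional segmenter (an
attention-gated 3D U-Net), and a probabilistic label refiner (a
semidense CRF). This note records the model, its assumptions, the
numerical choices, and what the synthetic phantom studies do and do not
demonstrate.

## Input frame and diffusion channels

All learning and inference happens in a pons-centered, 1 mm isotropic,
64×64×64 crop (`dwi_features.resample_crop`). The pons center comes
from a user-supplied mask's center of mass or an explicit coordinate;
localization itself is out of scope. Channels are ordered (low-b, FA,
PFM1, PFM2, PFM3). Low-b is the voxelwise mean of all volumes with
b ≤ 50 s/mm² (a tolerance covering common scanner practice for
"b=0"); low-b and each PFM channel are min–max normalized to [0,1]
inside the crop, FA is already in [0,1] and left untouched. A fixed
normalization rule was required for cross-scan comparability; min–max
inside the crop is the simplest choice that is invariant to global
scanner gain.

The diffusion tensor is fit by ordinary least squares in log-signal
space under the monoexponential model S_g = S0·exp(−b gᵀDg), with
signals floored at 1e-6·S0 before the log. OLS (rather than WLS or
robust variants) is deterministic and exact on noiseless data, which
makes the parameter-recovery property testable to solver precision; at
phantom-scale SNR the WLS refinement is immaterial. Eigenvalues are
clamped at zero before scalar derivation, so FA ∈ [0,1] everywhere by
construction. FA = √(3/2)·‖λ−λ̄‖/‖λ‖, MD = λ̄, AD = λ₁,
RD = (λ₂+λ₃)/2; V1 is the principal eigenvector, sign-canonicalized
(first nonzero component ≥ 0) and flagged unreliable where
λ₁ ≈ λ₂ (relative gap < 1e-3).

## Probabilistic fiber map

The PFM encodes anchor-pair connectivity as image contrast. Three
channels correspond to streamlines connecting thalamus↔medulla,
cerebellar gray matter↔ventral diencephalon, and ventral
diencephalon↔medulla. Per channel: seed 5 points per voxel (uniformly
jittered within the voxel) in both anchor ROIs, track bidirectionally,
keep exactly the streamlines with at least one point in each ROI of the
pair, count distinct streamlines per voxel (a streamline increments a
voxel at most once), clip the counts at the 99th percentile of nonzero
values and divide by that clip value.

The tracker is a tensor-based probabilistic walker: each 0.5 mm step
direction is drawn from a von Mises–Fisher distribution on the sphere
centered on the sign-aligned local V1 with concentration κ = 30, and
the streamline terminates when it leaves the tracking mask
(FA > 0.10 ∪ anchor ROIs), deviates more than 45° from the previous
step, or reaches 120 mm. κ = 30 concentrates ~95% of samples within
~20° of the mean direction — dispersive enough to explore branch
geometry, tight enough that a coherent tube is recovered essentially
completely (the zero-dispersion limit κ → ∞ is exact and is used as
the deterministic oracle). The step length (half the voxel size)
guarantees no voxel is skipped on straight paths with point-membership
rasterization. All randomness flows from one seed; tracking is
bit-reproducible.

Assumption inherited by the design: a single tensor per voxel. Crossing
fibers are not modeled; the phantoms avoid tube intersections for this
reason, and performance near real crossings is not demonstrated by any
test here.

## Attention-gated U-Net

Five resolution levels, feature widths 24·2^(n−1) = [24, 48, 96, 192,
384], spatial sizes [64, 32, 16, 8, 4]; per level two 3×3×3
convolutions with ELU activations; max-pool stride-2 downsampling;
trilinear-upsample + convolution between decoder levels; final 1×1×1
convolution to 17 logits and a SoftMax. Each convolution is followed by
per-channel instance normalization with learned affine terms. The
architecture summary this follows does not mention normalization, but
at batch size 1 the plain stack is not trainable in practice: logits
grow unboundedly, the SoftMax saturates, and the Dice gradient
vanishes (we measured exactly this failure). Instance norm is the
standard remedy for single-volume 3D training and changes none of the
audited quantities (levels, widths, kernels, gate placement).

The attention gate acts only on the finest skip connection:

    gated = Fd1 ∘ σ( φa ⊗ relu(Fe1) + Σ_{n=2..4} φn ⊗ tanh(U(Fdn)) )

with all φ 1×1×1 single-channel convolutions, U trilinear upsampling to
full resolution, and ∘ broadcasting the single-channel gate over Fd1's
channels. Three deliberate readings of the ambiguous formula are baked
in and documented: (1) the tanh-transformed decoder signals are summed
*inside* the sigmoid with the encoder term; (2) the gating sum stops at
level 4 — the coarsest level's 4³ features are excluded; (3) the gate
multiplies the *decoder* feature Fd1, not the encoder feature as in
conventional attention U-Nets. An independent straight-line
transcription of the formula serves as the oracle in the tests. With
all gate weights zero the gate is exactly σ(0) = 0.5.

Losses: soft Dice over the 16 foreground labels with ε = 1e-5
smoothing (1 − mean_v (2Σ S·g + ε)/(ΣS + Σg + ε)). The training recipe
includes the background term in that mean
(`dice_loss(include_background=True)`): a loss blind to background
leaves the background channel unsupervised, and we observed it collapse
on subjects outside the training suite — thin-bundle labels flooding
thousands of background voxels, which ruins volume reliability. The
foreground-only form remains the default of the exported op. Also
available: a boundary loss —
the mean L1 distance between foreground logits and the *negated*
signed distance map, so logits are trained positive inside a structure
(the sign convention was open; this one makes the logit a smooth
inside-ness score); and a hybrid α·Dice + (1−α)·boundary with α = 0.5.
SDMs are Euclidean distances to the label's boundary voxels, negative
inside, zero on the boundary, and a constant grid-diagonal for absent
labels. Optimization is Adam; the training loop is batch-size 1,
deterministic per seed, with augmentation (random affine ±10°/±10%
scale, smooth elastic deformation, ±10% per-channel intensity jitter,
Rician noise injection) applied identically to channels and labels.

The network, its gradients and the optimizer are implemented in-repo on
numpy: reverse-mode autodiff with im2col convolutions chunked along
depth to bound memory, and per-axis interpolation-matrix resampling so
the upsampling adjoint is exactly the transposed matrix.

## Semidense CRF

The SoftMax field S (N voxels × 17 labels) is refined under three
potentials: unary ψu = −log S weighted wu; a pairwise
spatial-intensity similarity, approximated semidensely by convolving
the probability field with an isotropic Gaussian K_σK (σK = 5 voxels,
truncated at 3σ, reflect boundary so constants are preserved — the
defining trivial limit of the approximation) over a Chebyshev
neighborhood of half-span 3; and a foreground-label entropy ψH
weighted λ that sharpens foreground probabilities without background
interference (label 0 is background everywhere; one printed form
indexes background as v=1, the indicator form as v≠0 — we fix 0).

`crf_energy` evaluates the composite energy exactly as printed,
including the 1/(4πσbσK) pairwise factor taken at face value, and
reports a per-term breakdown; it is a diagnostic oracle, checked
against a brute-force triple loop, and deliberately independent of the
solver so the solver can be swapped without changing the acceptance
surface.

The mean-field update (the update equations were not specified; this
scheme is the coordinate-wise stationarity contribution of each term)
computes per-voxel logits

    wu·log S + (K_σK ⊗ Q)/(2 σb σK) + λ·1[v≠0]·log Q

and softmax-renormalizes, for exactly `iters` = 5 iterations, no early
stopping — cost is linear in the iteration count and independent of
content. With pairwise and entropy disabled and wu = 1 the update is
the identity (tested to 1e-12). Probabilities are floored at 1e-12
before any log. Argmax ties are broken toward background,
conservative for small structures.

Scale analysis used for the denoising demonstrations: a corrupted voxel
with wrong-label confidence p flips back when the smoothed
neighborhood support difference (≈ΔQ/(2σbσK)) exceeds the unary
log-odds ln(p/(1−p−ε)). On 16³ two-region instances we use σK = 2 (the
region-width rule regions ≥ 3σK cannot hold at σK = 5 on a 16-voxel
frame) and σb = 0.5, giving support scale ≈ 0.44 against unary
log-odds 0.25 at p = 0.55 — the neighborhood term dominates by
construction. σK = 5 and half-span 3 remain the full-frame defaults;
for 32³ phantom work the kernel is scaled to σK = 2 to match bundle
radii.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline relies
on, not brainstem anatomy: eight bilateral tubes (cubic-spline
centerlines, mirror-symmetric about the mid-sagittal plane, radii
chosen so per-bundle voxel counts span a ≳5× range, matching the
field's observation that segmentation accuracy is volume-dependent),
four anchor-ROI slabs at the tube endpoints, and a 30-direction
b = 1000 s/mm² shell plus two b0 volumes synthesized from axially
symmetric tensors whose eigenvalues are the closed-form inversion of
the FA formula at fixed MD = 0.7e-3 mm²/s. Background is nearly
isotropic (FA 0.05). Rician noise is |signal + complex Gaussian| with
σ = 3% of the background S0 — HCP-grade SNR ≈ 33. Tube FA targets
(0.60–0.80) and low-b targets (0.60–0.72 of background) sit in the
range of real deep white matter.

Two special constructions: the *connectivity-ambiguous pair* — two
near-parallel tubes with identical FA, low-b and radius, one reaching
the thalamus, one the ventral diencephalon. Both run at the same
mid-frame y for three quarters of their length and only bend apart in
a short terminal segment into endpoints just inside the adjacent
borders of the two rostral masks; their lateral slots are randomly
swapped across a suite. Neither scalar contrast nor bulk geometry then
carries identity information — only connectivity (i.e., the PFM
channel) labels the tube along its whole length. Ambiguity accuracy is scored as *per-pair*
Dice: predicted and true labels are grouped by anchor-pair family
before overlap is computed, because membership within a family (e.g.,
MLc vs MLF, both thalamus↔medulla) is positional rather than
connectivity-determined. The second construction is the *lesion*
transform — a radial
Gaussian mass-effect displacement applied consistently to all channels
and labels (backward warp with the negated field, accurate to first
order at the small amplitudes used) plus a hemorrhage-like core (dark,
near-isotropic, label 0).

What the phantoms do **not** contain: crossing or kissing fibers,
partial voluming, susceptibility distortion, ghosting, anatomically
realistic bundle shapes, or inter-protocol domain shift. Passing the
phantom studies therefore demonstrates the machinery (each operator
matches its oracle; connectivity information flows end to end), not
clinical performance.

## Desk-scale study sizes

The training/ablation/reliability studies run on one CPU in minutes by
scaling the problem down, not by changing the method: 32³ phantoms
(whole volumes as network inputs), carrying four bilateral bundles
(MLc, SCP, LFB, MLr — all three fiber-map channels represented) in a
layout verified to keep ≥ ~2 voxels of clearance between every pair of
tubes, including mirror twins, under the per-subject jitter. Real
bundles are several voxels thick and mutually separated at acquisition
resolution; shrinking the frame while keeping the full eight-bundle
layout's geometric *fractions* fixed makes the thinnest bundles
sub-voxel and merges near-midline left/right twins — scaling
artifacts, not a harder version of the same problem. A packing
analysis shows eight bundles cannot fit a 32-cube resolvably: every
lateral slot can host only one thalamus-ending and one VDC-ending
tube, because all rostral endpoints crowd those two bands. The
eight-bundle layout remains the 64-cube default. Training uses a
U-Net with base width 6 ([6,12,24,48,96]), 20 training phantoms (10
perturbed full-layout + 10 ambiguous-pair, an even split so the
connectivity rule is represented strongly enough to be learned rather
than memorized) with an 80/20 split, 28 epochs of Adam at lr 3e-3 (the
higher rate suits the reduced width; 1e-3 remains the library
default), light augmentation, and an 8-phantom held-out suite (4
full-layout + 4 ambiguous). The zero-PFM ablation model is trained identically on
the same stacks with fiber-map channels zeroed. The test-retest study
segments 20 synthetic subjects (random geometry/contrast
perturbations) twice with independent noise and computes per-bundle
volume ICC(A,1) — two-way mixed-effects, absolute agreement, single
measurement, with F-distribution confidence bounds.

## Known limitations

- Single-tensor tracking cannot represent crossings; PFM contrast in
  crossing regions of real brains will be weaker than in phantoms.
- The 1/(2π) pairwise factor in the printed energy is adopted
  verbatim; its derivation is unknown, and the energy's sign makes the
  pairwise term reward smoothed-probability differences. Since the
  solver is stationarity-based and tested on its own limits, the
  energy's role here is purely diagnostic.
- Min–max channel normalization is sensitive to single extreme voxels
  in principle; the PFM channels are percentile-clipped upstream, which
  bounds that risk for the channels where it matters.
- The left/right integer coding is self-consistent but arbitrary;
  external label files using another convention must be remapped.
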