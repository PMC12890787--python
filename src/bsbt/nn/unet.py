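"""Attention-gated five-level 3D U-Net for bundle segmentation.

Architecture: five resolution levels with feature widths
``base * 2**(n-1)`` (defaults to [24, 48, 96, 192, 384]), two 3x3x3
convolutions with ELU activations per level, max-pool stride-2
downsampling, trilinear-upsample + convolution between decoder levels,
and a final 1x1x1 convolution to the class logits.

The attention gate acts only on the finest skip connection: the gate
field is ``sigmoid(phi_a * relu(Fe1) + sum_n phi_n * tanh(U(Fdn)))``
with 1x1x1 convolutions ``phi`` producing a single channel, gating
signals taken from decoder levels 2..N-1 (the coarsest level is
excluded), each trilinearly upsampled to full resolution. The gate
multiplies the decoder feature ``Fd1`` (not the encoder feature, unlike
conventional attention U-Nets) before the final decoding convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


@dataclass
class UNetSpec:
    levels: int = 5
    base_features: int = 24
    in_channels: int = 5
    n_classes: int = 17
    input_size: int = 64
    kernel: int = 3
    attention: bool = True

    def feature_widths(self) -> list[int]:
        return [self.base_features * 2 ** (n - 1) for n in range(1, self.levels + 1)]

    def spatial_sizes(self) -> list[int]:
        return [self.input_size // 2 ** (n - 1) for n in range(1, self.levels + 1)]

    def validate(self) -> None:
        if self.input_size % 2 ** (self.levels - 1) != 0:
            raise ValueError("input_size must be divisible by 2**(levels-1)")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")


def _he_init(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    fan_in = cin * k**3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k, k))


class Conv3d:
    def __init__(self, rng, cin: int, cout: int, k: int):
        self.k = k
        self.w = Parameter(_he_init(rng, cout, cin, k))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, self.k)

    def params(self):
        return [self.w, self.b]


class InstanceNorm:
    def __init__(self, c: int):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gamma, self.beta)

    def params(self):
        return [self.gamma, self.beta]


class ConvBlock:
    """Two same-padded convolutions, each followed by instance
    normalization and an ELU activation.

    Instance norm (channelwise spatial normalization) is the standard
    stabilizer for batch-size-1 volumetric training; without it the
    five-level stack saturates its SoftMax early and Dice gradients
    vanish.
    """

    def __init__(self, rng, cin: int, cout: int, k: int):
        self.c1 = Conv3d(rng, cin, cout, k)
        self.n1 = InstanceNorm(cout)
        self.c2 = Conv3d(rng, cout, cout, k)
        self.n2 = InstanceNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.elu(self.n2(self.c2(ag.elu(self.n1(self.c1(x))))))

    def params(self):
        return (
            self.c1.params() + self.n1.params() + self.c2.params() + self.n2.params()
        )


@dataclass
class AttentionGateWeights:
    """1x1x1 gating convolutions: phi_a on the encoder pathway, phi_n on
    each upsampled decoder gating signal; all map to a single channel."""

    phi_a: Conv3d = None
    phi_n: dict = field(default_factory=dict)   # level -> Conv3d

    def params(self):
        out = self.phi_a.params()
        for c in self.phi_n.values():
            out += c.params()
        return out


def attention_gate(
    fd1: Tensor,
    fe1: Tensor,
    gating: dict[int, Tensor],
    w: AttentionGateWeights,
) -> Tensor:
    """Gate the finest decoder feature with multi-scale decoder signals.

    Returns ``fd1 * sigmoid(phi_a(relu(fe1)) + sum_n phi_n(U(gating[n])))``
    where U is trilinear upsampling to fd1's resolution and the gate (a
    single channel) broadcasts across fd1's channels.
    """
    if fd1.data.shape[1:] != fe1.data.shape[1:]:
        raise ValueError(
            f"Fd1 {fd1.data.shape} and Fe1 {fe1.data.shape} must share "
            "spatial dimensions"
        )
    target = fd1.data.shape[1:]
    pre = w.phi_a(ag.relu(fe1))
    for n in sorted(gating):
        up = ag.upsample_trilinear(gating[n], target)
        pre = pre + w.phi_n[n](ag.tanh(up))
    gate = ag.sigmoid(pre)      # (1, D, H, W), broadcasts over channels
    return ag.mul(fd1, gate)


class AttentionUNet3D:
    """The full encoder/decoder with optional attention ablation."""

    def __init__(self, spec: UNetSpec, rng_seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        k = spec.kernel
        widths = spec.feature_widths()
        L = spec.levels

        self.enc = []
        cin = spec.in_channels
        for n in range(L):
            self.enc.append(ConvBlock(rng, cin, widths[n], k))
            cin = widths[n]

        # decoder level n (1-based, fine to coarse): upsample from n+1,
        # reduce width, concat encoder skip, two convs
        self.up_conv = {}
        self.dec = {}
        for n in range(L - 1, 0, -1):   # levels L-1 .. 1 produce Fd_{n}
            self.up_conv[n] = Conv3d(rng, widths[n], widths[n - 1], k)
            self.dec[n] = ConvBlock(rng, 2 * widths[n - 1], widths[n - 1], k)

        if spec.attention:
            self.gate_w = AttentionGateWeights(phi_a=Conv3d(rng, widths[0], 1, 1))
            for n in range(2, L):       # decoder levels 2..L-1; coarsest excluded
                self.gate_w.phi_n[n] = Conv3d(rng, widths[n - 1], 1, 1)
        else:
            self.gate_w = None

        self.head = Conv3d(rng, widths[0], spec.n_classes, 1)

    def params(self):
        out = []
        for b in self.enc:
            out += b.params()
        for n in self.up_conv:
            out += self.up_conv[n].params() + self.dec[n].params()
        if self.gate_w is not None:
            out += self.gate_w.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def forward_logits(self, x: Tensor) -> Tensor:
        """Input (in_channels, D, H, W) -> logits (n_classes, D, H, W)."""
        if x.data.shape[0] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, "
                f"got {x.data.shape[0]}"
            )
        L = self.spec.levels
        skips = []
        h = x
        for n in range(L):
            h = self.enc[n](h)
            skips.append(h)
            if n < L - 1:
                h = ag.maxpool2(h)

        fd = {L: skips[-1]}             # bottleneck acts as the coarsest Fd
        for n in range(L - 1, 0, -1):
            target = skips[n - 1].data.shape[1:]
            up = self.up_conv[n](ag.upsample_trilinear(fd[n + 1], target))
            if n == 1 and self.gate_w is not None:
                gating = {m: fd[m] for m in self.gate_w.phi_n}
                up = attention_gate(up, skips[0], gating, self.gate_w)
            h = self.dec[n](ag.concat_channels(skips[n - 1], up))
            fd[n] = h
        return self.head(fd[1])

    def predict_softmax(self, stack: np.ndarray, ablate_pfm: str = "none",
                        v1: np.ndarray | None = None) -> np.ndarray:
        """SoftMax inference on a channel-last stack (D, H, W, C).

        ``ablate_pfm='zero'`` replaces channels 3-5 with zeros;
        ``'v1'`` replaces them with the principal-eigenvector components.
        Returns a channel-last probability field (D, H, W, V).
        """
        x = np.asarray(stack, dtype=np.float32)
        if ablate_pfm not in ("none", "zero", "v1"):
            raise ValueError(f"unknown ablate_pfm {ablate_pfm!r}")
        if ablate_pfm == "zero":
            x = x.copy()
            x[..., 2:5] = 0.0
        elif ablate_pfm == "v1":
            if v1 is None:
                raise ValueError("ablate_pfm='v1' requires the V1 field")
            x = x.copy()
            x[..., 2:5] = v1
        if x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"stack has {x.shape[-1]} channels, model expects "
                f"{self.spec.in_channels}"
            )
        xt = Tensor(np.moveaxis(x, -1, 0))
        logits = self.forward_logits(xt)
        probs = ag.softmax_channels(logits)
        return np.moveaxis(probs.data.astype(np.float64), 0, -1)

    # -- persistence ----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()]

    def save(self, path) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.state_arrays())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.spec)))

    @classmethod
    def load(cls, path) -> "AttentionUNet3D":
        import json
        from pathlib import Path

        path = Path(path)
        spec = UNetSpec(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(spec)
        with np.load(path.with_suffix(".npz")) as z:
            arrays = [z[k] for k in z.files]
        for p, a in zip(model.params(), arrays, strict=True):
            p.data = a.astype(np.float32)
        return model
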