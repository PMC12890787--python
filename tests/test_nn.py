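"""Network engine: gate formula, architecture audit, losses, training
bookkeeping, inference contracts."""

import numpy as np
import pytest

from bsbt.nn import autograd as ag
from bsbt.nn.autograd import Tensor
from bsbt.nn.losses import (
    boundary_loss,
    dice_loss,
    one_hot,
    sdm_stack,
    signed_distance_map,
)
from bsbt.nn.unet import (
    AttentionGateWeights,
    AttentionUNet3D,
    Conv3d,
    UNetSpec,
    attention_gate,
)


def reference_gate(fd1, fe1, gating, w):
    """Independent literal transcription of the gating formula with plain
    numpy loops over channels: Fd1 o sigmoid(phi_a x relu(Fe1) +
    sum_n phi_n x tanh(U(Fdn)))."""

    def conv1(x, conv):
        # 1x1x1 convolution = channel mixing
        wmat = conv.w.data.reshape(conv.w.data.shape[0], conv.w.data.shape[1])
        return np.tensordot(wmat, x, axes=([1], [0])) + conv.b.data[
            :, None, None, None
        ]

    def upsample(x, shape):
        from bsbt.nn.autograd import interp_matrix

        y = x
        for ax in range(3):
            M = interp_matrix(y.shape[1 + ax], shape[ax])
            y = np.moveaxis(np.tensordot(M, y, axes=([1], [1 + ax])), 0, 1 + ax)
        return y

    pre = conv1(np.maximum(fe1, 0.0), w.phi_a)
    for n in sorted(gating):
        up = upsample(gating[n], fd1.shape[1:])
        pre = pre + conv1(np.tanh(up), w.phi_n[n])
    gate = 1.0 / (1.0 + np.exp(-pre))
    return fd1 * gate


def _mk_gate_weights(rng, c1, cn, zero=False):
    gw = AttentionGateWeights(phi_a=Conv3d(rng, c1, 1, 1))
    gw.phi_n = {2: Conv3d(rng, cn[0], 1, 1), 3: Conv3d(rng, cn[1], 1, 1)}
    if zero:
        for c in [gw.phi_a, *gw.phi_n.values()]:
            c.w.data[:] = 0
            c.b.data[:] = 0
    return gw


class TestAttentionGate:
    def test_zero_weights_give_half_gate(self):
        rng = np.random.default_rng(0)
        gw = _mk_gate_weights(rng, 4, (6, 8), zero=True)
        fd1 = Tensor(rng.standard_normal((4, 8, 8, 8)).astype(np.float32))
        fe1 = Tensor(rng.standard_normal((4, 8, 8, 8)).astype(np.float32))
        gating = {
            2: Tensor(rng.standard_normal((6, 4, 4, 4)).astype(np.float32)),
            3: Tensor(rng.standard_normal((8, 2, 2, 2)).astype(np.float32)),
        }
        out = attention_gate(fd1, fe1, gating, gw)
        np.testing.assert_allclose(out.data, 0.5 * fd1.data, rtol=1e-6)

    def test_saturated_bias_passes_fd1_through(self):
        rng = np.random.default_rng(0)
        gw = _mk_gate_weights(rng, 4, (6, 8), zero=True)
        gw.phi_a.b.data[:] = 50.0     # sigmoid(50) ~ 1
        fd1 = Tensor(rng.standard_normal((4, 8, 8, 8)).astype(np.float32))
        fe1 = Tensor(rng.standard_normal((4, 8, 8, 8)).astype(np.float32))
        gating = {
            2: Tensor(rng.standard_normal((6, 4, 4, 4)).astype(np.float32)),
            3: Tensor(rng.standard_normal((8, 2, 2, 2)).astype(np.float32)),
        }
        out = attention_gate(fd1, fe1, gating, gw)
        np.testing.assert_allclose(out.data, fd1.data, rtol=1e-5, atol=1e-6)

    def test_matches_literal_transcription_oracle(self):
        """Random inputs against an independent straight-line transcription
        of the gate formula."""
        rng = np.random.default_rng(42)
        gw = _mk_gate_weights(rng, 5, (7, 9))
        fd1 = rng.standard_normal((5, 8, 8, 8)).astype(np.float32)
        fe1 = rng.standard_normal((5, 8, 8, 8)).astype(np.float32)
        g2 = rng.standard_normal((7, 4, 4, 4)).astype(np.float32)
        g3 = rng.standard_normal((9, 2, 2, 2)).astype(np.float32)
        out = attention_gate(
            Tensor(fd1), Tensor(fe1), {2: Tensor(g2), 3: Tensor(g3)}, gw
        )
        want = reference_gate(fd1, fe1, {2: g2, 3: g3}, gw)
        np.testing.assert_allclose(out.data, want, atol=1e-6)

    def test_gate_range_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        gw = _mk_gate_weights(rng, 4, (6, 8))
        fd1 = Tensor(np.ones((4, 8, 8, 8), np.float32))
        fe1 = Tensor(rng.standard_normal((4, 8, 8, 8)).astype(np.float32))
        gating = {
            2: Tensor(rng.standard_normal((6, 4, 4, 4)).astype(np.float32)),
            3: Tensor(rng.standard_normal((8, 2, 2, 2)).astype(np.float32)),
        }
        out = attention_gate(fd1, fe1, gating, gw)   # fd1 == 1 -> output = gate
        assert out.data.min() > 0.0 and out.data.max() < 1.0

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        gw = _mk_gate_weights(rng, 4, (6, 8))
        with pytest.raises(ValueError):
            attention_gate(
                Tensor(np.zeros((4, 8, 8, 8))),
                Tensor(np.zeros((4, 4, 4, 4))),
                {},
                gw,
            )


class TestArchitectureAudit:
    def test_feature_widths_levels_and_kernels(self):
        """The published layout: five levels, widths 24*2^(n-1), 3-cube
        kernels, 5-channel input, 17-class output."""
        spec = UNetSpec()
        assert spec.feature_widths() == [24, 48, 96, 192, 384]
        assert spec.spatial_sizes() == [64, 32, 16, 8, 4]
        model = AttentionUNet3D(spec, rng_seed=0)
        widths = spec.feature_widths()
        for n, block in enumerate(model.enc):
            cin = 5 if n == 0 else widths[n - 1]
            assert block.c1.w.data.shape == (widths[n], cin, 3, 3, 3)
            assert block.c2.w.data.shape == (widths[n], widths[n], 3, 3, 3)
        for n in range(4, 0, -1):
            assert model.up_conv[n].w.data.shape == (
                widths[n - 1],
                widths[n],
                3,
                3,
                3,
            )
            assert model.dec[n].c1.w.data.shape == (
                widths[n - 1],
                2 * widths[n - 1],
                3,
                3,
                3,
            )
        assert model.head.w.data.shape == (17, 24, 1, 1, 1)
        # gate: phi on encoder pathway + decoder levels 2..4, single channel
        assert model.gate_w.phi_a.w.data.shape == (1, 24, 1, 1, 1)
        assert sorted(model.gate_w.phi_n) == [2, 3, 4]
        for n, conv in model.gate_w.phi_n.items():
            assert conv.w.data.shape == (1, widths[n - 1], 1, 1, 1)

    def test_forward_shape_contract_small(self):
        spec = UNetSpec(base_features=2, input_size=16)
        model = AttentionUNet3D(spec, rng_seed=0)
        S = model.predict_softmax(np.zeros((16, 16, 16, 5), np.float32))
        assert S.shape == (16, 16, 16, 17)
        np.testing.assert_allclose(S.sum(axis=-1), 1.0, atol=1e-5)

    def test_ablated_attention_has_no_gate(self):
        spec = UNetSpec(base_features=2, input_size=16, attention=False)
        model = AttentionUNet3D(spec, rng_seed=0)
        assert model.gate_w is None
        S = model.predict_softmax(np.zeros((16, 16, 16, 5), np.float32))
        assert S.shape == (16, 16, 16, 17)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            UNetSpec(input_size=60).validate()


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        labels = np.zeros((4, 4, 4), int)
        labels[1:3, 1:3, 1:3] = 1
        oh = one_hot(labels, 3)
        loss = dice_loss(Tensor(oh), oh)
        assert float(loss.data) < 1e-3

    def test_uniform_prediction_hand_computed(self):
        """Uniform probabilities over 17 labels on a 2-cube, single-label
        truth: Dice_v = (2*8/17 + eps) / (8/17*... ) evaluated by hand."""
        V, n = 17, 8
        labels = np.ones((2, 2, 2), int)
        oh = one_hot(labels, V)
        probs = np.full((V, 2, 2, 2), 1.0 / V, dtype=np.float32)
        eps = 1e-5
        inter = {v: (1.0 / V) * n if v == 1 else 0.0 for v in range(1, V)}
        psum = n / V
        expected = 1 - np.mean(
            [
                (2 * inter[v] + eps) / (psum + (n if v == 1 else 0) + eps)
                for v in range(1, V)
            ]
        )
        loss = dice_loss(Tensor(probs), oh)
        assert float(loss.data) == pytest.approx(expected, rel=1e-4)

    def test_disjoint_prediction_near_one(self):
        labels = np.zeros((4, 4, 4), int)
        labels[0] = 1
        pred = np.zeros((4, 4, 4), int)
        pred[3] = 2
        loss = dice_loss(Tensor(one_hot(pred, 3)), one_hot(labels, 3))
        assert float(loss.data) > 0.99


class TestSignedDistance:
    def test_logits_equal_negative_sdm_give_zero_loss(self):
        labels = np.zeros((6, 6, 6), int)
        labels[2:5, 2:5, 2:5] = 1
        sdms = sdm_stack(labels, 3)
        logits = np.concatenate([np.zeros((1, 6, 6, 6), np.float32), -sdms])
        loss = boundary_loss(Tensor(logits), sdms)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-7)

    def test_single_voxel_matches_brute_force(self):
        labels = np.zeros((5, 5, 5), int)
        labels[2, 2, 2] = 1
        sdm = signed_distance_map(labels, 1)
        # brute force: distance to the only boundary voxel (the voxel itself)
        for i in np.ndindex(5, 5, 5):
            d = np.linalg.norm(np.array(i) - 2)
            assert sdm[i] == pytest.approx(d if labels[i] == 0 else -d)

    def test_boundary_voxels_are_zero_and_signs_correct(self):
        labels = np.zeros((8, 8, 8), int)
        labels[2:6, 2:6, 2:6] = 1
        sdm = signed_distance_map(labels, 1)
        assert sdm[2, 3, 3] == 0.0            # boundary voxel
        assert sdm[3, 3, 3] < 0               # interior
        assert sdm[0, 0, 0] > 0               # exterior

    def test_absent_label_constant_positive(self):
        sdm = signed_distance_map(np.zeros((4, 4, 4), int), 2)
        assert (sdm > 0).all()
        assert np.unique(sdm).size == 1


class TestTraining:
    def test_determinism_and_bookkeeping(self):
        """Same seed -> identical history; running-min of train loss is
        nonincreasing by construction."""
        from bsbt.nn.train import AugmentParams, train

        rng = np.random.default_rng(0)
        spec = UNetSpec(levels=3, base_features=2, in_channels=2, n_classes=3,
                        input_size=8)
        ds = []
        for _ in range(4):
            lab = np.zeros((8, 8, 8), int)
            c = rng.integers(2, 6, 3)
            lab[c[0] - 1 : c[0] + 1, c[1] - 1 : c[1] + 1, c[2] - 1 : c[2] + 1] = (
                rng.integers(1, 3)
            )
            x = np.stack([lab == 1, lab == 2], axis=-1).astype(np.float32)
            x += rng.normal(0, 0.05, x.shape).astype(np.float32)
            ds.append((x, lab))
        aug = AugmentParams(enabled=False)
        hists = []
        for _ in range(2):
            m = AttentionUNet3D(spec, rng_seed=7)
            hists.append(
                train(m, ds, epochs=3, augment=aug, rng_seed=11, lr=1e-3)
            )
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss
        run_min = np.minimum.accumulate(hists[0].train_loss)
        assert (np.diff(run_min) <= 1e-12).all()

    def test_split_validation(self):
        from bsbt.nn.train import train

        spec = UNetSpec(levels=3, base_features=2, in_channels=2, n_classes=3,
                        input_size=8)
        m = AttentionUNet3D(spec, rng_seed=0)
        with pytest.raises(ValueError):
            train(m, [], epochs=1)
        ds = [(np.zeros((8, 8, 8, 2), np.float32), np.zeros((8, 8, 8), int))] * 2
        with pytest.raises(ValueError):
            train(m, ds, epochs=1, val_fraction=0.9)


class TestInference:
    def test_softmax_rows_sum_to_one(self, rng):
        spec = UNetSpec(base_features=2, input_size=16)
        m = AttentionUNet3D(spec, rng_seed=1)
        S = m.predict_softmax(rng.random((16, 16, 16, 5)).astype(np.float32))
        np.testing.assert_allclose(S.sum(axis=-1), 1.0, atol=1e-5)
        assert S.min() >= 0

    def test_zero_pfm_ablation_is_definitional(self, rng):
        spec = UNetSpec(base_features=2, input_size=16)
        m = AttentionUNet3D(spec, rng_seed=1)
        x = rng.random((16, 16, 16, 5)).astype(np.float32)
        a = m.predict_softmax(x, ablate_pfm="zero")
        x2 = x.copy()
        x2[..., 2:5] = 0
        b = m.predict_softmax(x2)
        np.testing.assert_array_equal(a, b)

    def test_channel_mismatch_rejected(self):
        spec = UNetSpec(base_features=2, input_size=16)
        m = AttentionUNet3D(spec, rng_seed=1)
        with pytest.raises(ValueError):
            m.predict_softmax(np.zeros((16, 16, 16, 3), np.float32))

    def test_save_load_round_trip(self, tmp_path, rng):
        spec = UNetSpec(base_features=2, input_size=16)
        m = AttentionUNet3D(spec, rng_seed=1)
        x = rng.random((16, 16, 16, 5)).astype(np.float32)
        before = m.predict_softmax(x)
        m.save(tmp_path / "weights")
        m2 = AttentionUNet3D.load(tmp_path / "weights")
        np.testing.assert_array_equal(m2.predict_softmax(x), before)


class TestEquivariance:
    def test_translation_equivariance_smoke(self, rng):
        """Translating the input by 8 voxels translates the argmax output,
        asserted at >= 95% agreement in the padding-valid interior.

        A shallow spec is used so the receptive field stays local: in the
        true interior zero-padding cannot influence the features and
        equivariance is exact there; deeper specs couple every voxel to
        the border through the bottleneck."""
        spec = UNetSpec(levels=2, base_features=2, input_size=32, attention=False)
        m = AttentionUNet3D(spec, rng_seed=2)
        x = rng.random((32, 32, 32, 5)).astype(np.float32)
        shift, slack = 8, 10
        a = m.predict_softmax(x).argmax(-1)
        b = m.predict_softmax(np.roll(x, shift, axis=0)).argmax(-1)
        a_shift = np.roll(a, shift, axis=0)
        interior = np.s_[shift + slack : -slack, slack:-slack, slack:-slack]
        assert a_shift[interior].size > 0
        agreement = (a_shift[interior] == b[interior]).mean()
        assert agreement >= 0.95
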