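"""CRF potentials, the energy functional vs a brute-force oracle, and
mean-field refinement behavior."""

import numpy as np
import pytest

from bsbt.crf import (
    CRFParams,
    crf_argmax,
    crf_energy,
    entropy_potential,
    mean_field_refine,
    smoothed_probabilities,
    unary_potential,
)


def random_softmax(shape, n_labels, rng):
    S = rng.random(shape + (n_labels,))
    return S / S.sum(axis=-1, keepdims=True)


def brute_force_energy(S, params):
    """Literal triple-loop transcription of the composite energy."""
    S = np.maximum(np.asarray(S, float), 1e-12)
    Sk = smoothed_probabilities(S, params.sigma_k)
    nx, ny, nz, V = S.shape
    total = 0.0
    seen_pairs = set()
    for i in np.ndindex(nx, ny, nz):
        for v in range(V):
            fg = 1.0 if v != 0 else 0.0
            total -= np.log(S[i + (v,)]) * (
                fg * params.lam * S[i + (v,)] + params.wu
            )
        for dx in range(-params.nbhd, params.nbhd + 1):
            for dy in range(-params.nbhd, params.nbhd + 1):
                for dz in range(-params.nbhd, params.nbhd + 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    j = (i[0] + dx, i[1] + dy, i[2] + dz)
                    if not (0 <= j[0] < nx and 0 <= j[1] < ny and 0 <= j[2] < nz):
                        continue
                    key = (min(i, j), max(i, j))
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    diff2 = float(((Sk[j] - Sk[i]) ** 2).sum())
                    total -= diff2 / (4 * np.pi * params.sigma_b * params.sigma_k)
    return total


class TestPotentials:
    def test_unary_closed_forms(self):
        S = np.array([[[[1.0, np.exp(-1.0)]]]])
        psi = unary_potential(S)
        np.testing.assert_allclose(psi[0, 0, 0], [0.0, 1.0], atol=1e-12)

    def test_unary_matches_loop_oracle(self, rng):
        S = random_softmax((3, 3, 3), 4, rng)
        psi = unary_potential(S)
        for i in np.ndindex(3, 3, 3):
            for v in range(4):
                assert psi[i + (v,)] == pytest.approx(-np.log(S[i + (v,)]))

    def test_entropy_zero_for_onehot_foreground(self):
        S = np.zeros((1, 1, 1, 5))
        S[0, 0, 0, 2] = 1.0
        assert entropy_potential(S)[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_entropy_max_for_uniform_foreground(self):
        V = 17
        S = np.zeros((1, 1, 1, V))
        S[..., 1:] = 1.0 / 16
        np.testing.assert_allclose(
            entropy_potential(S)[0, 0, 0], np.log(16), rtol=1e-9
        )

    def test_entropy_matches_loop_oracle(self, rng):
        S = random_softmax((3, 3, 3), 5, rng)
        psi = entropy_potential(S)
        for i in np.ndindex(3, 3, 3):
            expected = -sum(S[i + (v,)] * np.log(S[i + (v,)]) for v in range(1, 5))
            assert psi[i] == pytest.approx(expected, rel=1e-9)


class TestSmoothing:
    def test_constant_field_unchanged_in_interior(self):
        S = np.full((9, 9, 9, 3), 1.0 / 3)
        Sk = smoothed_probabilities(S, sigma_k=1.0)
        np.testing.assert_allclose(Sk[4, 4, 4], 1.0 / 3, rtol=1e-6)

    def test_delta_matches_explicit_stencil(self):
        S = np.zeros((9, 9, 9, 1))
        S[4, 4, 4, 0] = 1.0
        Sk = smoothed_probabilities(S, sigma_k=1.0)
        # scipy's separable kernel: discrete Gaussian truncated at 3 sigma
        x = np.arange(-3, 4)
        k1 = np.exp(-(x**2) / 2.0)
        k1 /= k1.sum()
        stencil = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        np.testing.assert_allclose(
            Sk[1:8, 1:8, 1:8, 0], stencil, rtol=1e-9, atol=1e-15
        )

    def test_label_sum_preserved_in_interior(self, rng):
        S = random_softmax((11, 11, 11), 4, rng)
        Sk = smoothed_probabilities(S, sigma_k=1.0)
        np.testing.assert_allclose(
            Sk[4:7, 4:7, 4:7].sum(axis=-1), 1.0, atol=1e-5
        )


class TestEnergy:
    def test_constant_field_has_zero_pairwise(self):
        S = np.full((6, 6, 6, 3), 1.0 / 3)
        rep = crf_energy(S, CRFParams(sigma_k=1.0, nbhd=2))
        assert rep.pairwise == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_instances(self, seed):
        """Vectorized energy equals the literal triple loop (20 instances)."""
        rng = np.random.default_rng(seed)
        for _ in range(7):
            S = random_softmax((6, 6, 6), 3, rng)
            params = CRFParams(
                wu=float(rng.uniform(0.5, 2.0)),
                lam=float(rng.uniform(0.0, 0.5)),
                sigma_b=float(rng.uniform(0.5, 2.0)),
                sigma_k=1.0,
                nbhd=int(rng.integers(1, 3)),
            )
            rep = crf_energy(S, params)
            oracle = brute_force_energy(S, params)
            assert rep.total == pytest.approx(oracle, rel=1e-8)

    def test_unary_term_linear_in_wu(self, rng):
        S = random_softmax((5, 5, 5), 3, rng)
        p1 = CRFParams(wu=1.0, sigma_k=1.0)
        p2 = CRFParams(wu=2.0, sigma_k=1.0)
        r1, r2 = crf_energy(S, p1), crf_energy(S, p2)
        assert r2.unary == pytest.approx(2 * r1.unary, rel=1e-12)
        assert r2.pairwise == pytest.approx(r1.pairwise, rel=1e-12)
        assert r2.entropy == pytest.approx(r1.entropy, rel=1e-12)

    def test_report_total_is_sum_of_terms(self, rng):
        S = random_softmax((5, 5, 5), 4, rng)
        rep = crf_energy(S, CRFParams(sigma_k=1.5))
        assert rep.total == pytest.approx(
            rep.unary + rep.pairwise + rep.entropy, rel=1e-10
        )


def two_region_instance(rng, n=16, corrupt_frac=0.05, wrong_conf=0.55, n_labels=3):
    """Two-region probability field with a fraction of voxels flipped
    toward the wrong foreground label."""
    truth = np.ones((n, n, n), dtype=int)
    truth[:, n // 2 :, :] = 2
    S = np.full((n, n, n, n_labels), 0.02 / (n_labels - 2) if n_labels > 2 else 0.0)
    S[..., 0] = 0.02
    conf = 0.96
    for v in (1, 2):
        S[truth == v, v] = conf
        S[truth == v, 3 - v] = 1 - conf - 0.02
    flip = rng.random(truth.shape) < corrupt_frac
    wrong = 3 - truth
    S[flip] = 0.02
    S[flip, wrong[flip]] = wrong_conf
    S[flip, truth[flip]] = 1.0 - wrong_conf - 0.02
    S /= S.sum(axis=-1, keepdims=True)
    return S, truth, flip


class TestMeanField:
    def test_unary_only_fixed_point(self, rng):
        """With pairwise/entropy off and wu=1 refinement is the identity."""
        S = random_softmax((6, 6, 6), 4, rng)
        params = CRFParams(
            wu=1.0, lam=0.0, pairwise_on=False, entropy_on=False, iters=4
        )
        Q = mean_field_refine(S, params)
        np.testing.assert_allclose(Q, S, atol=1e-12)

    def test_uniform_field_symmetry_never_broken(self):
        """Spatial symmetry and foreground-label exchange symmetry are
        preserved; the entropy term may only shift background vs
        foreground mass."""
        S = np.full((6, 6, 6, 4), 0.25)
        Q = mean_field_refine(S, CRFParams(sigma_k=1.0, iters=3))
        # identical at every voxel
        np.testing.assert_allclose(
            Q, np.broadcast_to(Q[0, 0, 0], Q.shape), atol=1e-7
        )
        # identical across foreground labels
        np.testing.assert_allclose(
            Q[..., 1:], np.broadcast_to(Q[..., 1:2], Q[..., 1:].shape), atol=1e-7
        )
        # with the entropy term off, full label symmetry holds too
        Q0 = mean_field_refine(S, CRFParams(sigma_k=1.0, iters=3, entropy_on=False))
        np.testing.assert_allclose(Q0, 0.25, atol=1e-7)

    def test_rows_sum_to_one_each_iteration(self, rng):
        S = random_softmax((8, 8, 8), 5, rng)
        for iters in (1, 3, 5):
            Q = mean_field_refine(S, CRFParams(sigma_k=1.0, iters=iters))
            np.testing.assert_allclose(Q.sum(axis=-1), 1.0, atol=1e-6)
            assert Q.min() >= 0

    def test_denoising_reduces_argmax_errors(self):
        """Two-region instances with 5% corrupted probabilities: refinement
        strictly reduces argmax errors (the CRF's purpose)."""
        params = CRFParams(sigma_b=0.5, sigma_k=2.0, iters=5)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            S, truth, _ = two_region_instance(rng)
            before = int((np.argmax(S, axis=-1) != truth).sum())
            after = int((crf_argmax(mean_field_refine(S, params)) != truth).sum())
            if after < before:
                wins += 1
        assert wins >= 19

    def test_cost_linear_in_iterations(self, rng):
        """Fixed iteration count: no early stopping regardless of content."""
        import time

        S = random_softmax((16, 16, 16), 4, rng)
        t = {}
        for iters in (2, 8):
            t0 = time.perf_counter()
            mean_field_refine(S, CRFParams(sigma_k=1.0, iters=iters))
            t[iters] = time.perf_counter() - t0
        # 8 iterations should cost noticeably more than 2 (not constant)
        assert t[8] > 1.5 * t[2]


class TestArgmax:
    def test_onehot_identity(self):
        Q = np.zeros((2, 2, 2, 4))
        lab = np.array([[[1, 3], [0, 2]], [[2, 2], [1, 0]]])
        for i in np.ndindex(2, 2, 2):
            Q[i + (lab[i],)] = 1.0
        np.testing.assert_array_equal(crf_argmax(Q), lab)

    def test_background_wins_exact_ties(self):
        Q = np.full((1, 1, 1, 3), 0.2)
        Q[0, 0, 0, 0] = 0.4
        Q[0, 0, 0, 2] = 0.4
        assert crf_argmax(Q)[0, 0, 0] == 0

    def test_matches_loop_oracle(self, rng):
        Q = rng.random((4, 4, 4, 6))
        got = crf_argmax(Q)
        for i in np.ndindex(4, 4, 4):
            assert got[i] == int(np.argmax(Q[i]))


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CRFParams(sigma_k=0.0)
        with pytest.raises(ValueError):
            CRFParams(nbhd=0)
        with pytest.raises(ValueError):
            CRFParams(iters=0)
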