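"""HiLo reconstruction: demodulation, fusion identity, eta selection."""

import math

import numpy as np
import pytest

import cdslm as c
from cdslm.hilo import (HiLoParams, ReconstructionPair, auto_eta,
                        default_eta_grid, demodulate, eta_theoretical,
                        hilo_reconstruct, hilo_stack)
from cdslm.scope import DomainError


def smooth_scene(n=128):
    yy, xx = np.mgrid[0:n, 0:n]
    return (500.0 + 400.0 * np.exp(-((yy - n / 2) ** 2 + (xx - n / 2) ** 2)
                                   / (2 * 30.0 ** 2))
            + 100.0 * np.sin(2 * np.pi * yy / 50.0))


def structured_from_uniform(U, k, M=1.0):
    x = np.arange(U.shape[1])
    return U * (1.0 + M * np.cos(2 * np.pi * k * x)[None, :]) / 2.0


class TestDemodulate:
    def test_balanced_pair_cancels(self):
        pair = ReconstructionPair(np.full((16, 16), 100.0),
                                  np.full((16, 16), 50.0), 0.125)
        assert not demodulate(pair).any()

    def test_absolute_value(self):
        pair = ReconstructionPair(np.full((16, 16), 10.0),
                                  np.full((16, 16), 20.0), 0.125)
        np.testing.assert_allclose(demodulate(pair), 30.0)

    def test_cosine_identity(self):
        U = np.full((16, 64), 100.0)
        k = 1 / 8
        pair = ReconstructionPair(U, structured_from_uniform(U, k), k)
        x = np.arange(64)
        expected = np.tile(100.0 * np.abs(np.cos(2 * np.pi * k * x)), (16, 1))
        np.testing.assert_allclose(demodulate(pair), expected, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ReconstructionPair(np.zeros((8, 8)), np.zeros((8, 9)), 0.1)

    def test_commutes_with_transposition_along_rows(self):
        rng = np.random.default_rng(0)
        U = rng.uniform(0, 100, (32, 64))
        S = rng.uniform(0, 100, (32, 64))
        pair = ReconstructionPair(U, S, 0.1)
        flipped = ReconstructionPair(U[::-1], S[::-1], 0.1)
        np.testing.assert_array_equal(demodulate(pair)[::-1],
                                      demodulate(flipped))


class TestReconstruct:
    def test_eta_zero_is_pure_highpass(self):
        U = smooth_scene()
        k = 1 / 16
        pair = ReconstructionPair(U, structured_from_uniform(U, k), k)
        I = hilo_reconstruct(pair, HiLoParams(eta=0.0, cutoff_frequency=k / 2))
        from scipy.ndimage import gaussian_filter
        from cdslm.hilo import lp_sigma_px
        expected = U - gaussian_filter(U, lp_sigma_px(k / 2), mode="reflect")
        np.testing.assert_allclose(I, expected, atol=1e-9)

    def test_zero_pair_gives_zero(self):
        pair = ReconstructionPair(np.zeros((32, 32)), np.zeros((32, 32)), 0.1)
        assert not hilo_reconstruct(
            pair, HiLoParams(eta=1.0, cutoff_frequency=0.05)).any()

    def test_flat_field_identity(self):
        """With M=1, eta=pi/2 and cutoff k/2, the reconstruction of a
        smooth in-focus scene reproduces the uniform image (mean of
        |cos| being 2/pi)."""
        U = smooth_scene()
        k = 1 / 16
        pair = ReconstructionPair(U, structured_from_uniform(U, k), k)
        I = hilo_reconstruct(pair, HiLoParams(eta=math.pi / 2,
                                              cutoff_frequency=k / 2))
        interior = (slice(16, -16), slice(16, -16))
        err = np.linalg.norm((I - U)[interior]) / np.linalg.norm(U[interior])
        assert err < 0.02

    def test_identity_error_shrinks_with_cutoff_ratio(self):
        """The flat-field identity is asymptotic: error decreases as the
        LP cutoff moves away from the modulation frequency."""
        U = smooth_scene()
        k = 1 / 8
        pair = ReconstructionPair(U, structured_from_uniform(U, k), k)
        interior = (slice(16, -16), slice(16, -16))
        errs = []
        for ratio in (0.5, 0.25, 0.125):
            I = hilo_reconstruct(pair, HiLoParams(eta=math.pi / 2,
                                                  cutoff_frequency=k * ratio))
            errs.append(np.linalg.norm((I - U)[interior])
                        / np.linalg.norm(U[interior]))
        assert errs[2] < errs[0]

    def test_cutoff_above_modulation_warns(self):
        U = smooth_scene(64)
        k = 1 / 16
        pair = ReconstructionPair(U, structured_from_uniform(U, k), k)
        with pytest.warns(RuntimeWarning):
            hilo_reconstruct(pair, HiLoParams(eta=1.0, cutoff_frequency=k))

    def test_linear_on_sign_constant_inputs(self):
        """For pairs with U - 2S of constant sign the absolute value is
        inert and the reconstruction is jointly linear in (U, S)."""
        rng = np.random.default_rng(3)
        U = rng.uniform(100, 200, (32, 32))
        S = rng.uniform(0, 40, (32, 32))  # U - 2S > 0 everywhere
        p = HiLoParams(eta=1.3, cutoff_frequency=0.05)
        k = 0.125
        a = hilo_reconstruct(ReconstructionPair(U, S, k), p)
        b = hilo_reconstruct(ReconstructionPair(2 * U, 2 * S, k), p)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-9)


class TestEta:
    def test_theoretical_value_at_full_modulation(self):
        assert eta_theoretical(1.0) == pytest.approx(math.pi / 2)

    def test_half_modulation(self):
        assert eta_theoretical(0.5) == pytest.approx(math.pi)

    def test_product_invariant(self):
        for M in (0.2, 0.5, 0.9, 1.0):
            assert eta_theoretical(M) * M == pytest.approx(math.pi / 2)

    def test_nonpositive_m_rejected(self):
        with pytest.raises(DomainError):
            eta_theoretical(0.0)

    def test_single_candidate_returned(self):
        U = smooth_scene(64)
        k = 1 / 16
        pair = ReconstructionPair(U, structured_from_uniform(U, k), k)
        assert auto_eta([pair], [2.5]) == 2.5

    def test_candidate_order_irrelevant(self, matched_scope):
        pairs = [matched_scope.acquire(z, 0.0, seed=int(z)).pair
                 for z in (60.0, 90.0)]
        grid = default_eta_grid(8)
        assert auto_eta(pairs, grid) == auto_eta(pairs, grid[::-1])

    def test_zero_stack_rejected(self):
        pair = ReconstructionPair(np.zeros((32, 32)), np.zeros((32, 32)), 0.1)
        with pytest.raises(DomainError):
            auto_eta([pair], [1.0, 2.0],
                     HiLoParams(eta=1.0, cutoff_frequency=0.05))


class TestHiloStack:
    def test_single_plane_matches_direct_call(self, matched_scope):
        pair = matched_scope.acquire(90.0, 0.0, seed=1).pair
        params = HiLoParams.for_pair(pair)
        stack = hilo_stack([pair], params)
        np.testing.assert_array_equal(stack[0],
                                      hilo_reconstruct(pair, params))

    def test_background_haze_suppressed(self):
        """Out-of-focus haze excited by the sheet wings is attenuated in
        the reconstruction relative to the uniform image."""
        vol, air = c.make_foam_volume(25.0, 4.0, (64, 96, 96), (1, 1, 2),
                                      seed=2, intensity=400.0)
        sheet = c.LightSheetModel(waist_fwhm_um=30.0)
        det = c.DetectionModel(depth_of_field_um=4.0, base_blur_sigma_um=0.8,
                               image_shape=(96, 96))
        scope = c.VirtualScope(vol, sheet, det,
                               c.RefractiveIndexProfile.matched())
        z_idx = 40
        rec = scope.acquire(z_idx * 2.0, 0.0, seed=3)
        recon = hilo_stack([rec.pair])[0]
        background = air[z_idx]  # off-structure pixels at the sheet plane
        assert np.clip(recon, 0, None)[background].mean() \
            < rec.uniform[background].mean()

    def test_deterministic_given_seeds(self, matched_scope):
        pairs1 = [matched_scope.acquire(90.0, 0.0, seed=9).pair]
        pairs2 = [matched_scope.acquire(90.0, 0.0, seed=9).pair]
        np.testing.assert_array_equal(hilo_stack(pairs1), hilo_stack(pairs2))
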