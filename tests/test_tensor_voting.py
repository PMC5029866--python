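"""Stick-vote decay kernel, vote casting, map combination, seed detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvseg.preprocessing import compute_gradients
from tvseg.tensor_voting import (
    SaliencyMap,
    VotingParams,
    cast_votes,
    combine_saliency,
    decay_kernel_value,
    detect_seeds,
    stick_geometry,
)

from .conftest import make_gradient_field


class TestDecayKernel:
    def test_unit_at_origin(self):
        assert decay_kernel_value(0.0, 0.0, VotingParams(sigma=5)) == 1.0

    @pytest.mark.parametrize("sigma", [2.0, 5.0, 9.0])
    def test_inverse_e_at_one_sigma_arc(self, sigma):
        val = decay_kernel_value(sigma, 0.0, VotingParams(sigma=sigma))
        assert np.isclose(val, np.exp(-1.0), atol=1e-12)

    def test_curvature_constant_formula(self):
        # c = -16 * log(0.1) * (sigma - 1) / pi^2, evaluated directly
        p10 = VotingParams(sigma=5.0, log_base_ten=True)
        assert np.isclose(p10.curvature_constant, 16.0 * 4.0 / np.pi**2, atol=1e-12)
        pe = VotingParams(sigma=5.0, log_base_ten=False)
        assert np.isclose(
            pe.curvature_constant, -16.0 * np.log(0.1) * 4.0 / np.pi**2, atol=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        s=st.floats(0.0, 20.0),
        ds=st.floats(0.1, 5.0),
        k=st.floats(0.0, 2.0),
        dk=st.floats(0.05, 1.0),
    )
    def test_strictly_decreasing_in_s2_and_k2(self, s, ds, k, dk):
        params = VotingParams(sigma=5.0)
        assert decay_kernel_value(s + ds, k, params) < decay_kernel_value(s, k, params)
        assert decay_kernel_value(s, k + dk, params) < decay_kernel_value(s, k, params)


class TestStickGeometry:
    def test_straight_continuation_has_zero_curvature(self):
        # receiver on the stick axis: arc degenerates to the chord
        s, k, length = stick_geometry((0, 0), (0, 7.0), stick_orientation=0.0)
        assert np.isclose(s, 7.0) and k == 0.0 and np.isclose(length, 7.0)

    def test_perpendicular_receiver_half_circle(self):
        # chord at 90 degrees to the stick, l = 2: s = pi, k = 1
        s, k, length = stick_geometry((0, 0), (2.0, 0.0), stick_orientation=0.0)
        assert np.isclose(s, np.pi) and np.isclose(k, 1.0) and np.isclose(length, 2.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(50):
            voter = rng.uniform(-10, 10, 2)
            receiver = voter + rng.uniform(-8, 8, 2)
            if np.allclose(receiver, voter):
                continue
            beta = rng.uniform(-np.pi, np.pi)
            s, k, length = stick_geometry(voter, receiver, beta)
            # oracle: acute angle between chord line and stick axis via
            # unit-vector dot product, then the two printed formulas
            chord = receiver - voter
            l_exp = np.linalg.norm(chord)
            u = np.array([np.cos(beta), np.sin(beta)])  # (col, row) axis
            cosang = abs(chord[1] * u[0] + chord[0] * u[1]) / l_exp
            a = np.arccos(np.clip(cosang, -1, 1))
            if a < 1e-12:
                s_exp, k_exp = l_exp, 0.0
            else:
                s_exp, k_exp = a * l_exp / np.sin(a), 2 * np.sin(a) / l_exp
            assert np.isclose(length, l_exp, atol=1e-9)
            assert np.isclose(s, s_exp, atol=1e-9)
            assert np.isclose(k, k_exp, atol=1e-9)

    def test_self_vote_is_an_error(self):
        with pytest.raises(ValueError):
            stick_geometry((3, 3), (3, 3), 0.0)


class TestCastVotes:
    def test_zero_gradient_image_gives_zero_map(self):
        gray = np.full((20, 20), 0.5)
        votes = cast_votes(gray, compute_gradients(gray), VotingParams(sigma=3))
        assert np.all(votes.values == 0.0)

    @pytest.mark.parametrize("mode", ["parallel", "perpendicular"])
    def test_single_voter_matches_direct_evaluation(self, mode):
        params = VotingParams(sigma=4.0)
        h = w = 31
        gray = np.full((h, w), 0.3)
        mag = np.zeros((h, w))
        mag[15, 15] = 2.0
        alpha = 0.7
        grad = make_gradient_field(mag, np.full((h, w), alpha))
        votes = cast_votes(gray, grad, params, mode=mode)

        beta = alpha + (0.0 if mode == "parallel" else np.pi / 2)
        expected = np.zeros((h, w))
        weight = 2.0 * (1.0 - 0.3)
        for r in range(h):
            for c in range(w):
                if (r, c) == (15, 15):
                    continue
                s, k, length = stick_geometry((15, 15), (r, c), beta)
                if length > params.support_radius:
                    continue
                chord = np.arctan2(r - 15, c - 15)
                acute = abs((chord - beta + np.pi / 2) % np.pi - np.pi / 2)
                if acute > params.angular_aperture:
                    continue
                expected[r, c] = weight * decay_kernel_value(s, k, params)
        np.testing.assert_allclose(votes.values, expected, atol=1e-12)

    def test_vote_accumulation_is_additive(self):
        params = VotingParams(sigma=3.0, gradient_floor=0.1)
        h = w = 25
        gray = np.full((h, w), 0.2)
        mag1 = np.zeros((h, w)); mag1[8, 8] = 1.5
        mag2 = np.zeros((h, w)); mag2[16, 14] = 0.9
        direction = np.full((h, w), -1.1)
        both = make_gradient_field(mag1 + mag2, direction)
        v_both = cast_votes(gray, both, params).values
        v1 = cast_votes(gray, make_gradient_field(mag1, direction), params).values
        v2 = cast_votes(gray, make_gradient_field(mag2, direction), params).values
        np.testing.assert_allclose(v_both, v1 + v2, atol=1e-9)

    def test_maps_nonnegative_and_finite(self, dark_disk):
        gray, *_ = dark_disk
        grad = compute_gradients(gray)
        for mode in ("parallel", "perpendicular"):
            v = cast_votes(gray, grad, VotingParams(sigma=5), mode=mode).values
            assert np.all(v >= 0) and np.all(np.isfinite(v))

    def test_mirror_symmetry(self, rng):
        params = VotingParams(sigma=3.0)
        gray = rng.uniform(0, 1, (24, 24))
        votes = cast_votes(gray, compute_gradients(gray), params).values
        mirrored = cast_votes(
            gray[:, ::-1], compute_gradients(gray[:, ::-1]), params
        ).values
        np.testing.assert_allclose(
            votes[3:-3, 3:-3], mirrored[:, ::-1][3:-3, 3:-3], atol=1e-6
        )

    def test_dark_disk_center_peak(self, dark_disk):
        # the raw parallel map of a nucleus larger than sigma is an
        # interior ridge ring; at the detection scale (smoothing = sigma)
        # the field peaks at the disk center
        from scipy import ndimage

        gray, center, radius, inside = dark_disk
        par = cast_votes(gray, compute_gradients(gray), VotingParams(sigma=5))
        smoothed = ndimage.gaussian_filter(par.values, 5.0)
        peak = np.unravel_index(np.argmax(smoothed), smoothed.shape)
        assert np.hypot(peak[0] - center[0], peak[1] - center[1]) <= 2.0

    def test_shape_mismatch_rejected(self, dark_disk):
        gray, *_ = dark_disk
        grad = compute_gradients(gray[:-2])
        with pytest.raises(ValueError):
            cast_votes(gray, grad)


class TestCombineSaliency:
    def test_identical_maps_cancel_to_zero(self, rng):
        v = rng.uniform(0, 1, (10, 10))
        out = combine_saliency(SaliencyMap(v, "parallel"), SaliencyMap(v.copy(), "perpendicular"))
        assert np.all(out.values == 0.0)
        assert out.kind == "combined"

    def test_constant_offset_cancels_to_zero(self, rng):
        v = rng.uniform(0, 1, (10, 10))
        out = combine_saliency(SaliencyMap(v, "parallel"), SaliencyMap(v + 0.7, "perpendicular"))
        assert np.all(out.values == 0.0)

    def test_kind_mismatch_rejected(self, rng):
        v = rng.uniform(0, 1, (5, 5))
        with pytest.raises(ValueError):
            combine_saliency(SaliencyMap(v, "perpendicular"), SaliencyMap(v, "parallel"))

    def test_disk_boundary_ring_is_bright(self, dark_disk):
        gray, center, radius, inside = dark_disk
        grad = compute_gradients(gray)
        params = VotingParams(sigma=5)
        par = cast_votes(gray, grad, params, mode="parallel")
        perp = cast_votes(gray, grad, params, mode="perpendicular")
        combined = combine_saliency(par, perp).values
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring_rows = np.clip(np.round(center[0] + radius * np.sin(theta)).astype(int), 0, 47)
        ring_cols = np.clip(np.round(center[1] + radius * np.cos(theta)).astype(int), 0, 47)
        ring_mean = combined[ring_rows, ring_cols].mean()
        center_mean = combined[22:27, 22:27].mean()
        assert ring_mean >= 2.0 * max(center_mean, 1e-12)


class TestDetectSeeds:
    @staticmethod
    def bump_map(centers, heights, shape=(80, 80), width=5.0):
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        v = np.zeros(shape)
        for (r0, c0), h in zip(centers, heights):
            v += h * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2))
        return SaliencyMap(v, "parallel")

    def test_constant_map_has_no_seeds(self):
        assert detect_seeds(SaliencyMap(np.full((30, 30), 0.8), "parallel")) == []

    def test_two_bumps_both_found(self):
        sal = self.bump_map([(20, 20), (20, 60)], [1.0, 0.8])
        seeds = detect_seeds(sal, min_distance=10, min_height_fraction=0.1, smooth_sigma=2)
        assert len(seeds) == 2
        found = sorted((s.row, s.col) for s in seeds)
        for (r, c), (r0, c0) in zip(found, [(20, 20), (20, 60)]):
            assert np.hypot(r - r0, c - c0) <= 1.0

    def test_wide_suppression_keeps_taller_bump(self):
        sal = self.bump_map([(20, 20), (20, 60)], [1.0, 0.8])
        seeds = detect_seeds(sal, min_distance=60, min_height_fraction=0.1, smooth_sigma=2)
        assert len(seeds) == 1
        assert np.hypot(seeds[0].row - 20, seeds[0].col - 20) <= 1.0
        # brute-force pairwise check of the suppression invariant
        all_seeds = detect_seeds(sal, min_distance=10, min_height_fraction=0.1, smooth_sigma=2)
        for a in all_seeds:
            for b in all_seeds:
                if a is not b:
                    assert np.hypot(a.row - b.row, a.col - b.col) >= 10

    def test_seeds_inside_isolated_dark_disk(self, dark_disk):
        gray, center, radius, inside = dark_disk
        par = cast_votes(gray, compute_gradients(gray), VotingParams(sigma=5))
        seeds = detect_seeds(par)
        assert seeds, "expected at least one seed"
        for s in seeds:
            assert inside[s.row, s.col]

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            detect_seeds(SaliencyMap(np.ones((5, 5)), "combined"))
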