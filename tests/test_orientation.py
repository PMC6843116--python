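"""Frangi vesselness, axial angles and the alignment statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from groovescreen import (
    FrangiParams,
    OrientationField,
    aligned_percentage,
    alignment_fraction,
    axial_delta,
    frangi_orientation,
    generate_stack,
    profile_stack,
    RunConfig,
    SynthConfig,
)

from .oracles import frangi_reference


class TestFrangiOrientation:
    def test_constant_image_all_zero(self):
        f = frangi_orientation(np.full((16, 16), 3.0))
        assert not f.vesselness.any()
        assert np.isnan(f.orientation_deg).all()

    def test_horizontal_ridge_orientation_zero(self):
        img = np.zeros((41, 81))
        img[20, :] = 100.0
        img = gaussian_filter(img, 1.5)
        f = frangi_orientation(img)
        assert f.vesselness[20, 40] > 0.3
        assert axial_delta(f.orientation_deg[20, 40], 0.0) < 1.0

    def test_dark_ridge_mode(self):
        img = np.full((41, 81), 100.0)
        img[20, :] = 0.0
        img = gaussian_filter(img, 1.5)
        bright = frangi_orientation(img)
        dark = frangi_orientation(img, FrangiParams(bright_ridges=False))
        assert bright.vesselness[20, 40] == 0.0
        assert dark.vesselness[20, 40] > 0.3

    @pytest.mark.parametrize("size", [9, 16, 32])
    def test_matches_brute_force_oracle(self, size, rng):
        """Vesselness and orientation equal an explicit per-pixel eigen-solve."""
        img = gaussian_filter(rng.uniform(0, 100, (size, size)), 1.0)
        scales = (1.0, 2.0, 3.0)
        f = frangi_orientation(img, FrangiParams(scales_px=scales))
        ref_v, ref_theta, ok = frangi_reference(img, scales)
        np.testing.assert_allclose(f.vesselness, ref_v, atol=1e-6)
        both = ok & (f.vesselness > 1e-9) & np.isfinite(ref_theta)
        assert both.any()
        assert axial_delta(f.orientation_deg[both], ref_theta[both]).max() < 1e-6

    def test_vesselness_normalized_range(self, rng):
        img = gaussian_filter(rng.uniform(0, 1000, (32, 32)), 1.0)
        f = frangi_orientation(img)
        assert f.vesselness.min() >= 0.0
        assert f.vesselness.max() <= 1.0

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            FrangiParams(scales_px=())


class TestAxialDelta:
    @pytest.mark.parametrize(
        "theta,groove,expected",
        [(10, 0, 10), (150, 0, 30), (0, 90, 90), (179, 1, 2)],
    )
    def test_examples(self, theta, groove, expected):
        assert axial_delta(theta, groove) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(theta=st.floats(-720, 720, allow_nan=False))
    def test_identity_and_range(self, theta):
        assert axial_delta(theta, theta) == pytest.approx(0.0, abs=1e-9)
        d = axial_delta(theta, 0.0)
        assert 0.0 <= d <= 90.0

    @settings(max_examples=50, derandomize=True)
    @given(theta=st.floats(0, 180, exclude_max=True), k=st.integers(-3, 3))
    def test_periodicity_mod_180(self, theta, k):
        assert axial_delta(theta + 180.0 * k, 25.0) == pytest.approx(
            axial_delta(theta, 25.0), abs=1e-6
        )


def field_from_orientations(theta):
    v = np.ones_like(theta, dtype=float)
    return OrientationField(v, np.asarray(theta, dtype=float), np.ones_like(theta, dtype=float))


class TestAlignmentFraction:
    def test_uniform_orientations_give_one_third(self, rng):
        theta = rng.uniform(0, 180, (400, 250))  # 100,000 support pixels
        res = alignment_fraction(field_from_orientations(theta), np.ones_like(theta, bool), 55.0)
        assert res.support_px == 100_000
        assert res.aligned_pct == pytest.approx(33.3, abs=1.0)

    def test_all_at_groove_angle_is_hundred(self):
        theta = np.full((50, 50), 42.0)
        res = alignment_fraction(field_from_orientations(theta), np.ones((50, 50), bool), 42.0)
        assert res.aligned_pct == 100.0

    def test_exact_threshold_not_aligned(self):
        theta = np.full((10, 10), 60.0)
        res = alignment_fraction(field_from_orientations(theta), np.ones((10, 10), bool), 30.0)
        assert res.aligned_pct == 0.0  # strict <30 deg

    def test_empty_support_is_undefined(self):
        theta = np.full((10, 10), np.nan)
        res = alignment_fraction(field_from_orientations(theta), np.ones((10, 10), bool), 0.0)
        assert res.aligned_pct is None
        assert res.support_px == 0

    def test_invariant_under_multiples_of_180(self, rng):
        theta = rng.uniform(0, 180, (60, 60))
        mask = np.ones((60, 60), bool)
        a = alignment_fraction(field_from_orientations(theta), mask, 20.0).aligned_pct
        b = alignment_fraction(field_from_orientations(theta + 360.0), mask, 20.0).aligned_pct
        c = alignment_fraction(field_from_orientations(theta), mask, 20.0 + 180.0).aligned_pct
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_shape_mismatch_rejected(self):
        theta = np.zeros((8, 8))
        with pytest.raises(ValueError):
            alignment_fraction(field_from_orientations(theta), np.ones((4, 4), bool), 0.0)

    def test_rotating_scene_and_groove_together(self):
        """Same draws measured against a rotated groove: alignment moves < 2 pp.

        With a fixed seed the two runs share every relative neurite angle, so
        the true aligned fraction is identical; only rasterization differs.
        Pooled over a few replicate fields so single borderline neurites do
        not dominate.
        """
        pooled = {20.0: [], 65.0: []}
        for groove in (20.0, 65.0):
            for seed in (31, 32, 33, 34):
                cfg = SynthConfig(
                    shape=(1, 256, 256), n_cells_surface=14.0, kappa_surface=2.0,
                    groove=dict(angle_deg=groove), seed=seed,
                )
                stack, _ = generate_stack(cfg)
                rows = profile_stack(stack, RunConfig(groove_angle_deg=groove))
                pooled[groove].append((rows[0].alignment_pct, rows[0].support_px))
        pct = {
            g: sum(p * s for p, s in v) / sum(s for _, s in v) for g, v in pooled.items()
        }
        assert abs(pct[20.0] - pct[65.0]) < 2.0


class TestAlignedPercentage:
    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            aligned_percentage(np.array([]), 0.0)

    def test_matches_alignment_fraction_convention(self, rng):
        theta = rng.uniform(0, 180, 10_000)
        pct = aligned_percentage(theta, 12.0)
        res = alignment_fraction(
            field_from_orientations(theta.reshape(100, 100)), np.ones((100, 100), bool), 12.0
        )
        assert pct == pytest.approx(res.aligned_pct)
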