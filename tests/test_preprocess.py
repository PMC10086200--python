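"""Resampling, filter bank and discretization."""

import numpy as np
import pytest

from batscan.grid import VolumeGrid
from batscan.preprocess import (
    FILTER_BANK,
    PreprocessConfig,
    apply_filter_bank,
    discretize,
    effective_bin_width,
    resample,
)


class TestResample:
    def test_identity_when_already_at_target(self):
        rng = np.random.default_rng(0)
        vol = VolumeGrid(rng.normal(size=(4, 8, 8)), spacing=(5.0, 1.0, 1.0))
        out = resample(vol, PreprocessConfig())
        assert out.spacing == (5.0, 1.0, 1.0)
        np.testing.assert_allclose(out.values, vol.values, atol=1e-9)

    def test_constant_volume_stays_constant(self):
        vol = VolumeGrid(np.full((4, 6, 6), 3.5), spacing=(5.0, 2.0, 2.0))
        out = resample(vol, PreprocessConfig())
        assert out.shape == (4, 12, 12)
        np.testing.assert_allclose(out.values, 3.5, atol=1e-9)

    def test_linear_upsample_matches_separable_oracle(self):
        """2x2 plane upsampled 2x with order 1 equals direct evaluation of
        separable linear interpolation at the output sample points."""
        plane = np.array([[0.0, 10.0], [10.0, 20.0]])
        vol = VolumeGrid(plane[None], spacing=(5.0, 2.0, 2.0))
        out = resample(vol, PreprocessConfig(target_spacing=(0.0, 1.0, 1.0),
                                             interpolation_order=1))
        # grid_mode zoom: x_in = (x_out + 0.5) / zoom - 0.5, edges clamped
        def oracle(r_out, c_out):
            def coord(x):
                return min(max((x + 0.5) / 2.0 - 0.5, 0.0), 1.0)
            r, c = coord(r_out), coord(c_out)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r1, c1 = min(r0 + 1, 1), min(c0 + 1, 1)
            fr, fc = r - r0, c - c0
            top = plane[r0, c0] * (1 - fc) + plane[r0, c1] * fc
            bot = plane[r1, c0] * (1 - fc) + plane[r1, c1] * fc
            return top * (1 - fr) + bot * fr

        expected = np.array([[oracle(r, c) for c in range(4)] for r in range(4)])
        np.testing.assert_allclose(out.values[0], expected, atol=1e-9)

    def test_mask_resampled_nearest_and_rebinarized(self):
        vol = VolumeGrid(np.zeros((2, 4, 4)), spacing=(5.0, 2.0, 2.0))
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, 1:3, 1:3] = True
        out, out_mask = resample(vol, PreprocessConfig(), mask)
        assert out_mask.dtype == bool
        assert out_mask.shape == out.shape
        assert out_mask.sum() == 4 * mask.sum()  # 2x in both in-plane axes

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(target_spacing=(0.0, -1.0, 1.0)).validate()


class TestFilterBank:
    def test_exactly_19_image_types(self):
        vol = VolumeGrid(np.random.default_rng(1).normal(size=(4, 8, 8)))
        out = apply_filter_bank(vol)
        assert list(out) == list(FILTER_BANK)
        assert len(out) == 19

    def test_zero_volume_linear_filters_vanish(self):
        vol = VolumeGrid(np.zeros((4, 8, 8)))
        out = apply_filter_bank(vol)
        for name in out:
            if name.startswith(("wavelet-", "log-sigma-")) or name in ("square", "gradient"):
                np.testing.assert_allclose(out[name].values, 0.0, atol=1e-12)

    def test_square_filter_pointwise_formula(self):
        """square(v) = v^2 / max|v| over the volume."""
        v = np.array([[[-2.0, 0.0, 1.0, 4.0]]])
        out = apply_filter_bank(VolumeGrid(v))
        np.testing.assert_allclose(out["square"].values, v**2 / 4.0, atol=1e-12)
        np.testing.assert_allclose(out["squareroot"].values,
                                   np.sign(v) * np.sqrt(4.0 * np.abs(v)), atol=1e-12)

    def test_filter_bank_deterministic(self):
        rng = np.random.default_rng(2)
        vol = VolumeGrid(rng.normal(size=(4, 6, 6)))
        a = apply_filter_bank(vol)
        b = apply_filter_bank(vol)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(filter_bank=("original", "sobel") + FILTER_BANK[1:18]).validate()


class TestDiscretize:
    def test_constant_roi_single_level(self):
        levels, n = discretize(np.full((2, 2, 2), -50.0), np.ones((2, 2, 2), bool), 25.0)
        assert n == 1
        assert set(np.unique(levels)) == {1}

    def test_hand_binning(self):
        values = np.array([[[-190.0, -165.0, -140.0]]])
        levels, n = discretize(values, np.ones_like(values, bool), 25.0)
        assert levels.ravel().tolist() == [1, 2, 3]
        assert n == 3

    def test_max_level_formula_random(self, rng):
        values = rng.normal(-100, 30, size=(3, 5, 5))
        mask = rng.random((3, 5, 5)) < 0.7
        mask.flat[0] = True
        bw = 7.0
        levels, n = discretize(values, mask, bw)
        inside = values[mask]
        assert n == int(np.floor((inside.max() - inside.min()) / bw)) + 1
        # brute-force per-voxel check
        expected = np.floor((inside - inside.min()) / bw).astype(int) + 1
        np.testing.assert_array_equal(levels[mask], expected)

    def test_monotone_in_value(self, rng):
        values = rng.normal(size=(2, 4, 4))
        mask = np.ones_like(values, bool)
        levels, _ = discretize(values, mask, 0.3)
        order = np.argsort(values.ravel())
        assert (np.diff(levels.ravel()[order]) >= 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), 25.0)

    def test_bin_width_cap(self):
        values = np.linspace(0, 1e6, 100)
        assert effective_bin_width(values, 25.0, 64) == pytest.approx(1e6 / 64)
        assert effective_bin_width(values, 25.0, None) == 25.0
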