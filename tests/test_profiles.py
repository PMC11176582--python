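import numpy as np
import pytest

from spherotype import profiles
from spherotype.profiles import (PlotProfile, ProfileROI, SpheroidStack,
                                 auto_roi, baseline_and_auc,
                                 extract_stack_profile, read_profile_csv,
                                 read_stack, smooth_profile,
                                 write_profile_csv, write_stack)
from spherotype.synthetic import SimulationConfig, generate_spheroid_stack

from conftest import make_profile, uniform_stack


class TestStackType:
    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            SpheroidStack(np.zeros((2, 1, 8, 8)), 1.0)

    def test_rejects_negative_intensity(self):
        vox = np.zeros((3, 1, 8, 8))
        vox[0, 0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            SpheroidStack(vox, 1.0)


class TestExtract:
    def test_uniform_stack_gives_flat_profile(self):
        stack = uniform_stack(value=2.5, z=4)
        roi = ProfileROI(center=(15.5, 15.5), length_px=20, width_px=5)
        prof = extract_stack_profile(stack, roi)
        for ch in stack.channel_names:
            assert np.allclose(prof.intensities[ch], 4 * 2.5, rtol=1e-12)

    def test_single_slice_equals_slice_profile(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, size=(3, 1, 16, 16))
        stack = SpheroidStack(img, 1.0)
        roi = ProfileROI(center=(7, 7), length_px=11, width_px=1)
        prof = extract_stack_profile(stack, roi)
        # odd length, width 1, angle 0, integer center: direct row slice
        row = img[0, 0, 7, 2:13]
        assert np.allclose(prof.intensities["CAM"], row)

    def test_stack_profile_is_sum_of_slice_profiles(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 10, size=(3, 5, 16, 16))
        stack = SpheroidStack(img, 1.0)
        roi = ProfileROI(center=(7.0, 7.0), length_px=12, width_px=3)
        total = extract_stack_profile(stack, roi)
        acc = np.zeros(12)
        for z in range(5):
            single = SpheroidStack(img[:, z:z + 1], 1.0)
            acc += extract_stack_profile(single, roi).intensities["PI"]
        assert np.allclose(total.intensities["PI"], acc, rtol=1e-12)

    def test_annulus_profile_matches_chord_integral_oracle(self):
        # full-image-width ROI: short-axis mean of an indicator annulus
        # equals the analytic chord-length integral / field height
        n, px = 201, 2.0
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - c, yy - c) * px
        r1, r2 = 100.0, 160.0
        ann = ((r >= r1) & (r <= r2)).astype(float)
        stack = SpheroidStack(np.stack([ann, ann, ann])[:, None], px)
        roi = ProfileROI(center=(c, c), length_px=n, width_px=n)
        prof = extract_stack_profile(stack, roi)

        x = (np.arange(n) - c) * px

        def chord(radius):
            return 2.0 * np.sqrt(np.clip(radius ** 2 - x ** 2, 0.0, None))

        oracle = (chord(r2) - chord(r1)) / (n * px)
        rms = np.sqrt(np.mean((prof.intensities["CAM"] - oracle) ** 2))
        assert rms <= 0.01 * oracle.max()

    def test_roi_outside_bounds_rejected(self):
        stack = uniform_stack(size=16)
        roi = ProfileROI(center=(8, 8), length_px=40, width_px=1)
        with pytest.raises(ValueError, match="bounds"):
            extract_stack_profile(stack, roi)

    def test_zero_length_roi_rejected(self):
        with pytest.raises(ValueError):
            ProfileROI(center=(8, 8), length_px=0, width_px=1)


class TestAutoROI:
    def test_centered_spheroid_center_within_2px(self, basic_spec,
                                                 small_image_config):
        stack, _ = generate_spheroid_stack(400.0, basic_spec, 0.0,
                                           small_image_config)
        roi = auto_roi(stack)
        c = (small_image_config.image_size_px - 1) / 2.0
        assert abs(roi.center[0] - c) <= 2.0
        assert abs(roi.center[1] - c) <= 2.0

    def test_off_center_spheroid_tracked(self, basic_spec,
                                         small_image_config):
        stack, _ = generate_spheroid_stack(400.0, basic_spec, 0.0,
                                           small_image_config)
        shift = 9
        vox = np.roll(stack.voxels, shift, axis=3)
        shifted = SpheroidStack(vox, stack.pixel_size_um)
        roi0 = auto_roi(stack)
        roi1 = auto_roi(shifted)
        assert roi1.center[0] - roi0.center[0] == pytest.approx(shift, abs=2.0)

    def test_blank_stack_rejected(self):
        stack = uniform_stack(value=1.0)
        with pytest.raises(ValueError, match="blank"):
            auto_roi(stack)

    def test_noise_only_stack_rejected(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(0, 1, size=(3, 1, 64, 64))
        with pytest.raises(ValueError, match="blank"):
            auto_roi(SpheroidStack(vox, 1.0))


class TestSmoothing:
    def test_window_one_is_identity(self):
        p = make_profile({"CAM": [1, 5, 2, 8, 3]})
        out = smooth_profile(p, window=1)
        assert np.array_equal(out.intensities["CAM"], p.intensities["CAM"])
        assert out.smoothed

    def test_hand_computed_shrunken_endpoints(self):
        p = make_profile({"CAM": [0, 3, 0, 3, 0]})
        out = smooth_profile(p, window=3)
        assert np.allclose(out.intensities["CAM"], [1.5, 1, 2, 1, 1.5])

    def test_constant_profile_unchanged(self):
        p = make_profile({"CAM": [4.0] * 9})
        for w in (1, 3, 5, 9):
            out = smooth_profile(p, window=w)
            assert np.allclose(out.intensities["CAM"], 4.0)

    @pytest.mark.parametrize("window", [0, 2, 4, 11])
    def test_invalid_window_rejected(self, window):
        p = make_profile({"CAM": [1.0] * 9})
        with pytest.raises(ValueError):
            smooth_profile(p, window=window)


class TestBaselineAUC:
    def test_constant_profile_has_zero_auc(self):
        p = make_profile({"CAM": [7.0] * 8}, smoothed=True)
        out = baseline_and_auc(p)
        baseline, auc = out["CAM"]
        assert baseline == 7.0
        assert auc == 0.0

    def test_hand_trapezoid(self):
        p = make_profile({"CAM": [0, 0, 0, 4]}, smoothed=True)
        out = baseline_and_auc(p)
        baseline, auc = out["CAM"]
        assert baseline == 0.0
        assert auc == pytest.approx(2.0)

    def test_quartile_baseline_reduces_auc_vs_min_baseline(self):
        # triangular pulse sitting on a sloped shelf: lower-quartile
        # baseline removes more area than the minimum would
        x = np.arange(101, dtype=float)
        y = np.zeros(101)
        y[40:61] = np.concatenate([np.linspace(0, 10, 11),
                                   np.linspace(10, 0, 11)[1:]])
        y += np.linspace(0.0, 2.0, 101)
        p = make_profile({"CAM": y}, smoothed=True)
        baseline, auc = baseline_and_auc(p)["CAM"]

        # dense-grid numeric oracle at both baselines
        xd = np.linspace(0, 100, 100001)
        yd = np.interp(xd, x, y)
        auc_min = np.trapezoid(np.clip(yd - yd.min(), 0, None), xd)
        auc_q = np.trapezoid(np.clip(yd - np.percentile(y, 25), 0, None), xd)
        assert auc == pytest.approx(auc_q, rel=0.01)
        assert auc < auc_min

    def test_unsmoothed_profile_rejected(self):
        p = make_profile({"CAM": [0, 1, 2, 3]})
        with pytest.raises(ValueError, match="smoothed"):
            baseline_and_auc(p)

    def test_short_profile_rejected(self):
        p = make_profile({"CAM": [0, 1, 2]}, smoothed=True)
        with pytest.raises(ValueError, match="short"):
            baseline_and_auc(p)

    def test_linearity_auc_scales_with_intensity(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 5, 50)
        p1 = make_profile({"CAM": y}, smoothed=True)
        p2 = make_profile({"CAM": 3.7 * y}, smoothed=True)
        b1, a1 = baseline_and_auc(p1)["CAM"]
        b2, a2 = baseline_and_auc(p2)["CAM"]
        assert b2 == pytest.approx(3.7 * b1)
        assert a2 == pytest.approx(3.7 * a1)


class TestTranslationInvariance:
    def test_profile_metrics_unchanged_when_roi_tracks_spheroid(
            self, basic_spec, small_image_config):
        stack, _ = generate_spheroid_stack(400.0, basic_spec, 0.0,
                                           small_image_config)
        shifted = SpheroidStack(np.roll(stack.voxels, 7, axis=3),
                                stack.pixel_size_um)
        results = []
        for s in (stack, shifted):
            roi = auto_roi(s)
            prof = smooth_profile(extract_stack_profile(s, roi), 3)
            results.append(baseline_and_auc(prof))
        for ch in ("CAM", "PI", "TL"):
            assert results[0][ch][0] == pytest.approx(results[1][ch][0],
                                                      rel=0.02, abs=1e-6)
            assert results[0][ch][1] == pytest.approx(results[1][ch][1],
                                                      rel=0.02)


class TestIO:
    def test_stack_roundtrip(self, tmp_path, basic_spec, small_image_config):
        stack, _ = generate_spheroid_stack(400.0, basic_spec, 0.0,
                                           small_image_config)
        path = tmp_path / "s.tif"
        write_stack(stack, path)
        back = read_stack(path)
        assert back.pixel_size_um == stack.pixel_size_um
        assert back.channel_names == stack.channel_names
        assert np.allclose(back.voxels, stack.voxels.astype(np.float32))

    def test_channel_order_override(self, tmp_path):
        stack = uniform_stack()
        path = tmp_path / "s.tif"
        write_stack(stack, path)
        back = read_stack(path, channel_order=("TL", "PI", "CAM"))
        assert back.channel_names == ("TL", "PI", "CAM")

    def test_profile_csv_roundtrip(self, tmp_path):
        p = make_profile({"CAM": [0, 1, 2, 3], "PI": [3, 2, 1, 0],
                          "TL": [5, 5, 5, 5]}, spacing_um=2.0)
        p = smooth_profile(p, 1)
        path = tmp_path / "p.csv"
        write_profile_csv(p, path)
        back = read_profile_csv(path)
        assert back.smoothed
        assert back.pixel_size_um == 2.0
        assert np.allclose(back.positions_um, p.positions_um)
        for ch in ("CAM", "PI", "TL"):
            assert np.allclose(back.intensities[ch], p.intensities[ch])
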