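import math

import numpy as np
import pytest

from freqcycle.metrics import (
    dice,
    evaluate_pair,
    hu_histogram,
    line_profile,
    mae,
    mse,
    nmse,
    psnr,
    ssim,
)
from freqcycle.volume import BodyMask, Volume3D


class TestPointwiseErrors:
    def test_perfect_prediction(self, rng):
        x = rng.normal(size=(3, 3, 3))
        assert mae(x, x) == 0.0
        assert mse(x, x) == 0.0
        assert nmse(x, x.copy()) == 0.0

    def test_two_voxel_hand_values(self):
        ref = np.array([[[0.0, 100.0]]])
        pred = np.array([[[10.0, 90.0]]])
        assert mae(ref, pred) == pytest.approx(10.0)
        assert mse(ref, pred) == pytest.approx(100.0)

    def test_constant_shift_bound(self, rng):
        ref = rng.normal(size=(4, 4, 4))
        pred = ref + 7.5  # pred >= ref everywhere -> MAE exactly the shift
        assert mae(ref, pred) == pytest.approx(7.5)

    def test_nmse_of_zero_prediction_is_one(self, rng):
        ref = rng.normal(0, 100, size=(4, 4, 4))
        assert nmse(ref, np.zeros_like(ref)) == pytest.approx(1.0)

    def test_nmse_scale_invariance(self, rng):
        ref, pred = rng.normal(size=(3, 3, 3)), rng.normal(size=(3, 3, 3))
        assert nmse(3.7 * ref, 3.7 * pred) == pytest.approx(nmse(ref, pred))

    def test_nmse_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            nmse(np.zeros((2, 2, 2)), np.ones((2, 2, 2)))

    def test_mae_squared_bounded_by_mse(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=(3, 3, 3)), rng.normal(size=(3, 3, 3))
            assert mae(a, b) ** 2 <= mse(a, b) + 1e-12

    def test_mask_restricts_voxels(self):
        ref = np.zeros((1, 2, 2))
        pred = np.array([[[10.0, 0.0], [0.0, 0.0]]])
        m = np.zeros((1, 2, 2), bool)
        m[0, 0, 0] = True
        assert mae(ref, pred, m) == pytest.approx(10.0)
        with pytest.raises(ValueError, match="no voxels"):
            mae(ref, pred, np.zeros((1, 2, 2), bool))


class TestPsnr:
    def test_closed_form_values(self):
        ref = np.full((2, 2, 2), 100.0)
        pred = ref - 1.0
        assert psnr(ref, pred) == pytest.approx(40.0)

    def test_ref_max_255_mse_25(self):
        ref = np.full((10, 10, 10), 200.0)
        ref[0, 0, 0] = 255.0
        pred = ref - 5.0  # mse 25
        assert psnr(ref, pred) == pytest.approx(20 * math.log10(255) - 10 * math.log10(25))
        assert psnr(ref, pred) == pytest.approx(34.1514, abs=1e-4)

    def test_perfect_prediction_is_infinity_sentinel(self, rng):
        x = np.abs(rng.normal(size=(3, 3, 3))) + 1
        assert psnr(x, x.copy()) == math.inf


class TestSsim:
    def test_identical_is_one(self, rng):
        x = rng.normal(0, 300, size=(8, 8, 8))
        assert ssim(x, x, mode="global") == pytest.approx(1.0)
        assert ssim(x, x, mode="windowed") == pytest.approx(1.0)

    def test_anticorrelated_is_negative(self, rng):
        x = rng.normal(0, 300, size=(8, 8, 8))
        y = -x + 2 * x.mean()
        assert ssim(x, y, mode="global", data_range=1.0) < 0

    def test_global_hand_oracle(self, rng):
        # direct evaluation of the single-window formula with independently
        # computed moments
        x = rng.normal(0, 10, size=(2, 2, 2))
        y = rng.normal(0, 10, size=(2, 2, 2))
        R = 100.0
        c1, c2 = (0.01 * R) ** 2, (0.03 * R) ** 2
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        expected = ((2 * mx * my + c1) * (2 * cov + c2)) / (
            (mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
        assert ssim(x, y, mode="global", data_range=R) == pytest.approx(expected, rel=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.normal(size=(6, 6, 6)), rng.normal(size=(6, 6, 6))
        for mode in ("global", "windowed"):
            assert ssim(x, y, mode=mode) == pytest.approx(ssim(y, x, mode=mode), rel=1e-12)

    def test_windowed_matches_skimage(self, rng):
        pytest.importorskip("skimage")
        from skimage.metrics import structural_similarity
        x = rng.normal(0, 300, size=(12, 12, 12))
        y = x + rng.normal(0, 50, size=(12, 12, 12))
        ours = ssim(x, y, mode="windowed", data_range=3000.0, window=7)
        ref = structural_similarity(x, y, win_size=7, data_range=3000.0,
                                    gaussian_weights=False, use_sample_covariance=False)
        # boundary handling differs (we use reflective filtering everywhere,
        # skimage crops the margin), hence a loose but meaningful agreement
        assert ours == pytest.approx(ref, abs=0.02)


class TestDice:
    def test_identical_disjoint_and_half(self):
        a = np.zeros((2, 10, 10), bool)
        a[:, :5] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        b = np.zeros_like(a)
        b[:, 2:7] = True  # |A| = |B| = 100, overlap 60
        assert dice(a, b) == pytest.approx(2 * 60 / 200)

    def test_both_empty_convention(self):
        e = np.zeros((2, 2, 2), bool)
        assert dice(e, e) == 1.0

    def test_monotone_in_overlap(self):
        a = np.zeros((1, 1, 100), bool)
        a[..., :50] = True
        prev = -1.0
        for shift in (40, 25, 10, 0):
            b = np.roll(a, shift, axis=2)
            d = dice(a, b)
            assert d >= prev
            prev = d


class TestHistogramAndProfile:
    def test_constant_volume_middle_bin(self):
        vol = Volume3D(np.zeros((3, 3, 3)))  # 0 is the centre of (-500, 500)
        counts, edges = hu_histogram(vol, -500, 500, bins=5)
        assert counts[2] == 27 and counts.sum() == 27
        assert edges[0] == -500 and edges[-1] == 500

    def test_out_of_range_excluded(self):
        data = np.array([[[-600.0, 0.0, 499.0, 500.0]]])
        counts, _ = hu_histogram(Volume3D(data), -500, 500, bins=10)
        assert counts.sum() == 2  # -600 below, 500 excluded by half-open bins

    def test_bad_bins(self):
        with pytest.raises(ValueError, match="bins"):
            hu_histogram(Volume3D(np.zeros((2, 2, 2))), -500, 500, bins=0)

    def test_profile_constant_row(self):
        data = np.zeros((2, 8, 8))
        data[1, 3, :] = 77.0
        prof = line_profile(Volume3D(data), 1, start=(0, 3), end=(7, 3), n_samples=15)
        np.testing.assert_allclose(prof, 77.0)

    def test_profile_step_transition_is_monotone(self):
        data = np.zeros((1, 4, 20))
        data[..., 10:] = 100.0
        prof = line_profile(Volume3D(data), 0, start=(0, 2), end=(19, 2), n_samples=40)
        assert prof[0] == 0.0 and prof[-1] == 100.0
        assert (np.diff(prof) >= -1e-9).all()

    def test_profile_degenerate_and_bounds(self):
        vol = Volume3D(np.arange(8.0).reshape(2, 2, 2))
        prof = line_profile(vol, 0, (1, 1), (1, 1), n_samples=5)
        np.testing.assert_allclose(prof, vol.data[0, 1, 1])
        with pytest.raises(ValueError, match="outside"):
            line_profile(vol, 0, (0, 0), (5, 0))
        with pytest.raises(ValueError, match="slice"):
            line_profile(vol, 9, (0, 0), (1, 1))


class TestEvaluatePair:
    def test_perfect_pair_report(self, rng):
        x = Volume3D(np.abs(rng.normal(0, 300, size=(4, 4, 4))) + 1)
        rep = evaluate_pair(x, x.copy())
        assert rep.mae == 0.0 and rep.mse == 0.0 and rep.nmse == 0.0
        assert rep.psnr == math.inf
        assert rep.ssim == pytest.approx(1.0)
        assert rep.clip_range == (0.0, 3000.0)
        assert rep.mask_used is False

    def test_noise_monotonicity(self, rng, small_phantom):
        ct, _ = small_phantom
        maes = []
        for sigma in (10.0, 60.0, 150.0):
            vals = []
            for seed in range(3):
                noisy = ct.data + np.random.default_rng(seed).normal(0, sigma, ct.shape)
                vals.append(evaluate_pair(ct, Volume3D(noisy, ct.spacing)).mae)
            maes.append(np.mean(vals))
        assert maes[0] < maes[1] < maes[2]

    def test_clipping_convention_applied(self):
        # values outside [0, 3000] must not influence the metrics
        ref = Volume3D(np.full((2, 2, 2), 3500.0))   # clips to 3000
        pred = Volume3D(np.full((2, 2, 2), 3200.0))  # clips to 3000
        rep = evaluate_pair(ref, pred)
        assert rep.mae == 0.0

    def test_report_serializes(self, rng):
        import json
        x = Volume3D(np.abs(rng.normal(100, 50, size=(3, 3, 3))))
        y = Volume3D(np.abs(rng.normal(100, 50, size=(3, 3, 3))))
        rep = evaluate_pair(x, y, mask=BodyMask(np.ones((3, 3, 3), bool)))
        parsed = json.loads(rep.to_json())
        assert parsed["mask_used"] is True
        assert set(parsed) >= {"mae", "mse", "nmse", "psnr", "ssim", "clip_range"}
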