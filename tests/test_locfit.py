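"""Detection, MLE localization, CRLB, precision summary, blink merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forktrap import CameraModel, simgen
from forktrap.locfit import (
    DetectionConfig,
    crlb_precision,
    detect_candidates,
    fit_crop,
    localize_stack,
    merge_blinks,
    render,
    summarize_precision,
)


class TestDetection:
    def test_blank_frames_rarely_trigger(self, camera32):
        cfg = DetectionConfig(threshold_sd=5.0)
        empty = 0
        for s in range(30):
            frames, _ = simgen.gen_smlm_frames(
                np.empty((0, 2)), [], camera32, n_frames=1, background=5.0, seed=s
            )
            if len(detect_candidates(frames[0], camera32, cfg)) == 0:
                empty += 1
        assert empty >= 29  # false positives in at most ~1/30 noise frames

    def test_bright_emitter_found_within_one_pixel(self, camera32):
        pos_px = (17.0, 12.0)  # (col, row)
        pos_nm = np.array([[(pos_px[0] + 0.5) * 65.0, (pos_px[1] + 0.5) * 65.0]])
        frames, _ = simgen.gen_smlm_frames(
            pos_nm, 5000.0, camera32, n_frames=1, background=10.0, seed=0
        )
        cands = detect_candidates(frames[0], camera32)
        assert len(cands) == 1
        row, col = cands[0]
        assert abs(row - pos_px[1]) <= 1 and abs(col - pos_px[0]) <= 1

    def test_uniform_variance_rescaling_leaves_candidates_unchanged(self, camera32):
        frames, _ = simgen.gen_smlm_frames(
            np.array([[16 * 65.0, 16 * 65.0]]), 3000.0, camera32,
            n_frames=1, background=10.0, seed=1,
        )
        cam2 = CameraModel(
            offset_map=camera32.offset_map,
            variance_map=2.0 * camera32.variance_map,
            gain_map=camera32.gain_map,
        )
        a = detect_candidates(frames[0], camera32)
        b = detect_candidates(frames[0], cam2)
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, camera32):
        with pytest.raises(ValueError):
            detect_candidates(np.zeros((16, 16)), camera32)


class TestFitCrop:
    def test_noiseless_centered_psf_fit_at_center(self, camera9):
        from forktrap.simgen import _integrated_gaussian_image

        mu = 100.0 + 2.0 * (_integrated_gaussian_image((9, 9), 4.0, 4.0, 5000.0, 1.3) + 5.0)
        emitters, bg, _ = fit_crop(mu, camera9)
        assert len(emitters) == 1
        x, y, n = emitters[0]
        assert x == pytest.approx(4.0, abs=1e-3)
        assert y == pytest.approx(4.0, abs=1e-3)
        assert n == pytest.approx(5000.0, rel=0.02)

    def test_position_error_consistent_with_crlb(self, camera9):
        """Empirical localization error sd within 20% of the CRLB (5000 ph)."""
        center = np.array([[4.5 * 65.0, 4.5 * 65.0]])
        errs, crlbs = [], []
        for s in range(150):
            frames, _ = simgen.gen_smlm_frames(
                center, 5000.0, camera9, n_frames=1, background=10.0, seed=s
            )
            res = fit_crop(frames[0], camera9)
            if res is None or len(res[0]) != 1:
                continue
            emitters, bg, _ = res
            x, y, n = emitters[0]
            errs.append([(x - 4.0) * 65.0, (y - 4.0) * 65.0])
            crlbs.append(crlb_precision([(x, y, n)], bg, camera9)[0])
        errs = np.array(errs)
        emp = np.sqrt(np.mean(errs**2))
        assert emp == pytest.approx(np.mean(crlbs), rel=0.2)

    def test_two_emitters_resolved_by_push_and_pull(self, camera9):
        pos = np.array([[2.5 * 65.0, 4.5 * 65.0], [5.5 * 65.0, 4.5 * 65.0]])
        hits = 0
        for s in range(15):
            frames, _ = simgen.gen_smlm_frames(
                pos, 5000.0, camera9, n_frames=1, background=10.0, seed=s
            )
            res = fit_crop(frames[0], camera9)
            if res is not None and len(res[0]) == 2:
                hits += 1
        assert hits >= 13  # >= ~90 % of repeats select the two-emitter model


class TestCrlb:
    def test_inverse_sqrt_photon_scaling(self, camera9):
        c1 = crlb_precision([(4.0, 4.0, 1000.0)], 1.0, camera9)[0]
        c4 = crlb_precision([(4.0, 4.0, 4000.0)], 1.0, camera9)[0]
        assert c1 / c4 == pytest.approx(2.0, rel=0.1)

    def test_zero_background_closed_form(self):
        cam = CameraModel.ideal((9, 9), variance=1e-6, gain=1.0)
        s_px = 1.3
        n = 2000.0
        crlb = crlb_precision([(4.0, 4.0, n)], 1e-9, cam, psf_sigma_px=s_px)[0]
        # pixelation widens the effective PSF: sigma_a^2 = s^2 + a^2/12
        expected = np.sqrt(s_px**2 + 1.0 / 12.0) * 65.0 / np.sqrt(n)
        assert crlb == pytest.approx(expected, rel=0.05)

    def test_higher_readout_variance_strictly_worse(self, camera9):
        noisy = CameraModel.ideal((9, 9), variance=100.0)
        c_lo = crlb_precision([(4.0, 4.0, 1000.0)], 5.0, camera9)[0]
        c_hi = crlb_precision([(4.0, 4.0, 1000.0)], 5.0, noisy)[0]
        assert c_hi > c_lo


class TestEndToEnd:
    def test_recall_precision_isolated_emitters(self, camera32):
        """Isolated 5000-photon emitters recovered with recall/precision >= 0.95."""
        rng = np.random.default_rng(0)
        tp = fp = fn = 0
        for s in range(40):
            pos = rng.uniform(8 * 65.0, 24 * 65.0, size=(1, 2))
            frames, _ = simgen.gen_smlm_frames(
                pos, 5000.0, camera32, n_frames=1, background=10.0, seed=s
            )
            locs = localize_stack(frames, camera32)
            d = np.hypot(locs["x_nm"] - pos[0, 0], locs["y_nm"] - pos[0, 1])
            matched = (d < 100).sum()
            tp += min(matched, 1)
            fp += len(locs) - min(matched, 1)
            fn += 1 - min(matched, 1)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_offset_calibration_invariance(self, camera32):
        pos = np.array([[16.2 * 65.0, 15.7 * 65.0]])
        frames, _ = simgen.gen_smlm_frames(pos, 5000.0, camera32, background=10.0, seed=2)
        shifted_cam = CameraModel(
            offset_map=camera32.offset_map + 37.0,
            variance_map=camera32.variance_map,
            gain_map=camera32.gain_map,
        )
        a = localize_stack(frames, camera32)
        b = localize_stack(frames + 37.0, shifted_cam)
        assert len(a) == len(b) == 1
        # identical up to optimizer round-off on the shifted input
        assert abs(a["x_nm"][0] - b["x_nm"][0]) < 0.1
        assert abs(a["y_nm"][0] - b["y_nm"][0]) < 0.1
        assert a["photons"][0] == pytest.approx(b["photons"][0], rel=1e-3)


class TestPrecisionSummary:
    def test_constant_sample_returns_constant(self):
        assert summarize_precision([12.0] * 60) == 12.0

    def test_symmetric_gaussian_center_near_mean(self, rng):
        vals = rng.normal(10.0, 2.0, size=3000)
        assert summarize_precision(vals) == pytest.approx(10.0, abs=0.5)

    def test_right_skewed_center_below_mean(self, rng):
        vals = stats.skewnorm.rvs(6.0, loc=8.0, scale=4.0, size=3000, random_state=rng)
        assert summarize_precision(vals) < vals.mean()


def _rec(frame, x, y, photons=1000.0):
    return {
        "frame": frame, "x_nm": x, "y_nm": y, "photons": photons,
        "background": 1.0, "crlb_nm": 10.0, "channel": "ch0", "n_merged": 1,
    }


class TestMergeBlinks:
    def test_consecutive_frames_same_position_merge(self):
        df = pd.DataFrame([_rec(5, 100.0, 100.0), _rec(6, 100.0, 100.0)])
        out = merge_blinks(df, avg_precision=10.0)
        assert len(out) == 1
        assert out["n_merged"].iloc[0] == 2
        assert out["photons"].iloc[0] == 2000.0

    def test_frame_gap_prevents_merging(self):
        df = pd.DataFrame([_rec(5, 100.0, 100.0), _rec(7, 100.0, 100.0)])
        out = merge_blinks(df, avg_precision=10.0)
        assert len(out) == 2

    def test_chained_drift_beyond_total_threshold_still_merges(self):
        # hops of 20 nm < 25 nm gate, total drift 40 nm > gate: greedy chain
        df = pd.DataFrame(
            [_rec(1, 0.0, 0.0), _rec(2, 20.0, 0.0), _rec(3, 40.0, 0.0)]
        )
        out = merge_blinks(df, avg_precision=10.0, factor=2.5)
        assert len(out) == 1
        assert out["n_merged"].iloc[0] == 3

    def test_photon_weighted_mean_position(self):
        df = pd.DataFrame([_rec(1, 0.0, 0.0, 3000.0), _rec(2, 10.0, 0.0, 1000.0)])
        out = merge_blinks(df, avg_precision=10.0)
        assert out["x_nm"].iloc[0] == pytest.approx(2.5)

    def test_idempotent_on_separated_events(self, rng):
        pts = rng.uniform(0, 10000, size=(40, 2))
        rows = []
        for i, (x, y) in enumerate(pts):
            for f in range(3 * i, 3 * i + 2):  # each event spans 2 frames
                rows.append(_rec(f, x + rng.normal(0, 3), y + rng.normal(0, 3)))
        df = pd.DataFrame(rows)
        once = merge_blinks(df, avg_precision=10.0)
        twice = merge_blinks(once, avg_precision=10.0)
        pd.testing.assert_frame_equal(once, twice)


class TestRender:
    def test_single_record_mass_one(self):
        df = pd.DataFrame([_rec(0, 500.0, 500.0)])
        img, _ = render(df)
        assert img.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_distant_records_two_maxima(self):
        df = pd.DataFrame([_rec(0, 500.0, 500.0), _rec(0, 600.0, 500.0)])
        img, _ = render(df)
        from scipy.ndimage import maximum_filter

        peaks = (img == maximum_filter(img, size=5)) & (img > 0.3 * img.max())
        assert peaks.sum() == 2

    def test_zero_blur_is_pure_histogram(self):
        df = pd.DataFrame([_rec(0, 500.0, 500.0), _rec(0, 505.0, 505.0)])
        img, _ = render(df, blur_sigma_nm=0.0)
        vals = np.sort(img.ravel())
        assert vals[-1] in (1.0, 2.0)
        assert img.sum() == 2.0
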