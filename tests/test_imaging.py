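"""Ratio images, registration and the local-maxima particle detector."""

import math

import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

import sevquant as sq
from sevquant.imaging import Frame, RatioImage
from conftest import match_detections


def structured_frame(seed=0, shape=(128, 128), stage="background"):
    rng = np.random.default_rng(seed)
    base = gaussian_filter(1000.0 * (1.0 + rng.normal(0, 0.2, shape)), 2)
    return Frame(base, stage=stage)


def noise_ratio_map(seed, shape=(96, 96), sd=0.005):
    rng = np.random.default_rng(seed)
    return 1.0 + rng.normal(0, sd, shape)


def brute_force_detect(values, cfg: sq.DetectionConfig, kind="ratio"):
    """Independent maxima oracle: exhaustive scan, threshold, greedy merge."""
    thr = cfg.threshold_for(kind)
    sm = gaussian_filter(values, cfg.smoothing_sigma, mode="nearest")
    h, w = values.shape
    cands = []
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            neigh = [
                sm[y + dy, x + dx]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)
            ]
            if sm[y, x] > max(neigh) and values[y, x] > thr and sm[y, x] > thr:
                cands.append((y, x))
    cands.sort(key=lambda p: (-sm[p], p[0], p[1]))
    accepted = []
    for y, x in cands:
        if all((y - ay) ** 2 + (x - ax) ** 2 >= cfg.min_separation**2 for ay, ax in accepted):
            accepted.append((y, x))
    return sorted(accepted)


class TestRatioAndDifference:
    def test_frame_over_itself_is_one(self):
        f = structured_frame(stage="pre_wash")
        bg = Frame(f.pixels.copy(), stage="background")
        assert np.allclose(sq.ratio_image(f, bg).values, 1.0)
        assert np.allclose(sq.difference_image(f, bg).values, 0.0)

    def test_particle_free_simulated_pair_statistics(self):
        cfg = sq.SimConfig(n_particles=0, seed=2)
        images, _ = sq.simulate_frame_stack(cfg)
        r = sq.ratio_image(images.panorama.frames[0], images.panorama.background)
        assert abs(r.values.mean() - 1.0) < 0.001
        assert r.values.std() == pytest.approx(0.005, rel=0.2)

    def test_fluorescence_difference_statistics_and_peak(self):
        cfg = sq.SimConfig(
            positions=((50.0, 50.0),),
            size_dist=sq.SizeDistSpec(components=((1.0, 150.0, 0.0),)),
            label_fraction={"fluor_cy3": 1.0},
            fluor_noise_sd=0.0,
            image_shape=(128, 128),
            seed=6,
        )
        images, gt = sq.simulate_frame_stack(cfg)
        st = images.fluorescence["fluor_cy3"]
        d = sq.difference_image(st.frames[0], st.background)
        expected_peak = float(gt.particles["fluor_fluor_cy3"].iloc[0])
        assert d.values.max() == pytest.approx(expected_peak, abs=30)  # 3 sigma of bg noise
        off_spot = d.values[70:, 70:]
        assert abs(off_spot.mean()) < 1.0
        assert off_spot.std() == pytest.approx(10.0, rel=0.2)

    def test_nonpositive_background_rejected_with_count(self):
        f = structured_frame(stage="pre_wash")
        bad = structured_frame(stage="background")
        bad.pixels[:3, :5] = 0.0
        with pytest.raises(sq.ValidationError, match="15"):
            sq.ratio_image(f, bad)


class TestRegistration:
    def test_identical_frames_zero_shift(self):
        bg = structured_frame()
        moved = Frame(bg.pixels.copy(), stage="pre_wash")
        _, shift = sq.register_to_background(moved, bg)
        assert shift == pytest.approx((0.0, 0.0))

    def test_integer_shift_recovered_exactly(self):
        bg = structured_frame(seed=1)
        rolled = Frame(np.roll(bg.pixels, (3, -2), axis=(0, 1)), stage="pre_wash")
        aligned, shift = sq.register_to_background(rolled, bg)
        assert tuple(shift) == (3.0, -2.0)
        interior = aligned.mask()
        assert np.allclose(aligned.pixels[interior], bg.pixels[interior], rtol=1e-3)

    def test_subpixel_shift_recovered_within_tenth_pixel(self):
        bg = structured_frame(seed=2)
        moved = np.real(np.fft.ifftn(fourier_shift(np.fft.fftn(bg.pixels), (0.5, 0.25))))
        _, shift = sq.register_to_background(Frame(moved, stage="pre_wash"), bg)
        assert shift[0] == pytest.approx(0.5, abs=0.1)
        assert shift[1] == pytest.approx(0.25, abs=0.1)

    def test_structureless_frames_raise_registration_error(self):
        rng = np.random.default_rng(5)
        a = Frame(1000 * (1 + rng.normal(0, 0.005, (96, 96))), stage="pre_wash")
        b = Frame(1000 * (1 + rng.normal(0, 0.005, (96, 96))), stage="background")
        with pytest.raises(sq.RegistrationError):
            sq.register_to_background(a, b)


class TestThresholdAndStats:
    @pytest.mark.parametrize(
        "mean,sd,k,expected",
        [(1.0, 0.005, 3.0, 1.015), (0.0, 10.0, 3.0, 30.0), (7.0, 2.0, 0.0, 7.0)],
    )
    def test_gaussian_threshold_arithmetic(self, mean, sd, k, expected):
        assert sq.detection_threshold(mean, sd, k) == pytest.approx(expected)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.detection_threshold(1.0, 0.0, 3.0)

    def test_background_stats_constant_image(self):
        m = RatioImage(np.full((64, 64), 1.25), "panorama", "pre_wash")
        assert sq.estimate_background_stats(m) == pytest.approx((1.25, 0.0))

    def test_background_stats_recover_simulated_noise(self):
        m = RatioImage(noise_ratio_map(3, (128, 128)), "panorama", "pre_wash")
        mean, sd = sq.estimate_background_stats(m)
        assert mean == pytest.approx(1.0, abs=0.001)
        assert sd == pytest.approx(0.005, rel=0.1)

    def test_clipping_rejects_extreme_outliers(self):
        vals = noise_ratio_map(4, (128, 128))
        rng = np.random.default_rng(5)
        idx = rng.choice(vals.size, size=vals.size // 100, replace=False)
        vals.flat[idx] = 2.0  # 1 % extreme outliers
        mean, sd = sq.estimate_background_stats(RatioImage(vals, "panorama", "pre_wash"))
        assert mean == pytest.approx(1.0, abs=0.0015)
        assert sd == pytest.approx(0.005, rel=0.1)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.estimate_background_stats(RatioImage(np.ones((10, 10)), "panorama", "pre_wash"))


class TestFindParticles:
    def test_particle_free_map_has_no_detections(self):
        m = RatioImage(noise_ratio_map(7), "panorama", "pre_wash")
        assert len(sq.find_particles(m)) == 0

    def test_matches_brute_force_oracle_on_random_small_maps(self):
        """Exact agreement with the exhaustive-scan oracle on <=64x64 maps."""
        cfg = sq.DetectionConfig()
        rng = np.random.default_rng(8)
        for trial in range(20):
            vals = 1.0 + rng.normal(0, 0.005, (48, 48))
            for _ in range(rng.integers(0, 8)):
                y, x = rng.uniform(4, 44, 2)
                c = rng.uniform(0.02, 0.3)
                yy, xx = np.mgrid[0:48, 0:48]
                vals += c * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 1.3**2))
            det = sq.find_particles(RatioImage(vals, "panorama", "pre_wash"), cfg)
            got = sorted((d.y, d.x) for d in det)
            assert got == brute_force_detect(vals, cfg)

    def test_two_adjacent_peaks_merge_to_higher(self):
        """Two above-threshold peaks 1 px apart count as one particle."""
        vals = np.ones((9, 9))
        yy, xx = np.mgrid[0:9, 0:9]
        vals += 0.10 * np.exp(-((yy - 4.0) ** 2 + (xx - 3.0) ** 2) / (2 * 0.7**2))
        vals += 0.06 * np.exp(-((yy - 4.0) ** 2 + (xx - 4.0) ** 2) / (2 * 0.7**2))
        det = sq.find_particles(RatioImage(vals, "panorama", "pre_wash"))
        assert [(d.y, d.x) for d in det] == [(4, 3)]

    def test_high_recall_and_precision_on_simulated_particles(self):
        """>=95 % precision and recall for well-spaced particles >=5 % contrast."""
        cfg = sq.SimConfig(
            n_particles=50,
            size_dist=sq.SizeDistSpec(components=((1.0, 120.0, 40.0),), min_nm=62.0),
            seed=12,
        )
        images, gt = sq.simulate_frame_stack(cfg)
        frame = images.panorama.pre_wash()[-1]
        det = sq.find_particles(sq.ratio_image(frame, images.panorama.background))
        settled = gt.settled_by(cfg.pre_wash_times[-1])
        assert (sq.contrast_from_size(settled.true_size_nm.to_numpy()) >= 5.0).all()
        _, precision, recall = match_detections(det, settled[["true_y", "true_x"]].to_numpy())
        assert precision >= 0.95
        assert recall >= 0.95

    def test_min_separation_invariant_holds_pairwise(self, detected_run):
        pre, post, fluor = detected_run
        cfg = sq.DetectionConfig()
        for ds in (pre, post, fluor):
            pos = ds.positions()
            if len(pos) < 2:
                continue
            d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            assert d2.min() >= cfg.min_separation**2

    def test_detection_is_translation_equivariant(self):
        rng = np.random.default_rng(10)
        vals = 1.0 + rng.normal(0, 0.005, (96, 96))
        for y, x, c in [(30, 40, 0.1), (60, 20, 0.2), (70, 70, 0.06)]:
            yy, xx = np.mgrid[0:96, 0:96]
            vals += c * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 1.3**2))
        shift = (5, -7)
        shifted = np.roll(vals, shift, axis=(0, 1))
        a = {(d.y, d.x) for d in sq.find_particles(RatioImage(vals, "panorama", "pre_wash"))}
        b = {(d.y, d.x) for d in sq.find_particles(RatioImage(shifted, "panorama", "pre_wash"))}
        expected = {((y + shift[0]) % 96, (x + shift[1]) % 96) for y, x in a}
        assert b == expected

    def test_raising_k_sigma_never_increases_count(self):
        rng = np.random.default_rng(11)
        vals = 1.0 + rng.normal(0, 0.005, (96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        for y, x in rng.uniform(8, 88, (10, 2)):
            vals += rng.uniform(0.01, 0.2) * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2 * 1.3**2)
            )
        m = RatioImage(vals, "panorama", "pre_wash")
        counts = [
            len(sq.find_particles(m, sq.DetectionConfig(k_sigma=k)))
            for k in (1.0, 2.0, 3.0, 5.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_detected_contrast_above_floor(self, detected_run):
        pre, _, _ = detected_run
        thr_contrast = (sq.detection_threshold(1.0, 0.005, 3.0) - 1.0) * 100.0
        assert all(d.contrast_pct > thr_contrast for d in pre)


class TestSevLikeClassification:
    @pytest.mark.parametrize(
        "contrast,expected",
        [(18.0, True), (40.0, False), (1.5, True), (18.0001, False)],
    )
    def test_boundary_inclusive_at_18pct(self, contrast, expected):
        det = sq.Detection(y=0, x=0, contrast_pct=contrast)
        assert sq.imaging.classify_sev_like(det, sq.DetectionConfig()) is expected
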