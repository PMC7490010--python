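"""LoG detector: response correctness against a brute-force convolution
oracle, localization, proximity suppression, features, and filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punckit import (
    DetectionParams,
    ReleaseKineticsParams,
    detect_spots,
    filter_spots,
    log_response,
    simulate_movie,
    spot_features,
)
from punckit.detection import DetectionError, SpotRecord
from .conftest import gaussian_spot_image


def brute_force_log(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct nested-loop convolution with an explicitly sampled LoG kernel
    (zero-sum corrected), symmetric-reflect padding."""
    rad = max(1, int(math.ceil(4 * sigma)))
    ax = np.arange(-rad, rad + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    s2 = sigma**2
    g = np.exp(-r2 / (2 * s2)) / (2 * math.pi * s2)
    k = -(r2 - 2 * s2) / s2 * g
    k -= k.mean()
    p = np.pad(img, rad, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (p[i : i + 2 * rad + 1, j : j + 2 * rad + 1] * k).sum()
    return out


class TestLogResponse:
    def test_constant_image_gives_zero(self):
        img = np.full((33, 33), 512.0)
        assert np.abs(log_response(img, 1.2)).max() < 1e-9

    def test_centered_gaussian_peaks_at_center(self):
        img = gaussian_spot_image((21, 21), [(10, 10)], sigma=1.3, background=0.0)
        resp = log_response(img, 1.3)
        assert np.unravel_index(resp.argmax(), resp.shape) == (10, 10)

    def test_matches_brute_force_oracle_off_center_spot(self):
        img = gaussian_spot_image((21, 21), [(7.0, 13.0)], sigma=1.1)
        resp = log_response(img, 1.1)
        oracle = brute_force_log(img, 1.1)
        assert np.abs(resp - oracle).max() <= 1e-6 * np.abs(oracle).max()

    def test_matches_oracle_on_random_images(self):
        rng = np.random.default_rng(0)
        sigma = 1.3
        margin = int(math.ceil(3 * sigma))
        for _ in range(20):
            img = rng.uniform(0.0, 1000.0, size=(32, 32))
            resp = log_response(img, sigma)[margin:-margin, margin:-margin]
            oracle = brute_force_log(img, sigma)[margin:-margin, margin:-margin]
            assert np.abs(resp - oracle).max() <= 1e-6 * np.abs(oracle).max()

    def test_rejects_non_finite_pixels(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(DetectionError):
            log_response(img, 1.0)


class TestDetectSpots:
    def test_blank_image_yields_no_spots(self, default_det):
        assert detect_spots(np.full((64, 64), 200.0), 0.0, default_det) == []

    def test_single_spot_localized_within_one_pixel(self, default_det):
        img = gaussian_spot_image((64, 64), [(32, 32)])
        spots = detect_spots(img, 0.0, default_det)
        assert len(spots) == 1
        assert abs(spots[0].x_px - 32) <= 1 and abs(spots[0].y_px - 32) <= 1
        assert spots[0].x_um == pytest.approx(spots[0].x_px * 0.16)

    def test_close_pair_suppressed_to_single_record(self):
        # two identical spots 2 px apart with a ~4 px blob diameter
        det = DetectionParams(blob_diameter=0.64, pixel_size=0.16, quality_threshold=50.0)
        img = gaussian_spot_image((64, 64), [(30, 30), (30, 32)], sigma=1.4)
        spots = detect_spots(img, 0.0, det)
        assert len(spots) == 1

    def test_quality_increases_with_amplitude(self):
        det = DetectionParams(quality_threshold=50.0)
        qualities = []
        for amp in (500, 1000, 2000, 4000, 8000):
            img = gaussian_spot_image((41, 41), [(20, 20)], amplitude=amp)
            (spot,) = detect_spots(img, 0.0, det)
            qualities.append(spot.quality)
        assert all(a < b for a, b in zip(qualities, qualities[1:]))

    def test_undetectable_scale_raises(self):
        det = DetectionParams(blob_diameter=0.2, pixel_size=0.16)
        with pytest.raises(DetectionError):
            detect_spots(np.zeros((32, 32)), 0.0, det)

    def test_recall_and_precision_on_noise_free_field(self, noise_free_acq, default_det):
        movie, _, truth = simulate_movie(
            ReleaseKineticsParams(mode="vehicle"), noise_free_acq, seed=42
        )
        spots = detect_spots(movie.frames[0], 0.0, default_det)
        true_pos = truth.puncta[["y_px", "x_px"]].to_numpy()
        matched = set()
        tp = 0
        for s in spots:
            d = np.hypot(true_pos[:, 0] - s.y_px, true_pos[:, 1] - s.x_px)
            j = int(d.argmin())
            if d[j] <= 2.0 and j not in matched:
                matched.add(j)
                tp += 1
        assert tp / len(true_pos) >= 0.95  # recall
        assert tp / len(spots) >= 0.95  # precision


class TestSpotFeatures:
    def test_uniform_image_contrast_zero(self):
        contrast, _, _ = spot_features(np.full((21, 21), 7.0), (10, 10), 3.0)
        assert contrast == pytest.approx(0.0)

    def test_disc_on_background_contrast_one_third(self):
        # disc at 2a on background a: (2a - a)/(2a + a) = 1/3
        img = np.full((41, 41), 5.0)
        yy, xx = np.mgrid[0:41, 0:41]
        img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 3.0**2] = 10.0
        contrast, _, _ = spot_features(img, (20, 20), 3.0)
        assert contrast == pytest.approx(1.0 / 3.0)

    def test_total_intensity_sums_disc(self):
        img = np.zeros((41, 41))
        yy, xx = np.mgrid[0:41, 0:41]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 3.0**2
        img[disc] = 4.0
        _, total, _ = spot_features(img, (20, 20), 3.0)
        assert total == pytest.approx(disc.sum() * 4.0)

    def test_border_disc_flagged_clipped(self):
        feats = spot_features(np.ones((21, 21)), (1, 1), 3.0)
        assert feats.clipped

    def test_zero_radius_raises(self):
        with pytest.raises(DetectionError):
            spot_features(np.ones((9, 9)), (4, 4), 0.0)


def _make_spot(quality=400.0, contrast=0.5, total=1000.0, x=10.0, y=10.0):
    return SpotRecord(
        frame=0, t_s=0.0, x_px=x, y_px=y, x_um=x * 0.16, y_um=y * 0.16,
        quality=quality, contrast=contrast, total_intensity=total, radius_um=0.25,
    )


class TestFilterSpots:
    def test_no_thresholds_is_identity(self, default_det):
        spots = [_make_spot(), _make_spot(quality=301.0)]
        assert filter_spots(spots, default_det) == spots

    def test_contrast_minimum(self):
        det = DetectionParams(contrast_min=0.2)
        spots = [_make_spot(contrast=0.1), _make_spot(contrast=0.3)]
        assert filter_spots(spots, det) == [spots[1]]

    def test_exclusion_mask_removes_covered_spot(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10, 10] = True
        det = DetectionParams(exclusion_mask=mask)
        spots = [_make_spot(x=10.0, y=10.0), _make_spot(x=20.0, y=20.0)]
        assert filter_spots(spots, det) == [spots[1]]

    def test_idempotent(self):
        det = DetectionParams(contrast_min=0.2, total_intensity_min=500.0)
        spots = [_make_spot(contrast=c, total=t) for c in (0.1, 0.3) for t in (100, 900)]
        once = filter_spots(spots, det)
        assert filter_spots(once, det) == once

    @settings(deadline=None, derandomize=True)
    @given(perm=st.permutations(range(6)))
    def test_survivors_invariant_to_input_order(self, perm):
        det = DetectionParams(contrast_min=0.25)
        spots = [_make_spot(contrast=0.1 * i, total=100.0 * i) for i in range(6)]
        shuffled = [spots[i] for i in perm]
        expected = {id(s) for s in filter_spots(spots, det)}
        assert {id(s) for s in filter_spots(shuffled, det)} == expected
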