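"""Trajectory analysis: baseline normalization, boxcar smoothing, band-rule
decay times, replicate summaries, binning, and parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punckit import (
    CellTimeSeries,
    KineticsParams,
    NormalizedSeries,
    bin_curve,
    boxcar_smooth,
    decay_time,
    normalize_counts,
    summarize_replicate,
)
from punckit.kinetics import KineticsError


def _cell_series(timestamps, counts, qc=True):
    return CellTimeSeries(
        cell_id=1, condition="emt", replicate="r1",
        timestamps=np.asarray(timestamps, dtype=float),
        counts=np.asarray(counts), cyto_mean=np.ones(len(counts)), qc_pass=qc,
    )


def _norm(timestamps, values, cell_id=1):
    return NormalizedSeries(
        cell_id=cell_id, condition="emt", replicate="r1",
        timestamps=np.asarray(timestamps, dtype=float),
        normalized=np.asarray(values, dtype=float),
    )


class TestNormalizeCounts:
    def test_constant_counts_normalize_to_one(self, default_kinp):
        s = _cell_series(np.arange(0, 100, 5.0), np.full(20, 7))
        ns = normalize_counts(s, default_kinp)
        np.testing.assert_allclose(ns.normalized, 1.0)

    def test_baseline_mean_example(self, default_kinp):
        s = _cell_series([0.0, 20.0, 40.0, 70.0], [10, 12, 14, 6])
        ns = normalize_counts(s, default_kinp)
        np.testing.assert_allclose(
            ns.normalized, [10 / 12, 1.0, 14 / 12, 0.5], rtol=1e-12
        )

    def test_zero_baseline_raises(self, default_kinp):
        s = _cell_series([0.0, 30.0, 70.0], [0, 0, 5])
        with pytest.raises(KineticsError):
            normalize_counts(s, default_kinp)

    def test_failed_qc_rejected(self, default_kinp):
        s = _cell_series([0.0, 30.0, 70.0], [5, 5, 5], qc=False)
        with pytest.raises(KineticsError):
            normalize_counts(s, default_kinp)

    def test_baseline_is_strictly_before_cutoff(self):
        # a frame stamped exactly at the window end is post-baseline
        p = KineticsParams(baseline_window=60.0)
        s = _cell_series([0.0, 59.9, 60.0], [10, 10, 100])
        ns = normalize_counts(s, p)
        assert ns.normalized[0] == pytest.approx(1.0)


class TestBoxcarSmooth:
    def test_truncated_edge_example(self):
        np.testing.assert_allclose(boxcar_smooth([0, 1, 2, 3, 4], 3), [0.5, 1, 2, 3, 3.5])

    def test_k1_identity(self):
        np.testing.assert_array_equal(boxcar_smooth([3.0, 1.0, 4.0], 1), [3.0, 1.0, 4.0])

    def test_empty_raises(self):
        with pytest.raises(KineticsError):
            boxcar_smooth([], 3)

    @settings(deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=-100, max_value=100), min_size=1, max_size=40),
        k=st.integers(min_value=1, max_value=15),
    )
    def test_preserves_length_and_constants(self, values, k):
        out = boxcar_smooth(values, k)
        assert len(out) == len(values)
        const = boxcar_smooth([5.0] * len(values), k)
        np.testing.assert_allclose(const, 5.0)
        assert out.min() >= min(values) - 1e-9 and out.max() <= max(values) + 1e-9


class TestDecayTime:
    def test_single_frame_exactly_at_fraction(self, default_kinp):
        est = decay_time([100.0, 160.0, 200.0], [0.9, 0.50, 0.2], 0.5, default_kinp)
        assert est.method == "band_average"
        assert est.time == pytest.approx(100.0)

    def test_band_average_of_three_frames(self, default_kinp):
        est = decay_time(
            [150.0, 155.0, 165.0], [0.508, 0.501, 0.493], 0.5, default_kinp
        )
        assert est.method == "band_average" and est.n_frames_in_band == 3
        assert est.time == pytest.approx((150 + 155 + 165) / 3 - 60)

    def test_interpolated_crossing_when_band_skipped(self, default_kinp):
        est = decay_time([100.0, 110.0], [0.60, 0.40], 0.5, default_kinp)
        assert est.method == "interpolated"
        assert est.time == pytest.approx(105.0 - 60.0)

    def test_not_reached_is_distinguished(self, default_kinp):
        est = decay_time(np.arange(0, 300, 5.0), np.full(60, 1.0), 0.5, default_kinp)
        assert est.method == "not_reached" and est.time is None and not est.reached

    def test_pre_drug_band_frames_ignored(self, default_kinp):
        # a noisy pre-drug touch of the band must not contaminate the average
        est = decay_time(
            [30.0, 100.0, 110.0], [0.505, 0.60, 0.40], 0.5, default_kinp
        )
        assert est.method == "interpolated"
        assert est.time == pytest.approx(45.0)

    def test_ordering_for_monotone_decay(self, default_kinp):
        t = np.arange(0, 480, 5.0)
        s = np.exp(-0.02 * np.maximum(t - 60.0, 0.0))
        times = {
            f: decay_time(t, s, f, default_kinp).time for f in (2 / 3, 0.5, 1 / 3)
        }
        assert times[2 / 3] <= times[0.5] <= times[1 / 3]


class TestSummarizeReplicate:
    def test_single_cell_equals_own_decay(self, default_kinp):
        t = np.arange(0, 480, 5.0)
        v = np.exp(-0.02 * np.maximum(t - 60.0, 0.0))
        cell = _norm(t, v)
        summary = summarize_replicate([cell], default_kinp)
        sm = boxcar_smooth(v, default_kinp.boxcar_k)
        expected = decay_time(t, sm, 0.5, default_kinp)
        assert summary.decay_time(0.5).time == pytest.approx(expected.time)

    def test_two_identical_cells_match_single(self, default_kinp):
        t = np.arange(0, 480, 5.0)
        v = np.exp(-0.02 * np.maximum(t - 60.0, 0.0))
        one = summarize_replicate([_norm(t, v)], default_kinp)
        two = summarize_replicate([_norm(t, v, 1), _norm(t, v, 2)], default_kinp)
        assert two.decay_time(0.5).time == pytest.approx(one.decay_time(0.5).time)

    def test_mixed_step_and_constant_cells(self, default_kinp):
        t = np.arange(0, 300, 5.0)
        flat = np.ones_like(t)
        step = (t < 60.0).astype(float)
        summary = summarize_replicate([_norm(t, flat, 1), _norm(t, step, 2)], default_kinp)
        assert summary.decay_time(2 / 3).reached
        assert not summary.decay_time(1 / 3).reached

    def test_no_cells_raises(self, default_kinp):
        with pytest.raises(KineticsError):
            summarize_replicate([], default_kinp)


class TestBinCurve:
    def test_singleton_bins_have_zero_sd(self, default_kinp):
        c = _norm([1.0, 7.0, 12.0], [0.9, 0.8, 0.7])
        curve = bin_curve([c], default_kinp)
        np.testing.assert_array_equal(curve.sd, 0.0)
        np.testing.assert_array_equal(curve.n, 1)

    def test_two_observations_in_one_bin(self, default_kinp):
        c = _norm([1.0, 3.0], [0.4, 0.6])
        curve = bin_curve([c], default_kinp)
        assert curve.mean[0] == pytest.approx(0.5)
        assert curve.sd[0] == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_bin_edge_goes_right(self, default_kinp):
        c = _norm([5.0], [0.5])
        curve = bin_curve([c], default_kinp)
        assert curve.bin_centers[0] == pytest.approx(7.5)  # bin [5, 10)

    def test_every_observation_in_exactly_one_bin(self, default_kinp):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 100, 57))
        c = _norm(t, rng.uniform(0, 1, 57))
        curve = bin_curve([c], default_kinp)
        assert curve.n.sum() == 57


class TestParameterRecovery:
    def test_half_life_recovered_from_sampled_exponential_counts(self, default_kinp):
        # ground-truth counts (no imaging noise): replicate t_1/2 within 20%
        # of the boxcar-bias-corrected analytic crossing
        lam = 0.021
        rng = np.random.default_rng(12)
        t = np.arange(0.0, 480.0, 5.0)
        cells = []
        for cid in range(8):
            release = 60.0 + rng.exponential(1 / lam, size=30)
            counts = (release[None, :] > t[:, None]).sum(axis=1)
            cells.append(_norm(t, counts / 30.0, cid))
        summary = summarize_replicate(cells, default_kinp)
        w = default_kinp.boxcar_k / 2 * 5.0
        bias = np.sinh(lam * w) / (lam * w)
        expected = np.log(2 * bias) / lam
        assert summary.decay_time(0.5).time == pytest.approx(expected, rel=0.20)
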