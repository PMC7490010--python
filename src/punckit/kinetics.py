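"""Decay-time analysis of puncta-count trajectories.

Each cell's puncta counts are normalized to its own pre-drug baseline (mean
count over the first 60 s), replicate-mean trajectories are smoothed with a
boxcar (rolling-mean) filter, and the characteristic decay times t_2/3,
t_1/2, t_1/3 — seconds after drug addition at which the smoothed normalized
count passes two-thirds, one-half, one-third — are read off via a band rule:
all frames whose smoothed value lies within ±0.01 of the target fraction
are collected and their timestamps averaged.  When sampling skips the band
entirely (steep decays at ~5 s frame intervals), the crossing is linearly
interpolated instead and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cells import CellTimeSeries


class KineticsError(ValueError):
    """Raised for invalid kinetics inputs (empty series, zero baseline...)."""


DEFAULT_FRACTIONS = (2.0 / 3.0, 0.5, 1.0 / 3.0)


@dataclass(frozen=True)
class KineticsParams:
    """Trajectory-analysis parameters.

    baseline_window — seconds of pre-drug trial used as the count baseline
    (default 60 s, strictly t < 60); boxcar_k — rolling-mean width in
    observations (default 10); band_halfwidth — half-width of the decay-time
    band in normalized units (default 0.01, i.e. 0.49–0.51 for t_1/2);
    bin_width — seconds per summary bin (default 5); drug_time — seconds
    from trial start at which the drug is added (default 60).
    """

    baseline_window: float = 60.0
    boxcar_k: int = 10
    band_halfwidth: float = 0.01
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    bin_width: float = 5.0
    drug_time: float = 60.0

    def __post_init__(self) -> None:
        if self.baseline_window <= 0 or self.bin_width <= 0 or self.boxcar_k < 1:
            raise KineticsError("baseline_window, bin_width, boxcar_k must be positive")
        if self.band_halfwidth <= 0:
            raise KineticsError("band_halfwidth must be positive")
        if not all(0 < f < 1 for f in self.fractions):
            raise KineticsError("fractions must lie in (0, 1)")
        if len(self.fractions) > 1:
            spacing = min(
                abs(a - b)
                for i, a in enumerate(self.fractions)
                for b in self.fractions[i + 1 :]
            )
            if self.band_halfwidth >= spacing:
                raise KineticsError("band_halfwidth must be below fraction spacing")
        if self.drug_time < 0:
            raise KineticsError("drug_time must be >= 0")


@dataclass
class NormalizedSeries:
    """A cell's baseline-normalized puncta-count trajectory."""

    cell_id: int
    condition: str
    replicate: str
    timestamps: np.ndarray
    normalized: np.ndarray
    smoothed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if len(self.timestamps) != len(self.normalized):
            raise KineticsError("timestamps/normalized length mismatch")


@dataclass
class DecayEstimate:
    """Time after drug addition at which a fraction of puncta remains.

    ``method`` is ``band_average`` when ≥1 frame fell inside the ±band,
    ``interpolated`` when the crossing was bridged linearly between frames,
    and ``not_reached`` when the trajectory never descends to the fraction
    (``time`` is then None).
    """

    fraction: float
    time: Optional[float]
    n_frames_in_band: int
    method: str  # band_average | interpolated | not_reached

    @property
    def reached(self) -> bool:
        return self.method != "not_reached"


@dataclass
class ReplicateSummary:
    """Decay times extracted from one replicate's mean trajectory."""

    replicate: str
    condition: str
    estimates: dict[float, DecayEstimate] = field(default_factory=dict)

    def decay_time(self, fraction: float) -> DecayEstimate:
        key = min(self.estimates, key=lambda f: abs(f - fraction))
        if abs(key - fraction) > 1e-9:
            raise KeyError(f"no estimate for fraction {fraction}")
        return self.estimates[key]


@dataclass
class BinnedCurve:
    """Mean ± sd of pooled normalized counts in fixed time bins."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    condition: str = ""


def normalize_counts(series: CellTimeSeries, p: KineticsParams) -> NormalizedSeries:
    """Divide a cell's counts by its mean count over frames with
    t < baseline_window (the pre-drug interval)."""
    if series.qc_pass is False:
        raise KineticsError(f"cell {series.cell_id}: failed QC, not normalizable")
    baseline_idx = series.timestamps < p.baseline_window
    if not baseline_idx.any():
        raise KineticsError(f"cell {series.cell_id}: no frames before baseline end")
    baseline = float(series.counts[baseline_idx].mean())
    if baseline == 0:
        raise KineticsError(f"cell {series.cell_id}: zero baseline count")
    return NormalizedSeries(
        cell_id=series.cell_id,
        condition=series.condition,
        replicate=series.replicate,
        timestamps=series.timestamps.copy(),
        normalized=series.counts / baseline,
    )


def boxcar_smooth(values: Sequence[float], k: int) -> np.ndarray:
    """Centered rolling mean of width ``k`` observations.

    Windows truncate at the boundaries, so the output length equals the
    input length.  For even ``k`` the filter is kept symmetric the textbook
    way — a (k+1)-tap window with half weight on both end taps — instead of
    placing the extra observation on one side, which would shift crossing
    times by half a frame interval.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise KineticsError("cannot smooth an empty series")
    if k < 1:
        raise KineticsError("window must be >= 1")
    if k % 2 == 1:
        weights = np.ones(k)
    else:
        weights = np.ones(k + 1)
        weights[0] = weights[-1] = 0.5
    # weights length is always odd; take the centered slice of the full
    # convolution so short inputs (n < k) keep their length
    half = len(weights) // 2
    num = np.convolve(values, weights, mode="full")[half : half + values.size]
    den = np.convolve(np.ones_like(values), weights, mode="full")[half : half + values.size]
    return num / den


def decay_time(
    timestamps: Sequence[float],
    smoothed: Sequence[float],
    fraction: float,
    p: KineticsParams,
) -> DecayEstimate:
    """Band-rule decay-time extraction on a smoothed trajectory.

    Frames at t >= drug_time whose smoothed value lies within
    ±band_halfwidth of ``fraction`` are averaged; with an empty band the
    first downward crossing after drug_time is linearly interpolated.
    """
    t = np.asarray(timestamps, dtype=float)
    s = np.asarray(smoothed, dtype=float)
    if t.size != s.size or t.size == 0:
        raise KineticsError("timestamps/smoothed mismatch or empty")
    post = t >= p.drug_time
    in_band = post & (np.abs(s - fraction) <= p.band_halfwidth)
    if in_band.any():
        return DecayEstimate(
            fraction=fraction,
            time=float(t[in_band].mean() - p.drug_time),
            n_frames_in_band=int(in_band.sum()),
            method="band_average",
        )
    # interpolated fallback: first downward crossing at or after drug_time
    for i in range(t.size - 1):
        if t[i + 1] < p.drug_time:
            continue
        if s[i] > fraction >= s[i + 1]:
            tc = t[i] + (s[i] - fraction) / (s[i] - s[i + 1]) * (t[i + 1] - t[i])
            return DecayEstimate(
                fraction=fraction,
                time=float(max(tc - p.drug_time, 0.0)),
                n_frames_in_band=0,
                method="interpolated",
            )
    return DecayEstimate(
        fraction=fraction, time=None, n_frames_in_band=0, method="not_reached"
    )


def _nearest_resample(ts: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Sample ``values`` onto ``grid`` by nearest-timestamp alignment."""
    idx = np.searchsorted(ts, grid)
    idx = np.clip(idx, 1, len(ts) - 1)
    left, right = ts[idx - 1], ts[idx]
    idx -= grid - left < right - grid
    return values[idx]


def summarize_replicate(
    cells: Sequence[NormalizedSeries], p: KineticsParams
) -> ReplicateSummary:
    """Decay times of the replicate-mean trajectory.

    Cells (imaged asynchronously in general) are aligned onto the union of
    their time grids by nearest-frame resampling, averaged, smoothed with
    the boxcar, and the band rule applied per fraction.
    """
    if not cells:
        raise KineticsError("no QC-passing cells in replicate")
    grid = np.unique(np.concatenate([c.timestamps for c in cells]))
    stack = np.vstack(
        [_nearest_resample(c.timestamps, c.normalized, grid) for c in cells]
    )
    mean_traj = stack.mean(axis=0)
    smoothed = boxcar_smooth(mean_traj, p.boxcar_k)
    summary = ReplicateSummary(
        replicate=cells[0].replicate, condition=cells[0].condition
    )
    for f in p.fractions:
        summary.estimates[f] = decay_time(grid, smoothed, f, p)
    return summary


def bin_curve(cells: Sequence[NormalizedSeries], p: KineticsParams) -> BinnedCurve:
    """Pool normalized counts across cells into half-open time bins
    [i*bin_width, (i+1)*bin_width) and report per-bin mean, sample sd, n
    (sd reported as 0 for singleton bins)."""
    if not cells:
        raise KineticsError("no series to bin")
    t = np.concatenate([c.timestamps for c in cells])
    v = np.concatenate([c.normalized for c in cells])
    idx = np.floor(t / p.bin_width).astype(int)
    bins = np.unique(idx)
    centers, means, sds, ns = [], [], [], []
    for b in bins:
        vals = v[idx == b]
        centers.append((b + 0.5) * p.bin_width)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
        ns.append(vals.size)
    return BinnedCurve(
        bin_centers=np.asarray(centers),
        mean=np.asarray(means),
        sd=np.asarray(sds),
        n=np.asarray(ns),
        condition=cells[0].condition,
    )
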