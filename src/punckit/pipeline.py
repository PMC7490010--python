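"""End-to-end orchestration: simulate -> detect -> QC -> normalize ->
summarize, plus cross-condition statistical comparison.

This is the programmatic counterpart of the command-line pipeline; every
stage delegates to the corresponding module so the CLI, tests, and the
reproduction script share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cells import CellROI, CellTimeSeries, build_cell_series, qc_photobleach
from .detection import DetectionParams, SpotRecord, detect_spots
from .io import MovieStack
from .kinetics import (
    BinnedCurve,
    KineticsParams,
    NormalizedSeries,
    ReplicateSummary,
    bin_curve,
    normalize_counts,
    summarize_replicate,
)
from .stats import WelchResult, welch_t
from .synthetic import (
    AcquisitionParams,
    GroundTruth,
    ReleaseKineticsParams,
    simulate_movie,
)


@dataclass
class ReplicateResult:
    """Everything measured from one imaging trial."""

    replicate: str
    condition: str
    summary: ReplicateSummary
    cells: list[NormalizedSeries]
    all_series: list[CellTimeSeries]
    n_qc_failed: int
    truth: Optional[GroundTruth] = None


@dataclass
class ConditionResult:
    condition: str
    replicates: list[ReplicateResult] = field(default_factory=list)

    def decay_times(self, fraction: float) -> list[float]:
        """Per-replicate decay times (s) for replicates that reached the
        fraction."""
        out = []
        for r in self.replicates:
            est = r.summary.decay_time(fraction)
            if est.reached:
                out.append(float(est.time))
        return out

    def mean_decay_time(self, fraction: float) -> float:
        times = self.decay_times(fraction)
        return float(np.mean(times)) if times else float("nan")

    def binned_curve(self, p: KineticsParams) -> BinnedCurve:
        cells = [c for r in self.replicates for c in r.cells]
        return bin_curve(cells, p)


def detect_movie_spots(
    movie: MovieStack,
    det: DetectionParams,
    rois: Optional[Sequence[CellROI]] = None,
) -> list[list[SpotRecord]]:
    """Run the LoG detector on every frame; when ROIs carry nucleus masks,
    their union becomes the exclusion mask (nuclear-spot suppression)."""
    params = det
    if rois is not None:
        nuclei = [r.nucleus_mask for r in rois if r.nucleus_mask is not None]
        if nuclei:
            exclusion = np.any(np.stack(nuclei), axis=0)
            if det.exclusion_mask is not None:
                exclusion = exclusion | det.exclusion_mask
            params = DetectionParams(
                blob_diameter=det.blob_diameter,
                quality_threshold=det.quality_threshold,
                contrast_min=det.contrast_min,
                total_intensity_min=det.total_intensity_min,
                pixel_size=det.pixel_size,
                exclusion_mask=exclusion,
            )
    return [
        detect_spots(movie.frames[i], t=movie.timestamps[i], params=params, frame=i)
        for i in range(movie.n_frames)
    ]


def analyze_movie(
    movie: MovieStack,
    rois: Sequence[CellROI],
    det: DetectionParams,
    kinp: KineticsParams,
    replicate: str = "",
    truth: Optional[GroundTruth] = None,
) -> ReplicateResult:
    """Detection, per-cell series, QC, normalization, and replicate summary
    for one movie."""
    spots_by_frame = detect_movie_spots(movie, det, rois)
    series = build_cell_series(movie, rois, spots_by_frame)
    passing: list[NormalizedSeries] = []
    n_failed = 0
    for s in series:
        if qc_photobleach(s):
            passing.append(normalize_counts(s, kinp))
        else:
            n_failed += 1
    summary = summarize_replicate(passing, kinp)
    return ReplicateResult(
        replicate=replicate or str(movie.replicate),
        condition=movie.condition,
        summary=summary,
        cells=passing,
        all_series=series,
        n_qc_failed=n_failed,
        truth=truth,
    )


def run_condition(
    kin: ReleaseKineticsParams,
    acq: AcquisitionParams,
    det: DetectionParams,
    kinp: KineticsParams,
    n_replicates: int,
    seed,
    condition: str = "",
    keep_truth: bool = False,
) -> ConditionResult:
    """Simulate and analyze ``n_replicates`` independent imaging trials.

    Per-replicate random streams are spawned deterministically from the
    single seed, so results are reproducible bit-for-bit.
    """
    condition = condition or kin.mode
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    result = ConditionResult(condition=condition)
    for i, child in enumerate(children):
        rep_id = f"{condition}-r{i + 1}"
        movie, rois, truth = simulate_movie(
            kin, acq, np.random.default_rng(child), condition=condition, replicate=rep_id
        )
        rep = analyze_movie(
            movie, rois, det, kinp, replicate=rep_id, truth=truth if keep_truth else None
        )
        result.replicates.append(rep)
    return result


def compare_conditions(
    a: ConditionResult, b: ConditionResult, kinp: KineticsParams
) -> pd.DataFrame:
    """Welch's t-test on per-replicate decay times for each fraction."""
    rows = []
    for f in kinp.fractions:
        ta, tb = a.decay_times(f), b.decay_times(f)
        res: Optional[WelchResult] = None
        if len(ta) >= 2 and len(tb) >= 2:
            res = welch_t(ta, tb)
        rows.append(
            {
                "fraction": f,
                "condition_a": a.condition,
                "condition_b": b.condition,
                "mean_a_s": float(np.mean(ta)) if ta else np.nan,
                "mean_b_s": float(np.mean(tb)) if tb else np.nan,
                "n_a": len(ta),
                "n_b": len(tb),
                "t": res.t if res else np.nan,
                "df": res.df if res else np.nan,
                "p": res.p if res else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fraction",
            "condition_a",
            "condition_b",
            "mean_a_s",
            "mean_b_s",
            "n_a",
            "n_b",
            "t",
            "df",
            "p",
        ],
    )
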