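"""Per-cell measurements: spot-to-cell assignment, count/intensity time
series, the photobleaching QC rule, and still-image per-cell quantification.

Cell regions are supplied as binary masks (manually drawn in the original
workflow); nuclei, when provided, are excluded both from puncta counting and
from the cytoplasmic-intensity average.  The QC rule discards cells whose
smoothed cytoplasmic reporter intensity drops more than 10% below its
early-trial baseline (photobleaching or focal drift), evaluated on a rolling
mean so single-frame glitches are not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .detection import DetectionParams, SpotRecord, detect_spots


class CellQuantError(ValueError):
    """Raised for inconsistent masks, frames, or empty inputs."""


@dataclass
class CellROI:
    """One cell's region of interest within a field."""

    cell_id: int
    mask: np.ndarray
    nucleus_mask: Optional[np.ndarray] = None
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise CellQuantError(f"cell {self.cell_id}: empty mask")
        if self.nucleus_mask is not None:
            self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
            if self.nucleus_mask.shape != self.mask.shape:
                raise CellQuantError(
                    f"cell {self.cell_id}: nucleus mask shape mismatch"
                )

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        """Cell mask minus nucleus (whole mask when no nucleus is given)."""
        if self.nucleus_mask is None:
            return self.mask
        return self.mask & ~self.nucleus_mask


@dataclass
class CellTimeSeries:
    """Puncta counts and cytoplasmic reporter intensity over a trial."""

    cell_id: int
    condition: str
    replicate: str
    timestamps: np.ndarray
    counts: np.ndarray
    cyto_mean: np.ndarray
    qc_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.cyto_mean = np.asarray(self.cyto_mean, dtype=float)
        n = len(self.timestamps)
        if len(self.counts) != n or len(self.cyto_mean) != n:
            raise CellQuantError("timestamps/counts/cyto_mean length mismatch")
        if np.any(self.counts < 0):
            raise CellQuantError("negative puncta count")


@dataclass
class CellIntensityRecord:
    """Per-cell mean-intensity measurement for still-image IF or PLA."""

    cell_id: int
    condition: str
    experiment: str
    modality: str
    mean_intensity: float
    normalized_intensity: Optional[float] = None
    puncta_count: Optional[int] = None


def count_puncta_in_cell(spots: Iterable[SpotRecord], roi: CellROI) -> int:
    """Number of spots whose center pixel lies inside the cell mask and, when
    a nucleus mask is present, outside the nucleus.  Pixel membership of the
    rounded center decides; boundary pixels count."""
    mask = roi.cytoplasm_mask
    h, w = mask.shape
    n = 0
    for s in spots:
        r, c = int(round(s.y_px)), int(round(s.x_px))
        if 0 <= r < h and 0 <= c < w and mask[r, c]:
            n += 1
    return n


def build_cell_series(
    movie,
    rois: Sequence[CellROI],
    spots_by_frame: Sequence[Sequence[SpotRecord]],
) -> list[CellTimeSeries]:
    """Assemble per-cell count and cytoplasmic-intensity time series.

    ``movie`` provides ``frames`` (T, H, W) and ``timestamps`` (T,); spots
    must be grouped per frame in the same order.
    """
    frames = np.asarray(movie.frames)
    timestamps = np.asarray(movie.timestamps, dtype=float)
    if frames.shape[0] != len(timestamps):
        raise CellQuantError(
            f"{frames.shape[0]} frames but {len(timestamps)} timestamps"
        )
    if len(spots_by_frame) != frames.shape[0]:
        raise CellQuantError(
            f"{len(spots_by_frame)} spot frames for {frames.shape[0]} image frames"
        )
    out: list[CellTimeSeries] = []
    for roi in rois:
        cyto = roi.cytoplasm_mask
        if not cyto.any():
            raise CellQuantError(f"cell {roi.cell_id}: empty cytoplasm mask")
        counts = [count_puncta_in_cell(fs, roi) for fs in spots_by_frame]
        cyto_mean = frames[:, cyto].mean(axis=1)
        out.append(
            CellTimeSeries(
                cell_id=roi.cell_id,
                condition=roi.condition or getattr(movie, "condition", ""),
                replicate=roi.replicate or str(getattr(movie, "replicate", "")),
                timestamps=timestamps,
                counts=np.asarray(counts, dtype=int),
                cyto_mean=np.asarray(cyto_mean, dtype=float),
            )
        )
    return out


def qc_photobleach(
    series: CellTimeSeries, max_decrease: float = 0.10, window: int = 10
) -> bool:
    """Photobleaching / focal-drift QC.

    The cytoplasmic intensity trace is normalized to the mean of its first
    ``window`` frames, smoothed with a rolling mean of the same width, and
    the cell fails if the smoothed trace ever drops below ``1 - max_decrease``.
    The verdict is stored on ``series.qc_pass`` and returned.
    """
    from .kinetics import boxcar_smooth  # local import to avoid a cycle

    if len(series.cyto_mean) < window:
        raise CellQuantError(
            f"cell {series.cell_id}: {len(series.cyto_mean)} frames < "
            f"{window}-frame baseline"
        )
    baseline = float(series.cyto_mean[:window].mean())
    if baseline <= 0:
        raise CellQuantError(f"cell {series.cell_id}: non-positive QC baseline")
    normalized = series.cyto_mean / baseline
    smoothed = boxcar_smooth(normalized, window)
    verdict = bool(smoothed.min() >= 1.0 - max_decrease)
    series.qc_pass = verdict
    return verdict


def quantify_still(
    images: Mapping[str, Sequence[np.ndarray]],
    rois: Mapping[str, Sequence[Sequence[CellROI]]],
    modality: str = "IF",
    experiment: str = "exp1",
    detection: Optional[DetectionParams] = None,
) -> list[CellIntensityRecord]:
    """Per-cell mean intensity (and optional puncta count) for still images.

    ``images[condition]`` is a list of fields and ``rois[condition]`` the
    matching per-field ROI lists.  When ``detection`` is given, puncta are
    detected per field and counted per cell.
    """
    records: list[CellIntensityRecord] = []
    for condition, imgs in images.items():
        if condition not in rois:
            raise CellQuantError(f"no ROIs for condition {condition!r}")
        field_rois = rois[condition]
        if len(field_rois) != len(imgs):
            raise CellQuantError(
                f"condition {condition!r}: {len(imgs)} images but "
                f"{len(field_rois)} ROI sets"
            )
        for img, roi_list in zip(imgs, field_rois):
            img = np.asarray(img, dtype=float)
            spots = None
            if detection is not None:
                spots = detect_spots(img, t=0.0, params=detection)
            for roi in roi_list:
                if roi.mask.shape != img.shape:
                    raise CellQuantError(
                        f"cell {roi.cell_id}: mask shape {roi.mask.shape} != "
                        f"image shape {img.shape}"
                    )
                rec = CellIntensityRecord(
                    cell_id=roi.cell_id,
                    condition=condition,
                    experiment=experiment,
                    modality=modality,
                    mean_intensity=float(img[roi.mask].mean()),
                )
                if spots is not None:
                    rec.puncta_count = count_puncta_in_cell(spots, roi)
                records.append(rec)
    return records


def normalize_by_max_condition(
    records: Sequence[CellIntensityRecord],
) -> list[CellIntensityRecord]:
    """Normalize each cell's intensity by the largest per-condition mean.

    Normalization is performed separately within each (experiment, modality)
    group, so IF and PLA intensities are each scaled against their own
    maximum condition.  Condition means are bounded by 1 after scaling;
    individual cells in the max condition may exceed 1.
    """
    if not records:
        raise CellQuantError("no records to normalize")
    groups: dict[tuple[str, str], list[CellIntensityRecord]] = {}
    for r in records:
        groups.setdefault((r.experiment, r.modality), []).append(r)
    for (experiment, modality), recs in groups.items():
        cond_values: dict[str, list[float]] = {}
        for r in recs:
            cond_values.setdefault(r.condition, []).append(r.mean_intensity)
        max_mean = max(float(np.mean(v)) for v in cond_values.values())
        if max_mean <= 0:
            raise CellQuantError(
                f"({experiment}, {modality}): max condition mean <= 0"
            )
        for r in recs:
            r.normalized_intensity = r.mean_intensity / max_mean
    return list(records)
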