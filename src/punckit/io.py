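"""File formats: multi-page TIFF movies with JSON timestamp sidecars,
label-image ROI masks, spot tables (native and TrackMate-compatible), and
CSV serialization of the analysis products.

Timestamps live in a JSON sidecar next to the TIFF rather than in TIFF
tags: every TIFF writer round-trips it, and it mirrors workflows where
per-frame acquisition times come from microscope metadata exported
separately from the pixel data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .cells import CellIntensityRecord, CellROI, CellTimeSeries
from .detection import SpotRecord
from .kinetics import BinnedCurve, ReplicateSummary

PathLike = Union[str, Path]


class MovieIOError(ValueError):
    """Raised for malformed movie bundles or spot tables."""


SPOT_COLUMNS = [
    "frame",
    "t_s",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "quality",
    "contrast",
    "total_intensity",
    "radius_um",
    "cell_id",
]

_TRACKMATE_REQUIRED = ["POSITION_X", "POSITION_Y", "POSITION_T", "FRAME", "QUALITY"]


@dataclass
class MovieStack:
    """A time-ordered stack of 2-D intensity frames with irregular
    per-frame timestamps and a physical pixel size."""

    frames: np.ndarray  # (T, H, W)
    timestamps: np.ndarray  # (T,) seconds
    pixel_size: float  # um / px
    drug_time: float = 60.0
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise MovieIOError("frames must be a (T, H, W) array")
        if self.frames.shape[0] != self.timestamps.size:
            raise MovieIOError(
                f"{self.frames.shape[0]} frames but {self.timestamps.size} timestamps"
            )
        if self.pixel_size <= 0:
            raise MovieIOError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MovieBundle:
    """Paths making up one stored movie: TIFF stack, JSON sidecar, and
    optional ROI label images."""

    tiff_path: Path
    sidecar_path: Path
    roi_path: Optional[Path] = None
    nucleus_roi_path: Optional[Path] = None


def sidecar_path_for(tiff_path: PathLike) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_movie(movie: MovieStack, tiff_path: PathLike) -> MovieBundle:
    """Write a movie as multi-page float32 TIFF plus a JSON sidecar holding
    timestamps, pixel size, drug time, condition, and replicate id."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        tiff_path, movie.frames.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "timestamps_s": [float(t) for t in movie.timestamps],
        "pixel_size_um": float(movie.pixel_size),
        "drug_time_s": float(movie.drug_time),
        "condition": movie.condition,
        "replicate": str(movie.replicate),
    }
    scpath = sidecar_path_for(tiff_path)
    scpath.write_text(json.dumps(sidecar, indent=1))
    return MovieBundle(tiff_path=tiff_path, sidecar_path=scpath)


def read_movie(bundle: Union[MovieBundle, PathLike]) -> MovieStack:
    """Read a movie bundle back into a :class:`MovieStack`.

    Accepts either a :class:`MovieBundle` or a TIFF path (the sidecar is
    then found by swapping the extension for ``.json``).
    """
    if not isinstance(bundle, MovieBundle):
        bundle = MovieBundle(
            tiff_path=Path(bundle), sidecar_path=sidecar_path_for(bundle)
        )
    if not bundle.tiff_path.exists():
        raise MovieIOError(f"missing TIFF: {bundle.tiff_path}")
    if not bundle.sidecar_path.exists():
        raise MovieIOError(f"missing sidecar: {bundle.sidecar_path}")
    frames = tifffile.imread(bundle.tiff_path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    meta = json.loads(bundle.sidecar_path.read_text())
    timestamps = meta.get("timestamps_s")
    if timestamps is None:
        raise MovieIOError(f"sidecar {bundle.sidecar_path} lacks 'timestamps_s'")
    if len(timestamps) != frames.shape[0]:
        raise MovieIOError(
            f"sidecar has {len(timestamps)} timestamps for {frames.shape[0]} frames"
        )
    if "pixel_size_um" not in meta:
        raise MovieIOError(
            "sidecar lacks 'pixel_size_um'; spot detection needs it to convert "
            "the blob diameter from um to px"
        )
    return MovieStack(
        frames=frames,
        timestamps=np.asarray(timestamps, dtype=float),
        pixel_size=float(meta["pixel_size_um"]),
        drug_time=float(meta.get("drug_time_s", 60.0)),
        condition=str(meta.get("condition", "")),
        replicate=str(meta.get("replicate", "")),
    )


def rois_to_labels(rois: Sequence[CellROI]) -> tuple[np.ndarray, np.ndarray]:
    """Render ROIs as (cell label image, nucleus label image); labels are
    cell ids, 0 is background."""
    shape = rois[0].mask.shape
    cells = np.zeros(shape, dtype=np.uint16)
    nuclei = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        cells[roi.mask] = roi.cell_id
        if roi.nucleus_mask is not None:
            nuclei[roi.nucleus_mask] = roi.cell_id
    return cells, nuclei


def labels_to_rois(
    cell_labels: np.ndarray,
    nucleus_labels: Optional[np.ndarray] = None,
    condition: str = "",
    replicate: str = "",
) -> list[CellROI]:
    rois = []
    for cid in np.unique(cell_labels):
        if cid == 0:
            continue
        nuc = None
        if nucleus_labels is not None:
            nuc = nucleus_labels == cid
            if not nuc.any():
                nuc = None
        rois.append(
            CellROI(
                cell_id=int(cid),
                mask=cell_labels == cid,
                nucleus_mask=nuc,
                condition=condition,
                replicate=replicate,
            )
        )
    return rois


def write_rois(rois: Sequence[CellROI], path: PathLike) -> tuple[Path, Path]:
    """Write cell and nucleus label images as TIFF; the nucleus image goes
    next to ``path`` with a ``.nuclei`` infix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells, nuclei = rois_to_labels(rois)
    nucleus_path = path.with_suffix(".nuclei" + path.suffix)
    tifffile.imwrite(path, cells)
    tifffile.imwrite(nucleus_path, nuclei)
    return path, nucleus_path


def read_rois(
    path: PathLike, condition: str = "", replicate: str = ""
) -> list[CellROI]:
    path = Path(path)
    cells = tifffile.imread(path)
    nucleus_path = path.with_suffix(".nuclei" + path.suffix)
    nuclei = tifffile.imread(nucleus_path) if nucleus_path.exists() else None
    return labels_to_rois(cells, nuclei, condition=condition, replicate=replicate)


def spots_to_frame(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    rows = [
        {
            "frame": s.frame,
            "t_s": s.t_s,
            "x_px": s.x_px,
            "y_px": s.y_px,
            "x_um": s.x_um,
            "y_um": s.y_um,
            "quality": s.quality,
            "contrast": s.contrast,
            "total_intensity": s.total_intensity,
            "radius_um": s.radius_um,
            "cell_id": s.cell_id,
        }
        for s in spots
    ]
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def write_spots_csv(spots: Sequence[SpotRecord], path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spots_to_frame(spots).to_csv(path, index=False)
    return path


def read_trackmate_spots(
    path: PathLike, pixel_size: Optional[float] = None
) -> list[SpotRecord]:
    """Read a TrackMate spot-statistics CSV export.

    Supports both the single-header dialect and the newer export with three
    extra descriptive header rows (full names / short names / units), which
    are recognized by their non-numeric FRAME entries and skipped.
    TrackMate positions are in physical units (um); pixel coordinates are
    derived when ``pixel_size`` is given, otherwise set equal to the um
    values.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _TRACKMATE_REQUIRED if c not in df.columns]
    if missing:
        raise MovieIOError(
            "TrackMate CSV is missing required columns: " + ", ".join(missing)
        )
    numeric_cols = list(_TRACKMATE_REQUIRED)
    for opt in ("CONTRAST", "TOTAL_INTENSITY"):
        if opt in df.columns:
            numeric_cols.append(opt)
    num = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    num = num[num["FRAME"].notna()]  # drops the extra header rows
    records = []
    for _, row in num.iterrows():
        x_um, y_um = float(row["POSITION_X"]), float(row["POSITION_Y"])
        scale = pixel_size if pixel_size else 1.0
        records.append(
            SpotRecord(
                frame=int(row["FRAME"]),
                t_s=float(row["POSITION_T"]),
                x_px=x_um / scale,
                y_px=y_um / scale,
                x_um=x_um,
                y_um=y_um,
                quality=float(row["QUALITY"]),
                contrast=float(row["CONTRAST"]) if "CONTRAST" in num else float("nan"),
                total_intensity=(
                    float(row["TOTAL_INTENSITY"])
                    if "TOTAL_INTENSITY" in num
                    else float("nan")
                ),
                radius_um=float("nan"),
            )
        )
    return records


def series_to_frame(series_list: Sequence[CellTimeSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for i in range(len(s.timestamps)):
            rows.append(
                {
                    "cell_id": s.cell_id,
                    "condition": s.condition,
                    "replicate": s.replicate,
                    "frame": i,
                    "t_s": s.timestamps[i],
                    "puncta_count": int(s.counts[i]),
                    "cyto_mean": s.cyto_mean[i],
                    "qc_pass": s.qc_pass,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "condition",
            "replicate",
            "frame",
            "t_s",
            "puncta_count",
            "cyto_mean",
            "qc_pass",
        ],
    )


def summaries_to_frame(summaries: Sequence[ReplicateSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for frac, est in sorted(s.estimates.items(), reverse=True):
            rows.append(
                {
                    "replicate": s.replicate,
                    "condition": s.condition,
                    "fraction": frac,
                    "time_s": est.time if est.time is not None else np.nan,
                    "method": est.method,
                    "n_frames_in_band": est.n_frames_in_band,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["replicate", "condition", "fraction", "time_s", "method", "n_frames_in_band"],
    )


def binned_to_frame(curve: BinnedCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_center_s": curve.bin_centers,
            "mean": curve.mean,
            "sd": curve.sd,
            "n": curve.n,
            "condition": curve.condition,
        }
    )


def intensity_records_to_frame(records: Sequence[CellIntensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "experiment": r.experiment,
                "modality": r.modality,
                "mean_intensity": r.mean_intensity,
                "normalized_intensity": r.normalized_intensity,
                "puncta_count": r.puncta_count,
            }
            for r in records
        ],
        columns=[
            "cell_id",
            "condition",
            "experiment",
            "modality",
            "mean_intensity",
            "normalized_intensity",
            "puncta_count",
        ],
    )
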