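"""Synthetic SunTag-like time-lapse movies and IF/PLA-like still images.

The generator emulates the statistical structure of live-cell puncta-release
trials: ~8 min movies sampled at irregular intervals (truncated-normal
intervals with mean 5.4 s, sd 1.9 s, clipped to [2.5, 9.8] s), a field of
7-12 elliptical cells each carrying ~30 diffraction-limited puncta over a
diffuse cytoplasmic reporter background, drug addition at 60 s, and
condition-dependent puncta-disappearance kinetics:

``vehicle``      no disappearances (untreated control);
``instant``      all puncta vanish at drug addition (limit case);
``exponential``  per-punctum release at rate ``k_rel`` from drug addition
                 (emetine-like: no lag, single rate-limiting step);
``two_stage``    an exponential binding delay (rate ``k_bind``) followed by
                 release (rate ``k_rel``), i.e. a hypoexponential with a lag
                 phase (cycloheximide-like: drug access to the A site is
                 rate-limiting).

Fluorescence is conserved on release: a released punctum's integrated flux
is redistributed into its cell's diffuse cytoplasmic level, so the cell's
mean reporter intensity is unchanged by release (as in the real system,
where released nascent chains keep their bound fluorophores and diffuse
into the cytoplasm).  Mild exponential photobleaching and Poisson +
Gaussian read noise are applied on top.  Nuclei are rendered as
punctum-free elliptical regions so nuclear-suppression filtering can be
exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .cells import CellROI
from .io import MovieStack

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


class SimulationError(ValueError):
    """Raised for invalid generator parameters or infeasible geometry."""


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ReleaseKineticsParams:
    """Per-punctum disappearance kinetics.

    ``k_rel`` is the release rate (s^-1); ``k_bind`` the drug-binding rate
    (s^-1, two_stage only); ``drug_time`` seconds from trial start.  With
    ``chains_per_punctum > 1`` each punctum carries several nascent chains
    released independently, the punctum dims gradually, and it stops being
    rendered once its surviving-intensity fraction falls below
    ``detect_fraction``.
    """

    mode: str = "vehicle"  # vehicle | instant | exponential | two_stage
    k_rel: Optional[float] = None
    k_bind: Optional[float] = None
    drug_time: float = 60.0
    chains_per_punctum: int = 1
    detect_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("vehicle", "instant", "exponential", "two_stage"):
            raise SimulationError(f"unknown kinetics mode {self.mode!r}")
        if self.mode in ("exponential", "two_stage"):
            if self.k_rel is None or self.k_rel <= 0:
                raise SimulationError(f"mode {self.mode!r} requires k_rel > 0")
        if self.mode == "two_stage":
            if self.k_bind is None or self.k_bind <= 0:
                raise SimulationError("two_stage mode requires k_bind > 0")
        if self.drug_time < 0:
            raise SimulationError("drug_time must be >= 0")
        if self.chains_per_punctum < 1:
            raise SimulationError("chains_per_punctum must be >= 1")
        if not 0 < self.detect_fraction <= 1:
            raise SimulationError("detect_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging-trial geometry, optics, and noise.

    Defaults reproduce the study conditions: 480 s trials, frame intervals
    5.4 +/- 1.9 s clipped to [2.5, 9.8] s, 256x256 px fields at 0.16 um/px,
    PSF sigma 0.17 um, 8 cells of ~30 puncta each, 16-bit-like intensity
    scale, and a bleach rate giving < 5% signal loss over the trial.
    """

    trial_duration: float = 480.0
    interval_mean: float = 5.4
    interval_sd: float = 1.9
    interval_min: float = 2.5
    interval_max: float = 9.8
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.16  # um / px
    psf_sigma: float = 0.17  # um
    cells_per_field: int = 8
    puncta_per_cell: int = 30
    background_level: float = 200.0
    cell_fill: float = 600.0
    nucleus_fill: float = 400.0
    spot_amplitude: float = 3000.0
    bleach_rate: float = 1e-4  # s^-1; e^(-rate*480) ~ 0.953
    poisson_gain: Optional[float] = 1.0  # None disables shot noise
    read_noise_sd: float = 10.0
    min_separation_px: float = 5.0
    edge_softness_px: float = 2.0

    def __post_init__(self) -> None:
        if not (self.interval_min <= self.interval_mean <= self.interval_max):
            raise SimulationError("need interval_min <= interval_mean <= interval_max")
        for name in (
            "trial_duration",
            "interval_sd",
            "pixel_size",
            "psf_sigma",
            "background_level",
            "cell_fill",
            "spot_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        if self.bleach_rate < 0 or self.read_noise_sd < 0:
            raise SimulationError("bleach_rate and read_noise_sd must be >= 0")
        if self.cells_per_field < 1 or self.puncta_per_cell < 0:
            raise SimulationError("cells_per_field >= 1, puncta_per_cell >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size


@dataclass(frozen=True)
class StillCondition:
    label: str
    puncta_per_cell: float
    cell_intensity: float


@dataclass(frozen=True)
class StillImageParams:
    """Still-image (IF / PLA) experiment layout.

    Defaults mirror the observed contrast between specific and control
    labeling: ~200 puncta per cell in the positive condition versus ~4 in
    antibody-omission controls, with correspondingly scaled diffuse cell
    intensities.
    """

    conditions: tuple[StillCondition, ...] = (
        StillCondition("puromycin", 200.0, 900.0),
        StillCondition("control", 4.0, 350.0),
    )
    cells_per_condition: int = 32
    raster: AcquisitionParams = field(default_factory=AcquisitionParams)
    spot_amplitude: float = 2000.0
    min_separation_px: float = 2.0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise SimulationError("need at least one condition")
        for c in self.conditions:
            if c.puncta_per_cell < 0:
                raise SimulationError(f"{c.label}: puncta_per_cell must be >= 0")
            if c.cell_intensity <= 0:
                raise SimulationError(f"{c.label}: cell_intensity must be > 0")
        if self.cells_per_condition < 1:
            raise SimulationError("cells_per_condition must be >= 1")


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests.

    ``puncta`` — one row per punctum: cell_id, x_px, y_px, release_time_s
    (inf when never released); ``counts`` — per frame x cell true visible
    count; ``cyto`` — per frame x cell true (noise-free) mean cytoplasmic
    level.
    """

    puncta: pd.DataFrame
    counts: pd.DataFrame
    cyto: pd.DataFrame


def sample_release_times(
    kin: ReleaseKineticsParams, n: int, seed: RngLike
) -> np.ndarray:
    """Per-punctum disappearance times (s from trial start).

    vehicle -> all inf; instant -> all at drug_time; exponential ->
    drug_time + Exp(k_rel); two_stage -> drug_time + Exp(k_bind) + Exp(k_rel).
    """
    if n < 0:
        raise SimulationError("n must be >= 0")
    rng = _as_rng(seed)
    if kin.mode == "vehicle":
        return np.full(n, np.inf)
    if kin.mode == "instant":
        return np.full(n, float(kin.drug_time))
    if kin.mode == "exponential":
        return kin.drug_time + rng.exponential(1.0 / kin.k_rel, size=n)
    # two_stage
    return (
        kin.drug_time
        + rng.exponential(1.0 / kin.k_bind, size=n)
        + rng.exponential(1.0 / kin.k_rel, size=n)
    )


def sample_timestamps(acq: AcquisitionParams, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing frame times on [0, trial_duration]: intervals are
    normal(mean, sd) resampled until inside [interval_min, interval_max]."""
    times = [0.0]
    while True:
        while True:
            dt = rng.normal(acq.interval_mean, acq.interval_sd)
            if acq.interval_min <= dt <= acq.interval_max:
                break
        t = times[-1] + dt
        if t > acq.trial_duration:
            break
        times.append(t)
    return np.asarray(times)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _make_cell_rois(
    acq: AcquisitionParams, rng: np.random.Generator, condition: str, replicate: str
) -> list[CellROI]:
    """Jittered-grid layout of elliptical cells with elliptical nuclei."""
    n = acq.cells_per_field
    h, w = acq.image_shape
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    pitch_r, pitch_c = h / nrows, w / ncols
    slots = [(i, j) for i in range(nrows) for j in range(ncols)]
    rng.shuffle(slots)
    rois: list[CellROI] = []
    for cid, (i, j) in enumerate(slots[:n], start=1):
        cr = (i + 0.5) * pitch_r + rng.uniform(-3, 3)
        cc = (j + 0.5) * pitch_c + rng.uniform(-3, 3)
        max_ax = 0.45 * min(pitch_r, pitch_c)
        a = rng.uniform(0.75, 1.0) * max_ax
        b = rng.uniform(0.75, 1.0) * max_ax
        angle = rng.uniform(0, math.pi)
        mask = _ellipse_mask((h, w), (cr, cc), (a, b), angle)
        nucleus = _ellipse_mask((h, w), (cr, cc), (0.4 * a, 0.4 * b), angle)
        rois.append(
            CellROI(
                cell_id=cid,
                mask=mask,
                nucleus_mask=nucleus & mask,
                condition=condition,
                replicate=replicate,
            )
        )
    return rois


def _place_puncta(
    roi: CellROI,
    n: int,
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform punctum positions in the cytoplasm (cell minus nucleus) with
    a minimum pairwise separation; bounded rejection sampling."""
    cyto = roi.cytoplasm_mask
    rows, cols = np.nonzero(cyto)
    if rows.size == 0:
        raise SimulationError(f"cell {roi.cell_id}: no cytoplasm pixels")
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            k = rng.integers(rows.size)
            r = rows[k] + rng.uniform(-0.5, 0.5)
            c = cols[k] + rng.uniform(-0.5, 0.5)
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= min_separation**2
                for pr, pc in placed
            ):
                placed.append((r, c))
                break
        else:
            raise SimulationError(
                f"cell {roi.cell_id}: could not place punctum after {max_tries} tries"
            )
    return np.asarray(placed).reshape(n, 2)


def _add_gaussian_spot(
    image: np.ndarray, row: float, col: float, amplitude: float, sigma_px: float
) -> None:
    """Accumulate a 2-D Gaussian into ``image`` over a +/- 4 sigma patch."""
    h, w = image.shape
    rad = int(math.ceil(4 * sigma_px))
    r0, r1 = max(int(row) - rad, 0), min(int(row) + rad + 1, h)
    c0, c1 = max(int(col) - rad, 0), min(int(col) + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma_px**2)
    )


def _apply_noise(
    clean: np.ndarray, acq: AcquisitionParams, rng: np.random.Generator
) -> np.ndarray:
    out = clean
    if acq.poisson_gain is not None and acq.poisson_gain > 0:
        out = rng.poisson(np.maximum(out, 0.0) / acq.poisson_gain) * acq.poisson_gain
    if acq.read_noise_sd > 0:
        out = out + rng.normal(0.0, acq.read_noise_sd, size=clean.shape)
    return out.astype(np.float32)


def simulate_movie(
    kin: ReleaseKineticsParams,
    acq: AcquisitionParams,
    seed: RngLike,
    condition: str = "",
    replicate: str = "",
) -> tuple[MovieStack, list[CellROI], GroundTruth]:
    """Render one imaging trial and its ground truth.

    Frames are background + per-cell diffuse cytoplasm (soft-edged so mask
    boundaries do not masquerade as blobs) + Gaussian-PSF puncta visible
    while their release time has not passed, with released flux returned to
    the cell's diffuse pool, global exponential photobleaching, and Poisson
    then Gaussian noise.
    """
    rng = _as_rng(seed)
    condition = condition or kin.mode
    timestamps = sample_timestamps(acq, rng)
    rois = _make_cell_rois(acq, rng, condition, replicate)
    h, w = acq.image_shape
    sigma_px = acq.psf_sigma_px

    # static per-cell structures; released flux goes back into the soft
    # cytoplasm footprint (released chain complexes stay nucleus-excluded),
    # so the cytoplasmic mean is conserved under release
    soft = {}
    soft_nuc = {}
    soft_cyto = {}
    cyto_areas = {}
    for roi in rois:
        soft[roi.cell_id] = ndimage.gaussian_filter(
            roi.mask.astype(float), acq.edge_softness_px
        )
        soft_nuc[roi.cell_id] = ndimage.gaussian_filter(
            roi.nucleus_mask.astype(float), acq.edge_softness_px
        )
        sc = np.clip(soft[roi.cell_id] - soft_nuc[roi.cell_id], 0.0, None)
        # normalize so the mean over the measured cytoplasm mask is 1:
        # redistributed flux then raises that mean by exactly flux/area
        sc /= sc[roi.cytoplasm_mask].mean()
        soft_cyto[roi.cell_id] = sc
        cyto_areas[roi.cell_id] = float(roi.cytoplasm_mask.sum())

    base = np.full((h, w), float(acq.background_level))
    for roi in rois:
        base += acq.cell_fill * soft[roi.cell_id]
        base += (acq.nucleus_fill - acq.cell_fill) * soft_nuc[roi.cell_id]

    # puncta: positions + release schedule
    puncta_rows = []
    chain_release: list[np.ndarray] = []  # per punctum, sorted chain release times
    inmask_flux: list[float] = []  # rendered flux inside the cytoplasm mask
    for roi in rois:
        pos = _place_puncta(roi, acq.puncta_per_cell, acq.min_separation_px, rng)
        rel = sample_release_times(kin, acq.puncta_per_cell * kin.chains_per_punctum, rng)
        rel = rel.reshape(acq.puncta_per_cell, kin.chains_per_punctum)
        for i in range(acq.puncta_per_cell):
            chains = np.sort(rel[i])
            chain_release.append(chains)
            probe = np.zeros((h, w))
            _add_gaussian_spot(probe, pos[i, 0], pos[i, 1], acq.spot_amplitude, sigma_px)
            inmask_flux.append(float(probe[roi.cytoplasm_mask].sum()))
            # punctum disappearance time: when surviving fraction drops
            # below detect_fraction (for a single chain: its release time)
            n_allowed = int(math.floor((1.0 - kin.detect_fraction) * len(chains)))
            if kin.chains_per_punctum == 1:
                vanish = chains[0]
            else:
                vanish = chains[n_allowed] if n_allowed < len(chains) else np.inf
            puncta_rows.append(
                {
                    "cell_id": roi.cell_id,
                    "y_px": pos[i, 0],
                    "x_px": pos[i, 1],
                    "release_time_s": float(vanish),
                }
            )
    puncta_df = pd.DataFrame(
        puncta_rows, columns=["cell_id", "y_px", "x_px", "release_time_s"]
    )

    frames = np.empty((len(timestamps), h, w), dtype=np.float32)
    count_rows = []
    cyto_rows = []
    for fi, t in enumerate(timestamps):
        clean = base.copy()
        counts = {roi.cell_id: 0 for roi in rois}
        released_flux = {roi.cell_id: 0.0 for roi in rois}
        for p_idx, prow in enumerate(puncta_rows):
            chains = chain_release[p_idx]
            surviving = float(np.count_nonzero(chains > t)) / len(chains)
            cid = prow["cell_id"]
            if t < prow["release_time_s"]:
                counts[cid] += 1
                _add_gaussian_spot(
                    clean,
                    prow["y_px"],
                    prow["x_px"],
                    acq.spot_amplitude * surviving,
                    sigma_px,
                )
                released_flux[cid] += inmask_flux[p_idx] * (1.0 - surviving)
            else:
                released_flux[cid] += inmask_flux[p_idx]
        for roi in rois:
            cid = roi.cell_id
            if released_flux[cid] > 0:
                clean += (released_flux[cid] / cyto_areas[cid]) * soft_cyto[cid]
        clean *= math.exp(-acq.bleach_rate * t)
        frames[fi] = _apply_noise(clean, acq, rng)
        for roi in rois:
            count_rows.append(
                {"frame": fi, "t_s": t, "cell_id": roi.cell_id, "true_count": counts[roi.cell_id]}
            )
            cyto = roi.cytoplasm_mask
            cyto_rows.append(
                {
                    "frame": fi,
                    "t_s": t,
                    "cell_id": roi.cell_id,
                    "true_cyto_mean": float(clean[cyto].mean()),
                }
            )

    movie = MovieStack(
        frames=frames,
        timestamps=timestamps,
        pixel_size=acq.pixel_size,
        drug_time=kin.drug_time,
        condition=condition,
        replicate=str(replicate),
    )
    truth = GroundTruth(
        puncta=puncta_df,
        counts=pd.DataFrame(count_rows, columns=["frame", "t_s", "cell_id", "true_count"]),
        cyto=pd.DataFrame(cyto_rows, columns=["frame", "t_s", "cell_id", "true_cyto_mean"]),
    )
    return movie, rois, truth


def simulate_still_experiment(
    params: StillImageParams, seed: RngLike
) -> tuple[dict[str, list[np.ndarray]], dict[str, list[list[CellROI]]], pd.DataFrame]:
    """Render still-image fields per condition.

    Per condition, cells carry Poisson-distributed puncta counts around the
    condition mean on a diffuse fill at the condition's mean intensity.
    Returns (images per condition, ROIs per condition per field, ground
    truth with per-cell true counts and noise-free mean intensities).
    """
    rng = _as_rng(seed)
    acq = params.raster
    sigma_px = acq.psf_sigma_px
    images: dict[str, list[np.ndarray]] = {}
    rois_out: dict[str, list[list[CellROI]]] = {}
    truth_rows = []
    next_cell_id = 1
    for cond in params.conditions:
        images[cond.label] = []
        rois_out[cond.label] = []
        remaining = params.cells_per_condition
        field_idx = 0
        while remaining > 0:
            n_cells = min(acq.cells_per_field, remaining)
            remaining -= n_cells
            facq = replace(acq, cells_per_field=n_cells)
            rois = _make_cell_rois(facq, rng, cond.label, str(field_idx))
            # re-number globally unique ids within the condition
            for roi in rois:
                roi.cell_id = next_cell_id
                next_cell_id += 1
            clean = np.full(acq.image_shape, float(acq.background_level))
            for roi in rois:
                softm = ndimage.gaussian_filter(
                    roi.mask.astype(float), acq.edge_softness_px
                )
                clean += cond.cell_intensity * softm
            for roi in rois:
                n_puncta = int(rng.poisson(cond.puncta_per_cell))
                pos = _place_puncta(roi, n_puncta, params.min_separation_px, rng)
                for i in range(n_puncta):
                    _add_gaussian_spot(
                        clean, pos[i, 0], pos[i, 1], params.spot_amplitude, sigma_px
                    )
                truth_rows.append(
                    {
                        "cell_id": roi.cell_id,
                        "condition": cond.label,
                        "field": field_idx,
                        "true_count": n_puncta,
                        "true_mean_intensity": float(clean[roi.mask].mean()),
                    }
                )
            images[cond.label].append(_apply_noise(clean, acq, rng))
            rois_out[cond.label].append(rois)
            field_idx += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_id", "condition", "field", "true_count", "true_mean_intensity"],
    )
    return images, rois_out, truth
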