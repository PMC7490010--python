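# Methods

This note records the models, parameter choices, and numerical conventions
behind `punckit`, and what the synthetic-data tests do and do not establish
about real data.

## Release kinetics model

Puncta disappearance is modeled **per punctum**: a punctum is rendered until
its release time and then vanishes, with its fluorescence returned to the
cell's diffuse cytoplasmic pool. The analysis readout is a count, not an
intensity, and whole-punctum loss is the minimal model that reproduces
count decay. (An optional graded mode, `chains_per_punctum > 1`, releases
chains independently, dims the punctum in proportion to survivors, and
stops rendering it when the surviving-intensity fraction falls below
`detect_fraction`, default 0.5.)

Release times are drawn from one of four regimes, all relative to drug
addition at `drug_time` (default 60 s):

| mode | release time τ | emulates |
|---|---|---|
| `vehicle` | ∞ | untreated control |
| `instant` | drug_time | limit case for tests |
| `exponential` | drug_time + Exp(k_rel) | emetine-like: no lag, one rate-limiting step |
| `two_stage` | drug_time + Exp(k_bind) + Exp(k_rel) | cycloheximide-like lag |

The two-stage (hypoexponential) form encodes the mechanistic reading that a
cycloheximide-stalled ribosome slows the drug's *access/binding* step rather
than the release step itself: survival is quadratic at early times (a lag
phase), unlike the memoryless exponential. With k_bind ≫ k_rel the two-stage
law converges to the exponential one (property-tested via
Kolmogorov–Smirnov distance).

Reference regimes used by the reproduction script and acceptance tests:

* emetine-like: `exponential`, k_rel = 0.021 s⁻¹ (analytic half-life
  ln 2 / k ≈ 33 s);
* cycloheximide-like: `two_stage`, mean binding delay 215 s
  (k_bind = 1/215 s⁻¹) with fast release k_rel = 0.2 s⁻¹, putting the
  half-life ≈ 2 min later than the emetine regime.

## Synthetic movies

Acquisition defaults are the study conditions: 480 s trials; frame
intervals drawn from a normal(5.4 s, 1.9 s) truncated by resampling to
[2.5, 9.8] s; 256×256 px fields at 0.16 µm/px (16 µm camera pixels at
100×; configurable); PSF σ = 0.17 µm; 8 cells per field with 30 puncta
each.

Cells are jitter-gridded ellipses; each contains a punctum-free elliptical
nucleus (0.4× the cell axes) so nuclear-suppression filtering is
exercisable. Puncta are placed uniformly in the cytoplasm with a 5 px
minimum separation (bounded rejection sampling) so that ground-truth counts
are unambiguous for the detector at the default blob scale.

Rendering per frame: background (200) + soft-edged diffuse cell fill (600;
nucleus 400) + Gaussian puncta (amplitude 3000 on a 16-bit-like scale),
multiplied by exp(−βt) photobleaching (β = 10⁻⁴ s⁻¹, ≈ 4.7% loss per
trial — "mild", comfortably inside the 10% QC bound), then Poisson shot
noise and Gaussian read noise (sd 10). Cell edges are softened (σ = 2 px)
because a hard intensity step at a mask boundary has a band-pass (LoG)
response that could masquerade as spots.

**Fluorescence conservation.** When a punctum releases, exactly the flux it
contributed inside the cytoplasm mask is redistributed over the cell's soft
cytoplasm footprint. This mirrors the physical situation — released
chains keep their fluorophores and diffuse within the cell — and is the
reason the 10% cytoplasmic-intensity QC does not discard drug-treated
cells: their mean intensity is invariant to release (machine-precision
exact in the noise-free generator) and declines only through bleaching.

The paper's hardware scale (camera gain, absolute spot amplitudes,
bleaching magnitude) is not recoverable from the text, so those defaults
are calibrated only to two constraints: control cells lose <10% cytoplasmic
signal, and default-amplitude puncta sit far above the quality threshold
(peak response ≈ amplitude/2 ≈ 1500 vs threshold 300).

**What the generator does not emulate:** cell movement and focal drift,
spatially varying background, punctum diffusion/motility between frames,
3-D defocus, camera fixed-pattern noise, and segmentation error (masks are
exact). Pipeline recovery results on synthetic data therefore validate the
*estimator chain*, not robustness to those real-data effects.

## Spot detection

Single-scale LoG detection at σ = (d/2)/√2 with d = 0.5 µm, the standard
2-D relation between blob diameter and the scale-normalized optimum.
Numerical conventions:

* the kernel is the analytic −σ²∇²G sampled to 4σ and corrected to zero
  sum, so a constant image gives an exactly zero response despite
  truncation;
* convolution uses reflective padding; maxima within ⌈σ⌉ of the border are
  discarded;
* maxima closer than one blob diameter keep only the highest quality, ties
  broken toward the smaller (row, col) index;
* localization is integer-pixel — counts, not positions, are the readout;
* *quality* is the peak response on the raw intensity scale. The default
  threshold 300 matches the workflow this pipeline reproduces, but its
  absolute calibration is scale-dependent and configurable.

Contrast is (mean(disc) − mean(annulus)) / (mean(disc) + mean(annulus))
with an annulus of width equal to the disc radius; total intensity is the
raw disc sum. Discs clipped by the image border are flagged.

## Per-cell quantification and QC

"Cytoplasmic" intensity is the mean over the cell mask minus the nucleus
mask when one is provided, else the whole mask (the measured region is not
further specified in the source workflow; this is our definition). A spot
belongs to a cell if its rounded center pixel is in that region.

QC: the cytoplasmic trace is normalized to the mean of its first 10 frames
and smoothed with a 10-observation rolling mean before applying the 10%
cutoff. Whether the original rule compared endpoint or any frame to
baseline is unstated; thresholding the smoothed minimum is our declared
choice — it discards genuine bleaching/drift while a single-frame focus
glitch (which moves a 10-frame mean by only a tenth of its depth) does not
condemn a cell.

Still-image mode: per-cell mean intensity, normalized by the **largest
per-condition mean** within each (experiment, modality) group, separately
for IF and PLA. Condition means are thereby bounded by 1; individual cells
in the maximal condition can exceed 1. Generator defaults put ~200
puncta/cell in the positive condition and ~4 (enforced < 8) in controls.

## Decay-time extraction

Counts are normalized per cell to the mean over frames with t strictly
< 60 s (a frame stamped exactly at 60 s is treated as post-baseline).
Replicate-mean trajectories are built by nearest-frame alignment onto the
union time grid (fields are imaged asynchronously in general), then
smoothed with a boxcar of k = 10 observations.

Boxcar conventions: centered window, truncated (not padded) at the
boundaries, output length preserved. For even k the filter uses k+1 taps
with half weight at both ends — the textbook symmetric centering — because
putting the extra observation on one side shifts every crossing time by
half a frame interval (~2.7 s here, a 7% bias on a 37 s half-life).

The band rule collects all frames at t ≥ drug_time with smoothed value
within ±0.01 of the target fraction and averages their timestamps;
restricting to post-drug frames keeps pre-drug noise near a fraction from
contaminating the average, and non-contiguous band frames are all included
(no contiguity requirement). At ~5 s sampling a steep decay can skip the
±0.01 band entirely, so an empty band falls back to linear interpolation
between the bracketing frames, flagged `interpolated` in the output.
A trajectory that never descends to the fraction reports `not_reached` —
a result, not an error (it is the expected vehicle outcome).

Smoothing flattens an exponential by the factor sinh(λw)/(λw) (w = half
window in seconds), which moves the apparent half-life from ln 2/λ to
ln(2·sinh(λw)/(λw))/λ — about +2 s at λ = 0.021 s⁻¹, k = 10, 5-s frames.
The analytic-consistency test holds the estimator to this closed form
within 10% on noiseless input.

Binned summary curves pool observations across cells into half-open
[i·5 s, (i+1)·5 s) bins (an edge value joins the right bin) with sample
sd (ddof = 1; 0 reported for singleton bins).

## Statistics

* **Welch's t**: t = (ā−b̄)/√(s²ₐ/nₐ+s²ᵦ/nᵦ) with Welch–Satterthwaite df,
  two-sided p. The df is reported real-valued, never rounded or pooled;
  for a 3-vs-4 comparison it generally differs from the pooled value 5.
  Sidedness of the original comparisons is not stated; two-sided is used
  throughout.
* **Mann–Whitney U**: exact p by the rank-count recurrence when both
  n ≤ 20 and no tie spans the groups (within-group ties leave U's null
  distribution intact), otherwise the tie-corrected normal approximation
  with continuity correction. The exact two-sided p is twice the lower
  folded-tail mass, capped at 1.

Null calibration (p-value uniformity, type-I error at α = 0.05 within
binomial 3σ over 2000 simulations) is property-tested for both.

## Problem sizes and determinism

The reproduction script and end-to-end tests use 3 replicates × 8 cells ×
30 puncta per condition — the scale of one imaging session — which puts
the between-replicate sd of t₁/₂ at ~3 s in the fast regime and ~15 s in
the slow one. All randomness flows from a single seed through spawned
per-replicate `numpy` generator streams; fixed seeds make every output
(including written CSV/TIFF files) bit-identical across runs.

The lag-ordering check compares a two-stage condition with k_bind = k_rel
(the maximal-lag hypoexponential shape) against an exponential condition
with the same analytic median (150 s), using mean t₂/₃ over 3-replicate
sets: matching medians isolates the lag *shape*, and the Erlang-like
choice makes the expected ordering margin (~19 s) several times the
sampling noise of a replicate-set mean.

## Known limitations

* Sub-pixel localization and frame-to-frame linking are deliberately out
  of scope (counts are the statistic); the detector is single-scale.
* The decay-time band rule is a nonparametric threshold statistic; no
  exponential/hypoexponential model is fit to trajectories.
* Decay times later than the trial end (≈ 420 s post-drug) are reported as
  `not_reached` rather than extrapolated.
* TrackMate CSV import maps positions as physical units (µm) and derives
  pixel coordinates only when a pixel size is supplied.
* The quality threshold, amplitudes, and noise defaults are mutually
  calibrated on the synthetic 16-bit-like scale; real data will need
  rescaled thresholds.
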