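# punckit

Simulation and quantification of puromycin-induced release of nascent
polypeptide chains from ribosomes, as read out by live-cell SunTag
translation-reporter imaging.

## The problem

In SunTag imaging, polysomes translating a reporter mRNA appear as
diffraction-limited fluorescent puncta over a diffuse cytoplasmic
background. Adding puromycin terminates translation and covalently tags the
nascent chain; if the tagged chain then dissociates from the ribosome, the
punctum fades into the background. The *rate* of this fading — and whether
elongation inhibitors such as emetine or cycloheximide slow it — decides
whether puromycin immunostaining can be trusted to mark the original site
of translation. `punckit` implements the quantitative analysis of such
experiments for imaging labs: per-frame spot counting, per-cell
quality control and normalization, and nonparametric decay-time statistics,
together with a synthetic-movie generator so the whole pipeline is testable
without any raw microscopy data.

## The method

For each cell in an imaging trial (≈ 8 min, irregular ~5.4 s frame
intervals, drug added at t = 60 s):

1. **Spot detection.** Puncta are local maxima of the scale-normalized
   Laplacian-of-Gaussian response, −σ²∇²(G_σ∗I), at the blob scale
   σ = (d/2)/√2 for an expected diameter d = 0.5 µm; the peak response is
   the spot *quality* (threshold 300), with optional contrast and
   total-intensity filters and nuclear-region exclusion.
2. **QC.** Cells whose smoothed cytoplasmic reporter intensity falls more
   than 10% below its early-trial baseline (photobleaching, focal drift)
   are discarded.
3. **Normalization.** Per-cell puncta counts *N(t)* are divided by the mean
   count over the pre-drug minute, giving *n(t)* with baseline 1.
4. **Decay times.** The replicate-mean trajectory is smoothed with a
   boxcar (rolling mean, k = 10 observations) and the times t₂/₃, t₁/₂,
   t₁/₃ after drug addition at which n(t) = 2/3, 1/2, 1/3 are extracted by
   averaging the timestamps of all frames within ±0.01 of each level
   (linear interpolation bridges levels skipped between frames).
5. **Statistics.** Welch's unequal-variance t-test compares decay times
   between conditions; the Mann–Whitney U test (exact for small samples)
   compares per-cell intensity distributions in the still-image
   (immunofluorescence / proximity-ligation) mode.

The synthetic generator renders movies with per-punctum disappearance
drawn from one of four kinetic regimes — `vehicle` (no release), `instant`,
`exponential` (rate k_rel; emetine-like, no lag), and `two_stage`
(exponential binding delay then release; cycloheximide-like lag) — with
Poisson + Gaussian noise, mild photobleaching, and conserved fluorescence
(released flux returns to the cytoplasmic pool). Ground truth (release
times, per-frame counts) is returned for recovery tests.

## Worked example

```python
from punckit import (AcquisitionParams, DetectionParams, KineticsParams,
                     ReleaseKineticsParams, run_condition)

acq, det, kinp = AcquisitionParams(), DetectionParams(), KineticsParams()
emetine = run_condition(
    ReleaseKineticsParams(mode="exponential", k_rel=0.021),
    acq, det, kinp, n_replicates=3, seed=1, condition="emetine",
)
vehicle = run_condition(
    ReleaseKineticsParams(mode="vehicle"),
    acq, det, kinp, n_replicates=3, seed=2, condition="vehicle",
)
for rep in emetine.replicates:
    est = rep.summary.decay_time(0.5)
    print(f"{rep.replicate}: t_1/2 = {est.time:.1f} s ({est.method})")
print(f"mean emetine t_1/2 = {emetine.mean_decay_time(0.5):.1f} s")
print(f"vehicle reached 1/2 in {len(vehicle.decay_times(0.5))}/3 replicates")
```

prints

```
emetine-r1: t_1/2 = 36.8 s (interpolated)
emetine-r2: t_1/2 = 41.1 s (interpolated)
emetine-r3: t_1/2 = 33.1 s (band_average)
mean emetine t_1/2 = 37.0 s
vehicle reached 1/2 in 0/3 replicates
```

Each replicate simulates one field of 8 cells × 30 puncta, detects spots
frame by frame, applies QC and normalization, and reads t₁/₂ off the
smoothed replicate-mean trajectory. With per-punctum release at
0.021 s⁻¹ the half-life lands well under 40 s, while untreated (vehicle)
cells never lose half their puncta. The `method` field records whether the
±0.01 band contained frames or the crossing was interpolated.

The same pipeline is scriptable from the shell:

```
punckit run-all --config config.yaml --seed 7 --outdir out/
```

which writes per-replicate decay-time summaries, binned mean ± sd curves,
and Welch comparisons as CSV (see `punckit --help` for the stage-by-stage
subcommands `simulate-movie`, `simulate-stills`, `detect`, `quantify`,
`kinetics`, `compare`).

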