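# Methods

This note documents the models, numerical choices and limitations of
`nmspont`: what the analysis computes, what the synthetic generator
emulates, and what passing the recovery suite does and does not show
about real recordings.

## Analysis pipeline

**Baseline and ΔF/F₀.** The baseline F₀(t) is a 1-D grayscale erosion
(centered sliding minimum) of the raw ROI trace, window `W` frames,
borders replicated. `W` defaults to 41 frames (≈ 2 min at the 3 s
volumetric frame interval): longer than the longest spontaneous event
(≈ 14 s), so events do not erode into the baseline, and short enough to
track slow drift in resting fluorescence. Erosion guarantees F₀ ≤ F,
hence ΔF/F₀ ≥ 0. The erosion is applied to the raw F series; the same
operator runs per pixel for activity maps.

Known bias: with additive noise of SD σ (relative), the sliding minimum
sits ≈ `E[min of W noise draws] ≈ −(2–3)σ` below the true baseline, so
ΔF/F₀ carries a small positive offset and above-threshold widths widen
by roughly `τ·ln(θ/(θ−offset))` — about +1 s at σ = 0.01, θ = 0.10 for
hair-cell kinetics. This is a property of the erosion-baseline method
itself, visible in the recovery numbers, and is left uncorrected.

**Events.** Only ΔF/F₀ > θ = 0.10 counts as signal (strict inequality;
the boundary value 0.10 is noise by definition). Peak picking is
`scipy.signal.find_peaks` with minimum height θ, minimum prominence
0.10 and minimum separation 2 frames (all configurable). Duration is
the contiguous above-θ time around the peak, counted in whole frames
(no interpolation); when several peaks share one above-θ segment it is
split at the troughs between them. A half-prominence width is available
as an option. Average magnitude divides the above-θ sum by the *total*
frame count; silent ROIs therefore contribute zeros to frequency and
average magnitude but are excluded from per-event means (no
survivorship bias). Per-neuromast values are unweighted means of the
per-ROI values.

**Correlations.** Full-recording sample Pearson R on ΔF/F₀ at native
sampling, no detrending or lag search. "Neighbors" (undefined in the
underlying protocol) are the k = 3 nearest same-class cells by
ROI-center Euclidean distance, k+1 on a distance tie at rank 3; the
hair-cell/supporting-cell pairing uses each hair cell's 3 nearest
supporting cells. Zero-variance traces have undefined R and are
excluded from class means with a log entry. Class summaries report
mean ± SEM.

**Latency.** Onset = first crossing of `onset_fraction` (default 0.2)
of each trace's own peak, linearly interpolated between frames;
latency = onset(bottom) − onset(top). The default fraction sits on the
early rise where the slope is steep, minimizing noise-induced onset
jitter; the estimator is exactly antisymmetric.

**Group comparison.** D'Agostino–Pearson normality (Shapiro–Wilk below
n = 8) gates a t-test vs a rank-based test (Mann–Whitney / Wilcoxon),
reporting which path was taken. No multiple-testing correction is
applied (single pairwise comparisons).

**Pre-processing.** Drift correction registers each volume to the first
frame (a running reference is available) by phase cross-correlation
with 10× upsampling, shifts with linear interpolation, edge fill at the
frame median, and flags the recording for discard when any shift
exceeds `max_drift_px` (default 10 px — "excessive" drift is a
judgment call and configurable). Maximum projection tiles z from the
apical surface; the final partial sub-volume is kept so the deepest
cells remain analyzable.

## Synthetic generator

The generator emulates the statistical structure of the recordings the
analysis was built for, not their optics.

**Transients.** Events are homogeneous Poisson trains (the underlying
arrival process is not characterized in vivo; rates are package
defaults chosen so a 900 s recording holds ~5–11 sparse events:
hair cells 0.012 /s, supporting cells 0.005 /s, efferents 0.01 /s).
A transient rises linearly over 3 s to amplitude A (hair cells 0.8,
supporting cells 0.5, efferents 0.6 ΔF/F₀ — package defaults) and
decays exponentially with

    τ = (D − rise·(1 − θ/A)) / ln(A/θ),

which makes the true above-θ time exactly the configured duration D
(hair cells D = 14.22 s, supporting cells D = 9.06 s, efferents 10 s —
the last is a package default, as no efferent duration is reported).
Overlapping transients sum. Raw fluorescence is
`F = baseline·(1 + a(t)) + baseline·ε(t)` with ε Gaussian
(SD 0.01 ΔF/F₀ by default; the efferent preset instead fixes the
noise *variance ratio* at 5% of the realized signal variance).

**Coupling.** A coupled population shares variance through a
standardized mixture: common train c and private trains e_i are
independent realizations of the same rate-λ process; each realization
is standardized empirically and combined as
`z_i = √φ·c̃ + √(1−φ)·ẽ_i`, then mapped back to the ΔF/F₀ scale with
the closed-form shot-noise (Campbell) mean and SD of the rate-λ
process. Expected pairwise Pearson R equals φ exactly, and the
empirical standardization pins the shared component's sample variance,
which is what keeps the per-neuromast estimate tight at sparse event
counts. Two costs are accepted: a coupled trace superposes both trains
(≈ 2λ apparent events), and shared/private events carry amplitudes
≈ √φ·A / √(1−φ)·A, which biases detected durations slightly low — in
practice partially cancelling the erosion-noise widening. Noise
attenuates measured correlation as `R = φ/(1+ρ)` with ρ the
noise-to-signal variance ratio; preset noise keeps ρ ≤ ~0.02 so class
means stay within recovery tolerances.

Preset coupling fractions: supporting-cell pairs φ = 0.50 (0.08 under
gap-junction block), hair-cell pairs φ = 0.28, efferent terminals
φ = 1.0 with 5% noise ratio (attenuated R ≈ 0.952), hair-cell↔
supporting-cell and hair-cell↔efferent φ = 0, bundle↔presynapse
(day-2 preset, late-stage cells) φ = 0.60.

**Conditions** are pure parameter transforms, assertable on the
returned model: MRS2500 and thapsigargin zero the supporting-cell rate
(thapsigargin also multiplies their resting fluorescence by 3 — the
elevation factor is a package default); FFA overrides supporting-cell
φ to 0.08; isradipine and the Ca_V1.3a-null genotype zero the
presynaptic rate and leave bundles untouched; BAPTA and the
Pcdh15a-null genotype multiply bundle and presynapse rates by a
residual fraction of 0.1; α-Btx + apamin changes nothing in hair
cells; day-6 maturity multiplies hair-cell and efferent rates by 0.1
and leaves supporting cells unchanged. Randomness is organized as one
independent stream per coupling group plus one per compartment, so a
condition that silences one compartment leaves all others bit-identical
at a matched seed.

**Movies.** Cells render as 3D Gaussian blobs (FWHM = the compartment's
ROI diameter: 5 µm hair-cell base, 2 µm bundle/presynapse/terminal,
3 µm supporting-cell soma) on a 1 × 0.325 × 0.325 µm voxel grid, with
Poisson shot noise on photon counts (background 20 counts,
`photon_scale` modelling exposure/collection efficiency), optional
Gaussian read noise and optional rigid drift accumulated per frame;
metadata records ground-truth ROI centers and the injected drift. The
wave preset renders a single elongated supporting cell at 10 frames/s,
single plane, with the activity of each image row delayed linearly from
0 at the top sub-ROI center to 300 ms at the bottom one; it renders
20× brighter than the volumetric presets because single-plane imaging
dwells an order of magnitude longer per plane. Two-color presets share
one clock at 5 s; the 242 ms sequential channel offset is ≪ the frame
interval and modeled as zero lag.

**What the generator does not emulate** — and hence what recovery does
not show about real data: realistic PSFs and scattering (blobs are
Gaussian), bleaching and focus drift, non-Poisson event statistics and
refractoriness, indicator nonlinearity and saturation, cell shape and
movement other than rigid drift, and any biophysics of MET/Ca_V1.3
channels or ER calcium handling. Passing recovery shows the *analysis*
is correct and well-calibrated under the stated statistical structure,
not that the biology matches that structure.

## Problem sizes and numerical choices

The recovery experiments use the study's own sample sizes: 6 neuromasts
× 10 cells (durations, neighbor correlations), 4 neuromasts × 10
terminals (synchrony), 34 hair-cell/efferent pairs, 32
bundle/presynapse cells, 4 neuromasts for the null and FFA classes, and
single wave cells for latency; all but the wave run at trace level, so
the whole suite takes seconds. The latency target reports the mean of
3 simulated cells, since single-event onset jitter from photon noise is
~45 ms SD while the reported quantity is a per-cell average.

Ties and degenerate inputs: neighbor distance ties at rank k extend the
neighbor set by one; zero-variance traces are excluded from correlation
means and skipped in compartment pairing with a log entry; constant
frames register with zero shift and a warning; a ΔF/F₀ threshold of
exactly θ does not count as signal; pixels whose erosion baseline
touches zero are masked from activity maps and counted. Seeds fan out
from a single integer through `numpy.random.SeedSequence` counters at
every level (pipeline stage, coupling group, compartment), which is
what makes condition contrasts exactly paired and reruns byte-identical.

## Known limitations

- The erosion-baseline duration widening and the coupled-mixture
  duration shortening are both ~1 s scale at default noise; they are
  documented, not corrected, because the analysis mirrors the field's
  procedure rather than an unbiased estimator.
- Pre-processing is translation-only; rotation, non-rigid deformation
  and dual-view fusion are out of scope.
- ROIs are supplied (or ground truth); there is no automatic
  segmentation, and no neuropil/background subtraction beyond the
  erosion baseline.
- Event inference is threshold/peak-based; no deconvolution to
  underlying calcium or spikes, and no calibration of ΔF/F₀ to calcium
  concentration.
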