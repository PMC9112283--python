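# nmspont

Quantification of spontaneous calcium activity in zebrafish lateral-line
neuromasts, with a matched synthetic-data generator.

During development, the cells of the neuromast — mechanosensory hair
cells, the surrounding supporting cells, and the cholinergic efferent
terminals contacting the hair cells — are all spontaneously active.
This package implements the analysis used to quantify that activity in
fast volumetric light-sheet (diSPIM) GCaMP6s/RGECO1 recordings, for
people who study developing sensory organs with genetically encoded
calcium indicators:

- **Pre-processing** — rigid 3D drift correction by phase
  cross-correlation, sub-volume maximum intensity projection (e.g.
  every 6 µm for hair cells, 4 µm for supporting cells), residual 2D
  registration, with a discard flag for excessive drift.
- **ΔF/F₀ traces** — per-ROI mean intensity F(t) with a per-timepoint
  baseline F₀(t) computed by 1-D grayscale **erosion** (a centered
  sliding minimum, default window 41 frames ≈ 2 min), so
  ΔF/F₀ = (F − F₀)/F₀ ≥ 0.
- **Event statistics** — signals must exceed θ = 0.10 ΔF/F₀ to count;
  per ROI the pipeline reports the *average magnitude*
  (Σ ΔF/F₀·[ΔF/F₀ > θ] / total frames), event frequency, peak
  magnitude and threshold-width duration, averaged per neuromast.
- **Correlation structure** — full-recording Pearson R per cell pair:
  neighbor-averaged per-cell values (each cell vs its 3–4 nearest
  neighbors), all-pairs terminal synchrony, within-cell bundle ↔
  presynapse coupling, and correlation heat maps.
- **Spatial analysis** — pixelwise mean-ΔF/F₀ activity maps, signed ΔF
  snapshot series, apex→base onset-latency estimation for
  intracellular calcium waves, and a generic profile-FWHM estimator.
- **Synthetic data** — a generator emulating the recordings
  (3 s volumes for 15 min; 5 s two-color volumes; 10 frames/s single
  plane), with Poisson event trains, calibrated transient templates,
  shared-variance population coupling, pharmacology/genotype condition
  switches and volumetric movie rendering — so every analysis stage is
  verifiable by parameter recovery.

The coupling model: each standardized activity signal in a coupled
population is `z_i = √φ·c̃ + √(1−φ)·ẽ_i` with `c̃` a common and `ẽ_i`
private standardized transient realizations, so the expected pairwise
Pearson correlation equals the shared-variance fraction φ exactly.  A
transient rises linearly for 3 s to amplitude A and decays with
τ = (D − rise·(1 − θ/A)) / ln(A/θ), making the true above-θ time equal
the configured duration D.

## Worked example

```python
from nmspont.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(preset="supporting_day3", seed=4, n_cells=6,
                     out_dir="run_demo")
res = run_pipeline(cfg)
print(res["summary_neuromast"].round(4).to_string(index=False))
print(res["correlations"])
```

prints

```
neuromast_id  n_rois  frequency_per_s  mean_peak_dff  mean_duration_s  average_magnitude
         nm1       6           0.0063          0.426          10.3881             0.0149
{'SC_SC_neighbor': {'mean_R': 0.5010095316951226, 'n': 6}}
```

Six simulated supporting cells produced events at ~0.006 /s with a mean
above-threshold duration of ~10.4 s (ground truth 9.06 s, one 3 s frame
of widening from the noisy erosion baseline), and the neighbor-averaged
Pearson correlation recovered the preset's gap-junction coupling of
φ = 0.50.  The run directory contains the tidy trace/event/summary CSVs
and a manifest; re-running the same config and seed reproduces them
byte for byte.

Short narrative scripts in `examples/` cover each capability
(simulation + event detection, correlation structure under gap-junction
block, movie pre-processing, wave latency, two-color pairings); a thin
CLI (`nmspont simulate|preprocess|extract|events|run`) wraps the same
functions for shell use.

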