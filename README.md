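# tonodepth

Surface-based, depth-resolved tonotopy analysis for high-resolution auditory
midbrain fMRI — with a synthetic phantom generator for validating every step.

## The problem

The inferior colliculus (IC), the primary auditory midbrain nucleus,
represents sound frequency along its laminar (depth) axis: superficial tissue
prefers low frequencies, deeper tissue higher ones. Resolving this *tonotopy*
non-invasively requires ~1 mm fMRI and an analysis that respects the tissue
geometry: voxel statistics must be organized by *depth below the tissue
surface*, not by scanner axes. `tonodepth` implements that analysis chain for
sparse-sampling auditory fMRI:

1. **Tissue surface model** — marching-cubes isosurface of a binary tissue
   mask with volume-preserving (Taubin) smoothing; per-vertex outward
   normals, barycentric areas, and signed discrete mean curvature. The IC
   analysis region is the high-positive-curvature protrusions.
2. **Depth map** — nearest-neighbor Euclidean distance from every tissue
   voxel center to the surface vertices.
3. **Voxel frequency responses** — for stimulus conditions at frequencies
   `f_i` with response amplitudes `A(f_i)` (percent signal re the quiet
   reference), the preferred-frequency estimate is the amplitude-weighted
   centroid in log2-frequency (min-subtracted so the weights are positive
   definite),

       f_cent = Σ_i f_i A(f_i) / Σ_i A(f_i),

   the tuning width is the square root of the corresponding second central
   moment, and uncertainties come from bootstrap resampling of presentations
   (B = 1000, 68% percentile intervals).
4. **Virtual penetrations** — at every region vertex, a 1.2-mm-diameter
   cylinder along the inward mean surface normal of its 0.6-mm manifold
   patch samples `(depth, f_cent)` pairs over 0–5 mm; a straight line is
   fitted after removing 0–1.5 mm of superficial tissue (best fit chosen by
   residual variance), the slope `g` (octaves/mm) estimates the local
   tonotopic gradient, and its one-sided significance is the fraction of
   bootstrap refits with non-positive slope.
5. **Summaries** — surface areas with significant (p < 0.05) and trend
   (p < 0.16) gradients, mean slope, fit quality, the slope-weighted mean
   gradient direction `⟨n⟩ = Σ g_i n_i / Σ g_i` with sagittal/axial angles,
   and a per-session results table with mean ± sd columns.

Because no suitable public dataset carries this protocol, the package ships a
first-class **synthetic phantom**: a brainstem slab with two collicular
protrusions, a continuous planted preferred-frequency field (linear in depth
below a non-tonotopic rind, arranged in patchy sub-regions), and a simulated
sparse-sampling session (five bandpass-noise conditions log-spaced on
0.25–8 kHz plus quiet, 55 presentations per condition, thermal image SNR 25,
~1% evoked amplitudes). Ground truth is exported for parameter-recovery
scoring. An adaptive-staircase simulator reproduces the behavioral task
(two-interval frequency discrimination driven by interleaved two-up/one-down
staircases with cross-run re-initialization).

## Worked example

```python
from tonodepth import PipelineConfig, run_pipeline

cfg = PipelineConfig().with_seed(11)
res = run_pipeline(cfg, outdir="work")
print({k: round(v, 2) for k, v in res.row.items()})
```

prints (exact values depend on the seed):

```
{'sig_area_mm2': 66.25, 'trend_area_mm2': 116.15, 'total_area_mm2': 173.98,
 'mean_slope': 0.49, 'sagittal_angle_deg': -89.09, 'axial_angle_deg': 83.42,
 'mean_r2': 0.73, 'mean_d0': 0.51}
```

Reading: of the 174 mm² of detected collicular surface, 66 mm² carries a
significant (p < 0.05) depth gradient of preferred frequency; the mean fitted
gradient over significant penetrations is 0.49 octaves/mm (the planted
gradient is 0.53 octaves/mm — the centroid estimator slightly compresses
slopes, see `docs/methods.md`), linear fits explain ~73% of variance, and the
fits discard on average 0.51 mm of superficial tissue (planted rind 0.7 mm).
The mean gradient direction points inferior — into the tissue of this
upward-protruding phantom, as it should. All intermediate artifacts (NIfTI
volumes, OBJ/PLY meshes, CSV tables, JSON summaries) are written to `work/`.

The same stages are scriptable from a shell:

```bash
tonodepth pipeline --out work --seed 11        # everything end to end
tonodepth synth --out work                     # or stage by stage:
tonodepth surface --out work
tonodepth respond --out work
tonodepth penetrate --out work
tonodepth summarize --out work
tonodepth blur-control --out work --fwhm 2.0
tonodepth staircase --out stairs.json --seed 1
```

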