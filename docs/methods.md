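# Methods

This note documents the models, defaults and numerical choices behind
`tonodepth`, and what the synthetic phantom does and does not establish about
real data.

## The analysis model

**Surface.** The cerebrospinal-fluid/tissue boundary is extracted as a
marching-cubes isosurface at the 0.5 level of the binary mask (largest
connected body kept) and regularized with Taubin smoothing (λ = 0.5,
ν = 0.52, default 20 iterations — exposed as configuration because the right
amount depends on voxel size). Taubin's pass pair smooths without net
shrinkage, which matters because the surface position sets the depth origin.
All geometry lives in physical millimetres, axes (x=right, y=anterior,
z=superior), voxel centers at `(index + 0.5) · voxel_size`.

**Curvature and region.** Mean curvature uses the normal-cycle estimator:
the sum over edges inside a ball of (edge length in the ball) × (dihedral
angle, signed by convexity), halved, then normalized by the flat-disc area
π r². For a sphere the Euclidean ball of radius r cuts a cap of area exactly
π r², so the estimate is unbiased at any ball radius; the default radius
(1.0 mm) trades locality against marching-cubes surface noise. The analysis
region is the `n` largest connected components of vertices with curvature
above 0.05 mm⁻¹ (the protruding colliculi), after excluding vertices within
2.5 mm of the lateral/inferior bounding planes, where a cropped tissue block
ends in sharp artificial rims. The junction ring where a protrusion meets
the surrounding surface has mixed-sign curvature, so the detected region
excludes a collar of roughly one ball radius — detected region areas run
~20–30% below the analytic area of a full hemispherical cap.

**Depth.** Depth is the Euclidean distance from a voxel center to the
nearest surface *vertex* (not the nearest triangle), as a deliberate,
documented simplification: it carries a positive bias bounded by the local
vertex spacing (≲0.5 mm at 0.7-mm meshing), uniform enough not to distort
slopes.

**Frequency moments.** Amplitudes are quiet-referenced percent signal: each
presentation's amplitude minus the mean quiet-period amplitude of its run
(within-run referencing suppresses run-level drifts; the reference is common
to all conditions of a run and cancels in the centroid, which is invariant
to additive offsets and positive scaling). Moments are computed in
log2-frequency (octaves re 1 kHz): the stimuli are log-spaced and gradients
are reported in octaves/mm, so a linear-frequency moment could not produce
the right units. Min-subtraction makes weights positive definite; voxels
with all-equal amplitudes have undefined moments and are flagged NaN.
The tuning width is reported as the square root of the second central
moment, so it is in octaves rather than octaves².

**Bootstrap.** Presentations are resampled with replacement within each
condition, B = 1000; intervals are 16th/84th percentiles; one-sided p values
are the fraction of resamples on the non-hypothesized side of zero, clamped
to ≥ 1/(B+1). All voxels share the presentation-resample indices within a
resample, so each resample is a re-weighted session and spatial noise
correlation (e.g. from interpolation) propagates into the intervals
correctly. Implementation detail: resampling is expressed as a sparse
count-weight matrix multiplication, exactly equivalent to index-gather means
but vectorizable over ~10⁴ voxels.

**Penetrations and fits.** Cylinder membership is geometric (perpendicular
distance ≤ 0.6 mm, axial projection in 0–5 mm from the vertex along the
negated mean outward normal of the 0.6-mm manifold patch; manifold distance
is Dijkstra shortest-path along edges, an upper bound on the geodesic that
is accurate at this scale). Fits regress the voxel value on the depth-map
depth. The superficial cut d0 is searched on a 0.1-mm grid over 0–1.5 mm
with at least 4 voxels retained; the "best linear fit" criterion is the
**minimum residual variance** SSR/(n−2), not maximum R²: R² rewards span, so
it almost never trims a flat superficial segment (measured mean d0 ≈ 0.2 mm
against a planted 0.7-mm rind), while residual variance is span-neutral and
recovers d0 within the expected tolerance. Ties break toward smaller d0
(keep more data). During the bootstrap the member set and d0 stay fixed at
the point estimate — re-searching d0 inside every resample would let the
selection chase noise and bias p downward. Voxels without a detectable
sound response (one-sided sound-vs-quiet bootstrap p ≥ 0.05) are excluded
from fits: their moment estimates are noise-dominated and biased toward
mid-band frequency (see *Known limitations*). Voxels may belong to several
penetrations; no deduplication is attempted. Significance is one-sided for
positive gradients; no multiple-comparison correction is applied across
vertices.

**Direction convention.** `⟨n⟩ = Σ g_i n_i / Σ g_i` over significant
penetrations, normalized; 0° points anterior (+y), positive sagittal angles
rotate superior (atan2(n_z, n_y)), positive axial angles rotate rightward
(atan2(n_x, n_y)).

**Display.** Overlay opacity is 1 below p = 0.05, 0 at p ≥ 0.5, linear in
log p between. Report tables round half-away-from-zero: areas and angles to
integers, slopes/R²/d0 to two decimals.

## The phantom

**Geometry.** A brainstem slab carrying two spherical caps of radius 4.2 mm
(8.4-mm-wide protrusions; the human IC is < 9 mm across, and the analysis
fits extend to 5 mm depth, which requires protrusions of about this lateral
scale). The free-surface plane snaps to a functional-voxel boundary so the
voxelized volume is exact. Ground-truth depth is the distance to the
superior free surface, exact for the plane and spherical caps (a 0.1-mm
parametric sampling covers non-spherical semi-axes); slab side/bottom faces
are excluded from the depth definition and kept > 5 mm from any fitted
voxel.

**Planted field.** Patches are a seeded Voronoi tiling of each cap by
directions from the cap center (~3-mm patch scale); an exact count
`round(patch_fraction · n)` of cells is tonotopic, a sub-count carries a
negated gradient. Below a non-tonotopic rind (default 0.7 mm), preferred
frequency follows `base + g·(depth − rind)` with g = 0.53 octaves/mm.
The base frequency defaults to the stimulus-grid center (0.5 oct ≡
1.41 kHz), which keeps planted values inside the band where the five-point
centroid is nearly unbiased; edge-of-band bases additionally engage the
centroid's mid-band bias (below). The rind is modeled as *uniformly tuned to
the base frequency* — superficial tissue shows low-pass, non-gradient
responses, so profiles along a penetration are constant through the rind and
then rise. Untuned patches respond equally to every sound; tissue outside
the collicular columns is not auditory-responsive.

**Responses.** Tuning is Gaussian in log2-frequency (sd 1.0 octave — broad,
as expected for ~1.7 µL voxels containing millions of neurons; edge-
preferred voxels then naturally show low-/high-pass profiles). Each voxel's
noise-free response integrates the continuous field over the voxel volume
(3³ subsamples), the partial-volume behavior of real acquisition; without it
the planted field would be step-quantized at the functional voxel size.
The sparse session presents the monotonic five-tone + quiet cycle every
12 s, five cycles per run, 11 runs; each presentation is sampled by 4 image
volumes (120 volumes per 30-presentation run), and `snr = 25` is the
temporal SNR of those images, so the per-presentation flat-top amplitude —
their average, the primary data product — carries noise of sd
`baseline/snr/2`. Evoked amplitudes default to 1% of baseline. Noise is
Gaussian (at SNR 20–30, magnitude-image noise is effectively Gaussian). An
optional fixed-fraction undershoot carry-over from the preceding condition
(default off) emulates hemodynamic-undershoot frequency blurring. The depth
analysis consumes the functional data trilinearly resampled onto the 0.7-mm
structural grid the surface model is built from, as when functional volumes
are transformed into a structural reference volume; penetrations then hold
~14 voxels.

**Staircase observer.** P(correct) = 0.5 + 0.5·Φ((ln δ − ln α)/β) with
α = 4% (the 75%-correct point, inside the reported 3–8% difficulty range)
and β = 0.35. The two-up/one-down rule (step factor 1.12 ≈ 0.5 dB) converges
at the 70.7%-correct point; runs hold 25 discrimination trials (5 per
72-s cycle × 5 cycles), thresholds are latter-half means, and each new run
starts 30% above the previous threshold.

## Known limitations and measured properties

- **Centroid shrinkage.** The min-subtracted five-point centroid is pulled
  toward the middle of the stimulus band with strength ~1/(amplitude SNR).
  Consequences, measured on the phantom at study conditions: fitted depth
  slopes underestimate the planted gradient by a factor ≈ 0.7 (five-point
  sampling compression ×0.93, residual superficial-plateau inclusion ×~0.85,
  deep-end noise shrinkage ×~0.85); pooled recovered slopes run
  ≈ 0.38–0.45 octaves/mm against the planted 0.53. This mirrors the
  method's real-data behavior — measured gradients span less than the
  stimulus range — and should be kept in mind when reading absolute slopes.
- **Shared deep cores.** Penetrations of one protrusion converge with depth
  and share their deepest voxels, so per-session significance fractions have
  only a couple of effective independent "deep" noise draws per colliculus:
  single-session false-positive fractions under a zero-gradient phantom
  swing between ~0% and ~25% around a pooled mean of ~3–7%. Calibration
  statements therefore pool several session realizations.
- **Power.** At SNR 25 with 55 presentations and ~1% amplitudes, ~60–80% of
  penetrations fully inside a planted patch reach p < 0.05; penetrations
  straddling patch borders (most, at a 3-mm patch scale against a 1.2-mm
  probe) measure mixtures and are less often significant.
- **Surface dilution.** Voxels near the CSF boundary have partial-volume-
  diluted amplitudes; their centroids are noise-biased toward mid-band,
  which is why fits gate on sound-vs-quiet significance. The residual effect
  makes shallow estimates slightly mid-band-biased for edge-of-band fields.
- The phantom has no physiological noise, motion, B0/receive-field
  structure, or k-space effects (homomorphic normalization and DCT high-pass
  preprocessing are implemented and tested against synthetic gain fields and
  drifts, but the default phantom does not need them). Passing recovery
  tests show the *analysis chain* is correct and calibrated at thermal-noise
  conditions; they do not certify behavior under structured physiological
  noise.
- Mesh area converges to analytic values at the 1–2% level at the tested
  resolutions (sphere r = 10 mm at 0.5-mm voxels: +1.1%); a 20-mm digitized
  cube is ~2% low because smoothing rounds edges and corners.
- The blur control applies a true Gaussian at the stated FWHM. Note that a
  2-mm FWHM Gaussian reduces iid 1.2-mm voxel noise by ~3.9×, substantially
  more than the square root of the voxel-volume ratio (2.2×), which instead
  describes block-averaging into 2-mm cells; both measurements are reported
  by the acceptance script.

## Problem sizes used in validation

Default phantom grid 28×20×18 functional voxels (1.2 mm) ≈ 4700 tissue
voxels, ~24k structural voxels (0.7 mm), ~500 region vertices, 330
presentations/session, B = 1000. The pooled recovery study uses two phantom
layouts × two sessions; the null calibration pools ten sessions. These sizes
keep a full validation run in minutes on one CPU while leaving every
mechanism (geometry, bootstrap, selection) at its study-condition operating
point.
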