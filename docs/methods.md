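# Methods

## The simulated system

`fgsablate` models the closed loop of an automated fluorescence-guided
resection bench: sense (fluorescence + distance raster scans), fuse
(camera-mediated similarity registration), decide (threshold classification
and boundary formulation), act (laser ablation along the lifted cut path),
and verify (crater extraction and contour error metrics). Everything is
synthetic: the phantom, both sensors, the camera and the laser are
mathematical models with explicitly injected noise, so every error the
metrics report can be attributed to a modeled source.

## Phantom and emission model

The phantom is a 40 mm square, flat (z = 0) field with a closed tumor disk
(diameter 7.5, 10.0 or 12.5 mm) and four 3 mm fiducial disks on the corners
of a 20 mm square concentric with the tumor. Class boundaries are exact
disks — no diffusion. Composition (agarose, intralipid, hemoglobin;
absorption 14 cm⁻¹, reduced scattering 200 cm⁻¹) is carried as metadata
only.

The measured scalar per interrogation is a peak emission intensity modeled
linearly in fluorophore concentration:

    I = (g_FAD · FAD + g_NADH · NADH + b) · β(c),

with defaults g_FAD = 1 intensity/µM, g_NADH = 0.5 intensity/mM, b = 0.5,
so healthy tissue (16 µM FAD) reads 17.1 and tumor (1.6 µM) reads 2.7 —
the ~10× intensity contrast mirrors the 10× FAD contrast, and tumor is the
**low-intensity** class. The linear form is the simplest model preserving
the ordering the classifier needs; no radiative transfer is attempted.
β(c) = (1 − 0.2)^(c/25) is per-location photobleaching (20% loss per 25
irradiation cycles); fiducial (PTCDA) regions return a constant signature
(40.0) well above the tissue band and, being photostable, are not bleached.
Measurement noise is multiplicative Gaussian with cv 0.05 by default
(shot-noise-like, tunable to zero for oracle tests).

## Scanning

Grids are cell-centered: n = round(span/step) points per axis, which is
what makes a 27 mm span at 1 mm step produce exactly 27 × 27 = 729 points.
Spot averaging uses a 17-point stencil (center + 8 at r/√2 + 8 at r), a
cheap monotone approximation whose error against dense disk quadrature is
bounded by ~2/17 of the class contrast for an edge-centered spot; at the
0.75 mm spot scale this is negligible relative to the 1 mm grid. The
distance sensor returns the true surface height plus Gaussian roughness
(default sd 0.01 mm, the scale of bench triangulation sensors). Serpentine
vs raster-return ordering is configurable and verified not to change any
downstream result.

## Registration

The camera is fronto-parallel over a flat phantom, so a 4-DOF similarity
transform (scale, rotation, translation) suffices; it is estimated in
closed form (Procrustes/Umeyama without reflection) over the four ordered
fiducial correspondences. Laser-spot segmentation is replaced by synthetic
centroids with Gaussian pixel jitter (default 0.5 px at 0.1 mm/px ≈ 0.05 mm),
a stand-in for centroid-localization error; it is a sensitivity knob, not a
calibrated claim. Ground truth uses the *registered* fiducial positions, so
fiducial-localization error propagates into Q_GT exactly as on the bench.

## Boundary formulation

* **Threshold**: Otsu's between-class threshold on the tissue intensities
  (fiducial-band intensities ≥ 0.6 × signature excluded first); manual
  override supported. Ties (intensity exactly at threshold) classify as
  healthy, biasing toward under-resection.
* **Alpha shape**: Delaunay triangulation; triangles with circumradius
  above a selected radius are removed. The shrink factor in [0, 1]
  interpolates over the sorted circumradius spectrum between the convex
  hull (shrink 0) and the critical radius — the smallest radius whose kept
  triangles still cover all points in one connected region (shrink 1).
  Default shrink 0.5. The exterior ring of the kept-triangle union is the
  boundary; interior holes, when present, are ignored, and a
  multi-component result raises unless the caller asks for the largest
  component (the pipeline does).
* **Interior selection**: point-in-polygon with on-edge counted inside
  (shapely `covers`), cross-checked in the suite against a winding-number
  oracle.
* **Refinement**: the inside/outside indicator on the dense cloud's 2D
  projection is linearly interpolated onto a 150 × 150 mesh spanning the
  scan region (the mesh spans the scan region, not a tumor-local window;
  the window is configurable via the scan plan); the closed 0.5-level
  contour is extracted (marching squares), resampled at uniform arc length
  with 0.25 mm pitch (the firing pitch — no spline smoothing, and no
  curvature constraint is enforced), and each vertex snapped to its nearest
  cloud point so the shared 2D/3D index lifts the contour into the cutting
  path. Zero tumor-labeled points raise a "no tumor detected" error rather
  than failing downstream.

## Ablation and crater extraction

Each waypoint removes a radial Gaussian well with σ = spot/4 (0.2 mm for
the 0.80 mm spot, ≈95% of removal inside the spot) and peak depth
0.5 mm per dwell; PWM duty and firing rate are metadata since no
power-to-depth calibration curve is modeled. The difference of independent
pre/post depth scans is thresholded at a relative fraction (default 0.5) of
the maximum depth change — relative, hence scale-free in depth. Inner and
outer crater boundaries and the cutting center are extracted per angle
about the super-threshold region's centroid: along each of 360 rays the
first and last threshold crossings are located by linear interpolation
(sub-lattice precision), and the center is their midpoint. For a simply
connected (non-annular) region the inner contour is empty and the center
follows the per-ray depth ridge. The per-angle construction remains robust
when the depth-map lattice is coarse relative to the crater cross-section,
where a 2D level-set trace would fragment; the medial-axis alternative for
"center between inner and outer" was left unimplemented as the per-angle
midpoint matches it for the near-circular wells produced here.

## Error measurement

Q_GT is sampled at 360 vertices (1°; sampling adds ≪ 0.01 mm to RMSE).
Matching goes from each ground-truth vertex to the nearest *vertex* of the
evaluated contour; the same rule is applied to the TumorID boundary and the
crater center so the two errors are comparable. RMSE ≤ Max Error is
asserted per replicate.

## Experiment conditions and problem sizes

The replicate runner draws, per seed: the phantom placement (uniform within
±0.5 mm of the scan center — manual stage placement; this also randomizes
the grid-quantization phase so diameters are comparable), spectral noise,
camera jitter and surface roughness. Default grid: 3 diameters × 3
replicates, mirroring the bench protocol; distributional checks use 30
seeds per diameter, at a 0.5 mm distance-scan pitch — craters and
boundaries are resolved at sub-lattice precision by the interpolating
extractors, and the test suite verifies the 0.25 mm configuration
separately.

## What the generator does and does not emulate

Modeled: grid-resolution-limited boundary detection, spot-footprint mixing
at class edges, registration error from centroid jitter, sensor roughness,
crater geometry of overlapping Gaussian wells, fiducial-derived ground
truth. Not modeled: real emission spectra and tissue optics, camera
distortion/perspective, CIELAB segmentation failures, laser power drift,
thermal/char effects, robot kinematics and timing. Passing envelope tests
therefore shows that the *geometric pipeline* meets the printed error
bounds under calibrated synthetic noise; it does not certify performance on
real tissue, and the simulated errors (≈0.6 mm system RMSE) are smaller
than bench values (≈1.5 mm), which include unmodeled hardware error —
the printed envelopes are treated as upper bounds only.

## Known limitations

* The per-angle crater center is a radial function about the centroid;
  deeply non-star-shaped craters would need the medial-axis variant.
* Max-error statistics at the smallest tumor have a heavy tail: one noisy
  edge measurement can notch the alpha-shape boundary, and the replicate
  standard deviation of the system max error then hovers at the edge of
  0.2 mm for some seed sets.
* Median system RMSE drifts down weakly (~0.05 mm) from 7.5 to 12.5 mm
  tumors — a discretization effect that strong hardware noise would mask —
  so strict no-trend hypothesis tests at large replicate counts are
  marginal.
* Alpha-shape results on exactly cocircular point sets (perfect grids)
  depend on the triangulator's tie-breaking; registered real-valued
  positions avoid the degeneracy in practice.
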