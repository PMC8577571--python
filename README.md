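# fgsablate

A fully synthetic, end-to-end simulator of an automated fluorescence-guided
tumor ablation system, for researchers studying autonomous surgical sensing
and resection pipelines.

Intraoperative fluorescence-guided surgery exploits the Warburg effect:
healthy and neoplastic tissue carry different concentrations of the
endogenous fluorophores NADH and FAD, so a spectroscopic probe can tell them
apart from peak emission intensity alone. `fgsablate` builds a digital twin
of the bench experiment that validates such a system on optically tuned
agarose phantoms: a flat phantom with one circular tumor-mimicking inclusion
(FAD 1.6 µM versus 16 µM in the healthy background, NADH 1.2 mM in both)
and four PTCDA fiducial disks, interrogated by

1. a **fluorescence raster scan** — a 27 mm × 27 mm grid at 1 mm pitch
   (729 points), each measurement the spot-averaged (0.75 mm spot) peak
   intensity with multiplicative noise;
2. a **triangulation distance scan** — a dense 3D surface point cloud at
   0.25 mm pitch whose 2D projection shares the index of the 3D points.

Both streams are registered into one millimetre frame through a synthetic
monocular camera via a least-squares similarity transform over the fiducials.
The pipeline then thresholds intensities (Otsu; tumor is the low-FAD,
low-intensity class), wraps the tumor-labeled points in an **alpha shape**
(a shrink-parameterized concave hull built from the Delaunay triangulation),
selects the dense cloud points inside that edge, interpolates the
inside/outside indicator on a 150 × 150 mesh whose 0.5-level set is the
refined boundary, and lifts the refined contour to a 3D cutting path through
the shared cloud index. Ablation subtracts a Gaussian well
(σ = spot/4, 0.80 mm spot) per waypoint; the pre/post depth-difference map
yields the crater's inner/outer contours and their per-angle midpoint — the
executed-cut contour.

Accuracy is scored against a fiducial-derived ground-truth circle Q_GT
(center = fiducial centroid, radius = the mold's CAD radius). For a measured
contour matched nearest-point to Q_GT, with pairs (p_i, q_i):

    RMSE      = sqrt( (1/n) Σ ||p_i − q_i||² )
    Max Error = max_i ||p_i − q_i||

computed both for the raw fluorescence boundary (TumorID error, the
diagnostic arm alone) and the crater center (system error, end to end).

## Worked example

```python
from fgsablate import ExperimentConfig, run_replicate

config = ExperimentConfig()   # study defaults: 1 mm spectral raster, 0.25 mm distance scan
result = run_replicate(config, diameter_mm=10.0, seed=1)
print(f"TumorID  RMSE {result.tumorid_rmse_mm:.3f} mm   max error {result.tumorid_maxerr_mm:.3f} mm")
print(f"System   RMSE {result.system_rmse_mm:.3f} mm   max error {result.system_maxerr_mm:.3f} mm")
```

prints

```
TumorID  RMSE 0.620 mm   max error 1.135 mm
System   RMSE 0.587 mm   max error 1.114 mm
```

i.e. for this 10 mm tumor replicate the fluorescence-detected boundary sits
0.62 mm RMS from the true margin and the executed cut 0.59 mm, with the
single worst deviation at 1.1 mm — inside the true margin on average, the
healthy-tissue-sparing "undershoot" such a system should show.

The same is available from a shell:

```bash
fgs-ablate simulate --seed 1 --diameter 10.0 --out sim_out   # one replicate + figures
fgs-ablate run --seed 0 --out run_out                        # full diameter × replicate grid
fgs-ablate report --in run_out --out report.json             # aggregation + error plots
```

`simulate` writes the spectral scan and point cloud (CSV), all contours
(CSV), the depth-difference map (TIFF + JSON world coordinates) and a
two-panel figure of the classified scan and the crater.

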