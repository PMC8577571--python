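"""The two sensing streams: fluorescence raster scan and distance raster scan.

The spectroscopic arm interrogates a square grid (default 27 mm x 27 mm at
1 mm pitch -> 729 points) and records one peak-intensity scalar per point,
averaged over the excitation-spot footprint.  The surgical arm's
triangulation distance sensor scans the same surface at a finer pitch
(default 0.25 mm) and yields a dense 3D point cloud whose 2D projection
shares the same index ordering — that shared index is what later lifts the
refined 2D boundary into a 3D cutting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import EmissionModel, PhantomField, emission_at


@dataclass(frozen=True)
class ScanPlan:
    """Square raster-scan layout.

    The grid is cell-centered within the span: n = round(span/step) points
    per axis, each at the center of its 1-step cell, so a 27 mm span at
    1 mm step gives 27 points per axis (729 total).
    """

    span_mm: float = 27.0
    step_mm: float = 1.0
    origin_mm: tuple[float, float] = (0.0, 0.0)
    serpentine: bool = False

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.span_mm < self.step_mm:
            raise ValueError("span_mm must be at least step_mm")
        object.__setattr__(self, "origin_mm", tuple(self.origin_mm))

    @property
    def n_per_axis(self) -> int:
        return int(round(self.span_mm / self.step_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.n_per_axis
        return self.origin_mm[axis] + (np.arange(n) - (n - 1) / 2.0) * self.step_mm


def make_scan_grid(plan: ScanPlan) -> np.ndarray:
    """Ordered (n^2, 2) array of scan positions.

    Row-major over y (bottom row first); with ``plan.serpentine`` every
    other row is traversed right-to-left.  Ordering is a motion-planning
    detail and must not affect any downstream result.
    """
    xs, ys = plan.axis_coords(0), plan.axis_coords(1)
    rows = []
    for j, y in enumerate(ys):
        row_x = xs[::-1] if (plan.serpentine and j % 2 == 1) else xs
        rows.append(np.stack([row_x, np.full_like(row_x, y)], axis=-1))
    return np.concatenate(rows, axis=0)


@dataclass(frozen=True)
class SpectralScan:
    """One fluorescence raster scan: positions plus per-point peak intensity."""

    positions_mm: np.ndarray          # (N, 2)
    peak_intensity: np.ndarray        # (N,)
    cycle_index: np.ndarray           # (N,) irradiation cycle at acquisition
    clipped: np.ndarray               # (N,) True where spot footprint was clipped
    spot_diameter_mm: float = 0.0

    def __len__(self) -> int:
        return len(self.positions_mm)


@dataclass(frozen=True)
class SurfacePointCloud:
    """Dense distance-scan samples: 3D points and their index-paired 2D projection."""

    points_mm: np.ndarray   # (N, 3)
    step_mm: float

    @property
    def projected(self) -> np.ndarray:
        """Z-drop projection, sharing the same index as ``points_mm``."""
        return self.points_mm[:, :2]

    def __len__(self) -> int:
        return len(self.points_mm)


def _spot_stencil(radius: float) -> np.ndarray:
    """17-point footprint stencil: center + 8 at r/sqrt(2) + 8 at r."""
    if radius <= 0:
        return np.zeros((1, 2))
    ang = np.arange(8) * (np.pi / 4.0)
    ring = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return np.concatenate([np.zeros((1, 2)), ring * (radius / np.sqrt(2.0)), ring * radius])


def acquire_spectral_scan(field: PhantomField, model: EmissionModel, plan: ScanPlan,
                          spot_diameter_mm: float = 0.75, cycles: float = 0,
                          rng: np.random.Generator | None = None) -> SpectralScan:
    """Raster-scan the phantom and record one peak intensity per grid point.

    The recorded scalar is the area-average of the noise-free emission over
    the circular excitation-spot footprint (17-point stencil), with
    multiplicative noise applied once per measurement.  Stencil samples
    falling outside the phantom extent are dropped and the measurement is
    flagged as clipped.
    """
    grid = make_scan_grid(plan)
    offsets = _spot_stencil(spot_diameter_mm / 2.0)
    samples = grid[:, None, :] + offsets[None, :, :]          # (N, S, 2)
    flat = samples.reshape(-1, 2)
    inside = field.contains(flat)
    if not np.any(inside.reshape(len(grid), -1), axis=1).all():
        raise ValueError("a scan point's entire spot footprint lies outside the extent")
    vals = np.zeros(len(flat))
    vals[inside] = emission_at(field, model, flat[inside], cycles=cycles, rng=None)
    vals = vals.reshape(len(grid), -1)
    mask = inside.reshape(len(grid), -1)
    intensity = (vals * mask).sum(axis=1) / mask.sum(axis=1)
    if rng is not None and model.noise_cv > 0:
        intensity = intensity * (1.0 + model.noise_cv * rng.standard_normal(len(grid)))
    return SpectralScan(
        positions_mm=grid,
        peak_intensity=np.maximum(intensity, 0.0),
        cycle_index=np.full(len(grid), cycles),
        clipped=~mask.all(axis=1),
        spot_diameter_mm=spot_diameter_mm,
    )


def acquire_distance_scan(field: PhantomField, plan: ScanPlan,
                          roughness_sd_mm: float = 0.01,
                          rng: np.random.Generator | None = None,
                          surface_height_mm: float = 0.0) -> SurfacePointCloud:
    """Triangulation-sensor raster scan of the (flat) phantom surface.

    z is the nominal surface height plus Gaussian measurement roughness.
    """
    grid = make_scan_grid(plan)
    z = np.full(len(grid), float(surface_height_mm))
    if rng is not None and roughness_sd_mm > 0:
        z = z + roughness_sd_mm * rng.standard_normal(len(grid))
    pts = np.column_stack([grid, z])
    return SurfacePointCloud(points_mm=pts, step_mm=plan.step_mm)
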