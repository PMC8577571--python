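"""Laser-ablation simulation and crater quantification.

Material removal along the cutting path is modeled as a sum of radial
Gaussian craters (sigma = spot_diameter / 4, so ~95% of removal falls
within the spot).  Pre- and post-ablation depth maps are differenced, and
the annular super-threshold region's inner/outer boundaries and their
per-angle midpoint — the executed-cut contour — are extracted at
sub-lattice precision by linear interpolation of the threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .boundary import Contour, CutPath3D


class GridError(ValueError):
    """Depth-map lattices do not match."""


class OutOfRegionError(ValueError):
    """Cut-path waypoint outside the depth-map region."""


class NoCraterError(ValueError):
    """No super-threshold region in the difference map."""


@dataclass(frozen=True)
class DepthMap:
    """Regular-lattice surface-height field (mm).

    ``heights[j, i]`` is the height at (origin_x + i*spacing,
    origin_y + j*spacing); row index increases with y.
    """

    heights: np.ndarray
    origin_mm: tuple[float, float]
    spacing_mm: float

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or not np.all(np.isfinite(h)):
            raise ValueError("heights must be a finite 2D array")
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "origin_mm", tuple(self.origin_mm))

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin_mm[0] + np.arange(self.heights.shape[1]) * self.spacing_mm

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin_mm[1] + np.arange(self.heights.shape[0]) * self.spacing_mm

    def same_lattice(self, other: "DepthMap") -> bool:
        return (self.heights.shape == other.heights.shape
                and np.allclose(self.origin_mm, other.origin_mm)
                and np.isclose(self.spacing_mm, other.spacing_mm))

    @classmethod
    def flat(cls, span_mm: float, spacing_mm: float, origin_center: tuple[float, float] = (0.0, 0.0),
             roughness_sd_mm: float = 0.0, rng: np.random.Generator | None = None) -> "DepthMap":
        """Flat surface raster scan: zeros plus optional Gaussian roughness."""
        n = int(round(span_mm / spacing_mm))
        h = np.zeros((n, n))
        if rng is not None and roughness_sd_mm > 0:
            h = h + roughness_sd_mm * rng.standard_normal((n, n))
        x0 = origin_center[0] - (n - 1) / 2.0 * spacing_mm
        y0 = origin_center[1] - (n - 1) / 2.0 * spacing_mm
        return cls(heights=h, origin_mm=(x0, y0), spacing_mm=spacing_mm)


@dataclass(frozen=True)
class CraterModel:
    """Geometry of the well removed per laser dwell.

    The radial removal profile is Gaussian with sigma = spot_diameter / 4;
    PWM duty and mirror firing rate are process metadata and enter only
    through ``depth_per_dwell_mm``.
    """

    spot_diameter_mm: float = 0.80
    depth_per_dwell_mm: float = 0.5
    pwm_duty: float = 0.40          # metadata
    points_per_second: float = 20.0  # metadata

    def __post_init__(self) -> None:
        if self.depth_per_dwell_mm <= 0:
            raise ValueError("depth_per_dwell_mm must be positive")

    @property
    def sigma_mm(self) -> float:
        return self.spot_diameter_mm / 4.0


@dataclass(frozen=True)
class CraterContours:
    """Inner, outer and center contours of the ablation well.

    ``inner`` is None when the super-threshold region is simply connected
    (a filled pit rather than an annulus).
    """

    inner: Contour | None
    outer: Contour
    center: Contour


def simulate_ablation(pre: DepthMap, path: CutPath3D, crater: CraterModel) -> DepthMap:
    """Fire the laser at each waypoint: subtract one Gaussian well per dwell."""
    xs, ys = pre.x_coords, pre.y_coords
    post = pre.heights.copy()
    sig = crater.sigma_mm
    half_w = 4.0 * sig
    for wx, wy, _ in np.atleast_2d(path.waypoints) if len(path) else []:
        if not (xs[0] - pre.spacing_mm / 2 <= wx <= xs[-1] + pre.spacing_mm / 2
                and ys[0] - pre.spacing_mm / 2 <= wy <= ys[-1] + pre.spacing_mm / 2):
            raise OutOfRegionError(f"waypoint ({wx:.2f}, {wy:.2f}) outside depth map")
        i0, i1 = np.searchsorted(xs, [wx - half_w, wx + half_w])
        j0, j1 = np.searchsorted(ys, [wy - half_w, wy + half_w])
        sub_x = xs[i0:i1] - wx
        sub_y = ys[j0:j1] - wy
        r2 = sub_x[None, :] ** 2 + sub_y[:, None] ** 2
        post[j0:j1, i0:i1] -= crater.depth_per_dwell_mm * np.exp(-r2 / (2.0 * sig ** 2))
    return DepthMap(heights=post, origin_mm=pre.origin_mm, spacing_mm=pre.spacing_mm)


def difference_map(pre: DepthMap, post: DepthMap) -> DepthMap:
    """Depth of change, pre minus post (positive where material was removed)."""
    if not pre.same_lattice(post):
        raise GridError("pre and post depth maps must share the same lattice")
    return DepthMap(heights=pre.heights - post.heights,
                    origin_mm=pre.origin_mm, spacing_mm=pre.spacing_mm)


def _crossings(radii: np.ndarray, vals: np.ndarray, thresh: float):
    """First and last threshold up/down crossings along one radial profile.

    Returns (r_in, r_out, r_ridge) or None when the profile never reaches
    the threshold.  Crossing positions are linearly interpolated between
    radial samples for sub-lattice precision.
    """
    above = vals >= thresh
    if not above.any():
        return None
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    if first == 0:
        r_in = radii[0]
    else:
        f = (thresh - vals[first - 1]) / (vals[first] - vals[first - 1])
        r_in = radii[first - 1] + f * (radii[first] - radii[first - 1])
    if last == len(radii) - 1:
        r_out = radii[-1]
    else:
        f = (vals[last] - thresh) / (vals[last] - vals[last + 1])
        r_out = radii[last] + f * (radii[last + 1] - radii[last])
    seg = slice(first, last + 1)
    r_ridge = radii[seg][int(np.argmax(vals[seg]))]
    return r_in, r_out, r_ridge


def extract_crater_contours(diff: DepthMap, depth_threshold_fraction: float = 0.5,
                            n_angles: int = 360) -> CraterContours:
    """Locate the ablation well in a depth-difference map.

    The threshold is ``depth_threshold_fraction`` times the maximum depth
    change.  For each of ``n_angles`` rays from the super-threshold
    region's centroid, the innermost and outermost threshold crossings give
    the inner and outer contours and their midpoint gives the cutting
    center.  When the region is simply connected (the centroid itself is
    above threshold) the inner contour is empty and the center follows the
    ridge of maximum depth.
    """
    h = diff.heights
    max_depth = float(h.max())
    if max_depth <= 0:
        raise NoCraterError("difference map contains no removal")
    thresh = depth_threshold_fraction * max_depth
    mask = h >= thresh
    if not mask.any():
        raise NoCraterError("no super-threshold pixels")
    jj, ii = np.nonzero(mask)
    cx = float(diff.x_coords[ii].mean())
    cy = float(diff.y_coords[jj].mean())

    interp = RegularGridInterpolator((diff.y_coords, diff.x_coords), h,
                                     bounds_error=False, fill_value=0.0)
    corners = np.array([[diff.x_coords[k], diff.y_coords[m]]
                        for k in (0, -1) for m in (0, -1)])
    r_max = float(np.hypot(corners[:, 0] - cx, corners[:, 1] - cy).max())
    radii = np.arange(0.0, r_max, diff.spacing_mm / 4.0)
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    sample_x = cx + radii[None, :] * np.cos(angles)[:, None]
    sample_y = cy + radii[None, :] * np.sin(angles)[:, None]
    vals = interp(np.stack([sample_y, sample_x], axis=-1))

    annular = interp([[cy, cx]])[0] < thresh
    r_in = np.full(n_angles, np.nan)
    r_out = np.full(n_angles, np.nan)
    r_ridge = np.full(n_angles, np.nan)
    for k in range(n_angles):
        cr = _crossings(radii, vals[k], thresh)
        if cr is not None:
            r_in[k], r_out[k], r_ridge[k] = cr
    ok = np.isfinite(r_out)
    if ok.sum() < 3:
        raise NoCraterError("super-threshold region too fragmented for contouring")
    # fill missing angles by periodic interpolation
    for arr in (r_in, r_out, r_ridge):
        bad = ~np.isfinite(arr)
        if bad.any():
            arr[bad] = np.interp(angles[bad], angles[~bad], arr[~bad], period=2 * np.pi)

    def ring(radius_per_angle):
        return Contour(np.stack([cx + radius_per_angle * np.cos(angles),
                                 cy + radius_per_angle * np.sin(angles)], axis=-1))

    outer = ring(r_out)
    if annular:
        inner = ring(r_in)
        center = ring((r_in + r_out) / 2.0)
    else:
        inner = None
        center = ring(r_ridge)
    return CraterContours(inner=inner, outer=outer, center=center)


def removed_volume(diff: DepthMap) -> float:
    """Total removed volume in mm^3 (difference map integrated over cells)."""
    return float(diff.heights.sum() * diff.spacing_mm ** 2)
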