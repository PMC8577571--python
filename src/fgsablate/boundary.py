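"""Tumor-boundary formulation: threshold classification, alpha-shape edge,
interior selection and mesh-grid refinement with index-shared 3D lifting.

The fluorescence stream is thresholded into tumor / healthy (tumor is the
low-intensity class: 1.6 uM vs 16 uM FAD), the tumor-labeled points are
wrapped by an alpha shape (a concave generalization of the convex hull),
the dense distance-scan points inside that edge are selected, and the
inside/outside indicator is interpolated on a fine mesh whose 0.5-level set
is the refined boundary.  Because the 2D projection of the distance scan
shares indices with the 3D cloud, snapping each refined vertex to its
nearest cloud point lifts the 2D boundary into a 3D cutting path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import griddata
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure
from skimage.filters import threshold_otsu

from .phantom import TissueClass
from .scanning import SurfacePointCloud


class NoThresholdError(ValueError):
    """Intensity sample admits no between-class threshold (constant input)."""


class DegenerateInputError(ValueError):
    """Fewer than three non-collinear points."""


class MultiComponentError(ValueError):
    """Alpha shape splits into several components at the given shrink."""


class TopologyError(ValueError):
    """Contour is not a simple closed polygon."""


class RefinementError(ValueError):
    """Mesh refinement produced no closed 0.5-level contour."""


class NoTumorDetectedError(ValueError):
    """Too few tumor-labeled measurements to formulate a boundary."""


@dataclass(frozen=True)
class Contour:
    """Ordered closed sequence of 2D points (mm)."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if len(v) > 1:
            keep = np.ones(len(v), dtype=bool)
            keep[1:] = np.any(v[1:] != v[:-1], axis=1)
            if self.closed and keep.sum() > 1 and np.all(v[keep][-1] == v[keep][0]):
                keep[np.nonzero(keep)[0][-1]] = False
            v = v[keep]
        if len(v) < 3:
            raise ValueError("a contour needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    def to_polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def is_simple(self) -> bool:
        return self.to_polygon().is_valid


@dataclass(frozen=True)
class CutPath3D:
    """3D laser cutting trajectory lifted from the refined 2D boundary."""

    waypoints: np.ndarray       # (K, 3) mm
    source_indices: np.ndarray  # (K,) indices into the SurfacePointCloud

    def __post_init__(self) -> None:
        if len(self.waypoints) != len(self.source_indices):
            raise ValueError("waypoints and source_indices must pair one-to-one")

    def __len__(self) -> int:
        return len(self.waypoints)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def choose_threshold(intensities, manual: float | None = None) -> float:
    """Between-class intensity threshold (Otsu), or a manual override.

    Fiducial-signature intensities must be excluded by the caller before
    thresholding tissue intensities.
    """
    if manual is not None:
        return float(manual)
    vals = np.asarray(intensities, dtype=float).ravel()
    if len(np.unique(vals)) < 2:
        raise NoThresholdError("cannot threshold a constant intensity sample")
    return float(threshold_otsu(vals))


def classify(intensities, threshold: float, fiducial_min: float | None = None) -> np.ndarray:
    """Label each measurement: fiducial by signature band first, then
    tumor iff intensity < threshold (ties break to healthy, biasing the
    pipeline toward under- rather than over-resection)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.asarray(intensities, dtype=float).ravel()
    labels = np.where(vals < threshold, int(TissueClass.TUMOR), int(TissueClass.HEALTHY))
    if fiducial_min is not None:
        labels[vals >= fiducial_min] = int(TissueClass.FIDUCIAL)
    return labels


# ---------------------------------------------------------------------------
# alpha shape
# ---------------------------------------------------------------------------

def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.hypot(*(b - c).T)
    lb = np.hypot(*(a - c).T)
    lc = np.hypot(*(a - b).T)
    area2 = np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[~np.isfinite(r)] = np.inf
    return r


def _covering_and_connected(n_points: int, simplices: np.ndarray, kept: np.ndarray) -> bool:
    """Kept triangles use every point and form one vertex-connected region."""
    tri = simplices[kept]
    if len(tri) == 0:
        return False
    used = np.unique(tri)
    if len(used) != n_points:
        return False
    rows = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
    cols = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_points, n_points))
    n_comp, _ = connected_components(g, directed=False)
    return n_comp == 1


def alpha_boundary(points, shrink: float = 0.5, largest: bool = False) -> Contour:
    """Alpha-shape boundary of a 2D point set, parameterized by a shrink factor.

    ``shrink`` in [0, 1] interpolates over the spectrum of Delaunay
    circumradii between the convex hull (shrink = 0, no triangle removed)
    and the tightest single connected region covering all points
    (shrink = 1, critical radius).  Triangles with circumradius above the
    selected radius are removed; the exterior of the remaining region,
    ordered counter-clockwise, is returned.

    A multi-component result raises :class:`MultiComponentError` unless
    ``largest`` is set, in which case the largest-area component's exterior
    is returned.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must lie in [0, 1]")
    if len(pts) < 3:
        raise DegenerateInputError("alpha shape needs >= 3 points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # Qhull raises on collinear input
        raise DegenerateInputError(f"degenerate point set: {exc}") from exc
    if len(tri.simplices) == 0:
        raise DegenerateInputError("point set is collinear")
    radii = _circumradii(pts, tri.simplices)
    finite = radii[np.isfinite(radii)]
    if len(finite) == 0:
        raise DegenerateInputError("all triangles degenerate")

    # critical radius: smallest circumradius whose sub-level triangle set
    # still covers all points in a single connected region
    candidates = np.unique(finite)
    lo, hi = 0, len(candidates) - 1
    crit_idx = hi
    while lo <= hi:
        mid = (lo + hi) // 2
        if _covering_and_connected(len(pts), tri.simplices,
                                   radii <= candidates[mid] * (1 + 1e-12)):
            crit_idx = mid
            hi = mid - 1
        else:
            lo = mid + 1
    spectrum = candidates[crit_idx:]
    sel = spectrum[int(round((1.0 - shrink) * (len(spectrum) - 1)))]
    kept = radii <= sel * (1 + 1e-12)

    polys = [Polygon(pts[s]) for s, k in zip(tri.simplices, kept) if k]
    region = unary_union(polys)
    if region.geom_type == "MultiPolygon":
        if not largest:
            raise MultiComponentError(
                f"alpha shape has {len(region.geoms)} components at shrink={shrink}")
        region = max(region.geoms, key=lambda g: g.area)
    region = shapely.geometry.polygon.orient(region, sign=1.0)
    verts = np.asarray(region.exterior.coords)[:-1]
    return Contour(vertices=verts, closed=True)


# ---------------------------------------------------------------------------
# interior selection and refinement
# ---------------------------------------------------------------------------

def select_interior(points_2d, contour: Contour) -> np.ndarray:
    """Indices of points strictly inside or on the contour (on-edge inside)."""
    poly = contour.to_polygon()
    if not poly.is_valid:
        raise TopologyError("contour must be a simple closed polygon")
    pts = np.atleast_2d(np.asarray(points_2d, dtype=float))
    inside = shapely.covers(poly, shapely.points(pts))
    return np.nonzero(inside)[0]


def resample_closed(vertices: np.ndarray, pitch_mm: float) -> np.ndarray:
    """Uniform arc-length resampling of a closed polyline."""
    v = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(*np.diff(v, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    m = max(int(round(total / pitch_mm)), 8)
    s = np.arange(m) * total / m
    return np.stack([np.interp(s, cum, v[:, 0]), np.interp(s, cum, v[:, 1])], axis=-1)


def refine_boundary(raw_contour: Contour, interior_indices, cloud: SurfacePointCloud,
                    grid_n: int = 150, resample_pitch_mm: float = 0.25,
                    ) -> tuple[Contour, CutPath3D]:
    """Refine the coarse fluorescence boundary on an interpolated mesh-grid.

    An inside/outside indicator over the dense cloud's 2D projection is
    linearly interpolated onto a ``grid_n`` x ``grid_n`` mesh spanning the
    scanned region; the closed 0.5-level contour is extracted, resampled at
    uniform arc length (default pitch 0.25 mm, the cutting laser's firing
    pitch), and each refined vertex is snapped to its nearest cloud point so
    the shared index lifts the 2D boundary into a 3D cutting path.
    """
    if grid_n < 8:
        raise ValueError("grid_n must be >= 8")
    idx = np.asarray(interior_indices, dtype=int)
    if len(idx) == 0:
        raise NoTumorDetectedError("no interior points: nothing to refine")
    proj = cloud.projected
    indicator = np.zeros(len(proj))
    indicator[idx] = 1.0
    xs = np.linspace(proj[:, 0].min(), proj[:, 0].max(), grid_n)
    ys = np.linspace(proj[:, 1].min(), proj[:, 1].max(), grid_n)
    X, Y = np.meshgrid(xs, ys)
    Z = griddata(proj, indicator, (X, Y), method="linear", fill_value=0.0)
    contours = [c for c in measure.find_contours(Z, 0.5) if np.allclose(c[0], c[-1])]
    if not contours:
        raise RefinementError("0.5-level set is empty or open")
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]

    def to_mm(c):  # find_contours returns (row, col)
        return np.stack([xs[0] + c[:, 1] * dx, ys[0] + c[:, 0] * dy], axis=-1)

    best = max((to_mm(c) for c in contours), key=lambda v: Contour(v).area)
    refined = Contour(resample_closed(best[:-1], resample_pitch_mm))

    tree = cKDTree(proj)
    _, snap = tree.query(refined.vertices)
    keep = np.ones(len(snap), dtype=bool)
    keep[1:] = snap[1:] != snap[:-1]
    if snap[keep][-1] == snap[keep][0] and keep.sum() > 1:
        keep[np.nonzero(keep)[0][-1]] = False
    snap = snap[keep]
    path = CutPath3D(waypoints=cloud.points_mm[snap], source_indices=snap)
    return refined, path
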