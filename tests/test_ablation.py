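import numpy as np
import pytest

from fgsablate import (Contour, CraterModel, CutPath3D, DepthMap, difference_map,
                       extract_crater_contours, removed_volume, simulate_ablation)
from fgsablate.ablation import GridError, NoCraterError, OutOfRegionError
from oracles import gaussian_ring_depth


def circle_path(radius=5.0, pitch=0.25, center=(0.0, 0.0), z=0.0):
    m = int(round(2 * np.pi * radius / pitch))
    th = 2 * np.pi * np.arange(m) / m
    pts = np.stack([center[0] + radius * np.cos(th),
                    center[1] + radius * np.sin(th),
                    np.full(m, z)], axis=-1)
    return CutPath3D(waypoints=pts, source_indices=np.arange(m))


@pytest.fixture
def flat_map():
    # odd point count: the lattice contains the origin exactly
    return DepthMap.flat(span_mm=20.25, spacing_mm=0.25)


class TestSimulateAblation:
    def test_empty_path_leaves_surface_untouched(self, flat_map):
        path = CutPath3D(waypoints=np.zeros((0, 3)), source_indices=np.zeros(0, int))
        post = simulate_ablation(flat_map, path, CraterModel())
        np.testing.assert_array_equal(post.heights, flat_map.heights)

    def test_single_waypoint_gaussian_well(self, flat_map):
        path = CutPath3D(waypoints=np.array([[0.0, 0.0, 0.0]]),
                         source_indices=np.array([0]))
        crater = CraterModel(spot_diameter_mm=0.8, depth_per_dwell_mm=0.5)
        post = simulate_ablation(flat_map, path, crater)
        diff = flat_map.heights - post.heights
        j, i = np.unravel_index(np.argmax(diff), diff.shape)
        assert flat_map.x_coords[i] == pytest.approx(0.0, abs=0.25)
        assert flat_map.y_coords[j] == pytest.approx(0.0, abs=0.25)
        assert diff.max() == pytest.approx(0.5, rel=1e-6)
        # radial symmetry: equal depth at +-1 sigma along each axis
        interp = diff[j, i + 1], diff[j, i - 1], diff[j + 1, i], diff[j - 1, i]
        assert np.ptp(interp) < 1e-9

    def test_ring_depth_uniform_within_one_percent(self, flat_map):
        """Overlap-summed Gaussians along a circle: depth on the ring matches
        dense direct summation and varies < 1%."""
        crater = CraterModel(spot_diameter_mm=0.8, depth_per_dwell_mm=0.5)
        path = circle_path(radius=5.0, pitch=0.25)
        post = simulate_ablation(flat_map, path, crater)
        angles = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        oracle = gaussian_ring_depth(angles, 5.0, 0.25, crater.sigma_mm,
                                     crater.depth_per_dwell_mm)
        assert np.ptp(oracle) / oracle.mean() < 0.01
        # map depth at waypoints agrees with the dense summation oracle
        xs, ys = flat_map.x_coords, flat_map.y_coords
        diff = flat_map.heights - post.heights
        on_ring = gaussian_ring_depth(np.arctan2(path.waypoints[:, 1],
                                                 path.waypoints[:, 0]),
                                      5.0, 0.25, crater.sigma_mm, 0.5)
        ii = np.searchsorted(xs, path.waypoints[:, 0])
        jj = np.searchsorted(ys, path.waypoints[:, 1])
        grid_depth = diff[jj.clip(0, len(ys) - 1), ii.clip(0, len(xs) - 1)]
        assert np.all(grid_depth <= on_ring.max() + 1e-9)
        assert grid_depth.max() > 0.5 * on_ring.mean()

    def test_waypoint_outside_map_rejected(self, flat_map):
        path = CutPath3D(waypoints=np.array([[99.0, 0.0, 0.0]]),
                         source_indices=np.array([0]))
        with pytest.raises(OutOfRegionError):
            simulate_ablation(flat_map, path, CraterModel())

    def test_removed_volume_monotone_in_path_length_and_dwell_depth(self, flat_map):
        crater = CraterModel(depth_per_dwell_mm=0.5)
        vols = []
        for radius in (3.0, 4.0, 5.0):
            post = simulate_ablation(flat_map, circle_path(radius=radius), crater)
            vols.append(removed_volume(difference_map(flat_map, post)))
        assert vols[0] < vols[1] < vols[2]
        deeper = CraterModel(depth_per_dwell_mm=1.0)
        post = simulate_ablation(flat_map, circle_path(radius=3.0), deeper)
        assert removed_volume(difference_map(flat_map, post)) > vols[0]


class TestDifferenceMap:
    def test_identical_maps_difference_is_zero(self, flat_map):
        np.testing.assert_array_equal(difference_map(flat_map, flat_map).heights, 0.0)

    def test_disk_deepening_shows_up_exactly(self, flat_map):
        h = flat_map.heights.copy()
        xs, ys = np.meshgrid(flat_map.x_coords, flat_map.y_coords)
        disk = xs ** 2 + ys ** 2 <= 9.0
        post = DepthMap(h - 0.5 * disk, flat_map.origin_mm, flat_map.spacing_mm)
        d = difference_map(flat_map, post).heights
        assert np.all(d[disk] == 0.5) and np.all(d[~disk] == 0.0)

    def test_independent_roughness_adds_in_quadrature(self):
        """sd of the difference of two independent 0.01 mm-rough scans is
        sqrt(2) * 0.01 mm."""
        rng = np.random.default_rng(4)
        a = DepthMap.flat(27.0, 0.25, roughness_sd_mm=0.01, rng=rng)
        b = DepthMap.flat(27.0, 0.25, roughness_sd_mm=0.01, rng=rng)
        d = difference_map(a, b).heights
        assert np.std(d) == pytest.approx(np.sqrt(2) * 0.01, rel=0.05)

    def test_lattice_mismatch_rejected(self, flat_map):
        other = DepthMap.flat(20.0, 0.5)
        with pytest.raises(GridError):
            difference_map(flat_map, other)


def analytic_annular_well(span=20.0, spacing=0.25, ring_radius=5.0, sigma=0.2,
                          depth=1.0, center=(0.0, 0.0)):
    base = DepthMap.flat(span, spacing)
    xs, ys = np.meshgrid(base.x_coords, base.y_coords)
    r = np.hypot(xs - center[0], ys - center[1])
    return DepthMap(depth * np.exp(-((r - ring_radius) ** 2) / (2 * sigma ** 2)),
                    base.origin_mm, spacing)


class TestExtractCraterContours:
    def test_analytic_annular_well_center_radius(self):
        diff = analytic_annular_well()
        craters = extract_crater_contours(diff, 0.5)
        radii = np.hypot(*craters.center.vertices.T)
        assert np.all(np.abs(radii - 5.0) <= 0.25)
        assert craters.inner is not None
        inner_r = np.hypot(*craters.inner.vertices.T)
        outer_r = np.hypot(*craters.outer.vertices.T)
        assert np.all(inner_r <= radii) and np.all(radii <= outer_r)

    def test_translation_equivariance(self):
        shift = (2.0, -3.0)  # a lattice multiple of the 0.25 mm spacing
        a = extract_crater_contours(analytic_annular_well(), 0.5)
        b = extract_crater_contours(analytic_annular_well(center=shift), 0.5)
        np.testing.assert_allclose(b.center.vertices - shift, a.center.vertices,
                                   atol=0.05)

    def test_center_contour_stable_across_threshold_fractions(self):
        """Symmetric radial profile: center radius invariant (+- lattice
        spacing) to the threshold fraction over [0.3, 0.8] and even at 0.99."""
        diff = analytic_annular_well()
        ref = np.hypot(*extract_crater_contours(diff, 0.5).center.vertices.T)
        for frac in (0.3, 0.45, 0.6, 0.8, 0.99):
            r = np.hypot(*extract_crater_contours(diff, frac).center.vertices.T)
            assert np.all(np.abs(r - ref) <= 0.25)

    def test_simply_connected_pit_has_empty_inner_contour(self):
        base = DepthMap.flat(10.0, 0.25)
        xs, ys = np.meshgrid(base.x_coords, base.y_coords)
        r = np.hypot(xs, ys)
        diff = DepthMap(np.exp(-(r ** 2) / (2 * 1.0 ** 2)), base.origin_mm, 0.25)
        craters = extract_crater_contours(diff, 0.5)
        assert craters.inner is None

    def test_no_removal_rejected(self):
        with pytest.raises(NoCraterError):
            extract_crater_contours(DepthMap.flat(5.0, 0.25), 0.5)

    def test_closed_loop_circle_recovery(self):
        """Ablate a known 5 mm circle, extract the center contour, recover the
        radius within max(lattice spacing, spot/4)."""
        pre = DepthMap.flat(20.0, 0.25)
        crater = CraterModel(spot_diameter_mm=0.8, depth_per_dwell_mm=0.5)
        post = simulate_ablation(pre, circle_path(radius=5.0), crater)
        craters = extract_crater_contours(difference_map(pre, post), 0.5)
        radii = np.hypot(*craters.center.vertices.T)
        tol = max(0.25, crater.sigma_mm)
        assert abs(radii.mean() - 5.0) <= tol
        assert np.all(np.abs(radii - 5.0) <= 2 * tol)
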