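"""Ground truth, contour error metrics and the replicate experiment runner.

Ground truth is a circle: its center is the centroid of the four fiducial
centers (recovered through the camera registration, exactly as the pipeline
sees them) and its radius is the CAD radius of the tumor mold post.  Two
error measurements compare measured contours against this circle by
nearest-point matching:

* TumorID error — the raw fluorescence-classified boundary P_ID-EDGE,
  isolating the diagnostic arm;
* system error — the crater-center contour P_POST recovered from the
  pre/post depth difference, scoring the executed cut end to end.

Both use RMSE = sqrt(mean ||p_i - q_i||^2) and Max Error = max ||p_i - q_i||
over the matched pairs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import ablation, boundary, phantom, registration, scanning
from .ablation import CraterContours, CraterModel, DepthMap
from .boundary import Contour, CutPath3D, NoTumorDetectedError
from .phantom import EmissionModel, PhantomSpec, TissueClass
from .registration import FrameTransform
from .scanning import ScanPlan


class MatchError(ValueError):
    """Cannot match against an empty contour."""


class DegenerateFiducialsError(ValueError):
    """Fiducial centers are collinear or too few."""


@dataclass(frozen=True)
class GroundTruth:
    """Fiducial-derived ground-truth circle (role Q_GT)."""

    center_mm: tuple[float, float]
    radius_mm: float
    contour: Contour


def ground_truth_contour(fiducial_centers_global, cad_radius_mm: float,
                         n_gt: int = 360) -> GroundTruth:
    """Ground-truth circle from registered fiducial centers and the CAD radius."""
    fids = np.atleast_2d(np.asarray(fiducial_centers_global, dtype=float))
    if len(fids) < 3:
        raise DegenerateFiducialsError("need >= 3 fiducials")
    centered = fids - fids.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateFiducialsError("fiducial centers are collinear")
    center = fids.mean(axis=0)
    ang = 2.0 * np.pi * np.arange(n_gt) / n_gt
    verts = center + cad_radius_mm * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return GroundTruth(center_mm=(float(center[0]), float(center[1])),
                       radius_mm=float(cad_radius_mm),
                       contour=Contour(verts))


def match_nearest(gt: GroundTruth, contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """For each ground-truth vertex q_i, the nearest measured vertex p_i.

    Returns (P, Q) with |P| = |Q| = number of ground-truth vertices.
    """
    if contour is None or len(contour) == 0:
        raise MatchError("cannot match an empty contour")
    q = gt.contour.vertices
    tree = cKDTree(contour.vertices)
    _, idx = tree.query(q)
    return contour.vertices[idx], q


def rmse(P, Q) -> float:
    """Root-mean-square of pairwise Euclidean distances."""
    P = np.atleast_2d(np.asarray(P, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    if P.shape != Q.shape or len(P) < 1:
        raise ValueError("P and Q must be equal-size non-empty point sets")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def max_error(P, Q) -> float:
    """Greatest pairwise Euclidean distance."""
    P = np.atleast_2d(np.asarray(P, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    if P.shape != Q.shape or len(P) < 1:
        raise ValueError("P and Q must be equal-size non-empty point sets")
    return float(np.max(np.sqrt(np.sum((P - Q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one simulated resection experiment.

    Defaults are the study conditions: a 27 mm spectroscopic raster at 1 mm
    pitch with a 0.75 mm excitation spot, a 0.25 mm distance scan, a
    0.80 mm cutting spot, and the calibrated noise levels (spectral cv
    0.05, 0.5 px centroid jitter at 0.1 mm/px, 0.01 mm surface roughness,
    phantom placement within +/-0.5 mm of the scan center).
    """

    # phantom / replicates
    tumor_diameters_mm: tuple[float, ...] = (7.5, 10.0, 12.5)
    replicates: int = 3
    # scan geometry
    spectral_span_mm: float = 27.0
    spectral_step_mm: float = 1.0
    spot_diameter_mm: float = 0.75
    distance_step_mm: float = 0.25
    # pipeline
    alpha_shrink: float = 0.5
    refine_grid_n: int = 150
    cut_pitch_mm: float = 0.25
    n_gt: int = 360
    fiducial_band_fraction: float = 0.6   # of the fiducial signature
    # ablation
    ablation_spot_mm: float = 0.80
    depth_per_dwell_mm: float = 0.5
    depth_threshold_fraction: float = 0.5
    # camera
    camera_scale_mm_per_px: float = 0.1
    camera_rotation_deg: float = 5.0
    camera_translation_mm: tuple[float, float] = (2.0, -1.0)
    # noise
    spectral_cv: float = 0.05
    jitter_sd_px: float = 0.5
    roughness_sd_mm: float = 0.01
    placement_jitter_mm: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "tumor_diameters_mm", tuple(self.tumor_diameters_mm))
        object.__setattr__(self, "camera_translation_mm", tuple(self.camera_translation_mm))

    def noise_free(self) -> "ExperimentConfig":
        return replace(self, spectral_cv=0.0, jitter_sd_px=0.0,
                       roughness_sd_mm=0.0, placement_jitter_mm=0.0)

    # -- YAML round trip (nested sections, human-editable) --------------
    _SECTIONS = {
        "phantom": ("tumor_diameters_mm", "replicates"),
        "scan": ("spectral_span_mm", "spectral_step_mm", "spot_diameter_mm",
                 "distance_step_mm"),
        "pipeline": ("alpha_shrink", "refine_grid_n", "cut_pitch_mm", "n_gt",
                     "fiducial_band_fraction"),
        "ablation": ("ablation_spot_mm", "depth_per_dwell_mm",
                     "depth_threshold_fraction"),
        "camera": ("camera_scale_mm_per_px", "camera_rotation_deg",
                   "camera_translation_mm"),
        "noise": ("spectral_cv", "jitter_sd_px", "roughness_sd_mm",
                  "placement_jitter_mm"),
    }

    def to_yaml(self) -> str:
        d = asdict(self)
        nested = {sec: {k: d[k] for k in keys} for sec, keys in self._SECTIONS.items()}
        for sec in nested:
            for k, v in nested[sec].items():
                if isinstance(v, tuple):
                    nested[sec][k] = list(v)
        return yaml.safe_dump(nested, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        nested = yaml.safe_load(text) or {}
        flat = {}
        for sec in nested.values():
            flat.update(sec)
        for k in ("tumor_diameters_mm", "camera_translation_mm"):
            if k in flat:
                flat[k] = tuple(flat[k])
        return cls(**flat)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# single replicate
# ---------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    """Errors and (optionally) intermediate artifacts of one simulated resection."""

    diameter_mm: float
    seed: int
    tumorid_rmse_mm: float
    tumorid_maxerr_mm: float
    system_rmse_mm: float | None
    system_maxerr_mm: float | None
    registration_residual_mm: float
    n_tumor_points: int
    artifacts: dict = field(default_factory=dict, repr=False)

    def row(self) -> dict:
        return {k: v for k, v in asdict(self).items() if k != "artifacts"}


def run_replicate(config: ExperimentConfig, diameter_mm: float, seed,
                  run_system: bool = True, keep_artifacts: bool = False,
                  ) -> ReplicateResult:
    """One full sense -> classify -> cut -> quantify cycle.

    ``seed`` may be an int or a numpy SeedSequence.  With ``run_system``
    False the distance scan / ablation stages are skipped (TumorID-only
    evaluation, much faster).
    """
    rng = np.random.default_rng(seed)
    seed_label = int(seed) if np.isscalar(seed) else int(rng.integers(2 ** 31))

    # --- phantom placement and construction
    off = rng.uniform(-config.placement_jitter_mm, config.placement_jitter_mm, 2) \
        if config.placement_jitter_mm > 0 else np.zeros(2)
    spec = PhantomSpec(tumor_center_mm=(float(off[0]), float(off[1])),
                       tumor_diameter_mm=float(diameter_mm), seed=seed_label)
    fld = phantom.build_phantom(spec)
    model = EmissionModel(noise_cv=config.spectral_cv)

    # --- TumorID spectral raster scan
    plan_id = ScanPlan(span_mm=config.spectral_span_mm, step_mm=config.spectral_step_mm)
    scan = scanning.acquire_spectral_scan(fld, model, plan_id,
                                          spot_diameter_mm=config.spot_diameter_mm,
                                          rng=rng if config.spectral_cv > 0 else None)

    # --- camera observation and fiducial registration into the global frame
    cam = FrameTransform(scale=config.camera_scale_mm_per_px,
                         rotation=np.deg2rad(config.camera_rotation_deg),
                         translation=config.camera_translation_mm)
    fids = np.asarray(spec.fiducial_centers_mm)
    obs_fid = registration.observe_in_camera(fids, cam, config.jitter_sd_px, rng)
    est_tf, resid = registration.estimate_transform(obs_fid.pixel_points, fids)
    obs_scan = registration.observe_in_camera(scan.positions_mm, cam,
                                              config.jitter_sd_px, rng)
    pid_global = registration.to_global(obs_scan, est_tf)
    fid_global = registration.to_global(obs_fid, est_tf)

    # --- ground truth from registered fiducials + CAD radius
    gt = ground_truth_contour(fid_global, diameter_mm / 2.0, config.n_gt)

    # --- classification and raw fluorescence boundary (P_ID-EDGE)
    fid_min = config.fiducial_band_fraction * model.fiducial_signature
    tissue = scan.peak_intensity[scan.peak_intensity < fid_min]
    thr = boundary.choose_threshold(tissue)
    labels = boundary.classify(scan.peak_intensity, thr, fiducial_min=fid_min)
    tumor_pts = pid_global[labels == TissueClass.TUMOR]
    if len(tumor_pts) < 3:
        raise NoTumorDetectedError(
            f"only {len(tumor_pts)} tumor-labeled points (diameter {diameter_mm} mm)")
    p_id_edge = boundary.alpha_boundary(tumor_pts, shrink=config.alpha_shrink,
                                        largest=True)
    P, Q = match_nearest(gt, p_id_edge)
    result = ReplicateResult(
        diameter_mm=diameter_mm, seed=seed_label,
        tumorid_rmse_mm=rmse(P, Q), tumorid_maxerr_mm=max_error(P, Q),
        system_rmse_mm=None, system_maxerr_mm=None,
        registration_residual_mm=resid, n_tumor_points=int(len(tumor_pts)),
    )
    if keep_artifacts:
        result.artifacts.update(
            spec=spec, scan=scan, threshold=thr, labels=labels,
            registered_positions=pid_global, true_positions=scan.positions_mm,
            p_id_edge=p_id_edge, ground_truth=gt, transform=est_tf)
    if not run_system:
        return result

    # --- distance scan, interior selection, mesh refinement, 3D lifting
    plan_cnc = ScanPlan(span_mm=config.spectral_span_mm, step_mm=config.distance_step_mm)
    cloud = scanning.acquire_distance_scan(
        fld, plan_cnc, roughness_sd_mm=config.roughness_sd_mm,
        rng=rng if config.roughness_sd_mm > 0 else None)
    interior = boundary.select_interior(cloud.projected, p_id_edge)
    refined, cut_path = boundary.refine_boundary(
        p_id_edge, interior, cloud, grid_n=config.refine_grid_n,
        resample_pitch_mm=config.cut_pitch_mm)

    # --- ablation: pre/post raster depth scans and crater extraction
    crater = CraterModel(spot_diameter_mm=config.ablation_spot_mm,
                         depth_per_dwell_mm=config.depth_per_dwell_mm)
    true_surface = DepthMap.flat(config.spectral_span_mm, config.distance_step_mm)
    ablated = ablation.simulate_ablation(true_surface, cut_path, crater)
    noisy = config.roughness_sd_mm > 0
    pre_scan = DepthMap.flat(config.spectral_span_mm, config.distance_step_mm,
                             roughness_sd_mm=config.roughness_sd_mm,
                             rng=rng if noisy else None)
    post_scan = DepthMap(
        heights=ablated.heights + (config.roughness_sd_mm
                                   * rng.standard_normal(ablated.heights.shape)
                                   if noisy else 0.0),
        origin_mm=ablated.origin_mm, spacing_mm=ablated.spacing_mm)
    diff = ablation.difference_map(pre_scan, post_scan)
    craters = ablation.extract_crater_contours(diff, config.depth_threshold_fraction)

    P, Q = match_nearest(gt, craters.center)
    result.system_rmse_mm = rmse(P, Q)
    result.system_maxerr_mm = max_error(P, Q)
    if keep_artifacts:
        result.artifacts.update(cloud=cloud, refined=refined, cut_path=cut_path,
                                diff_map=diff, craters=craters)
    return result


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Per-replicate error table with per-diameter aggregates and provenance."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: ExperimentConfig
    base_seed: int

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config.config_hash,
            "base_seed": self.base_seed,
            "replicates": self.replicates.to_dict(orient="records"),
            "summary": self.summary.reset_index().to_dict(orient="records"),
        }, indent=2)


_METRICS = ["tumorid_rmse_mm", "tumorid_maxerr_mm", "system_rmse_mm", "system_maxerr_mm"]


def run_experiment(config: ExperimentConfig, base_seed: int = 0,
                   progress: bool = False) -> ErrorReport:
    """Run the replicate grid: every tumor diameter x ``config.replicates`` seeds.

    Per-replicate seeds are spawned deterministically from ``base_seed``,
    so identical (config, base_seed) pairs reproduce the report bitwise.
    """
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(config.tumor_diameters_mm) * config.replicates)
    rows = []
    k = 0
    for d in config.tumor_diameters_mm:
        for rep in range(config.replicates):
            res = run_replicate(config, d, children[k])
            row = res.row()
            row["replicate"] = rep
            rows.append(row)
            if progress:
                print(f"  diameter {d:5.1f} mm  replicate {rep:3d}  "
                      f"system RMSE {res.system_rmse_mm:.3f} mm", flush=True)
            k += 1
    table = pd.DataFrame(rows)
    summary = table.groupby("diameter_mm")[_METRICS].agg(["mean", "std", "median"])
    for row in table.itertuples():
        assert row.tumorid_rmse_mm <= row.tumorid_maxerr_mm + 1e-12
        assert row.system_rmse_mm <= row.system_maxerr_mm + 1e-12
    return ErrorReport(replicates=table, summary=summary, config=config,
                       base_seed=base_seed)


def signed_radial_errors(gt: GroundTruth, contour: Contour) -> np.ndarray:
    """Signed radial error of each matched point (positive = outside ground truth)."""
    P, _ = match_nearest(gt, contour)
    c = np.asarray(gt.center_mm)
    return np.hypot(P[:, 0] - c[0], P[:, 1] - c[1]) - gt.radius_mm
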