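"""Unified-frame construction: camera observation and similarity registration.

Both laser streams are observed by a monocular camera looking straight down
at the flat phantom; the fiducial disks, visible in the same image, anchor a
4-DOF similarity transform (scale, rotation, translation) from pixel
coordinates into the surgical arm's global millimetre frame.  Real image
segmentation of laser spots is replaced here by synthetic centroids plus
Gaussian pixel jitter; the jitter models the residual centroid-localization
error of the segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UnderdeterminedError(ValueError):
    """Too few / degenerate correspondences to estimate a transform."""


@dataclass(frozen=True)
class FrameTransform:
    """Similarity transform mapping camera pixels to global millimetres.

    mm = scale * R(rotation) @ px + translation
    """

    scale: float                      # mm per pixel
    rotation: float                   # radians, counter-clockwise
    translation: tuple[float, float]  # mm

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "translation", tuple(self.translation))

    def _matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, pixel_points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pixel_points, dtype=float))
        return self.scale * pts @ self._matrix().T + np.asarray(self.translation)

    def apply_inverse(self, mm_points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(mm_points, dtype=float))
        return (pts - np.asarray(self.translation)) @ self._matrix() / self.scale

    @property
    def inverse(self) -> "FrameTransform":
        R_inv = self._matrix().T
        t = -R_inv @ np.asarray(self.translation) / self.scale
        return FrameTransform(scale=1.0 / self.scale, rotation=-self.rotation,
                              translation=(t[0], t[1]))


@dataclass(frozen=True)
class CameraObservation:
    """Laser-centroid pixel coordinates as segmented from a camera frame."""

    pixel_points: np.ndarray
    jitter_sd_px: float = 0.0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.pixel_points, dtype=float))
        if not np.all(np.isfinite(pts)):
            raise ValueError("pixel coordinates must be finite")
        object.__setattr__(self, "pixel_points", pts)


def project_to_plane(points_3d) -> np.ndarray:
    """Z-drop projection (x, y, z) -> (x, y)."""
    pts = np.asarray(points_3d, dtype=float)
    return pts[..., :2]


def observe_in_camera(points_mm, transform: FrameTransform, jitter_sd_px: float = 0.0,
                      rng: np.random.Generator | None = None) -> CameraObservation:
    """Synthetic camera view of global-frame points: inverse transform + pixel jitter."""
    px = transform.apply_inverse(points_mm)
    if rng is not None and jitter_sd_px > 0:
        px = px + jitter_sd_px * rng.standard_normal(px.shape)
    return CameraObservation(pixel_points=px, jitter_sd_px=jitter_sd_px)


def estimate_transform(pixel_fiducials, global_fiducials) -> tuple[FrameTransform, float]:
    """Closed-form least-squares similarity fit over ordered correspondences.

    Returns the transform minimizing the sum of squared mm residuals
    (Procrustes / Umeyama solution without reflection) and the residual RMS
    in mm.  Raises :class:`UnderdeterminedError` for fewer than two distinct
    points.
    """
    p = np.atleast_2d(np.asarray(pixel_fiducials, dtype=float))
    q = np.atleast_2d(np.asarray(global_fiducials, dtype=float))
    if p.shape != q.shape or p.shape[0] < 2:
        raise UnderdeterminedError("need >= 2 ordered correspondences")
    mu_p, mu_q = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - mu_p, q - mu_q
    var_p = (pc ** 2).sum() / len(p)
    if var_p < 1e-24:
        raise UnderdeterminedError("pixel fiducials are coincident")
    cov = qc.T @ pc / len(p)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U @ Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S) / var_p)
    t = mu_q - scale * R @ mu_p
    tf = FrameTransform(scale=scale, rotation=float(np.arctan2(R[1, 0], R[0, 0])),
                        translation=(float(t[0]), float(t[1])))
    resid = tf.apply(p) - q
    return tf, float(np.sqrt((resid ** 2).sum(axis=1).mean()))


def to_global(observation: CameraObservation, transform: FrameTransform) -> np.ndarray:
    """Register camera pixel points into the global mm frame."""
    return transform.apply(observation.pixel_points)
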