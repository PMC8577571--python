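"""Figure-style plots: classified scan panels, difference maps, error boxes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ablation import CraterContours, DepthMap
from .boundary import Contour
from .evaluation import ErrorReport, GroundTruth
from .phantom import TissueClass


def plot_classified_scan(positions, labels, raw_boundary: Contour | None = None,
                         refined: Contour | None = None, ax=None):
    """Classified raster points with the raw and refined boundaries overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    positions = np.asarray(positions)
    labels = np.asarray(labels)
    colors = {TissueClass.HEALTHY: "#c9b47c", TissueClass.TUMOR: "#6a3d9a",
              TissueClass.FIDUCIAL: "#e31a1c"}
    for cls, col in colors.items():
        m = labels == cls
        ax.scatter(positions[m, 0], positions[m, 1], s=8, c=col, label=cls.name.lower())
    for contour, style, name in ((raw_boundary, "b-", "raw boundary"),
                                 (refined, "g-", "cut path")):
        if contour is not None:
            v = np.vstack([contour.vertices, contour.vertices[:1]])
            ax.plot(v[:, 0], v[:, 1], style, lw=1.5, label=name)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.legend(fontsize=7)
    return ax


def plot_difference_map(diff: DepthMap, gt: GroundTruth | None = None,
                        craters: CraterContours | None = None, ax=None):
    """Depth-of-change image with ground-truth and cutting-center contours."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = diff.x_coords, diff.y_coords
    im = ax.imshow(diff.heights, origin="lower", cmap="viridis",
                   extent=(x[0], x[-1], y[0], y[-1]))
    plt.colorbar(im, ax=ax, label="depth of change (mm)")
    if gt is not None:
        v = np.vstack([gt.contour.vertices, gt.contour.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], "y-", lw=1.5, label="ground truth")
    if craters is not None:
        v = np.vstack([craters.center.vertices, craters.center.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], "r-", lw=1.5, label="cutting center")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.legend(fontsize=7)
    return ax


def plot_error_boxes(report: ErrorReport, metric: str = "system_rmse_mm", ax=None):
    """Per-diameter box plot of a replicate error metric."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = [g[metric].dropna().to_numpy()
              for _, g in report.replicates.groupby("diameter_mm")]
    labels = [f"{d:g}" for d in sorted(report.replicates["diameter_mm"].unique())]
    ax.boxplot(groups, tick_labels=labels)
    ax.set_xlabel("tumor diameter (mm)")
    ax.set_ylabel(metric.replace("_", " "))
    return ax
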