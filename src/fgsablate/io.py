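"""Plain-text and raster I/O: specs (YAML), scans/contours (CSV), depth maps (TIFF)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ablation import DepthMap
from .boundary import Contour
from .phantom import PhantomField, PhantomSpec, rasterize_classes
from .scanning import SpectralScan, SurfacePointCloud


# -- phantom spec -----------------------------------------------------------

def write_phantom_spec(spec: PhantomSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def read_phantom_spec(path) -> PhantomSpec:
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_class_raster(field: PhantomField, path, resolution_mm: float = 0.1) -> None:
    """8-bit labeled raster of the phantom class map (0 healthy, 1 tumor, 2 fiducial)."""
    tifffile.imwrite(str(path), rasterize_classes(field, resolution_mm))


# -- scans ------------------------------------------------------------------

def write_spectral_scan(scan: SpectralScan, path) -> None:
    pd.DataFrame({
        "x_mm": scan.positions_mm[:, 0],
        "y_mm": scan.positions_mm[:, 1],
        "intensity": scan.peak_intensity,
        "cycle": scan.cycle_index,
        "clipped": scan.clipped.astype(int),
    }).to_csv(path, index=False)


def read_spectral_scan(path, spot_diameter_mm: float = 0.0) -> SpectralScan:
    df = pd.read_csv(path)
    return SpectralScan(
        positions_mm=df[["x_mm", "y_mm"]].to_numpy(),
        peak_intensity=df["intensity"].to_numpy(),
        cycle_index=df["cycle"].to_numpy(),
        clipped=df["clipped"].to_numpy().astype(bool),
        spot_diameter_mm=spot_diameter_mm,
    )


def write_point_cloud(cloud: SurfacePointCloud, path) -> None:
    # index order is load-bearing: the 2D/3D index pairing lifts the cut path
    pd.DataFrame(cloud.points_mm, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def read_point_cloud(path, step_mm: float) -> SurfacePointCloud:
    df = pd.read_csv(path)
    return SurfacePointCloud(points_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                             step_mm=step_mm)


# -- contours ---------------------------------------------------------------

def write_contour(contour: Contour, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# closed: {str(contour.closed).lower()}\n")
        fh.write("x_mm,y_mm\n")
        for x, y in contour.vertices:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_contour(path) -> Contour:
    text = Path(path).read_text().splitlines()
    closed = text[0].split(":")[1].strip() == "true"
    df = pd.read_csv(path, comment="#")
    return Contour(vertices=df[["x_mm", "y_mm"]].to_numpy(), closed=closed)


# -- depth maps -------------------------------------------------------------

def write_depth_map(dm: DepthMap, path) -> None:
    """32-bit float TIFF plus a JSON sidecar carrying world coordinates."""
    path = Path(path)
    tifffile.imwrite(str(path), dm.heights.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"origin_mm": list(dm.origin_mm),
                                   "spacing_mm": dm.spacing_mm}))


def read_depth_map(path) -> DepthMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DepthMap(heights=tifffile.imread(str(path)).astype(float),
                    origin_mm=tuple(meta["origin_mm"]), spacing_mm=meta["spacing_mm"])
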