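"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: gift-wrapping
for convex hulls, winding numbers for point-in-polygon, dense quadrature
for spot averaging, and direct Gaussian summation for crater depth.
"""

import numpy as np


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull by gift wrapping; returns hull vertices in CCW order."""
    pts = np.asarray(points, float)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    return pts[hull]


def winding_inside(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Point-in-polygon by winding number; on-edge points count as inside."""
    pts = np.atleast_2d(points)
    poly = np.asarray(polygon, float)
    a = poly
    b = np.roll(poly, -1, axis=0)
    inside = np.zeros(len(pts), dtype=bool)
    for k, p in enumerate(pts):
        d1 = a - p
        d2 = b - p
        cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        dot = (d1 * d2).sum(axis=1)
        seg_len2 = ((b - a) ** 2).sum(axis=1)
        t = ((p - a) * (b - a)).sum(axis=1) / np.where(seg_len2 == 0, 1, seg_len2)
        proj = a + t[:, None].clip(0, 1) * (b - a)
        if np.min(((proj - p) ** 2).sum(axis=1)) < 1e-18:
            inside[k] = True  # on an edge
            continue
        angles = np.arctan2(cross, dot)
        inside[k] = abs(angles.sum()) > np.pi  # winding number != 0
    return inside


def dense_disk_average(fn, center, radius, n=400):
    """Area-average of fn(points) over a disk by dense rejection sampling grid."""
    u = (np.arange(n) + 0.5) / n * 2 - 1
    xx, yy = np.meshgrid(u, u)
    m = xx ** 2 + yy ** 2 <= 1.0
    pts = np.stack([center[0] + radius * xx[m], center[1] + radius * yy[m]], axis=-1)
    return float(np.mean(fn(pts)))


def gaussian_ring_depth(angles, ring_radius, pitch, sigma, depth):
    """Depth on the ring itself from summing Gaussian wells placed along it."""
    m = int(round(2 * np.pi * ring_radius / pitch))
    th = 2 * np.pi * np.arange(m) / m
    wells = ring_radius * np.stack([np.cos(th), np.sin(th)], axis=-1)
    eval_pts = ring_radius * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    d2 = ((eval_pts[:, None, :] - wells[None, :, :]) ** 2).sum(axis=-1)
    return depth * np.exp(-d2 / (2 * sigma ** 2)).sum(axis=1)
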