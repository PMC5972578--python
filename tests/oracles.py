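"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure-Python loops, direct formulas) kept
separate from the library code paths they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def point_on_segment(px, py, ax, ay, bx, by, tol=1e-9) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    seg_len = math.hypot(bx - ax, by - ay)
    if seg_len == 0:
        return math.hypot(px - ax, py - ay) <= tol
    if abs(cross) / seg_len > tol:
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    return -tol * seg_len <= dot <= seg_len ** 2 + tol * seg_len


def point_in_polygon(px: float, py: float, verts_xy: np.ndarray) -> bool:
    """Boundary-inclusive point-in-polygon by ray crossing."""
    verts = np.asarray(verts_xy, dtype=float)
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if point_on_segment(px, py, ax, ay, bx, by):
            return True
    inside = False
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def rasterise_polygon(verts_rowcol: np.ndarray, shape) -> np.ndarray:
    """Brute-force pixel-centre rasterisation (row, col vertices)."""
    verts_xy = np.asarray(verts_rowcol, dtype=float)[:, ::-1]
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            out[r, c] = point_in_polygon(c, r, verts_xy)
    return out


def gaussian_argmax(pixels: np.ndarray, means, covs, priors) -> np.ndarray:
    """Per-pixel ML class by direct log-density evaluation (first max wins)."""
    x = np.atleast_2d(np.asarray(pixels, dtype=float))
    n_classes = len(means)
    scores = np.empty((len(x), n_classes))
    for k in range(n_classes):
        cov = np.asarray(covs[k], dtype=float)
        inv = np.linalg.inv(cov)
        sign, logdet = np.linalg.slogdet(cov)
        assert sign > 0
        for i, xi in enumerate(x):
            d = xi - means[k]
            scores[i, k] = math.log(priors[k]) - 0.5 * logdet - 0.5 * d @ inv @ d
    return np.argmax(scores, axis=1)


def flood_fill_components(mask: np.ndarray, min_px: int = 1) -> list[dict]:
    """8-connected components by BFS; returns area and centroid per blob."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            pix = []
            while queue:
                r, c = queue.popleft()
                pix.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            if len(pix) >= min_px:
                arr = np.array(pix, dtype=float)
                comps.append({"area_px": len(pix),
                              "centroid": tuple(arr.mean(axis=0))})
    return comps


def point_to_segment_distance(px, py, ax, ay, bx, by) -> float:
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        return math.hypot(px - ax, py - ay)
    t = max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / seg2))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def point_to_polygon_distance(px, py, verts_xy: np.ndarray) -> float:
    """Minimum distance from a point to a closed polygon's boundary."""
    verts = np.asarray(verts_xy, dtype=float)
    n = len(verts)
    return min(point_to_segment_distance(px, py, *verts[i], *verts[(i + 1) % n])
               for i in range(n))


def brute_force_edt(region: np.ndarray) -> np.ndarray:
    """Distance from each true pixel to the nearest background pixel centre,
    with the canvas border (a virtual ring of background) included."""
    region = np.asarray(region, dtype=bool)
    h, w = region.shape
    bg = [(r, c) for r in range(-1, h + 1) for c in range(-1, w + 1)
          if not (0 <= r < h and 0 <= c < w) or not region[r, c]]
    bg = np.array(bg, dtype=float)
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if region[r, c]:
                out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1)).min()
    return out


def ols_slope(x, y) -> float:
    """Closed-form least-squares slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc ** 2).sum())


def random_star_polygon(rng: np.random.Generator, n_verts: int = 8,
                        centre=(16.0, 16.0), r_min=3.0, r_max=13.0) -> np.ndarray:
    """A random simple (star-shaped) polygon as (row, col) vertices."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_verts))
    radii = rng.uniform(r_min, r_max, n_verts)
    rows = centre[0] + radii * np.sin(angles)
    cols = centre[1] + radii * np.cos(angles)
    return np.column_stack([rows, cols])
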