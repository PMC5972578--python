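"""Individual protein-body extraction: areas, midpoints and outline distances.

Bodies are 8-connected components of the classified protein raster.  Each
body's midpoint is the pixel centroid of its component, and its distance is
the shortest Euclidean distance from that midpoint to the endosperm outline
polygon, reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from skimage import measure

from .imgio import HISTOGRAM_COLUMNS, EndospermMask
from .mlclassify import ProteinMask
from .zonegrad import ZonePartition

DEFAULT_MIN_AREA_PX = 4


@dataclass
class ProteinBody:
    """One connected stained deposit of storage protein.

    ``area`` is in square micrometres; ``midpoint`` in (row, col) pixel
    coordinates; ``distance`` (micrometres, shortest point-to-outline) and
    ``zone`` are filled in by :func:`body_distances`.
    """

    body_id: int
    area: float
    midpoint: tuple[float, float]
    area_px: int = 0
    distance: float | None = None
    zone: int | None = None


def extract_bodies(protein: ProteinMask, scale: float,
                   min_area_px: int = DEFAULT_MIN_AREA_PX) -> list[ProteinBody]:
    """Label 8-connected protein components and measure area and centroid.

    Components smaller than ``min_area_px`` pixels are discarded
    (``min_area_px=1`` keeps everything, including single-pixel specks).
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    labels = measure.label(protein.protein, connectivity=2)
    bodies = []
    for prop in measure.regionprops(labels):
        if prop.num_pixels < min_area_px:
            continue
        bodies.append(ProteinBody(
            body_id=len(bodies) + 1,
            area=float(prop.num_pixels) * scale ** 2,
            area_px=int(prop.num_pixels),
            midpoint=(float(prop.centroid[0]), float(prop.centroid[1])),
        ))
    return bodies


def body_distances(bodies: list[ProteinBody], mask: EndospermMask,
                   scale: float,
                   partition: ZonePartition | None = None) -> list[ProteinBody]:
    """Shortest Euclidean midpoint-to-outline distance for each body.

    The distance is the minimum over the outline polygon's segments,
    converted to micrometres.  When a zone partition is given, each body is
    also assigned the concentric zone its midpoint distance falls in.
    Midpoints must lie inside the endosperm region.
    """
    if not bodies:
        return bodies
    rows = np.array([b.midpoint[0] for b in bodies])
    cols = np.array([b.midpoint[1] for b in bodies])
    ir = np.clip(np.round(rows).astype(int), 0, mask.shape[0] - 1)
    ic = np.clip(np.round(cols).astype(int), 0, mask.shape[1] - 1)
    if not mask.region[ir, ic].all():
        bad = int(np.flatnonzero(~mask.region[ir, ic])[0])
        raise ValueError(
            f"body {bodies[bad].body_id} midpoint lies outside the endosperm mask")
    boundary = mask.polygon().exterior
    shapely.prepare(boundary)
    pts = shapely.points(cols, rows)  # (x, y)
    d_px = shapely.distance(boundary, pts)
    for b, d in zip(bodies, d_px):
        b.distance = float(d) * scale
        if partition is not None:
            b.zone = int(min(partition.K,
                             np.floor(d / partition.band_width) + 1))
            b.zone = max(b.zone, 1)
    return bodies


def default_bin_edges(bodies: list[ProteinBody], n_bins: int = 12) -> np.ndarray:
    """Log-spaced size bins spanning the observed body-area range.

    Protein-body sizes are heavily right-skewed (many small bodies, few large
    ones), so log spacing resolves the bulk without losing the tail.
    """
    areas = np.array([b.area for b in bodies])
    lo, hi = areas.min(), areas.max()
    if lo == hi:
        lo, hi = lo * 0.5, hi * 2.0
    return np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)


def body_size_histograms(bodies: list[ProteinBody], K: int,
                         bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Counts of bodies per (zone, size-bin); zones from body midpoints.

    Returns a tidy table with one row per zone x bin.  Bin intervals are
    half-open ``[low, high)`` with the top edge inclusive.
    """
    if bin_edges is None:
        if not bodies:
            raise ValueError("cannot derive bins from an empty body list")
        bin_edges = default_bin_edges(bodies)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 2:
        raise ValueError("at least one bin (two edges) is required")
    if not (np.diff(bin_edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    for k in range(1, K + 1):
        areas = np.array([b.area for b in bodies if b.zone == k])
        counts, _ = np.histogram(areas, bins=bin_edges)
        for i in range(len(bin_edges) - 1):
            rows.append({"zone": k, "bin_low": bin_edges[i],
                         "bin_high": bin_edges[i + 1], "count": int(counts[i])})
    return pd.DataFrame(rows, columns=HISTOGRAM_COLUMNS)


def bodies_to_frame(bodies: list[ProteinBody], section_id: str = "",
                    replicate_id: int = 1) -> pd.DataFrame:
    """Tidy per-body table (one row per protein body)."""
    return pd.DataFrame([{
        "section_id": section_id,
        "replicate_id": replicate_id,
        "body_id": b.body_id,
        "area_um2": b.area,
        "midpoint_row": b.midpoint[0],
        "midpoint_col": b.midpoint[1],
        "distance_um": b.distance,
        "zone": b.zone,
    } for b in bodies])
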