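"""Image, outline, ROI and table input/output.

All raster coordinates are (row, col), 0-based, with pixel centres at integer
coordinates.  Polygon vertices live in the same frame; on disk they are stored
as ``[x, y] = [col, row]`` pairs (the convention of most image annotation
tools).  Physical scale is micrometres per pixel and must always be supplied
explicitly — it is never guessed from image metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from skimage import measure


class ImageFormatError(ValueError):
    """Raised when an input image or mask violates a precondition."""


# ---------------------------------------------------------------------------
# Section images
# ---------------------------------------------------------------------------

@dataclass
class SectionImage:
    """An RGB micrograph of a stained grain section with its physical scale.

    Parameters
    ----------
    pixels:
        ``H x W x 3`` uint8 raster, 0–255 per channel.
    scale:
        Micrometres per pixel (> 0).
    id:
        Free-text section identifier.
    """

    pixels: np.ndarray
    scale: float
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError("non-RGB image: expected an H x W x 3 raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImageFormatError("empty image")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ImageFormatError("pixel values must be integer (0-255)")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def load_section(image_path: str | Path, scale: float, id: str | None = None) -> SectionImage:
    """Read a TIFF/PNG micrograph and attach its micrometre-per-pixel scale."""
    path = Path(image_path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"non-RGB image: {path} has shape {arr.shape}")
    return SectionImage(pixels=np.ascontiguousarray(arr, dtype=np.uint8),
                        scale=float(scale),
                        id=id if id is not None else path.stem)


def write_section(image: SectionImage, path: str | Path) -> None:
    """Write the raster to PNG or TIFF (lossless; round-trips byte-identically)."""
    iio.imwrite(Path(path), image.pixels)


# ---------------------------------------------------------------------------
# Endosperm masks
# ---------------------------------------------------------------------------

@dataclass
class EndospermMask:
    """The endosperm region enclosed by the manually drawn outline.

    ``region`` is a boolean raster (True = inside the outline); ``outline`` is
    the ordered closed polygon, an ``(N, 2)`` array of (row, col) vertices.
    The region is a single connected component and equals the rasterisation of
    the outline under the pixel-centre-inside rule (centres exactly on an edge
    count as inside).
    """

    region: np.ndarray
    outline: np.ndarray
    _polygon: shapely.Polygon | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        self.outline = np.asarray(self.outline, dtype=float)
        if self.region.ndim != 2:
            raise ImageFormatError("mask region must be a 2-D raster")
        if not self.region.any():
            raise ImageFormatError("empty region")
        n_comp = ndimage.label(self.region, structure=np.ones((3, 3)))[1]
        if n_comp != 1:
            raise ImageFormatError(f"disconnected region: {n_comp} components")

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape

    @property
    def area_px(self) -> int:
        return int(self.region.sum())

    def polygon(self) -> shapely.Polygon:
        """The outline as a shapely polygon in (x=col, y=row) coordinates."""
        if self._polygon is None:
            xy = self.outline[:, ::-1]
            self._polygon = shapely.Polygon(xy)
        return self._polygon


def polygon_to_region(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a closed polygon under the pixel-centre-inside rule.

    A pixel is inside iff its centre lies inside the polygon or exactly on its
    boundary.  ``vertices`` are (row, col) pairs.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    poly = shapely.Polygon(verts[:, ::-1])  # (x, y)
    if poly.is_empty or poly.area == 0:
        raise ImageFormatError("empty region: degenerate polygon")
    shapely.prepare(poly)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    return inside.reshape(h, w)


def mask_from_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> EndospermMask:
    region = polygon_to_region(vertices, shape)
    if not region.any():
        raise ImageFormatError("empty region: polygon encloses no pixel centre")
    return EndospermMask(region=region, outline=np.asarray(vertices, dtype=float))


def mask_from_label_image(label: np.ndarray) -> EndospermMask:
    """Build an EndospermMask from a 0/255 label raster.

    The outline polygon is traced by marching squares at the 0.5 level, so
    that it passes midway between foreground and background pixel centres and
    rasterises back to exactly the labelled region.  Regions with internal
    holes are rejected.
    """
    region = np.asarray(label) > 127
    if not region.any():
        raise ImageFormatError("empty region")
    n_comp = ndimage.label(region, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise ImageFormatError(f"disconnected region: {n_comp} components")
    filled = ndimage.binary_fill_holes(region)
    if filled.sum() != region.sum():
        raise ImageFormatError("region has internal holes; outline is ambiguous")
    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    if len(contours) != 1:
        raise ImageFormatError("could not trace a single outline for the region")
    outline = contours[0] - 1.0  # undo padding; (row, col) vertices
    return EndospermMask(region=region, outline=outline)


def load_mask(mask_path: str | Path, shape: tuple[int, int]) -> EndospermMask:
    """Load an endosperm mask from a polygon JSON or a 0/255 label image.

    Polygon files are JSON objects ``{"vertices_xy": [[x, y], ...]}``.  Label
    images must match ``shape`` exactly.
    """
    path = Path(mask_path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        verts_xy = np.asarray(data["vertices_xy"], dtype=float)
        mask = mask_from_polygon(verts_xy[:, ::-1], shape)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
        if arr.shape != tuple(shape):
            raise ImageFormatError(
                f"shape mismatch: mask {arr.shape} vs image {tuple(shape)}")
        mask = mask_from_label_image(arr)
    if mask.shape != tuple(shape):
        raise ImageFormatError(
            f"shape mismatch: mask {mask.shape} vs image {tuple(shape)}")
    return mask


def save_mask_polygon(mask: EndospermMask, path: str | Path) -> None:
    verts_xy = mask.outline[:, ::-1].tolist()
    Path(path).write_text(json.dumps({"vertices_xy": verts_xy}))


# ---------------------------------------------------------------------------
# Training ROIs
# ---------------------------------------------------------------------------

def load_rois(path: str | Path) -> list[dict]:
    """Read replicated training ROIs.

    The file is JSON: a list of replicates, each
    ``{"replicate_id": int, "rois": [{"label": str, "vertices_xy": [[x,y],...]}]}``.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return data


def save_rois(replicates: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(replicates))


def extract_roi_pixels(image: SectionImage, vertices_xy: np.ndarray) -> np.ndarray:
    """RGB samples (n, 3) at pixel centres covered by an ROI polygon."""
    verts = np.asarray(vertices_xy, dtype=float)[:, ::-1]  # -> (row, col)
    region = polygon_to_region(verts, image.shape)
    return image.pixels[region].astype(float)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

PER_ZONE_COLUMNS = ["section_id", "replicate_id", "zone", "mid_distance_um",
                    "zone_area_um2", "protein_area_um2", "raw_fraction"]
PER_BODY_COLUMNS = ["section_id", "replicate_id", "body_id", "area_um2",
                    "midpoint_row", "midpoint_col", "distance_um", "zone"]
HISTOGRAM_COLUMNS = ["zone", "bin_low", "bin_high", "count"]
CALIBRATION_COLUMNS = ["group", "nitrogen_pct", "n_to_protein",
                       "image_protein_fraction", "conversion_factor"]

_SCHEMAS = {
    "per_zone": PER_ZONE_COLUMNS,
    "per_body": PER_BODY_COLUMNS,
    "histogram": HISTOGRAM_COLUMNS,
    "calibration": CALIBRATION_COLUMNS,
}


def validate_table(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Check a result table against its fixed column schema."""
    expected = _SCHEMAS[kind]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns {missing}")
    if table[expected].isna().any().any():
        raise ValueError(f"{kind} table has missing values in key columns")
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 CSV ('.' decimal, 12 significant digits)."""
    table.to_csv(Path(path), index=False, float_format="%.12g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), encoding="utf-8")
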