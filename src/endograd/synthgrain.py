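"""Synthetic stained grain sections with exact ground truth.

Real micrographs of Naphthol-Blue-Black-stained sections come with no pixel
ground truth, so every stage of the measurement pipeline is exercised here on
generated sections instead: a two-lobed endosperm outline with a crease
indentation (the cross-section geometry of a wheat grain), protein bodies
placed by an inhomogeneous hard-core point process whose coverage follows a
programmed linear outer-to-inner gradient, body areas drawn log-normally with
a distance-dependent log-mean, and per-pixel Gaussian RGB stain/background
noise.  Rendering uses hard pixel membership (no anti-aliasing), so
ground-truth areas are exact pixel counts, and a one-pixel separation guard
keeps placed bodies distinct under 8-connectivity; ground truth is still
re-extracted from the rendered raster, so any merging would be reflected
honestly.  A fixed seed makes every artifact byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree

from . import bodymetrics, gradstats
from .bodymetrics import ProteinBody
from .imgio import EndospermMask, SectionImage, extract_roi_pixels, mask_from_polygon
from .mlclassify import ProteinMask, TrainingSet, classify_replicates, replicate_agreement
from .zonegrad import ZonePartition, distance_to_outline, make_zones, measure_zones


@dataclass
class SynthConfig:
    """Study conditions for one synthetic section.

    Geometry is in pixels, gradients in per-micrometre units.  The programmed
    protein coverage at inward distance d (um) is
    ``fraction_intercept + fraction_slope * d`` and the body-area law is
    ``ln area ~ Normal(size_log_intercept + size_log_slope * d, size_log_sd)``
    (area in um^2).  ``density_gradient`` optionally overrides the placement
    intensity directly as (intercept, slope) bodies per um^2 per um.
    """

    canvas: tuple[int, int] = (1000, 1500)
    scale: float = 1.0
    lobe_radius: float = 400.0
    lobe_offset: float = 310.0      # half-distance between lobe centres (px)
    crease_depth: float = 260.0     # how far the crease cuts in from the top (px)
    crease_width: float = 90.0      # crease opening at the outline (px)
    K: int = 5
    fraction_intercept: float = 0.14
    fraction_slope: float = -1.5e-4
    size_log_intercept: float = math.log(40.0)
    size_log_slope: float = -0.0012
    size_log_sd: float = 0.45
    density_gradient: tuple[float, float] | None = None
    stain_color: tuple[float, float, float] = (45.0, 45.0, 90.0)
    stain_sd: float = 12.0
    background_color: tuple[float, float, float] = (205.0, 195.0, 185.0)
    background_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stain_sd < 0 or self.background_sd < 0 or self.size_log_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


#: treatment-analogue parameter sets: steeper negative gradients under the
#: high-temperature analogue, shallower under the low-nitrogen analogue
PRESETS: dict[str, dict] = {
    "control": dict(fraction_intercept=0.14, fraction_slope=-1.5e-4,
                    size_log_intercept=math.log(40.0), size_log_slope=-0.0012),
    "high-temperature": dict(fraction_intercept=0.18, fraction_slope=-3.0e-4,
                             size_log_intercept=math.log(45.0),
                             size_log_slope=-0.0024),
    "low-nitrogen": dict(fraction_intercept=0.11, fraction_slope=-1.0e-4,
                         size_log_intercept=math.log(36.0),
                         size_log_slope=-0.0008),
}


def preset_config(name: str, **overrides) -> SynthConfig:
    """A SynthConfig for one of the named treatment analogues."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset '{name}'; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@dataclass
class GroundTruth:
    """Exact truth for a generated section.

    ``bodies`` carry exact pixel areas, centroids, outline distances and
    zones; ``per_zone_fraction`` is the realised protein area fraction of
    each concentric zone measured on the truth raster.
    """

    bodies: list[ProteinBody]
    per_zone_fraction: np.ndarray
    zone_mid_distance_um: np.ndarray
    protein: ProteinMask
    partition: ZonePartition
    config: SynthConfig = field(repr=False, default=None)


def grain_outline(config: SynthConfig) -> np.ndarray:
    """Two-lobed closed outline with a crease notch, as (row, col) vertices.

    Union of two circles (the lobes) minus a tapering wedge cut downward
    from the top edge (the crease), simplified to a manageable vertex count.
    """
    h, w = config.canvas
    cy = h / 2 + 0.08 * h            # lobes sit slightly low: crease at top
    cx = w / 2
    r = config.lobe_radius
    left = shapely.Point(cx - config.lobe_offset, cy).buffer(r, quad_segs=64)
    right = shapely.Point(cx + config.lobe_offset, cy).buffer(r, quad_segs=64)
    grain = left.union(right)
    top = grain.bounds[1]
    wedge = shapely.Polygon([
        (cx - config.crease_width / 2, top - 2),
        (cx + config.crease_width / 2, top - 2),
        (cx + 0.1 * config.crease_width, top + config.crease_depth),
        (cx - 0.1 * config.crease_width, top + config.crease_depth),
    ])
    grain = grain.difference(wedge).simplify(0.5)
    xy = np.asarray(grain.exterior.coords)
    verts = xy[:, ::-1]  # (row, col)
    if verts[:, 0].min() < 1 or verts[:, 0].max() > h - 2 \
            or verts[:, 1].min() < 1 or verts[:, 1].max() > w - 2:
        raise ValueError("grain outline does not fit the canvas; "
                         "shrink lobe_radius/lobe_offset or enlarge canvas")
    return verts


def _render_ellipse(r0: float, c0: float, area_px: float, ratio: float,
                    theta: float, shape: tuple[int, int]):
    """Pixel-centre membership of an ellipse; returns (rows, cols) indices."""
    a = math.sqrt(area_px * ratio / math.pi)
    b = math.sqrt(area_px / (ratio * math.pi))
    rmin = max(int(math.floor(r0 - a)), 0)
    rmax = min(int(math.ceil(r0 + a)), shape[0] - 1)
    cmin = max(int(math.floor(c0 - a)), 0)
    cmax = min(int(math.ceil(c0 + a)), shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        return np.array([], dtype=int), np.array([], dtype=int)
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    dy = rr - r0
    dx = cc - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    return rr[inside], cc[inside]


def generate_section(config: SynthConfig
                     ) -> tuple[SectionImage, EndospermMask, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Bodies are proposed zone by zone until each zone's programmed coverage
    target is met; a proposal is rejected if its (one-pixel-dilated)
    footprint touches an already placed body, so rendered components map
    one-to-one onto placed bodies.  The same seed always yields byte-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    outline = grain_outline(config)
    mask = mask_from_polygon(outline, config.canvas)
    dist = distance_to_outline(mask)
    partition = make_zones(mask, config.K)
    d_um = dist * config.scale

    # programmed coverage per pixel
    if config.density_gradient is not None:
        lam0, lam1 = config.density_gradient
        mean_area = np.exp(config.size_log_intercept + config.size_log_slope * d_um
                           + 0.5 * config.size_log_sd ** 2)
        frac = (lam0 + lam1 * d_um) * mean_area
    else:
        frac = config.fraction_intercept + config.fraction_slope * d_um
    inside = mask.region
    lo = frac[inside].min()
    if lo < 0 or (config.density_gradient is None and lo <= 0) \
            or frac[inside].max() >= 1:
        raise ValueError("programmed per-zone fractions fall outside (0, 1)")

    occupancy = np.zeros(config.canvas, dtype=bool)
    struct = np.ones((3, 3), dtype=bool)
    shape = config.canvas
    zones = partition.zone_of_pixel
    # pixels are credited to the zone they actually land in, so bodies that
    # straddle a band boundary do not inflate their seed zone; zones are
    # filled outermost-first so inward spill is compensated
    placed_in = np.zeros(config.K + 1)
    for k in range(1, config.K + 1):
        zone_px = partition.zone_region(k)
        idx_r, idx_c = np.nonzero(zone_px)
        target = float(frac[zone_px].sum())
        if target < 1.0:  # below one pixel of coverage: nothing to render
            continue
        while placed_in[k] < target:
            # one standardised size draw per body: on placement rejection the
            # position is redrawn but the draw is kept, so accepted body
            # sizes follow the programmed log-normal law without the
            # large-body selection bias a plain rejection sampler would have
            z_size = rng.normal(0.0, 1.0)
            ratio = rng.uniform(1.0, 1.6)
            theta = rng.uniform(0.0, math.pi)
            for attempt in range(200):
                j = int(rng.integers(len(idx_r)))
                r0 = idx_r[j] + rng.uniform(-0.5, 0.5)
                c0 = idx_c[j] + rng.uniform(-0.5, 0.5)
                mu = (config.size_log_intercept
                      + config.size_log_slope * float(d_um[idx_r[j], idx_c[j]]))
                area_px = math.exp(mu + config.size_log_sd * z_size) / config.scale ** 2
                rr, cc = _render_ellipse(r0, c0, area_px, ratio, theta, shape)
                if rr.size == 0:
                    continue
                keep = inside[rr, cc]
                rr, cc = rr[keep], cc[keep]
                if rr.size == 0:
                    continue
                # one-pixel guard: reject if the dilated footprint meets a body
                win = (max(rr.min() - 1, 0), min(rr.max() + 2, shape[0]),
                       max(cc.min() - 1, 0), min(cc.max() + 2, shape[1]))
                local = np.zeros((win[1] - win[0], win[3] - win[2]), dtype=bool)
                local[rr - win[0], cc - win[2]] = True
                dilated = ndimage.binary_dilation(local, structure=struct)
                if (dilated & occupancy[win[0]:win[1], win[2]:win[3]]).any():
                    continue
                occupancy[rr, cc] = True
                placed_in += np.bincount(zones[rr, cc],
                                         minlength=config.K + 1)
                break
            else:
                raise RuntimeError(
                    f"bodies cannot fit: zone {k} coverage target "
                    f"{target / zone_px.sum():.3f} unreachable (density too high)")

    # colour rendering: Gaussian RGB noise around class means, no anti-aliasing
    h, w = shape
    img = rng.normal(config.background_color, config.background_sd, (h, w, 3))
    n_prot = int(occupancy.sum())
    img[occupancy] = rng.normal(config.stain_color, config.stain_sd, (n_prot, 3))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = SectionImage(pixels=pixels, scale=config.scale,
                         id=f"synth-seed{config.seed}")

    truth_mask = ProteinMask(protein=occupancy, replicate_id=0)
    truth_bodies = bodymetrics.extract_bodies(truth_mask, config.scale,
                                              min_area_px=1)
    truth_bodies = bodymetrics.body_distances(truth_bodies, mask, config.scale,
                                              partition=partition)
    zm = measure_zones(partition, truth_mask, config.scale)
    truth = GroundTruth(
        bodies=truth_bodies,
        per_zone_fraction=np.array([m.raw_fraction for m in zm]),
        zone_mid_distance_um=np.array([m.mid_distance for m in zm]),
        protein=truth_mask,
        partition=partition,
        config=config,
    )
    return image, mask, truth


# ---------------------------------------------------------------------------
# Training ROI generation
# ---------------------------------------------------------------------------

def generate_training_rois(image: SectionImage, truth: GroundTruth,
                           n_protein: int = 10, n_background: int = 10,
                           seed: int = 0, replicate_id: int = 1,
                           ) -> tuple[TrainingSet, dict]:
    """Sample label-correct training ROIs from known truth regions.

    Protein ROIs are 2x2 blocks fully inside bodies, background ROIs 3x3
    blocks of unstained endosperm, both stratified over the concentric zones
    so the samples are spread across the grain (emulating the manual practice
    of drawing training samples from many parts of the section).  Returns the
    TrainingSet plus the ROI record (polygons) for file export.
    """
    rng = np.random.default_rng(seed)
    occ = truth.protein.protein
    region = truth.partition.zone_of_pixel > 0
    prot_ok = occ[:-1, :-1] & occ[1:, :-1] & occ[:-1, 1:] & occ[1:, 1:]
    bg = region & ~occ
    bg_ok = ndimage.minimum_filter(bg, size=3, mode="constant")
    zones = truth.partition.zone_of_pixel
    K = truth.partition.K

    def sample_blocks(ok: np.ndarray, n: int, half: int, what: str):
        picks = []
        for i in range(n):
            k = (i % K) + 1
            cand = ok & (zones[:ok.shape[0], :ok.shape[1]] == k)
            rr, cc = np.nonzero(cand)
            if rr.size == 0:
                rr, cc = np.nonzero(ok)
            if rr.size == 0:
                raise ValueError(f"insufficient {what} regions to sample ROIs")
            j = int(rng.integers(rr.size))
            picks.append((int(rr[j]), int(cc[j])))
        return picks

    rois = []
    roi_record = {"replicate_id": replicate_id, "rois": []}
    for (r, c) in sample_blocks(prot_ok, n_protein, 1, "protein"):
        verts_xy = [[c - 0.3, r - 0.3], [c + 1.3, r - 0.3],
                    [c + 1.3, r + 1.3], [c - 0.3, r + 1.3]]
        rois.append(("protein", extract_roi_pixels(image, np.asarray(verts_xy))))
        roi_record["rois"].append({"label": "protein", "vertices_xy": verts_xy})
    for (r, c) in sample_blocks(bg_ok, n_background, 1, "background"):
        verts_xy = [[c - 1.3, r - 1.3], [c + 1.3, r - 1.3],
                    [c + 1.3, r + 1.3], [c - 1.3, r + 1.3]]
        rois.append(("background", extract_roi_pixels(image, np.asarray(verts_xy))))
        roi_record["rois"].append({"label": "background", "vertices_xy": verts_xy})
    return TrainingSet(rois=rois, replicate_id=replicate_id), roi_record


# ---------------------------------------------------------------------------
# End-to-end recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """How well the pipeline recovered the generator's programmed truth."""

    zone_fraction_errors: np.ndarray
    body_recall: float
    body_precision: float
    conc_slope: float
    conc_slope_programmed: float
    size_slope: float
    size_slope_programmed: float
    replicate_agreement: float
    n_truth_bodies: int
    n_measured_bodies: int

    @property
    def zone_fraction_max_abs_error(self) -> float:
        return float(np.abs(self.zone_fraction_errors).max())

    @property
    def conc_slope_rel_error(self) -> float:
        return abs(self.conc_slope - self.conc_slope_programmed) \
            / abs(self.conc_slope_programmed)

    @property
    def size_slope_rel_error(self) -> float:
        return abs(self.size_slope - self.size_slope_programmed) \
            / abs(self.size_slope_programmed)


def _match_bodies(truth_pts: np.ndarray, found_pts: np.ndarray,
                  tol_px: float = 2.0) -> int:
    """One-to-one midpoint matches within tol_px (greedy nearest-first)."""
    if len(truth_pts) == 0 or len(found_pts) == 0:
        return 0
    tree = cKDTree(found_pts)
    dists, idx = tree.query(truth_pts, distance_upper_bound=tol_px)
    order = np.argsort(dists)
    used: set[int] = set()
    matched = 0
    for t in order:
        if not np.isfinite(dists[t]):
            break
        if idx[t] not in used:
            used.add(int(idx[t]))
            matched += 1
    return matched


def end_to_end_recovery(config: SynthConfig, n_replicates: int = 3,
                        min_area_px: int = 4) -> RecoveryReport:
    """Generate a section, run the full pipeline, compare to ground truth.

    Body recall/precision use one-to-one midpoint matching within 2 px
    against truth bodies at the same minimum-size filter.  Gradient slopes
    are fitted exactly as the pipeline does: per-zone mean fraction against
    mid-band distance, and pooled ln(body area) against body distance.
    """
    image, mask, truth = generate_section(config)
    trainings = []
    for i in range(n_replicates):
        ts, _ = generate_training_rois(image, truth, seed=config.seed * 1009 + i + 1,
                                       replicate_id=i + 1)
        trainings.append(ts)
    masks = classify_replicates(image, mask, trainings)
    agreement = replicate_agreement(masks, mask)
    off = ~np.eye(len(masks), dtype=bool)
    mean_agreement = float(agreement[off].mean()) if len(masks) > 1 else 1.0

    partition = truth.partition
    fractions = np.zeros((n_replicates, config.K))
    for i, pm in enumerate(masks):
        zm = measure_zones(partition, pm, config.scale)
        fractions[i] = [m.raw_fraction for m in zm]
    mean_fraction = fractions.mean(axis=0)
    zone_errors = mean_fraction - truth.per_zone_fraction

    conc_fit = gradstats.fit_gradient(truth.zone_mid_distance_um, mean_fraction,
                                      response="raw_fraction")

    truth_kept = [b for b in truth.bodies if b.area_px >= min_area_px]
    truth_pts = np.array([b.midpoint for b in truth_kept]).reshape(-1, 2)
    all_bodies: list[ProteinBody] = []
    found_first = None
    for pm in masks:
        bodies = bodymetrics.extract_bodies(pm, config.scale, min_area_px=min_area_px)
        bodies = bodymetrics.body_distances(bodies, mask, config.scale,
                                            partition=partition)
        if found_first is None:
            found_first = bodies
        all_bodies.extend(bodies)
    found_pts = np.array([b.midpoint for b in found_first]).reshape(-1, 2)
    matched = _match_bodies(truth_pts, found_pts, tol_px=2.0)
    recall = matched / len(truth_pts) if len(truth_pts) else 1.0
    precision = matched / len(found_pts) if len(found_pts) else 1.0

    d, logs = gradstats.log_transform_areas(all_bodies)
    size_fit = gradstats.fit_gradient(d, logs, response="log_body_area")

    return RecoveryReport(
        zone_fraction_errors=zone_errors,
        body_recall=float(recall),
        body_precision=float(precision),
        conc_slope=conc_fit.slope,
        conc_slope_programmed=config.fraction_slope,
        size_slope=size_fit.slope,
        size_slope_programmed=config.size_log_slope,
        replicate_agreement=mean_agreement,
        n_truth_bodies=len(truth_kept),
        n_measured_bodies=len(found_first),
    )


def small_config(seed: int = 0, **overrides) -> SynthConfig:
    """A reduced-canvas configuration for quick tests and examples."""
    kwargs = dict(canvas=(360, 520), lobe_radius=140.0, lobe_offset=105.0,
                  crease_depth=90.0, crease_width=40.0, seed=seed)
    kwargs.update(overrides)
    return SynthConfig(**kwargs)
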