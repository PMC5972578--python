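"""Batch orchestration: classify -> zones -> bodies -> calibrate -> trends.

A manifest CSV drives the batch, one row per section, with columns

    section_id, image_path, mask_path, rois_path, nitrogen_pct,
    temperature, nitrogen, timepoint, block

where ``rois_path`` is a JSON file of replicated training ROIs (see
:mod:`endograd.imgio`).  Conversion factors are computed per treatment x
experimental-replicate grouping (temperature, nitrogen, timepoint, block) by
pooling the zone measurements of all its sections and replicates; gradient
trends are fitted per treatment group (temperature, nitrogen, timepoint)
after averaging the classification replicates per zone (concentration) and
pooling bodies with their replicate ids retained (body size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bodymetrics, calibrate, gradstats, imgio, mlclassify, zonegrad
from .zonegrad import ZoneMeasurement

GROUP_KEYS = ("temperature", "nitrogen", "timepoint")
CALIBRATION_KEYS = GROUP_KEYS + ("block",)


@dataclass
class RunConfig:
    """Settings for one batch run."""

    manifest: pd.DataFrame
    scale: float
    K: int = 5
    n_replicates: int = 3
    min_area_px: int = bodymetrics.DEFAULT_MIN_AREA_PX
    n_to_protein: float = calibrate.DEFAULT_N_TO_PROTEIN
    regularisation: float = mlclassify.DEFAULT_REGULARISATION
    output_dir: Path | None = None
    seed: int = 0
    _root: Path = field(default_factory=Path, repr=False)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.manifest) < 1:
            raise ValueError("empty manifest")

    @classmethod
    def from_manifest_csv(cls, path: str | Path, **kwargs) -> "RunConfig":
        path = Path(path)
        return cls(manifest=pd.read_csv(path), _root=path.parent, **kwargs)

    def resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self._root / p


def _group_of(row: pd.Series, keys=GROUP_KEYS) -> tuple:
    return tuple(row.get(k, "") for k in keys)


def run_section(config: RunConfig, row: pd.Series):
    """Process one manifest row.

    Returns (per_zone table, per_body table, section-level CalibrationRecord
    or None when no nitrogen value is given).  Deterministic for fixed
    inputs: the classifier has no random component.
    """
    sid = str(row["section_id"])
    try:
        image = imgio.load_section(config.resolve(row["image_path"]), config.scale,
                                   id=sid)
        mask = imgio.load_mask(config.resolve(row["mask_path"]), image.shape)
        replicates = imgio.load_rois(config.resolve(row["rois_path"]))
        replicates = replicates[: config.n_replicates]
        trainings = []
        for rec in replicates:
            rois = [(r["label"], imgio.extract_roi_pixels(image, np.asarray(r["vertices_xy"])))
                    for r in rec["rois"]]
            trainings.append(mlclassify.TrainingSet(
                rois=rois, replicate_id=int(rec.get("replicate_id", len(trainings) + 1))))
        masks = mlclassify.classify_replicates(image, mask, trainings,
                                               regularisation=config.regularisation)
        partition = zonegrad.make_zones(mask, config.K)

        zone_rows, body_frames = [], []
        for pm in masks:
            for m in zonegrad.measure_zones(partition, pm, config.scale):
                zone_rows.append({
                    "section_id": sid, "replicate_id": pm.replicate_id,
                    "zone": m.zone, "mid_distance_um": m.mid_distance,
                    "zone_area_um2": m.zone_area,
                    "protein_area_um2": m.protein_area,
                    "raw_fraction": m.raw_fraction,
                })
            bodies = bodymetrics.extract_bodies(pm, config.scale,
                                                min_area_px=config.min_area_px)
            bodies = bodymetrics.body_distances(bodies, mask, config.scale,
                                                partition=partition)
            body_frames.append(bodymetrics.bodies_to_frame(
                bodies, section_id=sid, replicate_id=pm.replicate_id))
    except Exception as exc:
        raise RuntimeError(f"section '{sid}': {exc}") from exc

    per_zone = pd.DataFrame(zone_rows)
    per_body = pd.concat(body_frames, ignore_index=True) if body_frames else pd.DataFrame()
    record = None
    if "nitrogen_pct" in row.index and pd.notna(row["nitrogen_pct"]):
        zms = [ZoneMeasurement(r["zone"], r["mid_distance_um"],
                               r["zone_area_um2"], r["protein_area_um2"])
               for r in zone_rows]
        record = calibrate.compute_conversion_factor(
            float(row["nitrogen_pct"]), config.n_to_protein, zms, group=sid)
    return per_zone, per_body, record


def _calibrate_groups(config: RunConfig, per_zone: pd.DataFrame,
                      manifest: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-grouping conversion factors, applied to every per-zone row."""
    keys = [k for k in CALIBRATION_KEYS if k in manifest.columns]
    meta = manifest.set_index(manifest["section_id"].astype(str))
    cal_rows = []
    per_zone = per_zone.copy()
    per_zone["calibrated_concentration"] = np.nan
    section_group = {s: _group_of(meta.loc[s], keys) for s in meta.index}
    per_zone["_group"] = per_zone["section_id"].astype(str).map(section_group)
    for group, chunk in per_zone.groupby("_group", sort=True):
        sections = chunk["section_id"].astype(str).unique()
        npcts = meta.loc[sections, "nitrogen_pct"] if "nitrogen_pct" in meta.columns \
            else pd.Series(dtype=float)
        if npcts.empty or npcts.isna().any():
            missing = [s for s in sections
                       if npcts.empty or pd.isna(npcts.get(s, np.nan))]
            raise ValueError(
                f"missing nitrogen_pct for grouping {dict(zip(keys, group))} "
                f"(sections {missing})")
        zms = [ZoneMeasurement(r.zone, r.mid_distance_um, r.zone_area_um2,
                               r.protein_area_um2)
               for r in chunk.itertuples()]
        rec = calibrate.compute_conversion_factor(
            float(npcts.mean()), config.n_to_protein, zms,
            group="/".join(map(str, group)))
        per_zone.loc[chunk.index, "calibrated_concentration"] = (
            chunk["raw_fraction"] * rec.conversion_factor * 100.0)
        cal_rows.append({
            **dict(zip(keys, group)),
            "group": rec.group,
            "nitrogen_pct": rec.nitrogen_pct,
            "n_to_protein": rec.n_to_protein,
            "image_protein_fraction": rec.image_protein_fraction,
            "conversion_factor": rec.conversion_factor,
        })
    return per_zone.drop(columns="_group"), pd.DataFrame(cal_rows)


def _fit_gradients(per_zone: pd.DataFrame, per_body: pd.DataFrame,
                   manifest: pd.DataFrame) -> pd.DataFrame:
    keys = [k for k in GROUP_KEYS if k in manifest.columns]
    meta = manifest.set_index(manifest["section_id"].astype(str))
    sec_group = {s: _group_of(meta.loc[s], keys) for s in meta.index}
    fits = []

    conc = (per_zone.assign(_group=per_zone["section_id"].astype(str).map(sec_group))
            .groupby(["_group", "section_id", "zone"], sort=True)
            .agg(mid_distance_um=("mid_distance_um", "mean"),
                 value=("calibrated_concentration", "mean"))
            .reset_index())
    for group, chunk in conc.groupby("_group", sort=True):
        if len(chunk) >= 3 and chunk["mid_distance_um"].nunique() > 1:
            fit = gradstats.fit_gradient(chunk["mid_distance_um"], chunk["value"],
                                         group=group, response="concentration")
            if len(chunk) >= 4:
                fit = gradstats.quadratic_check(chunk["mid_distance_um"],
                                                chunk["value"], fit)
            fits.append(fit)

    if not per_body.empty:
        pb = per_body.assign(
            _group=per_body["section_id"].astype(str).map(sec_group))
        for group, chunk in pb.groupby("_group", sort=True):
            if len(chunk) >= 3 and chunk["distance_um"].nunique() > 1:
                fit = gradstats.fit_gradient(chunk["distance_um"],
                                             np.log(chunk["area_um2"]),
                                             group=group, response="log_body_area")
                if len(chunk) >= 4:
                    fit = gradstats.quadratic_check(chunk["distance_um"],
                                                    np.log(chunk["area_um2"]), fit)
                fits.append(fit)
    return gradstats.fits_to_frame(fits)


def run_batch(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every manifest row and aggregate tables, calibration and trends.

    Returns the dict of DataFrames {per_zone, per_body, calibration,
    gradients} and, when ``output_dir`` is set, writes each as CSV there.
    Rerunning with the same config and inputs reproduces the files exactly.
    """
    zone_frames, body_frames = [], []
    for _, row in config.manifest.iterrows():
        pz, pb, _ = run_section(config, row)
        zone_frames.append(pz)
        if not pb.empty:
            body_frames.append(pb)
    per_zone = pd.concat(zone_frames, ignore_index=True)
    per_body = pd.concat(body_frames, ignore_index=True) if body_frames \
        else pd.DataFrame(columns=imgio.PER_BODY_COLUMNS)
    imgio.validate_table(per_zone, "per_zone")

    per_zone, calibration = _calibrate_groups(config, per_zone, config.manifest)
    gradients = _fit_gradients(per_zone, per_body, config.manifest)

    out = {"per_zone": per_zone, "per_body": per_body,
           "calibration": calibration, "gradients": gradients}
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in out.items():
            imgio.write_table(table, outdir / f"{name}.csv")
    return out
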