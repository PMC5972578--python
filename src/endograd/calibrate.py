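"""Nitrogen-based calibration of image-derived protein area fractions.

Stain coverage on an area basis is only a proxy for protein concentration:
differences in grain water content or in protein density inside bodies shift
the detection efficiency between treatments.  A per-group conversion factor
anchors the image measurements to the chemically measured grain protein
concentration (Dumas nitrogen x a nitrogen-to-protein multiplier):

    conversion_factor = (nitrogen_pct * n_to_protein / 100)
                        / (total protein area / total grain area)

Applying the factor to per-zone area fractions rescales them so that their
area-weighted mean equals the measured grain protein percentage exactly.
The factor is a positive scalar, so zone ordering and gradient sign are
always preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .zonegrad import ZoneMeasurement

#: standard nitrogen-to-protein multiplier for wheat grain
DEFAULT_N_TO_PROTEIN = 5.7


@dataclass
class CalibrationRecord:
    """Links image area fraction to nitrogen-derived protein concentration."""

    nitrogen_pct: float
    n_to_protein: float
    measured_protein_fraction: float
    image_protein_fraction: float
    conversion_factor: float
    group: str = ""


@dataclass
class CalibratedZone(ZoneMeasurement):
    """Zone measurement with the calibrated concentration attached (% area)."""

    calibrated_concentration: float = 0.0


def compute_conversion_factor(nitrogen_pct: float, n_to_protein: float,
                              zone_measurements: list[ZoneMeasurement],
                              group: str = "") -> CalibrationRecord:
    """Derive the conversion factor for one treatment x replicate grouping.

    ``zone_measurements`` may pool several sections of the grouping; the
    image protein fraction is total protein area over total zoned area.
    Users who measured protein percentage directly (rather than nitrogen)
    should pass it as ``nitrogen_pct`` with ``n_to_protein=1``.
    """
    if nitrogen_pct <= 0:
        raise ValueError("nitrogen_pct must be positive")
    if n_to_protein <= 0:
        raise ValueError("n_to_protein must be positive")
    total_area = sum(m.zone_area for m in zone_measurements)
    total_protein = sum(m.protein_area for m in zone_measurements)
    if total_area <= 0:
        raise ValueError("total zone area is zero")
    if total_protein <= 0:
        raise ValueError("zero protein area: calibration undefined")
    measured = nitrogen_pct * n_to_protein / 100.0
    image_fraction = total_protein / total_area
    return CalibrationRecord(
        nitrogen_pct=nitrogen_pct,
        n_to_protein=n_to_protein,
        measured_protein_fraction=measured,
        image_protein_fraction=image_fraction,
        conversion_factor=measured / image_fraction,
        group=group,
    )


def apply_calibration(record: CalibrationRecord,
                      zone_measurements: list[ZoneMeasurement],
                      group: str = "") -> list[CalibratedZone]:
    """Rescale raw per-zone fractions to calibrated concentrations (percent).

    calibrated = raw_fraction * conversion_factor * 100.  When applied to the
    same pooled measurements the factor was derived from, the area-weighted
    mean calibrated concentration equals nitrogen_pct * n_to_protein exactly.
    """
    if record.group and group and record.group != group:
        raise ValueError(
            f"calibration group mismatch: record '{record.group}' vs data '{group}'")
    out = []
    for m in zone_measurements:
        out.append(CalibratedZone(
            zone=m.zone,
            mid_distance=m.mid_distance,
            zone_area=m.zone_area,
            protein_area=m.protein_area,
            calibrated_concentration=m.raw_fraction * record.conversion_factor * 100.0,
        ))
    return out
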