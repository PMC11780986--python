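"""Per-lesion, per-scan measurements on ADC maps.

Each delineated lesion (primary tumor GTV-P or lymph node GTV-N) is
reduced, per scan, to three numbers: the mean ADC over the region, the
absolute volume (voxel count times voxel volume), and the size of the
high-risk subvolume (HRS) — the set of in-lesion voxels whose ADC falls
strictly inside a fixed band, by default (600, 900) x 1e-6 mm^2/s, a
range associated with radioresistant tumor subregions.  Two bookkeeping
rules gate downstream statistics: lesions smaller than a minimum volume
are excluded entirely, and lesions whose HRS is below a minimum size keep
their ADC/volume series but drop out of HRS analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from .adc_mapping import ADCMap
from .longitudinal_stats import assign_week

if TYPE_CHECKING:  # pragma: no cover
    from .io_core import LesionMask, RunConfig

logger = logging.getLogger(__name__)

MM3_PER_CM3 = 1000.0


@dataclass
class LesionMeasurement:
    """One lesion's measurements on one scan.

    ``adc_mean`` is in mm^2/s (NaN when every in-mask voxel was
    undefined); volumes are in cm^3.  ``n_undefined`` counts in-mask
    voxels without a defined ADC, which are excluded from the mean but
    still counted in the volume (delineation defines the volume, not the
    fit).
    """

    patient_id: str
    lesion_id: str
    lesion_class: str
    day: int
    week: int
    adc_mean: float
    volume: float
    hrs_volume: float
    n_voxels: int
    n_hrs_voxels: int
    n_undefined: int
    gtv_excluded: bool = False
    hrs_excluded: bool = False


def voxel_volume_cm3(voxel_spacing) -> float:
    dx, dy, dz = voxel_spacing
    return dx * dy * dz / MM3_PER_CM3


def resample_mask_to_map(mask: "LesionMask", adc_map: ADCMap) -> "LesionMask":
    """Bring a lesion mask onto the ADC map grid.

    Masks are normally delineated on one of the DWI b-value images, so the
    grids coincide and the mask is returned unchanged.  Otherwise each
    output voxel takes the label of the physically nearest input voxel
    (nearest-neighbour in world coordinates; voxel centres sit at
    ``origin + (index + 1/2) * spacing``).
    """
    same_grid = (
        mask.mask.shape == adc_map.values.shape
        and np.allclose(mask.voxel_spacing, adc_map.voxel_spacing)
        and np.allclose(mask.origin, adc_map.origin)
    )
    if same_grid:
        return mask

    in_sp = np.asarray(mask.voxel_spacing, dtype=float)
    out_sp = np.asarray(adc_map.voxel_spacing, dtype=float)
    in_org = np.asarray(mask.origin, dtype=float)
    out_org = np.asarray(adc_map.origin, dtype=float)
    in_shape = np.asarray(mask.mask.shape)
    out_shape = np.asarray(adc_map.values.shape)

    in_lo, in_hi = in_org, in_org + in_shape * in_sp
    out_lo, out_hi = out_org, out_org + out_shape * out_sp
    if np.any(in_hi <= out_lo) or np.any(out_hi <= in_lo):
        raise ValueError(
            f"mask {mask.lesion_id} and ADC map {adc_map.patient_id} cover "
            "disjoint physical extents; cannot resample"
        )

    idx = []
    for ax in range(3):
        centers = out_org[ax] + (np.arange(out_shape[ax]) + 0.5) * out_sp[ax]
        nearest = np.floor((centers - in_org[ax]) / in_sp[ax]).astype(int)
        idx.append(np.clip(nearest, 0, in_shape[ax] - 1))
    resampled = mask.mask[np.ix_(idx[0], idx[1], idx[2])]
    return replace(
        mask,
        mask=resampled.astype(bool),
        voxel_spacing=tuple(adc_map.voxel_spacing),
        origin=tuple(adc_map.origin),
    )


def roi_mean_adc(adc_map: ADCMap, mask: "LesionMask") -> float:
    """Arithmetic mean ADC over defined in-mask voxels (mm^2/s).

    Undefined (NaN) voxels are left out of both numerator and denominator;
    NaN is returned when no defined voxel remains.
    """
    values = adc_map.values[mask.mask]
    defined = values[np.isfinite(values)]
    if defined.size == 0:
        logger.warning(
            "lesion %s/%s day %s: all in-mask voxels undefined; mean ADC dropped",
            mask.patient_id, mask.lesion_id, adc_map.day,
        )
        return float("nan")
    return float(defined.mean())


def roi_volume(mask: "LesionMask") -> float:
    """Absolute volume in cm^3: set-voxel count x voxel volume."""
    return int(mask.mask.sum()) * voxel_volume_cm3(mask.voxel_spacing)


def extract_hrs(
    adc_map: ADCMap, mask: "LesionMask", band: tuple[float, float]
) -> tuple[np.ndarray, float]:
    """High-risk subvolume: in-mask voxels with ADC strictly inside ``band``.

    ``band`` is (lower, upper) in mm^2/s, open at both ends.  Returns the
    HRS voxel mask and its volume in cm^3.  No connectivity filtering is
    applied: every qualifying voxel counts.
    """
    lower, upper = band
    if not lower < upper:
        raise ValueError("band lower bound must be below upper bound")
    with np.errstate(invalid="ignore"):
        hrs = mask.mask & (adc_map.values > lower) & (adc_map.values < upper)
    return hrs, int(hrs.sum()) * voxel_volume_cm3(mask.voxel_spacing)


def apply_exclusions(m: LesionMeasurement, config: "RunConfig") -> LesionMeasurement:
    """Flag lesions below the minimum volume / minimum HRS thresholds.

    Both rules are strict inequalities: a lesion exactly at a threshold
    survives.  Volume-excluded lesions contribute nothing downstream;
    HRS-excluded lesions keep ADC and volume series but no HRS series.
    """
    gtv_excluded = m.volume < config.gtv_min_volume
    hrs_excluded = m.hrs_volume < config.hrs_min_volume
    if gtv_excluded:
        logger.info(
            "excluded lesion %s/%s week %d: volume %.3f cm^3 < %.2f cm^3",
            m.patient_id, m.lesion_id, m.week, m.volume, config.gtv_min_volume,
        )
    elif hrs_excluded:
        logger.info(
            "HRS excluded for lesion %s/%s week %d: %.3f cm^3 < %.2f cm^3",
            m.patient_id, m.lesion_id, m.week, m.hrs_volume, config.hrs_min_volume,
        )
    return replace(m, gtv_excluded=bool(gtv_excluded), hrs_excluded=bool(hrs_excluded))


def measure_lesion(
    adc_map: ADCMap, mask: "LesionMask", config: "RunConfig", day: int
) -> LesionMeasurement:
    """Full per-scan measurement of one lesion, exclusion flags included."""
    mask_on_map = resample_mask_to_map(mask, adc_map)
    in_mask = adc_map.values[mask_on_map.mask]
    _, hrs_vol = extract_hrs(adc_map, mask_on_map, config.hrs_band)
    m = LesionMeasurement(
        patient_id=mask.patient_id,
        lesion_id=mask.lesion_id,
        lesion_class=mask.lesion_class,
        day=day,
        week=assign_week(day),
        adc_mean=roi_mean_adc(adc_map, mask_on_map),
        volume=roi_volume(mask_on_map),
        hrs_volume=hrs_vol,
        n_voxels=int(mask_on_map.mask.sum()),
        n_hrs_voxels=int(round(hrs_vol / voxel_volume_cm3(mask_on_map.voxel_spacing))),
        n_undefined=int((~np.isfinite(in_mask)).sum()),
    )
    return apply_exclusions(m, config)
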