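"""File formats, run configuration and the end-to-end pipeline driver.

All images travel as NIfTI (.nii/.nii.gz) with a diagonal affine built
from the voxel spacing; tabular data (manifest, metadata, measurements,
summaries) are plain CSV.  ADC is held internally in mm^2/s and converted
to the conventional 1e-6 mm^2/s only at the format boundary, so magnitude
mistakes cannot creep into the science.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .adc_mapping import ADCMap, compute_adc_map
from .lesion_metrics import LesionMeasurement, measure_lesion
from .longitudinal_stats import WeeklySummary, summarize_cohort
from .risk_stratification import PatientMeta, RiskRules, DEFAULT_RULES, classify_patient

logger = logging.getLogger(__name__)

ADC_OUTPUT_SCALE = 1e6  # mm^2/s -> 1e-6 mm^2/s at the format boundary

MEASUREMENT_COLUMNS = [
    "patient_id", "lesion_id", "lesion_class", "week", "day",
    "adc_mean_1e6_mm2_s", "volume_cm3", "hrs_volume_cm3",
    "gtv_excluded", "hrs_excluded", "n_voxels", "n_hrs_voxels", "n_undefined",
]


@dataclass
class DWISeries:
    """One scan's multi-b-value magnitude volumes on a common grid."""

    patient_id: str
    scan_day: int
    b_values: tuple[float, ...]
    volumes: list[np.ndarray]
    voxel_spacing: tuple[float, float, float]
    n_averages: tuple[int, ...] = ()
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.volumes) != len(self.b_values):
            raise ValueError("one volume per b-value required")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be non-negative")
        if list(self.b_values) != sorted(self.b_values) or len(set(self.b_values)) != len(self.b_values):
            raise ValueError("b-values must be strictly increasing")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"volumes on different grids: {shapes}")


@dataclass
class LesionMask:
    """Binary delineation of one lesion (primary tumor or lymph node)."""

    patient_id: str
    lesion_id: str
    lesion_class: str  # "GTV-P" | "GTV-N"
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.lesion_class not in ("GTV-P", "GTV-N"):
            raise ValueError(f"lesion_class must be GTV-P or GTV-N, got {self.lesion_class!r}")
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class RunConfig:
    """Analysis thresholds and fit settings.

    Defaults follow the MR-Linac head-and-neck protocol: two-point ADC fit
    on b = 150 and 500 s/mm^2, high-risk band (600, 900) x 1e-6 mm^2/s
    (adapted to the MR-Linac's known ADC underestimation, so other
    scanners will need other values), minimum analyzable lesion volume
    1 cm^3 and minimum HRS 0.2 cm^3, HRS prognostic-classification
    threshold 5.8 cm^3, relative repeatability coefficients 31% (GTV-P)
    and 23% (GTV-N), per-week significance level 5%.
    """

    adc_b_pair: tuple[float, float] | None = (150.0, 500.0)
    hrs_band: tuple[float, float] = (600e-6, 900e-6)
    gtv_min_volume: float = 1.0
    hrs_min_volume: float = 0.2
    hrs_classification_threshold: float = 5.8
    rel_rc: dict = field(default_factory=lambda: {"GTV-P": 0.31, "GTV-N": 0.23})
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.hrs_band[0] < self.hrs_band[1]:
            raise ValueError("hrs_band lower bound must be below upper bound")
        for name in ("gtv_min_volume", "hrs_min_volume", "hrs_classification_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "adc_b_pair" in raw and raw["adc_b_pair"] is not None:
            raw["adc_b_pair"] = tuple(raw["adc_b_pair"])
        if "hrs_band" in raw:
            raw["hrs_band"] = tuple(raw["hrs_band"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["adc_b_pair"] = list(self.adc_b_pair) if self.adc_b_pair else None
        d["hrs_band"] = list(self.hrs_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ScanRecord:
    """One manifest row: one lesion on one scan."""

    patient_id: str
    lesion_id: str
    lesion_class: str
    day: int
    mask_path: str
    b_values: tuple[float, ...]
    b_paths: tuple[str, ...]
    n_averages: tuple[int, ...]


# ---------------------------------------------------------------------------
# NIfTI helpers


def save_volume(path, array: np.ndarray, voxel_spacing, origin=(0.0, 0.0, 0.0),
                descrip: str = "") -> None:
    affine = np.diag(list(voxel_spacing) + [1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    img.header["descrip"] = descrip.encode()[:79]
    img.header.set_zooms(voxel_spacing)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float], tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return np.asarray(img.dataobj, dtype=np.float32), spacing, origin


def read_dwi_series(
    b_to_path: dict[float, str],
    patient_id: str,
    scan_day: int,
    n_averages: Sequence[int] | None = None,
) -> DWISeries:
    """Load one scan's per-b-value volumes, sorted ascending in b.

    Raises on a grid mismatch between volumes (the offending file is
    named) and on a missing file.
    """
    order = sorted(b_to_path)
    if n_averages is None:
        n_averages = [1] * len(order)
    else:
        n_averages = [n for _, n in sorted(zip(b_to_path, n_averages))]
    volumes, spacings, origins = [], [], []
    for b in order:
        path = Path(b_to_path[b])
        if not path.exists():
            raise FileNotFoundError(f"missing volume for b = {b}: {path}")
        arr, spacing, origin = load_volume(path)
        if volumes and (arr.shape != volumes[0].shape or not np.allclose(spacing, spacings[0])):
            raise ValueError(
                f"grid mismatch: {path} has shape {arr.shape} / spacing {spacing}, "
                f"expected {volumes[0].shape} / {spacings[0]}"
            )
        volumes.append(arr)
        spacings.append(spacing)
        origins.append(origin)
    return DWISeries(
        patient_id=patient_id,
        scan_day=scan_day,
        b_values=tuple(float(b) for b in order),
        volumes=volumes,
        voxel_spacing=spacings[0],
        n_averages=tuple(int(n) for n in n_averages),
        origin=origins[0],
    )


def save_mask(mask: LesionMask, path) -> None:
    save_volume(path, mask.mask.astype(np.uint8), mask.voxel_spacing, mask.origin,
                descrip=f"{mask.lesion_class} binary mask")


def load_mask(path, patient_id: str, lesion_id: str, lesion_class: str) -> LesionMask:
    arr, spacing, origin = load_volume(path)
    return LesionMask(
        patient_id=patient_id,
        lesion_id=lesion_id,
        lesion_class=lesion_class,
        mask=arr > 0.5,
        voxel_spacing=spacing,
        origin=origin,
    )


def write_adc_map(adc_map: ADCMap, path) -> None:
    """Write an ADC map in 1e-6 mm^2/s with the unit in the header."""
    save_volume(
        path,
        adc_map.values * ADC_OUTPUT_SCALE,
        adc_map.voxel_spacing,
        adc_map.origin,
        descrip="ADC [1e-6 mm^2/s]",
    )


# ---------------------------------------------------------------------------
# tabular I/O

MANIFEST_COLUMNS = [
    "patient_id", "lesion_id", "lesion_class", "day", "mask_path",
    "b_values", "b_value_paths", "n_averages",
]


def write_manifest(records: list[ScanRecord], path) -> None:
    rows = [
        dict(
            patient_id=r.patient_id,
            lesion_id=r.lesion_id,
            lesion_class=r.lesion_class,
            day=r.day,
            mask_path=r.mask_path,
            b_values=";".join(f"{b:g}" for b in r.b_values),
            b_value_paths=";".join(r.b_paths),
            n_averages=";".join(str(n) for n in r.n_averages),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[ScanRecord]:
    """Read the cohort manifest: one row per (patient, lesion, scan day).

    Rows with unparseable day fields are reported together by row number;
    duplicated (patient, lesion, day) rows are an error.  An empty
    manifest yields an empty list with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    if df.empty:
        warnings.warn(f"manifest {path} contains no scans", stacklevel=2)
        return []
    bad_rows = []
    days = []
    for i, raw in enumerate(df["day"]):
        try:
            days.append(int(raw))
        except ValueError:
            bad_rows.append(i + 2)  # 1-based, plus header line
            days.append(None)
    if bad_rows:
        raise ValueError(f"manifest {path}: unparseable day in rows {bad_rows}")
    keys = list(zip(df["patient_id"], df["lesion_id"], days))
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ValueError(f"manifest {path}: duplicated (patient, lesion, day) rows: {sorted(dupes)}")
    records = []
    for day, (_, row) in zip(days, df.iterrows()):
        records.append(
            ScanRecord(
                patient_id=row.patient_id,
                lesion_id=row.lesion_id,
                lesion_class=row.lesion_class,
                day=day,
                mask_path=row.mask_path,
                b_values=tuple(float(b) for b in row.b_values.split(";")),
                b_paths=tuple(row.b_value_paths.split(";")),
                n_averages=tuple(int(n) for n in row.n_averages.split(";")),
            )
        )
    return records


def write_measurements_table(measurements: list[LesionMeasurement], path) -> None:
    """Per-lesion CSV; ADC in 1e-6 mm^2/s, volumes in cm^3."""
    rows = [
        dict(
            patient_id=m.patient_id,
            lesion_id=m.lesion_id,
            lesion_class=m.lesion_class,
            week=m.week,
            day=m.day,
            adc_mean_1e6_mm2_s=m.adc_mean * ADC_OUTPUT_SCALE,
            volume_cm3=m.volume,
            hrs_volume_cm3=m.hrs_volume,
            gtv_excluded=m.gtv_excluded,
            hrs_excluded=m.hrs_excluded,
            n_voxels=m.n_voxels,
            n_hrs_voxels=m.n_hrs_voxels,
            n_undefined=m.n_undefined,
        )
        for m in measurements
    ]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_measurements_table(path) -> list[LesionMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            LesionMeasurement(
                patient_id=str(r.patient_id),
                lesion_id=str(r.lesion_id),
                lesion_class=str(r.lesion_class),
                week=int(r.week),
                day=int(r.day),
                adc_mean=float(r.adc_mean_1e6_mm2_s) / ADC_OUTPUT_SCALE,
                volume=float(r.volume_cm3),
                hrs_volume=float(r.hrs_volume_cm3),
                gtv_excluded=bool(r.gtv_excluded),
                hrs_excluded=bool(r.hrs_excluded),
                n_voxels=int(r.n_voxels),
                n_hrs_voxels=int(r.n_hrs_voxels),
                n_undefined=int(r.n_undefined),
            )
        )
    return out


def read_metadata(path) -> list[PatientMeta]:
    df = pd.read_csv(path, dtype=str)
    return [
        PatientMeta(
            patient_id=r.patient_id,
            site=r.site,
            t_stage=r.t_stage,
            n_stage=r.n_stage,
            p16=r.p16,
            smoking=r.smoking,
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# pipeline


def summary_table_for_disk(df: pd.DataFrame) -> pd.DataFrame:
    """Convert ADC rows of a summary table to 1e-6 mm^2/s for output."""
    if df.empty or "quantity" not in df.columns:
        return df
    df = df.copy()
    sel = df["quantity"] == "adc_mean"
    for col in ("median", "iqr", "baseline", "last_value", "slope", "intercept"):
        if col in df.columns:
            df.loc[sel, col] = df.loc[sel, col] * ADC_OUTPUT_SCALE
    return df


@dataclass
class PipelineResult:
    measurements: list[LesionMeasurement]
    summary: WeeklySummary
    groups: dict[str, str]


def measure_scan(record: ScanRecord, config: RunConfig, map_out: Path | None = None) -> LesionMeasurement:
    """ADC-map one scan and measure its lesion; optionally write the map."""
    series = read_dwi_series(
        dict(zip(record.b_values, record.b_paths)),
        record.patient_id,
        record.day,
        record.n_averages,
    )
    adc_map = compute_adc_map(series, config)
    if map_out is not None:
        write_adc_map(adc_map, map_out)
    mask = load_mask(record.mask_path, record.patient_id, record.lesion_id, record.lesion_class)
    return measure_lesion(adc_map, mask, config, record.day)


def run_pipeline(
    config: RunConfig,
    manifest_path,
    metadata_path,
    out_dir,
    risk_rules: RiskRules = DEFAULT_RULES,
    write_maps: bool = True,
) -> PipelineResult:
    """Execute every stage: ADC mapping, lesion metrics, cohort statistics.

    Writes ``measurements.csv``, ``weekly_summary.csv``,
    ``course_changes.csv``, ``regressions.csv`` and ``risk_groups.csv``
    (plus per-scan ADC maps under ``adc_maps/`` unless disabled) into
    ``out_dir``.  Deterministic: identical inputs and config give
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_manifest(manifest_path)
    metas = read_metadata(metadata_path)
    groups = {m.patient_id: classify_patient(m, risk_rules).label for m in metas}

    maps_dir = out_dir / "adc_maps"
    if write_maps:
        maps_dir.mkdir(exist_ok=True)
    measurements = []
    for rec in sorted(records, key=lambda r: (r.patient_id, r.lesion_id, r.day)):
        map_out = (
            maps_dir / f"{rec.patient_id}_{rec.lesion_id}_d{rec.day:03d}_adc.nii.gz"
            if write_maps
            else None
        )
        try:
            measurements.append(measure_scan(rec, config, map_out))
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed on {rec.patient_id}/{rec.lesion_id} day {rec.day}"
            ) from err

    write_measurements_table(measurements, out_dir / "measurements.csv")
    n_gtv = sum(m.gtv_excluded for m in measurements)
    n_hrs = sum(m.hrs_excluded and not m.gtv_excluded for m in measurements)
    logger.info(
        "pipeline: %d lesion-scans measured; %d below minimum volume, "
        "%d below minimum HRS", len(measurements), n_gtv, n_hrs,
    )

    summary = summarize_cohort(measurements, groups, config)
    float_fmt = "%.10g"
    for name, table in (
        ("weekly_summary.csv", summary.weekly),
        ("course_changes.csv", summary.course),
        ("regressions.csv", summary.regressions),
    ):
        summary_table_for_disk(table).to_csv(out_dir / name, index=False, float_format=float_fmt)
    pd.DataFrame(
        sorted(groups.items()), columns=["patient_id", "risk_group"]
    ).to_csv(out_dir / "risk_groups.csv", index=False)
    return PipelineResult(measurements=measurements, summary=summary, groups=groups)
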