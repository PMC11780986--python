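"""Synthetic longitudinal DWI cohort with planted, recoverable dynamics.

No imaging data from MR-Linac head-and-neck cohorts are publicly
deposited, so the pipeline is exercised on a fully synthetic stand-in: a
cohort of digital phantoms whose planted baselines and treatment-course
dynamics are drawn from lognormal distributions centred on the pooled
values reported for a 27-patient MR-Linac cohort (median pretreatment
mean ADC 1167/1002 x 1e-6 mm^2/s for primary tumors/nodes, volumes
9.1/6.0 cm^3, high-risk subvolumes 1.5/1.3 cm^3; week-7/baseline ratios
1.49/1.24 for ADC, 0.32/0.48 for volume, 0.07/0.13 for HRS).

Each lesion is a discretized sphere on its own grid whose voxel ADC field
is a two-component mixture — a low-ADC "high-risk" core inside the
detection band and a bulk compartment above it, shifted so the whole-
lesion mean equals the planted mean exactly.  Magnitude DWI signals
follow the mono-exponential decay with multi-average Rician noise, the
noise model of magnitude MR images.  Every planted value is written to a
ground-truth table so recovery can be tested at any noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .adc_mapping import signal_forward
from .io_core import DWISeries, LesionMask, ScanRecord, save_mask, save_volume, write_manifest
from .longitudinal_stats import assign_week
from .risk_stratification import PatientMeta, classify_patient

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Generator settings; defaults emulate the reference cohort conditions.

    Baseline medians and week-7 ratios are the pooled published cohort
    values; the lognormal ``dispersion`` (sigma of the log) and the
    risk-group sizes are generator choices, since per-patient spread and
    per-group counts are not published.  ``snr_b0`` is the signal-to-noise
    ratio of a single averaged b = 0 image inside the lesion; set it to
    None for noiseless phantoms.
    """

    n_patients: int = 27
    group_sizes: dict = field(
        default_factory=lambda: {"high": 7, "intermediate": 8, "low": 6, "non-OPC": 6}
    )
    node_count_probs: tuple[float, ...] = (0.15, 0.40, 0.30, 0.15)  # 0..3 nodes
    scan_days: tuple[int, ...] = (0, 4, 11, 18, 25, 32, 39, 46)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    b_values: tuple[float, ...] = (0.0, 150.0, 500.0)
    n_averages: tuple[int, ...] = (3, 5, 8)
    snr_b0: float | None = 50.0
    si0_lesion: float = 1000.0
    si0_background: float = 60.0

    baseline_adc_median: dict = field(
        default_factory=lambda: {"GTV-P": 1167e-6, "GTV-N": 1002e-6}
    )
    baseline_volume_median: dict = field(
        default_factory=lambda: {"GTV-P": 9.1, "GTV-N": 6.0}
    )
    baseline_hrs_median: dict = field(
        default_factory=lambda: {"GTV-P": 1.5, "GTV-N": 1.3}
    )
    adc_ratio_w7: dict = field(default_factory=lambda: {"GTV-P": 1.49, "GTV-N": 1.24})
    volume_ratio_w7: dict = field(default_factory=lambda: {"GTV-P": 0.32, "GTV-N": 0.48})
    hrs_ratio_w7: dict = field(default_factory=lambda: {"GTV-P": 0.07, "GTV-N": 0.13})
    dispersion: float = 0.25
    hrs_cap_fraction: float = 0.9

    # phantom ADC-field construction
    hrs_component_band: tuple[float, float] = (620e-6, 880e-6)
    bulk_floor: float = 950e-6
    bulk_sigma: float = 100e-6

    seed: int = 0

    def __post_init__(self):
        if sum(self.group_sizes.values()) != self.n_patients:
            raise ValueError("group sizes must sum to n_patients")
        for d in (self.baseline_adc_median, self.baseline_volume_median, self.baseline_hrs_median):
            if any(v <= 0 for v in d.values()):
                raise ValueError("planted medians must be positive")
        for cls in ("GTV-P", "GTV-N"):
            if not self.baseline_hrs_median[cls] < self.baseline_volume_median[cls]:
                raise ValueError("planted HRS volume must be below planted volume")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False, default_flow_style=None)


@dataclass
class PlantedTrajectory:
    """Ground-truth time course for one lesion.

    Mean ADC interpolates linearly from baseline to the drawn week-7
    value; volume and HRS decay exponentially, reaching the drawn week-7
    ratio (HRS additionally capped below the shrinking volume).
    """

    patient_id: str
    lesion_id: str
    lesion_class: str
    baseline_adc: float
    baseline_volume: float
    baseline_hrs: float
    adc_ratio: float
    volume_ratio: float
    hrs_ratio: float
    hrs_cap_fraction: float = 0.9

    def true_values(self, week: int) -> tuple[float, float, float]:
        """(mean ADC mm^2/s, volume cm^3, HRS cm^3) at a treatment week."""
        f = week / 7.0
        adc = self.baseline_adc * (1.0 + (self.adc_ratio - 1.0) * f)
        vol = self.baseline_volume * self.volume_ratio**f
        hrs = min(self.baseline_hrs * self.hrs_ratio**f, self.hrs_cap_fraction * vol)
        return adc, vol, hrs


@dataclass
class PatientPlan:
    meta: PatientMeta
    group: str
    lesions: list[PlantedTrajectory]


# ---------------------------------------------------------------------------
# parameter sampling


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _stratified_lognormal(
    rng: np.random.Generator, median: float, sigma: float, n: int
) -> np.ndarray:
    """n lognormal draws by stratified (quantile) sampling, shuffled.

    One draw per probability stratum ((i + u_i) / n with u_i uniform)
    keeps the marginal distribution the configured lognormal while
    pinning the realized sample median close to ``median`` — the cohort
    conditions are planted, not merely expected.  The shuffle removes any
    ordering so downstream assignment stays exchangeable.
    """
    u = (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
    z = stats.norm.ppf(u)
    rng.shuffle(z)
    return median * np.exp(sigma * z)


def _feasible_adc_floor(hrs_fraction: float, config: CohortConfig) -> float:
    """Smallest lesion mean ADC the two-component field can represent.

    The HRS component can pull the lesion mean down by at most its
    fraction times the band's upper edge (the worst case: draws near the
    upper edge compensate least), while bulk voxels stay at or above the
    bulk floor; a small margin absorbs voxel-count quantization and the
    spread of the uniform HRS draws.
    """
    hi = config.hrs_component_band[1]
    return config.bulk_floor * (1.0 - hrs_fraction) + hi * hrs_fraction + 20e-6


def _clamp_to_feasible(traj: PlantedTrajectory, config: CohortConfig) -> PlantedTrajectory:
    """Raise the drawn ADC trajectory onto the representable region.

    Only the low tail of the lognormal is affected, so planted cohort
    medians are unchanged; without this, draws far below the bulk floor
    could not be realized as phantom fields.
    """
    f0 = traj.baseline_hrs / traj.baseline_volume
    traj.baseline_adc = max(traj.baseline_adc, _feasible_adc_floor(f0, config))
    ratio = traj.adc_ratio
    for week in range(1, 8):
        _, vol, hrs = traj.true_values(week)
        floor_w = _feasible_adc_floor(hrs / vol, config)
        adc_w = traj.baseline_adc * (1.0 + (ratio - 1.0) * week / 7.0)
        if adc_w < floor_w:
            ratio = max(ratio, (floor_w / traj.baseline_adc - 1.0) * 7.0 / week + 1.0)
    traj.adc_ratio = ratio
    return traj


def _meta_for_group(pid: str, group: str, rng: np.random.Generator) -> PatientMeta:
    """Metadata fields guaranteed to classify into the intended group."""
    if group == "non-OPC":
        meta = PatientMeta(
            patient_id=pid,
            site=str(rng.choice(["hypopharynx"] * 5 + ["supraglottic-larynx"])),
            t_stage=str(rng.choice(["T2", "T3", "T4"])),
            n_stage=str(rng.choice(["N0", "N1", "N2b", "N2c"])),
            p16=str(rng.choice(["positive", "negative"])),
            smoking=str(rng.choice(["current", "former", "never"])),
        )
    elif group == "low":
        meta = PatientMeta(
            patient_id=pid,
            site="oropharynx",
            t_stage=str(rng.choice(["T1", "T2", "T3"])),
            n_stage=str(rng.choice(["N0", "N1", "N2a", "N2b"])),
            p16="positive",
            smoking="never",
        )
    elif group == "intermediate":
        meta = PatientMeta(
            patient_id=pid,
            site="oropharynx",
            t_stage=str(rng.choice(["T2", "T3"])),
            n_stage=str(rng.choice(["N2b", "N2c"])),
            p16="positive",
            smoking=str(rng.choice(["current", "former"])),
        )
    elif group == "high":
        meta = PatientMeta(
            patient_id=pid,
            site="oropharynx",
            t_stage=str(rng.choice(["T2", "T3", "T4"])),
            n_stage=str(rng.choice(["N1", "N2b", "N2c"])),
            p16="negative",
            smoking=str(rng.choice(["current", "former"])),
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown group {group!r}")
    assert classify_patient(meta).label == group
    return meta


def sample_patient_params(config: CohortConfig, rng: np.random.Generator) -> list[PatientPlan]:
    """Draw per-patient metadata and planted lesion trajectories.

    Baselines and week-7 ratios are drawn per lesion class from the
    configured lognormals with stratified sampling, so the realized
    cohort medians sit on the planted medians rather than fluctuating
    with the cohort size.
    """
    labels = [g for g, n in config.group_sizes.items() for _ in range(n)]
    metas, node_counts = [], []
    for i, group in enumerate(labels):
        pid = f"p{i + 1:02d}"
        metas.append(_meta_for_group(pid, group, rng))
        node_counts.append(
            int(rng.choice(len(config.node_count_probs), p=config.node_count_probs))
        )

    slots = []  # (patient index, lesion_id, lesion_class)
    for i, n_nodes in enumerate(node_counts):
        slots.append((i, "P", "GTV-P"))
        slots.extend((i, f"N{j + 1}", "GTV-N") for j in range(n_nodes))

    draws: dict[tuple[str, str], np.ndarray] = {}
    for cls in ("GTV-P", "GTV-N"):
        n_cls = sum(1 for s in slots if s[2] == cls)
        for name, medians in (
            ("adc", config.baseline_adc_median),
            ("volume", config.baseline_volume_median),
            ("hrs", config.baseline_hrs_median),
            ("adc_ratio", config.adc_ratio_w7),
            ("volume_ratio", config.volume_ratio_w7),
            ("hrs_ratio", config.hrs_ratio_w7),
        ):
            draws[(cls, name)] = _stratified_lognormal(
                rng, medians[cls], config.dispersion, n_cls
            )

    cursor = {"GTV-P": 0, "GTV-N": 0}
    lesions_by_patient: list[list[PlantedTrajectory]] = [[] for _ in labels]
    for i, lesion_id, cls in slots:
        j = cursor[cls]
        cursor[cls] += 1
        vol = float(draws[(cls, "volume")][j])
        hrs = min(float(draws[(cls, "hrs")][j]), config.hrs_cap_fraction * vol)
        traj = PlantedTrajectory(
            patient_id=metas[i].patient_id,
            lesion_id=lesion_id,
            lesion_class=cls,
            baseline_adc=float(draws[(cls, "adc")][j]),
            baseline_volume=vol,
            baseline_hrs=hrs,
            adc_ratio=float(draws[(cls, "adc_ratio")][j]),
            volume_ratio=float(draws[(cls, "volume_ratio")][j]),
            hrs_ratio=float(draws[(cls, "hrs_ratio")][j]),
            hrs_cap_fraction=config.hrs_cap_fraction,
        )
        lesions_by_patient[i].append(_clamp_to_feasible(traj, config))

    return [
        PatientPlan(meta=metas[i], group=labels[i], lesions=lesions_by_patient[i])
        for i in range(len(labels))
    ]


# ---------------------------------------------------------------------------
# phantom construction

_SPHERE_ORDER_CACHE: dict[tuple, np.ndarray] = {}


def _sphere_order(shape, spacing) -> np.ndarray:
    """Flat voxel indices sorted by physical distance from the grid centre.

    Ties are broken by flat index so sphere discretization is
    deterministic; the first k indices form the best k-voxel sphere.
    """
    key = (tuple(shape), tuple(spacing))
    if key not in _SPHERE_ORDER_CACHE:
        coords = [
            ((np.arange(n) - (n - 1) / 2.0) * s) ** 2 for n, s in zip(shape, spacing)
        ]
        d2 = (
            coords[0][:, None, None]
            + coords[1][None, :, None]
            + coords[2][None, None, :]
        ).ravel()
        _SPHERE_ORDER_CACHE[key] = np.lexsort((np.arange(d2.size), d2))
    return _SPHERE_ORDER_CACHE[key]


def _shift_to_mean(draws: np.ndarray, target_mean: float, floor: float) -> np.ndarray:
    """Additively shift draws to the exact target mean, respecting a floor.

    If the shift pushes values below the floor they are clipped and the
    deficit redistributed over the rest, keeping the mean exact.
    """
    draws = draws + (target_mean - draws.mean())
    for _ in range(20):
        low = draws < floor
        if not low.any():
            return draws
        if low.all():
            break
        deficit = float((floor - draws[low]).sum())
        draws[low] = floor
        draws[~low] -= deficit / (~low).sum()
    raise ValueError(
        "cannot realize the requested lesion mean ADC without the bulk "
        "component crossing the high-risk band; reduce the dispersion or "
        "raise the planted mean"
    )


def build_phantom_frame(
    adc_mean: float,
    volume: float,
    hrs_volume: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized-sphere lesion mask and voxelwise true-ADC field.

    The mask holds the ``round(volume / voxel volume)`` voxels nearest the
    grid centre.  The innermost ``round(hrs_volume / voxel volume)``
    voxels draw ADC uniformly inside the high-risk component band; the
    remaining bulk voxels draw from a truncated normal above the band,
    shifted so the in-mask mean equals ``adc_mean`` exactly.
    """
    shape, spacing = config.grid_shape, config.voxel_spacing
    voxvol = float(np.prod(spacing)) / 1000.0
    k = max(1, int(round(volume / voxvol)))
    n_total = int(np.prod(shape))
    if k > n_total:
        raise ValueError(f"lesion of {volume:.1f} cm^3 does not fit the {shape} grid")
    n_hrs = int(round(hrs_volume / voxvol))
    n_hrs = min(n_hrs, int(config.hrs_cap_fraction * k), max(k - 1, 0))

    order = _sphere_order(shape, spacing)
    mask = np.zeros(n_total, dtype=bool)
    mask[order[:k]] = True

    field = np.zeros(n_total, dtype=float)
    lo, hi = config.hrs_component_band
    hrs_draws = rng.uniform(lo, hi, size=n_hrs)
    n_bulk = k - n_hrs
    bulk_target = (k * adc_mean - hrs_draws.sum()) / n_bulk
    if bulk_target < config.bulk_floor:
        raise ValueError(
            f"infeasible lesion mean {adc_mean:.2e} mm^2/s: the bulk component "
            f"would need mean {bulk_target:.2e} below its floor "
            f"{config.bulk_floor:.2e}; reduce the dispersion"
        )
    sigma = config.bulk_sigma

    def trunc_mean(center: float) -> float:
        alpha = (config.bulk_floor - center) / sigma
        lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        return center + sigma * lam

    # centre the truncated normal so its mean lands on the bulk target
    center = optimize.brentq(
        lambda c: trunc_mean(c) - bulk_target, bulk_target - 25 * sigma, bulk_target
    )
    alpha = (config.bulk_floor - center) / sigma
    bulk_draws = stats.truncnorm.rvs(
        alpha, np.inf, loc=center, scale=sigma, size=n_bulk, random_state=rng
    )
    # guard a little above the detection band's upper edge (900e-6) so the
    # exact-mean shift can never move bulk voxels into the band
    bulk_draws = _shift_to_mean(bulk_draws, bulk_target, 905e-6)

    field[order[:n_hrs]] = hrs_draws
    field[order[n_hrs:k]] = bulk_draws
    return mask.reshape(shape), field.reshape(shape)


# ---------------------------------------------------------------------------
# signal simulation


def simulate_dwi_signal(
    adc_field: np.ndarray,
    mask: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "",
    scan_day: int = 0,
) -> DWISeries:
    """Forward-simulate multi-b-value magnitude volumes with Rician noise.

    Each acquired average is the modulus of the noiseless signal plus a
    complex zero-mean Gaussian of standard deviation SI0 / snr_b0; the
    stored volume is the mean over the protocol's number of averages.
    With ``snr_b0`` None the volumes equal the noiseless forward signals.
    """
    si0 = np.where(mask, config.si0_lesion, config.si0_background)
    volumes = []
    for b, n_avg in zip(config.b_values, config.n_averages):
        clean = signal_forward(si0, b, adc_field)
        if config.snr_b0 is None or np.isinf(config.snr_b0):
            volumes.append(clean.astype(np.float32))
            continue
        sigma = config.si0_lesion / config.snr_b0
        shape = (n_avg,) + clean.shape
        g1 = rng.standard_normal(shape, dtype=np.float32) * sigma
        g2 = rng.standard_normal(shape, dtype=np.float32) * sigma
        magnitude = np.sqrt((clean.astype(np.float32) + g1) ** 2 + g2**2)
        volumes.append(magnitude.mean(axis=0))
    return DWISeries(
        patient_id=patient_id,
        scan_day=scan_day,
        b_values=tuple(config.b_values),
        volumes=volumes,
        voxel_spacing=tuple(config.voxel_spacing),
        n_averages=tuple(config.n_averages),
    )


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig, out_dir) -> dict:
    """Write a full synthetic cohort to disk; deterministic given the seed.

    Produces per-scan per-b-value NIfTI volumes, per-scan lesion masks,
    ``manifest.csv``, ``metadata.csv``, the planted ground truth
    ``truth.csv`` and a YAML echo of the generator configuration.
    Returns the paths of the tabular outputs.
    """
    out_dir = Path(out_dir)
    images = out_dir / "images"
    masks = out_dir / "masks"
    images.mkdir(parents=True, exist_ok=True)
    masks.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    plans = sample_patient_params(config, rng)

    records: list[ScanRecord] = []
    truth_rows = []
    for plan in plans:
        for traj in plan.lesions:
            for day in config.scan_days:
                week = assign_week(day)
                adc, vol, hrs = traj.true_values(week)
                lesion_mask, adc_field = build_phantom_frame(adc, vol, hrs, config, rng)
                series = simulate_dwi_signal(
                    adc_field, lesion_mask, config, rng, traj.patient_id, day
                )
                stem = f"{traj.patient_id}_{traj.lesion_id}_d{day:03d}"
                b_paths = []
                for b, volarr in zip(series.b_values, series.volumes):
                    p = images / f"{stem}_b{int(b)}.nii.gz"
                    save_volume(p, volarr, config.voxel_spacing, descrip=f"DWI b={int(b)}")
                    b_paths.append(str(p))
                mask_path = masks / f"{stem}_mask.nii.gz"
                save_mask(
                    LesionMask(
                        patient_id=traj.patient_id,
                        lesion_id=traj.lesion_id,
                        lesion_class=traj.lesion_class,
                        mask=lesion_mask,
                        voxel_spacing=config.voxel_spacing,
                    ),
                    mask_path,
                )
                records.append(
                    ScanRecord(
                        patient_id=traj.patient_id,
                        lesion_id=traj.lesion_id,
                        lesion_class=traj.lesion_class,
                        day=day,
                        mask_path=str(mask_path),
                        b_values=tuple(config.b_values),
                        b_paths=tuple(b_paths),
                        n_averages=tuple(config.n_averages),
                    )
                )
                truth_rows.append(
                    dict(
                        patient_id=traj.patient_id,
                        lesion_id=traj.lesion_id,
                        lesion_class=traj.lesion_class,
                        risk_group=plan.group,
                        day=day,
                        week=week,
                        true_adc_mean_1e6=adc * 1e6,
                        true_volume_cm3=vol,
                        true_hrs_cm3=hrs,
                        adc_ratio_w7=traj.adc_ratio,
                        volume_ratio_w7=traj.volume_ratio,
                        hrs_ratio_w7=traj.hrs_ratio,
                    )
                )
        logger.info("generated patient %s (%s, %d nodes)",
                    plan.meta.patient_id, plan.group, len(plan.lesions) - 1)

    manifest_path = out_dir / "manifest.csv"
    write_manifest(records, manifest_path)
    metadata_path = out_dir / "metadata.csv"
    pd.DataFrame(
        [asdict(p.meta) for p in plans]
    ).to_csv(metadata_path, index=False)
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False, float_format="%.10g")
    config.to_yaml(out_dir / "config.yaml")
    return {
        "manifest": manifest_path,
        "metadata": metadata_path,
        "truth": truth_path,
        "out_dir": out_dir,
    }
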