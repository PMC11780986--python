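"""Weekly cohort statistics for longitudinal lesion measurements.

Per-lesion time series (mean ADC, absolute volume, high-risk-subvolume
size) are binned into treatment weeks, summarized as cohort medians and
interquartile ranges, converted into relative changes from the
pretreatment baseline, and tested week by week for a median change
different from zero with a one-sample Wilcoxon signed-rank test.  Simple
per-group linear regressions over treatment time and repeatability-
coefficient change flags complete the summary.

The Wilcoxon test uses the exact sign-flip null distribution (computed by
dynamic programming over midranks, so ties are handled) for small samples
and a tie-corrected normal approximation with continuity correction for
larger ones; exact zero changes are dropped before ranking, the classic
convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .io_core import RunConfig
    from .lesion_metrics import LesionMeasurement

logger = logging.getLogger(__name__)

#: largest sample for which the exact sign-flip null is enumerated
EXACT_N_MAX = 25

QUANTITIES = ("adc_mean", "volume", "hrs_volume")


@dataclass
class RegressionFit:
    """Ordinary-least-squares line of a quantity against treatment week."""

    group: str
    lesion_class: str
    quantity: str
    slope: float
    intercept: float
    n_points: int


@dataclass
class WeeklySummary:
    """Cohort-level result tables.

    weekly : per (lesion class, risk group, quantity, week) medians, IQRs,
        median relative change from baseline and Wilcoxon p-value.
    course : per-lesion baseline-to-last-week changes with repeatability
        flags and HRS threshold classification.
    regressions : per-group OLS fits of each quantity on week.
    """

    weekly: pd.DataFrame
    course: pd.DataFrame
    regressions: pd.DataFrame


def assign_week(day: int) -> int:
    """Map days since the first fraction to a treatment week.

    Pretreatment scans (day <= 0) are week 0; treatment days fall into
    7-day bins starting at day 1, capped at week 7.
    """
    if day <= 0:
        return 0
    return min(7, (int(day) - 1) // 7 + 1)


def relative_change(value_w: float, baseline: float) -> float:
    """Percent change from baseline: ``100 * (value_w - baseline) / baseline``."""
    if not baseline > 0:
        raise ValueError("baseline must be positive for a relative change")
    return 100.0 * (value_w - baseline) / baseline


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of an empty sequence is undefined")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def _signed_rank_statistic(x: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ and the midrank vector of |x| (zeros already removed)."""
    ranks = stats.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())
    return w_plus, ranks


def _exact_sign_flip_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p via the sign-flip null distribution.

    Each of the 2^n sign assignments is equally likely under the null;
    the distribution of W+ = sum of ranks with positive sign is built by
    dynamic programming.  Midranks are half-integers, so everything is
    doubled to stay on an integer lattice.
    """
    d = np.rint(2 * ranks).astype(np.int64)
    total = int(d.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for di in d:
        shifted = np.zeros_like(counts)
        shifted[di:] = counts[: total + 1 - di]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if w_plus > mean:
        z = (w_plus - mean - 0.5) / sd
    elif w_plus < mean:
        z = (w_plus - mean + 0.5) / sd
    else:
        z = 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_one_sample(changes: Sequence[float]) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value for median != 0.

    Exact sign-flip null for n <= 25 non-zero values (ties get midranks),
    normal approximation with continuity and tie correction above.  Exact
    zeros are dropped before ranking; an all-zero sample gives p = 1.
    """
    x = np.asarray(changes, dtype=float)
    x = x[x != 0]
    if x.size == 0:
        logger.warning("Wilcoxon test on all-zero sample; returning p = 1")
        return 1.0
    w_plus, ranks = _signed_rank_statistic(x)
    if x.size <= EXACT_N_MAX:
        return _exact_sign_flip_p(w_plus, ranks)
    return _normal_approx_p(w_plus, ranks)


def fit_group_regression(
    points: Iterable[tuple[float, float]],
    group: str = "all",
    lesion_class: str = "",
    quantity: str = "",
) -> RegressionFit:
    """OLS fit of pooled lesion-level observations against week."""
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 2 or np.unique(pts[:, 0]).size < 2:
        raise ValueError("regression needs observations at >= 2 distinct weeks")
    design = np.column_stack([np.ones(pts.shape[0]), pts[:, 0]])
    coef, *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    return RegressionFit(
        group=group,
        lesion_class=lesion_class,
        quantity=quantity,
        slope=float(coef[1]),
        intercept=float(coef[0]),
        n_points=pts.shape[0],
    )


def flag_rc_exceedance(
    changes: Sequence[float], lesion_class: str, rel_rc: dict[str, float]
) -> np.ndarray:
    """True where |percent change| strictly exceeds the repeatability coefficient.

    ``rel_rc`` maps lesion class to the relative repeatability coefficient
    as a fraction (0.31 means a 31% change is the smallest detectable).
    """
    rc_pct = 100.0 * rel_rc[lesion_class]
    return np.abs(np.asarray(changes, dtype=float)) > rc_pct


def classify_hrs(hrs_volume: float, threshold: float) -> str:
    """'above' iff the high-risk subvolume strictly exceeds the threshold (cm^3)."""
    if hrs_volume < 0:
        raise ValueError("hrs_volume must be non-negative")
    return "above" if hrs_volume > threshold else "below"


# ---------------------------------------------------------------------------
# cohort assembly


def _dedupe_weekly(measurements: list["LesionMeasurement"]) -> list["LesionMeasurement"]:
    """Keep the earliest scan when a lesion has several in one week."""
    best: dict[tuple[str, str, int], "LesionMeasurement"] = {}
    for m in measurements:
        key = (m.patient_id, m.lesion_id, m.week)
        if key not in best or m.day < best[key].day:
            best[key] = m
    return sorted(best.values(), key=lambda m: (m.patient_id, m.lesion_id, m.week))


def summarize_cohort(
    measurements: list["LesionMeasurement"],
    groups: dict[str, str],
    config: "RunConfig",
) -> WeeklySummary:
    """Assemble per-lesion measurements into the weekly cohort summary.

    Lesions excluded by the minimum-volume rule contribute nothing; lesions
    whose HRS falls below the minimum HRS size keep contributing ADC and
    volume but drop out of the weekly HRS series.  Relative changes need a
    week-0 baseline (for HRS, a baseline HRS above the minimum).  The
    course-of-treatment change uses each lesion's latest measured week.
    """
    usable = [m for m in _dedupe_weekly(measurements) if not m.gtv_excluded]
    n_gtv_dropped = len({(m.patient_id, m.lesion_id) for m in measurements if m.gtv_excluded})
    if n_gtv_dropped:
        logger.info("summarize_cohort: %d lesion-scans below the GTV volume threshold", n_gtv_dropped)

    rows = []
    for m in usable:
        rows.append(
            dict(
                patient_id=m.patient_id,
                lesion_id=m.lesion_id,
                lesion_class=m.lesion_class,
                group=groups.get(m.patient_id, "unknown"),
                week=m.week,
                adc_mean=m.adc_mean,
                volume=m.volume,
                hrs_volume=m.hrs_volume,
                hrs_excluded=m.hrs_excluded,
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        empty = pd.DataFrame()
        return WeeklySummary(weekly=empty, course=empty, regressions=empty)

    baselines = df[df.week == 0].set_index(["patient_id", "lesion_id"])

    def _rel_series(sub: pd.DataFrame, quantity: str) -> pd.Series:
        """Percent change from the lesion's week-0 value; NaN without baseline."""
        out = np.full(len(sub), np.nan)
        for i, (_, r) in enumerate(sub.iterrows()):
            key = (r.patient_id, r.lesion_id)
            if key not in baselines.index:
                continue
            base = baselines.loc[key]
            if quantity == "hrs_volume" and bool(base.hrs_excluded):
                continue  # no valid baseline HRS
            bval = float(base[quantity])
            if bval > 0 and np.isfinite(r[quantity]):
                out[i] = relative_change(float(r[quantity]), bval)
        return pd.Series(out, index=sub.index)

    weekly_rows = []
    course_rows = []
    regressions = []
    group_labels = ["all"] + sorted({g for g in df.group.unique()})

    for lesion_class in sorted(df.lesion_class.unique()):
        cls_df = df[df.lesion_class == lesion_class]
        for quantity in QUANTITIES:
            qdf = cls_df if quantity != "hrs_volume" else cls_df[~cls_df.hrs_excluded]
            if qdf.empty:
                continue
            rel = _rel_series(qdf, quantity)
            for group in group_labels:
                gdf = qdf if group == "all" else qdf[qdf.group == group]
                if gdf.empty:
                    logger.info("no %s lesions in group %s", lesion_class, group)
                    continue
                for week in sorted(gdf.week.unique()):
                    wdf = gdf[gdf.week == week]
                    vals = wdf[quantity].to_numpy(dtype=float)
                    vals = vals[np.isfinite(vals)]
                    if vals.size == 0:
                        continue
                    med, iqr = median_iqr(vals)
                    changes = rel.loc[wdf.index].dropna().to_numpy()
                    med_change = float(np.median(changes)) if changes.size else np.nan
                    if week == 0 or changes.size == 0:
                        p = np.nan
                    else:
                        p = wilcoxon_one_sample(changes)
                    weekly_rows.append(
                        dict(
                            lesion_class=lesion_class,
                            group=group,
                            quantity=quantity,
                            week=int(week),
                            n=int(len(wdf)),
                            median=med,
                            iqr=iqr,
                            median_rel_change_pct=med_change,
                            p_value=p,
                            significant=bool(p < config.alpha) if np.isfinite(p) else False,
                        )
                    )
                # pooled per-group regression over treatment time
                pts = gdf[["week", quantity]].dropna().to_numpy(dtype=float)
                if pts.shape[0] >= 2 and np.unique(pts[:, 0]).size >= 2:
                    regressions.append(
                        fit_group_regression(pts, group=group, lesion_class=lesion_class, quantity=quantity)
                    )

            # Per-lesion course-of-treatment endpoint: latest measured week.
            # The endpoint uses the measured value at the lesion's final scan
            # even when that HRS falls below the reporting minimum; the
            # minimum-HRS rule gates only the baseline (a lesion with no
            # meaningful pretreatment HRS has no HRS change to report).
            for (pid, lid), lesion_df in cls_df.groupby(["patient_id", "lesion_id"]):
                if (pid, lid) not in baselines.index:
                    logger.info("lesion %s/%s has no baseline; dropped from change series", pid, lid)
                    continue
                base = baselines.loc[(pid, lid)]
                if quantity == "hrs_volume" and bool(base.hrs_excluded):
                    continue
                last = lesion_df.loc[lesion_df.week.idxmax()]
                if last.week == 0:
                    continue
                bval = float(base[quantity])
                lval = float(last[quantity])
                if not (bval > 0 and np.isfinite(lval)):
                    continue
                change = relative_change(lval, bval)
                row = dict(
                    patient_id=pid,
                    lesion_id=lid,
                    lesion_class=lesion_class,
                    group=groups.get(pid, "unknown"),
                    quantity=quantity,
                    baseline=bval,
                    last_week=int(last.week),
                    last_value=lval,
                    rel_change_pct=change,
                    rc_exceeded=bool(
                        flag_rc_exceedance([change], lesion_class, config.rel_rc)[0]
                    ),
                )
                if quantity == "hrs_volume":
                    row["hrs_class_baseline"] = classify_hrs(bval, config.hrs_classification_threshold)
                    row["hrs_class_last"] = classify_hrs(lval, config.hrs_classification_threshold)
                course_rows.append(row)

    weekly = pd.DataFrame(weekly_rows)
    course = pd.DataFrame(course_rows)
    reg = pd.DataFrame([vars(r) for r in regressions])
    return WeeklySummary(weekly=weekly, course=course, regressions=reg)
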