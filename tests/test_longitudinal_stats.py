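"""Week binning, change statistics, Wilcoxon test, regressions, cohort summary."""

import itertools

import numpy as np
import pytest
from scipy import stats

from adctrack import RunConfig
from adctrack.lesion_metrics import LesionMeasurement
from adctrack.longitudinal_stats import (
    assign_week,
    classify_hrs,
    fit_group_regression,
    flag_rc_exceedance,
    median_iqr,
    relative_change,
    summarize_cohort,
    wilcoxon_one_sample,
)


def brute_force_wilcoxon_p(x):
    """Two-sided p by full 2^n enumeration of sign assignments."""
    x = np.asarray([v for v in x if v != 0], dtype=float)
    ranks = stats.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    n = len(x)
    stats_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = len(stats_all)
    p_le = sum(1 for w in stats_all if w <= w_obs + 1e-9) / total
    p_ge = sum(1 for w in stats_all if w >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


@pytest.mark.parametrize(
    "day, week",
    [(-14, 0), (-3, 0), (0, 0), (1, 1), (7, 1), (8, 2), (14, 2), (15, 3), (46, 7), (60, 7)],
)
def test_assign_week(day, week):
    assert assign_week(day) == week


@pytest.mark.parametrize(
    "value, baseline, expected",
    [(7.0, 7.0, 0.0), (1.49 * 8.0, 8.0, 49.0), (0.32 * 5.0, 5.0, -68.0)],
)
def test_relative_change(value, baseline, expected):
    assert relative_change(value, baseline) == pytest.approx(expected)


def test_relative_change_requires_positive_baseline():
    with pytest.raises(ValueError):
        relative_change(1.0, 0.0)


class TestMedianIqr:
    def test_singleton(self):
        assert median_iqr([5.0]) == (5.0, 0.0)

    def test_even_length(self):
        med, iqr = median_iqr([1, 2, 3, 4])
        assert med == 2.5 and iqr == pytest.approx(1.5)

    def test_matches_sort_based_oracle(self, rng):
        def quantile_oracle(sorted_vals, p):
            h = (len(sorted_vals) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        for n in (3, 10, 25, 100):
            vals = rng.normal(size=n).tolist()
            s = sorted(vals)
            med, iqr = median_iqr(vals)
            assert med == pytest.approx(quantile_oracle(s, 0.5), rel=1e-12)
            assert iqr == pytest.approx(
                quantile_oracle(s, 0.75) - quantile_oracle(s, 0.25), rel=1e-10, abs=1e-12
            )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestWilcoxon:
    def test_sign_symmetric_sample(self):
        assert wilcoxon_one_sample([3.0, -3.0, 8.0, -8.0]) == pytest.approx(1.0)

    def test_five_sample_matches_enumeration(self):
        x = [5.0, 10.0, 20.0, -3.0, 8.0]
        assert wilcoxon_one_sample(x) == pytest.approx(brute_force_wilcoxon_p(x), abs=1e-12)

    def test_all_positive_n6_smallest_p(self):
        assert wilcoxon_one_sample([1, 2, 3, 4, 5, 6]) == pytest.approx(2 / 64)

    def test_zeros_dropped_before_ranking(self):
        x = [5.0, 10.0, 20.0, -3.0, 8.0]
        assert wilcoxon_one_sample(x + [0.0, 0.0]) == wilcoxon_one_sample(x)

    def test_all_zero_sample(self):
        assert wilcoxon_one_sample([0.0, 0.0]) == 1.0

    def test_ties_get_midranks(self, rng):
        # duplicate magnitudes force midranks; enumeration is the oracle
        for _ in range(20):
            x = rng.choice([-8.0, -4.0, 4.0, 4.0, 8.0, 12.0], size=7).tolist()
            if all(v == 0 for v in x):
                continue
            assert wilcoxon_one_sample(x) == pytest.approx(brute_force_wilcoxon_p(x), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for n in (6, 9, 12):
            x = rng.normal(loc=0.6, size=n)
            expected = stats.wilcoxon(x, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_one_sample(x) == pytest.approx(expected, rel=1e-10)

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(loc=0.4, size=60)
        p = wilcoxon_one_sample(x)
        expected = stats.wilcoxon(
            x, alternative="two-sided", method="approx", correction=True
        ).pvalue
        assert p == pytest.approx(expected, rel=1e-6)


class TestRegression:
    def test_collinear_points_exact(self):
        pts = [(w, 100.0 + 10.0 * w) for w in range(8)]
        fit = fit_group_regression(pts)
        assert fit.slope == pytest.approx(10.0, abs=1e-9)
        assert fit.intercept == pytest.approx(100.0, abs=1e-9)

    def test_two_points_line_through_both(self):
        fit = fit_group_regression([(0, 5.0), (7, 19.0)])
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(5.0)

    def test_matches_normal_equations_oracle(self, rng):
        w = rng.integers(0, 8, size=50).astype(float)
        y = 3.0 - 0.4 * w + rng.normal(scale=2.0, size=50)
        fit = fit_group_regression(list(zip(w, y)))
        n = len(w)
        sw, sy = w.sum(), y.sum()
        sww, swy = (w * w).sum(), (w * y).sum()
        slope = (n * swy - sw * sy) / (n * sww - sw * sw)
        intercept = (sy - slope * sw) / n
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_single_week_raises(self):
        with pytest.raises(ValueError):
            fit_group_regression([(3, 1.0), (3, 2.0)])


RC = {"GTV-P": 0.31, "GTV-N": 0.23}


@pytest.mark.parametrize(
    "changes, lesion_class, expected",
    [
        ([49.0], "GTV-P", [True]),
        ([-20.0], "GTV-N", [False]),
        ([31.0], "GTV-P", [False]),  # strict: exactly at the RC is not flagged
        ([-35.0, 10.0, 23.0, -23.5], "GTV-N", [True, False, False, True]),
    ],
)
def test_flag_rc_exceedance(changes, lesion_class, expected):
    assert flag_rc_exceedance(changes, lesion_class, RC).tolist() == expected


@pytest.mark.parametrize(
    "hrs, expected", [(6.0, "above"), (1.5, "below"), (5.8, "below")]
)
def test_classify_hrs(hrs, expected):
    assert classify_hrs(hrs, 5.8) == expected


def _meas(pid, lid, cls, day, week, adc, vol, hrs, gtv_ex=False, hrs_ex=False):
    return LesionMeasurement(
        patient_id=pid, lesion_id=lid, lesion_class=cls, day=day, week=week,
        adc_mean=adc, volume=vol, hrs_volume=hrs,
        n_voxels=10, n_hrs_voxels=1, n_undefined=0,
        gtv_excluded=gtv_ex, hrs_excluded=hrs_ex,
    )


class TestSummarizeCohort:
    GROUPS = {"p01": "high", "p02": "low"}

    def test_single_lesion_two_weeks(self, run_config):
        ms = [
            _meas("p01", "P", "GTV-P", 0, 0, 1.0e-3, 10.0, 2.0),
            _meas("p01", "P", "GTV-P", 46, 7, 1.5e-3, 4.0, 0.5),
        ]
        s = summarize_cohort(ms, self.GROUPS, run_config)
        course_adc = s.course[(s.course.quantity == "adc_mean")]
        assert len(course_adc) == 1
        assert course_adc.iloc[0].rel_change_pct == pytest.approx(50.0)
        assert bool(course_adc.iloc[0].rc_exceeded)  # 50% > 31% for GTV-P
        w0 = s.weekly[(s.weekly.week == 0) & (s.weekly.group == "all")]
        assert (w0.median_rel_change_pct == 0).all()
        assert w0.p_value.isna().all()

    def test_volume_excluded_lesion_contributes_nothing(self, run_config):
        ms = [
            _meas("p01", "P", "GTV-P", 0, 0, 1.0e-3, 10.0, 2.0),
            _meas("p02", "P", "GTV-P", 0, 0, 9.9e-3, 0.5, 0.3, gtv_ex=True),
        ]
        s = summarize_cohort(ms, self.GROUPS, run_config)
        w0 = s.weekly[(s.weekly.quantity == "adc_mean") & (s.weekly.group == "all")]
        assert int(w0.iloc[0].n) == 1
        assert w0.iloc[0]["median"] == pytest.approx(1.0e-3)

    def test_hrs_excluded_keeps_adc_and_volume(self, run_config):
        ms = [_meas("p01", "P", "GTV-P", 0, 0, 1.0e-3, 10.0, 0.1, hrs_ex=True)]
        s = summarize_cohort(ms, self.GROUPS, run_config)
        assert set(s.weekly.quantity) == {"adc_mean", "volume"}

    def test_earliest_scan_wins_within_a_week(self, run_config):
        ms = [
            _meas("p01", "P", "GTV-P", 2, 1, 1.0e-3, 10.0, 2.0),
            _meas("p01", "P", "GTV-P", 5, 1, 2.0e-3, 12.0, 2.5),
        ]
        s = summarize_cohort(ms, self.GROUPS, run_config)
        w1 = s.weekly[(s.weekly.quantity == "adc_mean") & (s.weekly.week == 1) & (s.weekly.group == "all")]
        assert w1.iloc[0]["median"] == pytest.approx(1.0e-3)

    def test_no_cross_talk_between_lesions(self, run_config):
        base = [
            _meas("p01", "P", "GTV-P", 0, 0, 1.0e-3, 10.0, 2.0),
            _meas("p01", "P", "GTV-P", 46, 7, 1.4e-3, 5.0, 0.6),
            _meas("p02", "P", "GTV-P", 0, 0, 1.2e-3, 8.0, 1.0),
            _meas("p02", "P", "GTV-P", 46, 7, 1.8e-3, 3.0, 0.4),
        ]
        full = summarize_cohort(base, self.GROUPS, run_config)
        reduced = summarize_cohort(base[:2], self.GROUPS, run_config)
        for q in ("adc_mean", "volume", "hrs_volume"):
            a = full.course[(full.course.patient_id == "p01") & (full.course.quantity == q)]
            b = reduced.course[reduced.course.quantity == q]
            assert a.iloc[0].rel_change_pct == b.iloc[0].rel_change_pct

    def test_lesion_without_baseline_dropped_from_changes(self, run_config):
        ms = [_meas("p01", "P", "GTV-P", 25, 4, 1.0e-3, 10.0, 2.0)]
        s = summarize_cohort(ms, self.GROUPS, run_config)
        assert s.course.empty
        w4 = s.weekly[s.weekly.week == 4]
        assert w4.median_rel_change_pct.isna().all()
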