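"""Voxelwise apparent-diffusion-coefficient (ADC) estimation.

Diffusion-weighted MRI signal decays with the diffusion weighting ``b``
(s/mm^2) according to the mono-exponential model

    SI(b) = SI0 * exp(-b * ADC)

where ``SI0`` is the signal at b = 0 and ADC is the apparent diffusion
coefficient in mm^2/s.  Two estimators are provided:

* a two-point estimator using one low and one high b-value image, the
  standard choice on MR-Linac protocols where the b = 0 image is excluded
  to suppress perfusion contamination, and
* a log-linear ordinary-least-squares fit over an arbitrary number of
  b-values, for legacy four-b protocols.

Voxels whose signal is non-positive (noise floor, background air) have no
defined log-domain solution and are marked NaN rather than silently set to
zero; negative ADC estimates caused by noise are retained unclamped so that
region means stay unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io_core import DWISeries, RunConfig

logger = logging.getLogger(__name__)

#: Marker for voxels where the fit is undefined (non-positive signal).
UNDEFINED = np.nan


@dataclass
class ADCMap:
    """Voxelwise ADC map on the grid of its source DWI series.

    ``values`` are in mm^2/s; undefined voxels are NaN.  Human-facing
    output uses 1e-6 mm^2/s (see :mod:`adctrack.io_core`).
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    b_pair_used: tuple[float, float]
    patient_id: str = ""
    day: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


def signal_forward(si0, b, adc):
    """Mono-exponential DWI signal: ``SI0 * exp(-b * ADC)``.

    Accepts scalars or broadcastable arrays; b in s/mm^2, adc in mm^2/s.
    """
    si0 = np.asarray(si0, dtype=float)
    return si0 * np.exp(-np.asarray(b, dtype=float) * np.asarray(adc, dtype=float))


def fit_adc_two_point(s_low, s_high, b_low: float, b_high: float):
    """ADC from two signals: ``ln(S_low / S_high) / (b_high - b_low)``.

    Vectorized over voxel arrays.  Returns NaN wherever either signal is
    non-positive or non-finite; negative estimates are returned as-is.
    """
    if not b_high > b_low:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    valid = (s_low > 0) & (s_high > 0) & np.isfinite(s_low) & np.isfinite(s_high)
    out = np.full(np.broadcast(s_low, s_high).shape, UNDEFINED)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(np.where(valid, s_low, 1.0) / np.where(valid, s_high, 1.0))
    out[valid] = ratio[valid] / (b_high - b_low)
    if out.ndim == 0:
        return float(out)
    return out


def fit_adc_loglinear(signals: Sequence[float] | np.ndarray, b_values: Sequence[float]):
    """ADC as the negated OLS slope of ln(SI) on b.

    ``signals`` may be a 1-D vector (one voxel) or an array whose first
    axis runs over b-values (voxelwise fit).  Voxels with fewer than two
    positive signals are NaN.  With exactly two positive points this
    reduces to the two-point estimator.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if s.shape[0] != b.size:
        raise ValueError("first axis of signals must match number of b-values")
    scalar = s.ndim == 1
    s = s.reshape(b.size, -1)
    valid = (s > 0) & np.isfinite(s)
    n = valid.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(valid, np.log(np.where(valid, s, 1.0)), 0.0)
        bv = np.where(valid, b[:, None], 0.0)
        # per-voxel OLS slope on the valid points only
        sum_b = bv.sum(axis=0)
        sum_y = logs.sum(axis=0)
        sum_bb = (bv * bv).sum(axis=0)
        sum_by = (bv * logs).sum(axis=0)
        denom = n * sum_bb - sum_b**2
        slope = np.where(denom > 0, (n * sum_by - sum_b * sum_y) / np.where(denom > 0, denom, 1.0), np.nan)
    adc = -slope
    adc[n < 2] = UNDEFINED
    if scalar:
        return float(adc[0])
    return adc.reshape(signals.shape[1:])


def compute_adc_map(series: "DWISeries", config: "RunConfig") -> ADCMap:
    """Voxelwise two-point ADC map on the configured b-value pair.

    When ``config.adc_b_pair`` is None, a log-linear fit over every
    positive-b image in the series is used instead.
    """
    if config.adc_b_pair is None:
        bsel = [b for b in series.b_values]
        stack = np.stack([series.volumes[series.b_values.index(b)] for b in bsel])
        values = fit_adc_loglinear(stack, bsel)
        pair = (min(bsel), max(bsel))
    else:
        b_low, b_high = config.adc_b_pair
        for b in (b_low, b_high):
            if b not in series.b_values:
                raise ValueError(
                    f"b = {b} s/mm^2 required for ADC fit but series "
                    f"{series.patient_id} day {series.scan_day} has b-values "
                    f"{tuple(series.b_values)}"
                )
        s_low = series.volumes[series.b_values.index(b_low)]
        s_high = series.volumes[series.b_values.index(b_high)]
        values = fit_adc_two_point(s_low, s_high, b_low, b_high)
        pair = (b_low, b_high)
    amap = ADCMap(
        values=values,
        voxel_spacing=series.voxel_spacing,
        b_pair_used=pair,
        patient_id=series.patient_id,
        day=series.scan_day,
        origin=series.origin,
    )
    if amap.n_undefined:
        logger.debug(
            "ADC map %s day %s: %d undefined voxels",
            series.patient_id, series.scan_day, amap.n_undefined,
        )
    return amap
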