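# Methods

## Problem and model

`adctrack` analyzes longitudinal diffusion-weighted MRI (DWI) acquired
during fractionated, MR-guided radiotherapy of head-and-neck cancer.
The measured quantity is the apparent diffusion coefficient (ADC),
estimated voxelwise from the mono-exponential signal model

```
SI(b) = SI0 · exp(−b · ADC)
```

with diffusion weighting `b` in s/mm² and ADC in mm²/s. The default
estimator is the two-point fit on `b = 150` and `500` s/mm²,

```
ADC = ln(S_low / S_high) / (b_high − b_low),
```

which is the estimator of choice on MR-Linac protocols: the `b = 0`
image is excluded to suppress perfusion contamination, and the highest
b-values to limit noise-floor bias. A log-linear ordinary-least-squares
fit over all acquired b-values is available for legacy four-b protocols
(`adc_b_pair=None` or `(200, 500)`).

Numerical conventions for the fit:

- voxels with a non-positive or non-finite signal have no log-domain
  solution and are marked NaN ("undefined"), counted, and excluded from
  all region statistics — never silently zeroed;
- negative ADC estimates (possible under noise) are retained unclamped
  so that region means stay unbiased; they can never enter the
  high-risk band, which is strictly positive;
- no spatial smoothing or denoising precedes the fit.

## Lesion measurements

Per delineated lesion (primary tumor GTV-P, lymph nodes GTV-N) and per
scan the pipeline reports:

- **mean ADC** — arithmetic mean over defined in-mask voxels;
- **absolute volume** — set-voxel count × voxel volume (cm³);
- **high-risk subvolume (HRS)** — volume of in-mask voxels with ADC
  strictly inside the band `(600, 900) × 1e-6 mm²/s`, a low-ADC range
  associated with radioresistant tumor subregions. The band is open at
  both ends and applied voxelwise with no connectivity filtering. The
  thresholds are calibrated to the MR-Linac's known ADC underestimation
  and are configurable for other scanners.

Two strict-inequality gates control what enters cohort statistics:
lesions with volume < 1 cm³ are excluded from everything; lesions with
HRS < 0.2 cm³ keep their ADC and volume series but leave the weekly HRS
series. Boundary values survive. Masks delineated on a different grid
are brought onto the ADC map by nearest-neighbour assignment in world
coordinates (voxel centres at `origin + (index + ½)·spacing`; points on
a cell boundary belong to the upper cell).

## Longitudinal statistics

Scans are binned into treatment weeks: day ≤ 0 → week 0 (pretreatment),
otherwise `floor((day − 1)/7) + 1`, capped at week 7. When a lesion has
two scans in one week the earlier is used. Per week, lesion class and
risk group the pipeline reports medians and interquartile ranges
(Q3 − Q1, linear interpolation between order statistics), median
relative changes from baseline (`100·(x_w − x_0)/x_0`), and a two-sided
one-sample Wilcoxon signed-rank test of the changes against zero at
α = 0.05 per week (no multiplicity correction across weeks, mirroring
common practice for exploratory weekly testing).

The Wilcoxon test drops exact zeros before ranking (classic
convention), assigns midranks to ties, and uses the exact sign-flip
null distribution for n ≤ 25 — computed by dynamic programming over
doubled midranks, equivalent to full 2ⁿ enumeration — and a
tie-corrected normal approximation with continuity correction above.

Course-of-treatment change uses each lesion's **last measured week**
(scan counts vary in practice), requiring a valid baseline. For HRS the
baseline must pass the 0.2 cm³ gate, but the endpoint is the measured
HRS at the lesion's final scan even when it has shrunk below the gate:
a subvolume that collapses during therapy is the signal, not a missing
value. Changes are also flagged against relative repeatability
coefficients (31% GTV-P, 23% GTV-N, strict exceedance), and HRS sizes
are classified against the 5.8 cm³ prognostic threshold (strictly
above/below). Per risk group, ordinary least squares of each quantity
on week (pooled lesion-level observations, no random effects) gives the
trend lines.

Risk groups follow the p16/smoking/TNM recursive-partitioning scheme
for oropharyngeal carcinoma, with all non-oropharyngeal primaries in a
fourth group. The rule table is configuration: smoking status maps to
the pack-year dichotomy as never → below cutoff, current/former → above
(overridable), and the p16-negative non-smoker branch treats T1–T3 as
intermediate (the original scheme's published branches leave T1
unstated; the adjacent branch is used).

## Synthetic cohort generator

No imaging from comparable MR-Linac cohorts is publicly deposited, so
validation uses digital phantoms whose planted values are recoverable
by construction. Defaults emulate a 27-patient cohort (risk groups
7/8/6/6 — the split is a generator choice, only the 21/6 OPC/non-OPC
split is constrained), 0–3 nodes per patient (≈1.45 mean, targeting
≈39 nodes), eight scans on days 0–46 (one per displayed week), 3×3×4 mm
voxels on a 64×64×32 grid per lesion, b = 0/150/500 s/mm² with 3/5/8
averages.

Planted distributions are lognormal around the pooled reference values:
baseline mean ADC 1167/1002 ×1e-6 mm²/s (GTV-P/GTV-N), volume
9.1/6.0 cm³, HRS 1.5/1.3 cm³ (capped at 0.9× volume); week-7/baseline
ratios 1.49/1.24 (ADC), 0.32/0.48 (volume), 0.07/0.13 (HRS); log-sigma
0.25 for everything (per-patient spread is not published; 0.25 gives
IQRs of the same order as reported). Two generator design choices
matter for interpretation:

- **Stratified draws.** Each parameter is drawn with one sample per
  probability stratum (shuffled). The marginal distribution is the
  configured lognormal, but the realized sample median sits on the
  configured median instead of fluctuating with √n — the cohort
  *conditions* are planted, not merely expected. Recovery tests
  therefore probe the pipeline, not the luck of 27 draws.
- **Feasibility clamp.** The phantom ADC field is a two-component
  mixture (below), which cannot represent a lesion mean under
  ≈ `950·(1−f) + 880·f` ×1e-6 mm²/s at HRS fraction f. Drawn ADC
  trajectories are raised onto this floor; only the low lognormal tail
  is affected, so all planted medians are unchanged.

Trajectories interpolate ADC linearly in week and decay volume and HRS
exponentially to the drawn week-7 ratio (the simplest monotone family
through both endpoints; the reference trends are roughly monotone).

Each frame is a discretized sphere: the `round(V/voxel)` voxels nearest
the grid centre (ties by index). The innermost `round(HRS/voxel)`
voxels draw ADC uniformly in (620, 880) ×1e-6 mm²/s — deliberately
inside the (600, 900) detection band so measurement noise cannot
systematically push planted HRS voxels across the edges — and the bulk
draws from a truncated normal (σ = 100 ×1e-6, floor 950 ×1e-6, centre
solved by root-finding), then shifts additively so the in-mask mean
equals the planted mean exactly.

Signals are simulated per b-value as the mean of `n_averages`
independent Rician draws — `|SI + ε₁ + iε₂|` with
`ε ~ N(0, (SI0/snr_b0)²)` — with uniform in-lesion SI0 = 1000 a.u.,
low constant background, and default `snr_b0 = 50` per averaged image,
giving a voxelwise ADC error SD below 60 ×1e-6 mm²/s under the default
protocol (verified by Monte-Carlo in the tests).

What the phantoms do **not** emulate: realistic lesion shape and
heterogeneity beyond the two-compartment mixture, EPI distortion,
partial-volume effects, motion, delineation variability, and
scanner-to-scanner ADC bias. Passing recovery tests demonstrates that
the estimators and bookkeeping are correct, not that the pipeline is
robust to those real-world effects.

## Problem sizes and tolerances in the test suite

The recovery suite runs the full default cohort (27 patients, 8 weekly
scans, ≈66 lesions, ≈92 s end to end) and checks pooled baseline
medians to 10% (20% for HRS, which carries band-leakage and voxel
quantization) and course-of-treatment median changes to 10 percentage
points (15 for HRS). The noiseless end-to-end check uses a 6-patient,
3-timepoint cohort and a tolerance of max(3%, half a voxel): where the
planted HRS has shrunk to a few voxels, half-voxel quantization — not
estimator error — is the binding limit. Determinism is asserted
byte-for-byte on regenerated cohorts and reanalyzed outputs.

## Known limitations

- Two-scan weeks are resolved by "earliest wins"; no within-week
  averaging.
- Regression pools lesions without per-patient random effects, so
  patients with many nodes weigh more in GTV-N trends.
- The exact Wilcoxon cutover (n = 25) is a speed/precision compromise;
  the approximation's continuity correction makes the two regimes agree
  to ~1e-2 in p near the boundary, which does not affect 5%-level calls
  in practice.
- Undefined-ADC voxels still count toward lesion volume (delineation
  defines volume); only ADC and HRS statistics skip them.
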