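# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `hazelpheno`. Days are day-of-year (DOY, Jan 1 = 1);
index values are unitless EVI in [−1, 1].

## Preprocessing

**EVI.** Computed from NIR/red/blue surface reflectance with gain 2.5,
aerosol-resistance coefficients C1 = 6, C2 = 7.5 and canopy background
adjustment L = 1. A near-zero denominator (|den| < 1e−6) or a result
outside [−1, 1] marks the sample invalid (NaN) rather than clipping it: the
stated index range is a validity condition, not a transform.

**Maximum-value compositing.** Periods restart every January 1 and are
dated at their start (the MODIS convention); the final period is truncated
at December 31, so an 8-day calendar yields 46 periods per non-leap year,
the last starting December 27. The composite value is the maximum over
valid entries in the period; empty periods are emitted flagged `missing` so
the grid stays regular.

**Expert quality floors.** EVI ≤ 0.1 at any date, or ≤ 0.3 inside the
summer window (June 1 – August 31 inclusive, configurable; the window is
month-granular in its source), flags the entry `discarded`. The filter
report counts each rule separately and the unique total (an entry failing
both floors is counted once in the total), at whatever granularity the
caller feeds in — per pixel, per year, or pooled.

**Savitzky–Golay smoothing.** Third-degree polynomial, half-width 9
composite steps (window length 19). Discarded/missing entries are linearly
interpolated first so the filter sees a regular grid, and keep their flags
afterwards. Edges use a least-squares polynomial fit over the terminal
window (`scipy` `mode="interp"`) rather than mirror padding: polynomial
edge fitting reproduces any signal of degree ≤ 3 exactly all the way to the
boundary, which matters because early-season transitions (late January)
sit near the calendar edge; mirror padding would distort them.

Note a consequence measured on synthetic data: at 8-day cadence a 19-point
window spans ~72 days each side, and on clean, steep double-logistic
transitions it systematically shifts the recovered 50%-amplitude date by
~1.5 days (much more for the 20% date, which sits in the high-curvature
toe). The smoother is therefore part of the standard pipeline for noisy
real imagery, but the recovery experiments below fit the quality-filtered
composites directly — the bounded least-squares fit is itself the noise
handler, and the generator's truth is exactly a double logistic, so the
experiments measure the estimator rather than the smoother's distortion.

## Seasonal curve model

One season per pixel-year is modelled as a greendown-capable double
logistic

    f(t) = b + (A − g·(t − t_up)) · [σ((t − t_up)/s_up) − σ((t − t_down)/s_down)]

with σ(z) = 1/(1+e^−z). Parameters: winter baseline b, seasonal amplitude
A (envelope value at the spring midpoint), spring midpoint/scale t_up, s_up
(days), autumn midpoint/scale t_down, s_down, and linear greendown slope g
(index units per day) describing the gradual summer decline after the
spring plateau. With g = 0 the model reduces exactly to the plain double
logistic, so the symmetric case nests inside the fitted family.

The linear greendown envelope is applied smoothly over the whole season
rather than switched on at t_up. A switched envelope, A − g·(t−t_up) for
t > t_up only, puts a derivative kink in the middle of the rising limb;
the curvature change rate K′(t) used by the greenup/maturity metrics is a
third-derivative quantity, and the kink produces a spike four orders of
magnitude above the genuine K′ maxima, breaking both the analytic
extraction and any numerical-differentiation oracle. Away from the season
the sigmoid difference vanishes, so the smooth and switched forms are
numerically indistinguishable on the data.

**Fitting.** Bounded nonlinear least squares (`scipy.optimize.least_squares`)
on valid composites from the target year ± 32 days of neighbours (January
transitions sit near the calendar edge). Bounds: b ∈ [−0.2, 0.6], A ∈
[0.05, 1.2], scales ∈ [1, 60] days, midpoints inside the padded window,
g ∈ [0, 0.01]/day; cost tolerance 1e−8. Initialisation is deterministic:
b₀ = 5th percentile of the year's values, A₀ = 95th − 5th percentile
(below 0.05 raises a no-seasonality error), t_up/t_down from the
half-amplitude crossings of the series, scales 10 days. If the first
attempt does not converge, up to four seeded jittered restarts are tried;
on noiseless input every seed returns the same solution to 1e−6. A fit is
`converged` when the optimizer succeeds, t_up < t_down, and the amplitude
clears the floor; unconverged pixel-years propagate as all-missing metric
sets. At least 10 valid in-year points are required (configurable).

The fit is also exposed as a scikit-learn estimator
(`DoubleLogisticRegressor`: `fit(X, y)` on day-of-year vs index,
`predict`, `get_params`/`set_params`, fitted attributes `params_`,
`rmse_`, `converged_`), so it composes with sklearn model-selection
tooling; `fit_double_logistic` is the pipeline wrapper around it.

**Season geometry.** Peak = curve maximum on the daily grid, refined on
the continuous model; trough = minimum over days before the peak; baseline
and peak values are the curve values there, amplitude their difference. A
peak on the first or last grid day raises a boundary warning that marks
all metrics of that pixel-year low-confidence. The trough is *not*
boundary-checked: with a flat winter tail the minimum legitimately sits at
the padded-window edge for every normal season.

## Phenometric extraction

All eight metrics are confined to the rising segment [trough, peak].
Searches bracket on the 1-day grid and refine on the continuous analytic
curve (`brentq` for threshold crossings, bounded scalar minimisation for
extrema), so returned dates are floats with sub-daily precision; table
writers round to whole days, the reporting convention of the field. Ties
(plateaus) break to the earliest day. Derivatives up to third order are
analytic — curvature quantities amplify noise badly under numerical
differentiation of sampled values.

* **Threshold (trs2/trs5):** first day f(t) ≥ baseline + 0.2·amplitude
  (resp. 0.5). No crossing → missing with reason.
* **Derivative (der_sos/der_pos):** argmax of f′ on the rising segment;
  the peak day.
* **Tangent/recovery line (gu_ud/gu_sd):** line through (t*, f(t*)) with
  slope f′(t*), t* the fastest-increase day; intersections with the
  baseline value and the peak value. Intersections outside the grid are
  clipped and flagged low-confidence; non-positive slope → missing.
* **Curvature change rate (greenup/maturity):** first and last local maxima
  of K′(t), K = f″/(1+f′²)^{3/2}, scanned at 0.1-day resolution with a
  relative prominence floor (10⁻³ of the largest maximum) to ignore
  float-level ripples in the near-flat winter tail, then refined. Fewer
  than two maxima → missing.

An independent brute-force implementation (`hazelpheno.reference`) computes
the same eight dates from *samples only* of any callable curve on a
0.01-day grid with `np.gradient` derivatives, windowed (±0.5-day) maxima
detection, a 1-day edge margin against one-sided-stencil artefacts, and
cluster splitting. It shares no derivative code with the analytic path; the
two routes agree within 0.06 days across 100 random seasonal curves (the
tolerance asserted is 1 day). The synthetic-data generator tabulates its
ground truth with this reference, keeping truth independent of the code
under test.

## Ground observations

Ten hazelnut spring phases are modelled: reproductive 61P, 64P, 67P, 70P,
71P (female flowering through clusters visible) and vegetative 03VP, 07VP,
10V, 13V, 15V (swollen buds through more leaves unfolded). The
source-scale → BBCH mapping ships as an editable CSV with these ten codes
preloaded as identity entries; unmapped codes are preserved and reported,
duplicates collapse, unparseable dates are rejected and logged.

Onset per orchard-year-phase is `first-seen` (earliest recorded day) by
default — the phenology convention for "beginning of stage", whose error
under weekly visits is bounded by 7 days and averages 3.5 — with
`median-seen` as the alternative; neither is asserted as the historical
workflow's rule, which is not documented. December observations are
assigned to the following phenological year with negative DOY (Dec 20 →
−11, configurable), so December flowering compares against January
metrics without a ~330-day wrap artefact.

## Matchup statistics

Bias = mean(metric − phase): positive means the satellite metric falls
after the ground phase. RMSD = root mean square of the same differences;
RMSD² − bias² equals the population variance of the differences. Spearman
r_s uses average ranks for ties; the p-value is the scipy t-approximation
for n ≥ 10 and a two-sided permutation test below that (full enumeration
up to n = 8, i.e. 40 320 permutations, evaluated as one matrix product;
10⁵ seeded resamples for n = 9), because the t-approximation is unreliable
at the small per-cell n that coverage stratification produces. No
multiple-testing correction by default, matching per-cell p < 0.05
flagging; Benjamini–Hochberg is available opt-in. Cells with fewer than 3
pairs are suppressed. Stratification splits pixels at a 75% crop-coverage
threshold. Pooling across years is the default; per-year tables can be
built by filtering the inputs.

## Synthetic data

The generator emulates the target study setting: ~20 MODIS-like pixels
(one per surveyed orchard, identity link table), 8-day cadence over
2019–2022, weekly surveys of the ten phases, per-pixel coverage fractions,
and a West/East region split. Defaults — winter baseline 0.15–0.30,
amplitude 0.3–0.6, spring midpoint DOY 85–110, scales 6–15 days, autumn
midpoint DOY 280–310, greendown 0–0.001/day, Gaussian noise sd 0.02, 10%
composite dropout, coverage 0.35–1.0 — put the 50%-amplitude date in the
DOY 90–120 window typical of Black-Sea hazelnut spring. An optional
understory-greening bump (Gaussian hump, default amplitude 0.05 centred
DOY 45) injects the late-winter confounder that inflates early metrics,
for tests that need it; it is excluded from the truth curve.

Phase truth dates are a configured offset (plus Gaussian jitter, sd 2 d)
from a named true metric; the defaults are sign-consistent with the
observed ordering of satellite metrics around flowering and leaf phases,
but they are test scaffolding, not biology. Surveys record each phase on
the first weekly visit on/after its true date, so recorded − true ∈ [0, 7)
with mean 3.5 days.

Seeding is counter-based (`SeedSequence([seed, stream, pixel_index])`):
adding pixels never shifts earlier pixels' draws, and the same seed
reproduces byte-identical outputs.

What the generator does *not* emulate: atmospheric spike contamination
(so the expert filter discards ~0% of clean synthetic data, versus a few
percent on real imagery), spatial autocorrelation between pixels, multiple
growing seasons, leap-season boundary effects beyond simple padding, and
real reflectance physics. Passing tests therefore demonstrate estimator
correctness and pipeline integrity under the stated noise model, not
performance on real MODIS data.

## Validation quantities

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
at run time: the compositing calendar (46 periods, last start DOY 361);
the worst closed-form error on a rising logistic (gu_ud = m − 2s,
gu_sd = m + 2s, trs5 = m, trs2 = m − s·ln 4, der_sos = m); the maximum
implementation-vs-brute-force divergence over 100 random curves; median
|trs5 − truth| and convergence rate over 50 noisy pixel-years (noise 0.02,
dropout 10%); the mean recovered bias over 200 replicates of a +15-day
configured offset observed through weekly surveys (implied value −18.5 d);
the toy bias/RMSD vectors; the Savitzky–Golay cubic-reproduction error;
the expert-filter count on a constructed toy year and the discarded
fraction of a full simulated campaign; and a pipeline byte-determinism
flag. Problem sizes (50 pixel-years, 100 oracle curves, 200 replicates of
10 orchard-years) were chosen as the smallest designs whose Monte-Carlo
error is comfortably below the assertion tolerances.

## Known limitations

* The double-logistic parameterization is this package's own
  greendown-capable form; other fine-fitting families (sigmoidal greendown,
  piecewise logistics) would give slightly different curvature metrics.
* Single season per year by construction; double-cropping or evergreen
  signals will fail the amplitude floor or fit poorly.
* The Gu baseline/peak lines use the pre-season trough value and seasonal
  maximum; formulations using fitted asymptotes differ near boundary
  seasons.
* Leap years are handled by calendar arithmetic, but metrics are reported
  on a 365-day grid basis with padding; sub-day leap effects are ignored.
* The ASCII-grid map export requires pixels on a regular lon/lat grid;
  irregular layouts fall back to a point table.
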