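# hazelpheno

Land-surface spring phenology from satellite vegetation-index time series,
with statistical matchup against ground-observed BBCH phenophases.

The package targets the workflow used to monitor deciduous orchard crops
(the motivating system is hazelnut on the Turkish Black Sea coast) with
MODIS-like 8-day Enhanced Vegetation Index composites: per-pixel EVI series
are quality-filtered and smoothed, a seasonal double-logistic curve is
fitted per pixel-year at daily resolution, eight spring transition dates
("phenometrics") are extracted from the fitted curve, and those dates are
compared with phase-onset dates derived from weekly orchard surveys coded
on the BBCH scale. Because real orchard campaigns are rarely public, a
first-class synthetic-data generator produces pixels and matched surveys
with known ground truth, so every stage is testable end to end.

## Model and metrics

EVI is computed from surface reflectance as

    EVI = G (ρ_NIR − ρ_red) / (ρ_NIR + C1 ρ_red − C2 ρ_blue + L)

with G = 2.5, C1 = 6, C2 = 7.5, L = 1. Eight-day maximum-value composites
(46 per non-leap year, Jan 1 … Dec 27) are screened by expert floors
(EVI > 0.1 year-round, EVI > 0.3 in June–August) and smoothed with a
third-degree Savitzky–Golay filter (half-width 9 composite steps).

Each pixel-year is then fitted with a greendown-capable double logistic

    f(t) = b + (A − g·(t − t_up)) · [σ((t − t_up)/s_up) − σ((t − t_down)/s_down)]

where b is the winter baseline, A the seasonal amplitude, (t_up, s_up) and
(t_down, s_down) the spring/autumn midpoints and scales, and g a linear
summer greendown slope. From the daily fitted curve and its season geometry
(trough, peak, amplitude) eight spring phenometrics are extracted:

| metric | definition |
|---|---|
| `trs2_sos`, `trs5_sos` | first day the curve reaches 20% / 50% of the annual amplitude above baseline |
| `der_sos`, `der_pos` | day of the fastest increase; day of the curve maximum |
| `gu_ud`, `gu_sd` | upturn / stabilization dates: the tangent (recovery) line at the fastest-increase day intersected with the baseline and the peak line |
| `greenup`, `maturity` | first and last local maxima of the curvature change rate K′(t), K = f″/(1+f′²)^{3/2}, on the rising limb |

Ground surveys are reduced to one onset date per orchard-year-phase
(first-seen by default; median-seen available), and each (metric, phase)
cell is summarised by bias = mean(metric − phase) (positive: satellite
later than ground), RMSD, and Spearman rank correlation r_s with a
two-sided p-value (exact permutation below n = 10).

## Worked example

```python
from hazelpheno import (SimulationConfig, simulate_series, simulate_surveys,
                        fit_double_logistic, extract_all, load_observations,
                        phase_onsets, compare_all, link_table)
from hazelpheno.phenometrics import metrics_table

cfg = SimulationConfig(n_pixels=5, years=(2020, 2021),
                       noise_sd=0.02, dropout_prob=0.1, seed=42)
series, truth = simulate_series(cfg)

sets = [extract_all(fit_double_logistic(s, y)) for s in series for y in cfg.years]
metrics = metrics_table(sets)
print(metrics.drop(columns="reasons").head(4).to_string(index=False))
```

```
pixel_id  year  der_sos  der_pos  trs2_sos  trs5_sos  gu_ud  gu_sd  greenup  maturity
pixel_00  2020    103.0    156.0      84.0     102.0   77.0  126.0     73.0     133.0
pixel_00  2021    102.0    167.0      84.0     101.0   76.0  126.0     73.0     131.0
pixel_01  2020    106.0    156.0      83.0     103.0   76.0  130.0     72.0     140.0
pixel_01  2021     94.0    131.0      81.0      93.0   76.0  111.0     73.0     116.0
```

Each column is a day-of-year: e.g. pixel_00 in 2020 crossed half its
seasonal amplitude (`trs5_sos`) on day 102 (April 11) and peaked
(`der_pos`) on day 156. Comparing against the matched synthetic surveys:

```python
surveys = simulate_surveys(truth, cfg)
obs, qc = load_observations(surveys)
onsets = phase_onsets(obs)
table = compare_all(metrics, onsets, link=link_table(cfg))
print(table[(table.metric.isin(["trs5_sos", "greenup"]))
            & (table.phase.isin(["10V", "61P"]))].to_string(index=False))
```

```
stratum   metric phase  n  bias_days  rmsd_days      r_s  p_value  significant_05
    all trs5_sos   61P 10       36.1  36.528071 0.714895 0.020144            True
    all trs5_sos   10V 10       -5.2   6.324555 0.871187 0.001028            True
    all  greenup   61P 10       12.0  12.930584 0.506671 0.135039           False
    all  greenup   10V 10      -29.3  29.767432 0.649892 0.041944            True
```

The generator placed the synthetic female-flowering phase (61P) 15 days
before the curvature-rate `greenup` date; the recovered bias of +12 days is
that offset minus the ~3.5-day mean delay of weekly first-seen sampling.
`trs5_sos` tracks the leaf-emergence phase (10V) closely (bias −5.2 days,
r_s = 0.87).

A `hazelpheno` CLI wraps the same stages (`simulate`, `preprocess`, `fit`,
`extract`, `onsets`, `compare`, `map`, `run`); `hazelpheno run --config
cfg.yaml` executes the full pipeline and writes every intermediate CSV plus
a structured run log.

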