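# pneumolag

Distributed lag non-linear modelling of meteorological drivers of
pneumonia hospital admissions.

Daily hospital admissions for pneumonia respond to weather with a
delay: a cold spell or a dry spell can change admission rates days to
weeks later. `pneumolag` implements the full analysis chain used to
quantify such lagged associations in low-count, zero-heavy admission
series — the setting typical of district hospitals, where a day
averages roughly one admission and many days have none. It is written
for epidemiologists and biostatisticians analysing climate–health time
series, and ships a synthetic-data generator with known ground truth so
every stage can be validated end to end.

## The model

Admission counts `y_t` follow a zero-inflated negative binomial (ZINB)
mixture: with probability `π_t` the day is a structural zero, otherwise
`y_t ~ NB(μ_t, α)` with variance `μ + αμ²`. The rate component is

    log μ_t = β₀ + Σ_s cb_s(x_s; θ_s) + DOW_t + γ₁ sin(2πt/P) + γ₂ cos(2πt/P) + trend(t)

where `cb_s` is a *crossbasis* — the tensor product of a natural cubic
spline over exposure value and a natural cubic spline over lag
0…21 days, summed over the lag window — for mean temperature and
relative humidity, plus an unlagged spline for the diurnal temperature
range (DTR); `DOW` is day of week (Sunday reference), the Fourier pair
has a 6-month period (`P` = 182.625 d), and `trend` is a long-term
natural spline. The zero component is a logistic model with day of
week, the admission counts of the preceding three days (an
infectious-disease autocorrelation device), and optionally the same
Fourier pair.

Everything downstream is contrast algebra on the fitted crossbasis
coefficients:

* **Relative rates.** `log RR(x, ℓ) = [b_x(x) − b_x(c)] ⊗ b_ℓ(ℓ) · θ`,
  centred at reference exposures `c` (21 °C mean temperature, 67 % RH,
  1.3 °C DTR) so `RR(c) ≡ 1`; the cumulative association is the product
  over lags 0–21. Intervals are delta-method on the log scale.
* **Attributable fractions** (backward perspective). For each day,
  `b-AF_t = 1 − exp(−Σ_ℓ η(x_{t−ℓ}, ℓ))`: the share of that day's cases
  attributable to the exposures of the preceding three weeks, negative
  when those exposures were protective. Totals are count-weighted, with
  exposure-subrange decompositions (e.g. days below 14 °C / above
  26 °C), distribution-shift scenarios (e.g. +2 °C), and empirical 95 %
  intervals from 1000 Monte-Carlo draws of the coefficient vector.
* **Missing data.** Records missing an admission date are recovered as
  discharge date minus length of stay; missing lengths of stay are
  multiply imputed by predictive mean matching (20 imputations) and
  per-imputation fits are pooled by Rubin's rules at the coefficient
  level.

## Worked example

Simulate four years of a synthetic study and fit it:

```python
from pneumolag.synthetic import simulate_meteorology, simulate_admissions, default_truth
from pneumolag.model import ModelSpec, build_design, fit_from_bundle
from pneumolag.prediction import predict_rr
from pneumolag.attribution import mc_ci

met = simulate_meteorology(1500, seed=7)
daily = simulate_admissions(met, default_truth(), seed=7)
print("days:", len(daily), " mean admissions/day:", round(daily["count"].mean(), 2),
      " zero days:", f"{(daily['count'] == 0).mean():.0%}")

bundle = build_design(daily, ModelSpec())
fit = fit_from_bundle(bundle)
print("converged:", fit.converged, " dispersion alpha:", round(fit.alpha, 2))

cb = bundle.crossbases["mean_temp"]
cp = predict_rr(fit, cb, exposure_grid=[12.0, 30.0], center=21.0)
for x, rr, lo, hi in zip(cp.exposure_grid, cp.cum_rr, cp.cum_low, cp.cum_high):
    print(f"cumulative RR at {x:.0f} degC vs 21 degC: {rr:.2f} (95% CI {lo:.2f}-{hi:.2f})")

x_full = daily["mean_temp"].to_numpy()[bundle.first_valid - 21:]
af = mc_ci(fit, cb, x_full, bundle.y, center=21.0, n_mc=1000, seed=7)
print(f"temperature AF: {100*af.total_af:.1f}% "
      f"(95% CI {100*af.ci_low:.1f}% to {100*af.ci_high:.1f}%)")
```

which prints:

```
days: 1479  mean admissions/day: 1.19  zero days: 45%
converged: True  dispersion alpha: 0.23
cumulative RR at 12 degC vs 21 degC: 3.28 (95% CI 1.00-10.81)
cumulative RR at 30 degC vs 21 degC: 0.76 (95% CI 0.33-1.74)
temperature AF: -13.9% (95% CI -75.6% to 22.8%)
```

Cold days (12 °C vs the 21 °C reference) raise subsequent admissions
cumulatively over three weeks, hot days lower them, and the total
temperature AF is negative — on balance, departures from 21 °C averted
admissions in this draw — with wide intervals, as expected from ~1.3
events/day. The same analysis runs from the shell:

```sh
pneumolag simulate --days 3000 --seed 1 --out study/
pneumolag run --records study/records.csv --meteorology study/meteorology.csv --out results/
```

writing the coefficient table, RR tables (enough to replot lag-specific
and cumulative association curves), the attributable-fraction table in
percent, residual/ACF diagnostics and a run manifest.

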