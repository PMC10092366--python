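# fastslow

Do species' life-history strategies shape how their populations respond to
temperature and land-cover change? `fastslow` is an analysis pipeline for
that question: it turns vertebrate population time series (Living Planet
Database style), gridded monthly temperature, annual categorical land-cover
maps, and species trait tables into a fitted linear mixed model of
population trends on environmental change rates and the fast–slow
life-history continuum — together with a synthetic-data generator with
known ground truth, so every stage is testable without the original data
archives. It is aimed at macroecologists working with population-trend
compilations and at anyone auditing the robustness of trend–covariate
analyses.

## The statistics at the core

Each population's trend is its mean annual log10 rate of change,

    λ_t = log10(n_t / n_{t-1}),        λ̄ = (1/T) Σ_t λ_t ,

computed after replacing zero counts by 1% of the series' mean non-zero
abundance and imputing interior gaps on the log10 scale (linear regression
when fewer than six real observations; otherwise a penalized-regression-
spline GAM with basis dimension of half the series span). Populations need
at least 5 consecutive values inside the analysis window (default
1992–2018) and, where imputation was needed, a model fit R² ≥ 0.5.

Trends are modelled with crossed random intercepts for location and
species:

    λ̄ ~ ΔT + PC1 + Σ_i Lu_i + ΔT:PC1 + Σ_i Lu_i:PC1 + Σ_i Lu_i:ΔT
        + Σ_i Lu_i:PC1:ΔT + (1|Location) + (1|Species)

where ΔT is the OLS slope of annual mean temperature over the population's
window, Lu_i is the mean annual change of land-cover class i (8 classes:
forest, shrubs, natural grass, bare soil, cropland, snow/ice, urban,
water), and PC1 is the species' score on the fast–slow continuum — the
first principal component of four life-history traits (longevity, age at
maturity, reproductive events per year, offspring per event) after
removing body-mass allometry and taxonomic kinship by mixed-model
residualization, oriented so that high PC1 = fast (fecund, short-lived).
The full model is reduced by backward stepwise selection on AICc (ML fits,
marginality respected, REML refit of the winner); fixed effects are tested
with type-III Wald χ² and fit is summarized with marginal/conditional
pseudo-R². Two sensitivity protocols re-run the fit across imputation-R²
thresholds (0.3/0.5/0.7/0.9) and after trimming populations beyond the
2.5th/97.5th percentiles of λ̄.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data (each is a thin driver over the library; `fastslow all`
does the same in one command):

```sh
python analysis/01_simulate.py          --seed 1
python analysis/02_population_trends.py --seed 1
python analysis/03_environmental_change.py --seed 1
python analysis/04_life_history.py      --seed 1
python analysis/05_fit_trend_model.py   --seed 1
python analysis/06_sensitivity.py       --seed 1
```

With seed 1 the trend stage prints

```
retained 222 of 300 populations (window (1992, 2018), min length 5, R2 >= 0.5)
exclusion_reason
low imputation R2    44
too short            34
```

— 300 simulated series, of which 44 imputed too poorly and 34 were too
short inside the window. The model stage then reports

```
n = 222 populations; selected 24 fixed terms; AICc -737.2
marginal pseudo-R2 0.296, conditional 0.405
```

with a Table-1-style row per term (estimate, SE, Wald χ², p), e.g.
`delta_t 0.5493 (SE 0.1701), χ² = 10.42, p = .0012` — close to the
generating warming coefficient. The sensitivity stage reports which terms
flip sign or lose significance when extreme-trend populations are trimmed:

```
100 term x scenario rows; 8 sign flips, 14 significance changes vs baseline
```

illustrating (on data where we know the truth) how strongly trend–covariate
models can depend on a few extreme populations.

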