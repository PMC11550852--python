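# fertconv

β-convergence of fertility indicators over educational attainment.

`fertconv` is for demographers and social scientists who want to ask whether
countries are becoming more similar in the *level* (TFR, NRR) and *timing*
(mean age at childbearing, MACB) of fertility **as education expands**, rather
than simply as time passes. It provides the full analysis chain — panel
linking and validation, construction of the growth-over-education statistic,
outlier fencing, standardization, fixed-effects estimation with
cluster-robust inference, and a subgroup/indicator analysis grid — together
with a synthetic demographic-transition generator with known ground truth,
so every stage of the pipeline can be validated end to end without any
external data download.

## The model

Classical growth convergence regresses an indicator's growth rate over time
on its base level. `fertconv` implements the education-denominated variant:
for country *i* and base year *t* on a quinquennial lattice,

```
[ln FER_{i,t+5} − ln FER_{i,t}] / (EDU_{i,t+5} − EDU_{i,t})
        = α + β · FER_{i,t} + γ_i + ε_{i,t}
```

where `FER` is any fertility indicator, `EDU` any education measure (mean
years of schooling, or the share of women who attended/completed
primary/secondary/tertiary school), `γ_i` a country fixed effect, and
`ε_{i,t}` an error clustered at the country level. β < 0 is convergence:
countries starting with high fertility lose fertility proportionally faster
per unit of education gained, so the cross-country distribution compresses
along the education index. The classical time-denominated regression is the
special case where the denominator is the elapsed time itself
(`build_time_sample`).

Because a near-zero education change makes the ratio explode, rows with
ΔEDU ≈ 0 are excluded, and remaining extremes are trimmed by the quartile
fence rule `[Q1 − 3·IQR, Q3 + 3·IQR]` computed on each regression cell's
ratio distribution. Coefficients are reported standardized (outcome and
regressors z-scored on the estimation sample) so that differently scaled
indicators are comparable; the unstandardized fit is available via a flag.
Standard errors use the CR1 cluster sandwich; intervals and p-values use
the t distribution with G − 1 degrees of freedom (G = countries).

## Worked example

```python
import fertconv as fc

# a study-shaped synthetic panel: 146 countries, 1950–2015 every 5 years,
# three fertility indicators, seven education measures, known ground truth
res = fc.simulate_scenario(fc.default_scenario(seed=1))

sample = fc.trim_outliers(
    fc.build_edu_sample(res.panel, "TFR", "years_schooling")
)
fit = fc.fit_convergence(fc.standardize(sample), fixed_effects=True)
print(f"beta = {fit.beta:.3f}  (95% CI {fit.ci_low:.3f} to {fit.ci_high:.3f})")
print(f"flag = {fit.converged_flag}, countries = {fit.n_countries}, "
      f"intervals = {fit.n_obs}")
```

prints

```
beta = -0.945  (95% CI -0.963 to -0.926)
flag = convergence, countries = 146, intervals = 1898
```

The standardized β of −0.945 says that a one-standard-deviation higher base
TFR is associated with an almost one-standard-deviation more negative growth
rate of TFR per year of schooling gained — strong convergence, as planted
(this scenario's unstandardized ground truth is β = −0.04; the same fit with
`fc.fit_convergence(sample)` on the unstandardized sample returns −0.0404).
The 146 countries × 13 intervals give 1898 usable rows; none were excluded
for zero education change and none fell outside the quartile fences.

The full analysis grid and the two educational gradients:

```python
grid = fc.run_grid(res.panel, res.metadata, fc.GridSpec())   # 105 cells
fc.report(grid, "out/")            # tidy CSV + provenance + forest plots
print(fc.gradient_summary(grid))   # tertiary ≥ secondary ≥ primary?
                                   # completed ≥ attended?
```

The same operations are exposed as a CLI:

```bash
fertconv simulate --seed 1 --out sim/
fertconv fit sim/panel.csv --fertility TFR --education years_schooling
fertconv grid sim/panel.csv --metadata sim/metadata.csv --out out/
```

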