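# Methods

## The estimand

The package estimates β-convergence of a fertility indicator over an
education indicator on a country-year lattice. The unit of analysis is the
country-interval: for each country *i* and base year *t* with both
indicators observed at *t* and *t + h* (default horizon h = 5 years), the
outcome is the log change in fertility per unit change in education,

    r_it = [ln FER_{i,t+h} − ln FER_{i,t}] / (EDU_{i,t+h} − EDU_{i,t}),

regressed on the base level FER_{i,t} with a country intercept γ_i and an
error clustered by country:

    r_it = α + β FER_{i,t} + γ_i + ε_{it}.

β < 0 means countries with higher base fertility lose (log) fertility
faster per unit of education gained — cross-country convergence along the
education index. The time-denominated classical regression is the special
case with denominator h, provided by `build_time_sample`.

Natural logarithms are used throughout. For age-type indicators (mean age
at childbearing) the same equation applies; convergence there means ages
rise fastest where they start lowest, which corresponds to a positive α
and a small negative β in the indicator's units.

## Sample construction order

The pipeline applies, in this fixed order per regression cell (one
fertility × education pair within one subgroup):

1. **Subgroup filter** on country metadata (income group, SSA flag).
2. **Ratio construction** with exclusion of rows whose education change is
   below `zero_tol = 1e-9` in the education indicator's units (the ratio is
   undefined at ΔEDU = 0; near-zero changes produce arbitrarily extreme
   values). Nonpositive fertility endpoints are likewise excluded (log
   undefined). Negative education changes are retained by default — small
   declines are plausible when older, better-educated cohorts age out of
   the 25–64 window — and a strict flag excludes them.
3. **Fence trimming**: retain ratios in [Q1 − k·IQR, Q3 + k·IQR], default
   k = 3, with quartiles computed by linear interpolation on the cell's own
   ratio distribution. The rule is applied exactly once; re-fencing a
   trimmed sample could remove further rows, and the pipeline deliberately
   does not iterate. Fences are per cell, not pooled across cells, because
   pooled fences would mix indicators with different scales.
4. **Standardization**: outcome, base fertility, and covariates are
   z-scored (n − 1 denominator) on the post-trim estimation sample, so the
   reported coefficient is a standardized effect comparable across
   indicator scales. Degenerate (zero-variance) cells raise an error.
5. **Estimation** (below). Covariates (e.g. contraceptive prevalence at the
   base year) enter standardized alongside the base level, as additional
   slopes.

Trimming precedes standardization because the fences change the sample
moments; standardizing first would make the reported coefficients depend on
observations that are subsequently discarded.

## Estimation and inference

Country fixed effects are absorbed by within-country demeaning (the within
transformation), which is numerically more stable than explicit dummies at
scale; the least-squares-dummy-variables solution is retained in
`lsdv_oracle` as an independently coded equivalence oracle (explicit dummy
design, explicit per-cluster meat-matrix loop), not as a production path.

Variance uses the CR1 cluster-robust sandwich

    V = c (X'X)⁻¹ [Σ_g X_g'e_g e_g'X_g] (X'X)⁻¹,
    c = G/(G−1) · (N−1)/(N−K),

with clusters g = countries. K counts *all* model parameters, including the
G absorbed country intercepts, so the within-transform SE equals the LSDV
SE identically (by Frisch–Waugh–Lovell the β block of the two sandwiches
coincides; only the scalar c could differ, and counting absorbed intercepts
keeps it equal). This is the convention common in applied panel work;
software that omits absorbed effects from K will produce slightly smaller
SEs at small N.

Confidence intervals and two-sided p-values use the t distribution with
G − 1 degrees of freedom, a conservative cluster-count-based choice.
A fit is flagged `convergence` only when β < 0 *and* the 95% CI excludes
zero; `divergence` symmetrically for β > 0; otherwise `null`. Inference
requires at least two clusters; a slope with no within-country variation
under fixed effects raises an identification error rather than returning a
spurious estimate. No multiple-testing correction is applied across grid
cells: each cell reports its own 95% interval, and the gradient summary is
purely descriptive.

## The synthetic generator

The generator treats the estimating equation as the exact data-generating
process, because parameter recovery is the package's validation surface:

    ln FER_{i,t+h} = ln FER_{i,t}
                     + (α + β FER_{i,t} + γ_i + ε_it) · (EDU_{i,t+h} − EDU_{i,t}),

with γ_i ~ N(0, fe_sd²) and ε_it ~ N(0, noise_sd²) i.i.d. Education
expands along per-country logistic trajectories e_i(t) from an initial
level (U[0.5, 6] years) to an asymptote (U[8, 16], capped at 16), with
midpoint year U[1965, 2000] and rate U[0.04, 0.12]/yr — a stylized
Barro-Lee-type expansion. Trajectories are monotone nondecreasing by
construction; a zero expansion rate yields a stalled flat path, and a
`stall_prob` mode zeroes out random intervals to exercise the zero-ΔEDU
exclusion path. Cycle shares (% attended/completed primary/secondary/
tertiary) are monotone logistic links of the schooling index into [0, 100];
once a share saturates, its ΔEDU shrinks toward zero and the ratio explodes
— exactly the pathology the fence rule exists for, so the default panel
exercises it realistically.

Default study conditions mirror the analysis shape the package targets:
a balanced panel of 146 countries observed every 5 years 1950–2015
(14 lattice points), three fertility indicators — TFR (initial U[1.5, 8],
α = −0.02, β = −0.04, admissible range 0.2–12), NRR (initial U[0.7, 3.5],
same drift, range 0.1–5), MACB (initial U[22, 34], α = +0.12, β = −0.003,
range 15–50) — plus seven education measures. Metadata assigns World Bank
income quartiles and a 20% SSA share exactly (largest-remainder rounding),
correlated with initial fertility so subgroup analyses have realistic
composition. Noise defaults are fe_sd = 0.01 and noise_sd = 0.02 on the
drift scale, which put the fitted cluster-robust t statistics in the same
comfortably-significant regime the design anticipates at G ≈ 150.

Paths that leave the admissible band are clipped with a logged warning
(default) or rejection-resampled (`clip_mode="resample"`); this is
simulator hygiene with no empirical counterpart. A positive-β (divergence)
process is explosive in the level, so the divergence preset narrows the
education window (initial U[6, 8] to asymptote U[9, 11], total expansion
roughly 1–5 schooling years) and draws initial fertility from U[1.5, 3];
the unstable fixed point −α/β = 0.5 then lies below the initial range and
trajectories fan out upward without reaching the band edge. These choices
follow from the drift algebra, not from tuning.

**Gradient planting.** Per-measure true slopes (used to validate the
educational-gradient summary) are planted by emitting measure m as a
per-country linear rescale of the latent schooling index,
M_mi = a_mi · e_i with a_mi = (β_latent/β_m) · exp(η_mi),
η_mi ~ N(0, link_sd²), link_sd = 0.1. Dividing the log fertility change by
a_mi·Δe makes the slope of the ratio on base fertility equal β_m up to the
country jitter, so the planted ordering (tertiary −0.06 > secondary −0.04 >
primary −0.02 for completion; −0.05/−0.03/−0.015 for attendance) is the
ground truth of the recovered raw-scale coefficients. Standardized
coefficients are invariant to linear rescaling of the regressand, so the
ordering validation runs the grid unstandardized; a gradient in
*standardized* coefficients would require per-measure noise structure and
has no clean planted truth under this design.

## What the generator does and does not emulate

It reproduces the panel geometry (balanced quinquennial lattice, country
count), monotone education expansion with heterogeneous timing, the
convergence drift with country heterogeneity and clustered noise, the
share-saturation pathology, and income/region composition correlated with
fertility. It does not calibrate to real WPP or Barro-Lee moments, has no
mortality model behind NRR (simulated as level-like), no measurement error
in the indicators, no serial correlation in ε beyond what the fixed effect
induces, and no missingness. Passing recovery tests therefore demonstrates
the pipeline's correctness under the model's own assumptions — not that
the convergence model describes any real panel.

One finite-sample caveat the validation quantifies rather than hides: the
base-fertility regressor is predetermined, not strictly exogenous (today's
shock raises tomorrow's base level), so the within estimator carries a
small dynamic-panel (Nickell-type) bias of order 1/T. At T = 13 intervals
it measures ≈ −0.0001 on a true β of −0.04 with CI coverage ≈ 94%, inside
the validation tolerances.

## Validation studies and problem sizes

The acceptance script and the end-to-end tests run, on one CPU in well
under a minute: a noise-free exact-recovery check (50 countries, error
< 1e−10 expected); 200 Monte-Carlo replications of the stochastic recovery
scenario (150 countries) measuring mean bias and 95% CI coverage; 100
random small fixtures (3–8 clusters × 2–6 intervals) for within-vs-LSDV
agreement at 1e−8 relative; 200 replications of the divergence preset for
the sign-flip rate; 100 replications of the gradient scenario for the
ordering-recovery rate; and the hand-verified 5-point fence example
(sorted ratios −50, −1.1, −1.05, −1, −0.9 ⇒ Q1 = −1.1, Q3 = −1.0,
fences [−1.4, −0.7]). Replicate seeds are `base_seed + r`; the script
derives independent sub-seeds per study from `--seed` via
`numpy.random.SeedSequence`.

## Design choices where the design was open

- **Lattice anchoring**: the linking step anchors its 5-year lattice at the
  minimum common year rather than hard-coding 1950, so synthetic and real
  inputs with different spans link identically.
- **Balance enforcement** is a flag (default on): the headline design is a
  balanced panel, but survey-replication subsets are naturally unbalanced.
- **Metadata is an input**, not resolved from any classification source:
  income-group vintages differ across years and providers, so the analyst
  supplies the classification they intend.
- **Missing values** are dropped at link time with a logged count; no
  imputation.
- **Quartile convention**: linear interpolation between order statistics
  (the numpy default), stated because fence placement depends on it.
- **CR1 + t(G−1)** chosen as the most common applied convention;
  documented so users can reconcile against software using CR2/CR3 or
  residual degrees of freedom.
- **Grid failures are recorded, not raised**: a 105-cell run should
  complete and report per-cell failure reasons (empty subgroup, no within
  variation, single cluster) rather than abort.

## Known limitations

- Growth-convergence coefficients are descriptive regularities, not causal
  effects of education on fertility.
- The within estimator's dynamic-panel bias (above) is negligible at the
  default T but would grow for short panels (T ≤ 4).
- Cluster-robust inference needs a moderate number of clusters; with very
  few countries (< ~20) CR1 + t(G−1) can undercover, and subgroup cells
  that small should be read cautiously.
- The forest-style coefficient plot is a convenience, not a full figure
  system; it is best-effort and never fails a run.
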