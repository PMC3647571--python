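# Methods

## The equation system

Each of the five risk factors (HbA1c in DCCT %, systolic BP, TC:HDL, LDL in
mmol/L, BMI in kg/m²) follows

    RF_it = α RF_i,t−1 + β′ x_itj + ε_it,    ε_it = μ_i + ν_it,

with years since diagnosis t = 1, 2, …, a patient effect μ_i constant over
time, and i.i.d. shocks ν_it. The covariate vector contains ln(duration)
(duration is skewed, hence the log), a year-1 indicator capturing the sharp
first-year HbA1c response to initial treatment (HbA1c equation only), age
at diagnosis, a female indicator, current smoking status, current BMI, and
BMI² (retained only in the LDL equation, where the BMI effect tapers at
high BMI). All equations have 0 < α < 1, so levels converge: the gap
between two patients who differ only in their starting value shrinks by a
factor α per year, and a sustained one-unit covariate change moves the
long-run level by β/(1−α).

Unit conventions: the SBP equation is estimated and iterated on a SBP/10
scale; public interfaces always use mmHg. HbA1c is carried on the DCCT
scale; Swedish Mono-S assay values are converted as
DCCT = 0.923·Mono-S + 1.345 at ingestion when requested.

## The shipped coefficient set

The default set (`ndrpath/data/ndr_table2.yaml`) stores, per equation, the
constant, the lag coefficient, the covariate coefficients, and a
significance marker per coefficient ("1%", "5%", "10%", "ns" for estimated
but not significant, "na" for not included). Two conventions matter:

* Coefficients printed without significance stars (e.g. the positive
  smoking coefficient in the HbA1c equation, which is additionally flagged
  endogenous) are stored with marker `ns`; they are retained in unfiltered
  prediction but removed by the default 10% significance filter. The BMI²
  terms outside the LDL equation were estimated but their values not
  reported; they carry `ns` without a value and can never enter a
  prediction.
* Squared age/duration terms are representable in the schema but absent
  from the default set, which follows the published estimates literally.

`filter_significant` zeroes (never deletes) sub-threshold covariates, is
idempotent, and always keeps the constant and the lag.

## Trajectory engine

`simulate_path` iterates the five equations jointly from a baseline
profile. Design choices, in decreasing order of consequence:

1. **Contemporaneous BMI coupling.** Each year BMI is advanced first and
   the same-year predicted BMI (and BMI²) enters the other four equations.
   This makes the indirect effect of covariates through BMI part of every
   prediction and is what reproduces the published two-patient example
   paths.
2. **10% significance filter by default**, matching the filter used for
   out-of-sample prediction; an unfiltered mode (all printed coefficients)
   exists for sensitivity analysis and for self-consistency checks against
   the synthetic generator.
3. **Smoking frozen at baseline** (observed status changes little over the
   short follow-up); a user-supplied smoking path overrides this.
4. Duration-driven covariates (ln duration, the year-1 indicator) are
   recomputed each year; age at diagnosis and sex are fixed.

Reproduction precision: iterating the printed three-decimal coefficients
reproduces the published example paths to within 0.01 of every printed cell
for HbA1c, TC:HDL, LDL and BMI except the low-risk BMI value at year 5
(28.8104 computed vs 28.80 printed, a 0.0104 gap), and to within 0.08 mmHg
for SBP. Both residuals are consistent with the source tables having been
produced with unrounded coefficients: a BMI lag of ≈0.8109 or an SBP lag of
≈0.4663 — within rounding of the printed 0.811 and 0.466 — reproduces every
cell exactly. The package deliberately ships the printed values rather than
back-solved ones.

`steady_state` returns the fixed point (constant + β′x)/(1−α) of one
equation under frozen covariates; `long_term_effect` returns β/(1−α). The
published long-term table prints the BMI/smoking entry as a magnitude; the
engine returns the signed value (−1.958).

## System GMM estimator

`ndrpath.gmm` implements the Arellano–Bover/Blundell–Bond system estimator
directly from its moment conditions.

* **Differenced equations** (t ≥ 2, consecutive observations required;
  differences are never formed across gaps): instruments are lagged levels —
  lags ≥ 2 of the dependent variable, lags ≥ 1 of predetermined regressors,
  lags ≥ 2 of endogenous regressors — plus the first differences of strictly
  exogenous regressors.
* **Levels equations** (t ≥ 1): instruments are lagged differences — Δy_{t−1}
  for the dependent variable, Δx_t for predetermined, Δx_{t−1} for
  endogenous — plus the levels of strictly exogenous regressors and the
  constant. Their validity requires the initial-conditions (mean
  stationarity) assumption; the synthetic generator is built to satisfy it
  (below).
* Default regressor classification mirrors the shipped equations:
  ln(duration), age, sex (and the year-1 indicator) strictly exogenous;
  BMI (and BMI²) predetermined; smoking endogenous in the HbA1c equation
  and exogenous elsewhere.
* Missing values: a row enters an equation only if its dependent value,
  lag(s) and covariates are observed; instruments are built NaN-aware, so an
  unobservable lagged level or difference becomes a zero instrument rather
  than a corrupted one. Unbalanced panels and gaps therefore reduce the
  usable (t, lag) pairs per patient but never bias the moments.
* **Weighting.** One step uses the standard MA(1) kernel (2/−1 tridiagonal)
  on the differenced block and the identity on the levels block; two-step
  (the default) re-weights with the clustered moment covariance of the
  one-step residuals and applies the Windmeijer finite-sample correction to
  the standard errors. A rank-deficient weighting matrix below the
  parameter count raises an instrument-collinearity error naming the
  heaviest null-space loadings; mild deficiency falls back to a
  pseudo-inverse with a recorded note.
* **Diagnostics.** Hansen J = ḡ′Ŝ⁻¹ḡ at the final estimate with Ŝ from
  one-step residuals, χ² with (instruments − parameters) degrees of
  freedom; undefined (and signalled) for just-identified models or
  degenerate residuals. The Arellano–Bond AR(m) statistic uses the full
  three-term variance (residual term, estimation cross-term, coefficient
  variance term) on the first-differenced residuals; if the correction
  overshoots to a non-positive variance in a small sample, the leading term
  alone is used. AR(1) rejection is expected by construction (differencing
  makes Δν_t and Δν_{t−1} share ν_{t−1}); AR(2) rejection indicates shock
  serial correlation that invalidates the lag-2 instruments.
* **Instrument collapsing** (one column per lag distance instead of one per
  period-lag pair) is available and used in the Monte Carlo designs to keep
  the instrument count modest relative to the parameter count.
* Reported `person_years` counts patient-year observations of the dependent
  variable among patients contributing at least one moment row.

`pooled_ols` fits the levels equations by least squares and exists to
demonstrate the dynamic panel bias: with μ_i present, the lagged dependent
variable is positively correlated with the composite error and OLS
overstates α.

## Synthetic cohort generator

`generate_cohort` emulates the registry structure: diagnosis years staggered
over a window (default 2001–2004), yearly visits until a fixed end year
(default 2008, so follow-up is 4–7 years), annual dropout (default 5%),
per-visit measurement missingness (default 10%, applied after the baseline
year), and occasional missing baseline smoking/BMI (3%) to exercise the
inclusion filter.

Baseline covariates are independent truncated normals per sex with
registry-like means/SDs (about 59% men; ~21% smokers; e.g. male HbA1c
7.0 ± 1.4 %, female BMI 30.7 ± 5.9 kg/m²). Risk factors then evolve by the
equation system itself (all printed coefficients, same-year BMI coupling)
with normal μ_i and ν_it.

Two generator conventions deserve emphasis:

* **Noise split.** The between/within variance split is not identified by
  published cross-sectional summaries. The default sets
  σ_μ = SD(1−α)/√2 and σ_ν = SD√(1−α²)/√2, which makes the stationary
  cross-sectional variance equal the baseline variance, split equally
  between the permanent and transitory components; simulated dispersion then
  stays approximately constant over follow-up. Both SDs are exposed as
  parameters.
* **Stationarity-consistent baselines.** Baselines are drawn around
  mean + μ_i/(1−α) — each patient's own long-run level — with the
  independent residual variance shrunk so the total baseline SD still
  matches the registry value. This makes diagnosis-year deviations from the
  personal steady state uncorrelated with μ_i, which is precisely the
  initial-conditions assumption under which the levels-equation instruments
  of system GMM are valid. Drawing baselines independently of μ_i instead
  would deliberately violate those moments (and demonstrably biases α̂
  upward and collapses the Hansen p-values).

Smoking follows a single-possible-switch process: a configurable share of
baseline smokers (70%) and nonsmokers (95%) keeps an unchanged status
through their last visit, with any switch timed uniformly over follow-up —
matching how status stability was reported rather than imposing a per-year
Markov chain. An optional `nu_ar1` parameter gives the shocks AR(1)
structure; this deliberately violates the model's i.i.d. assumption and the
lag-2 moment conditions and exists to study the power of the AR(2) and
Hansen diagnostics. Treatment class (diet / oral agents / insulin, with
insulin more likely at young onset) only feeds the inclusion filter's
type 2 definition and never enters the equations.

`apply_inclusion_criteria` reproduces the registry filter: diagnosis year in
window, age 25–70 at diagnosis, type 2 by treatment (diet/OHA at any age,
insulin-containing only with onset ≥ 40), non-missing baseline smoking and
BMI, and — per target risk factor — a diagnosis-year measurement plus at
least two later ones (three observations being the minimum for the dynamic
model). `yearly_average` collapses repeated within-year visits by
arithmetic mean, never pooling across calendar years.

What the generator does **not** emulate: baseline correlations between risk
factors (default zero, user-overridable only via the parameter object),
informative dropout or missingness (both are completely at random),
comorbidity/mortality structure, and treatment effects on the equations.
Passing tests on these cohorts therefore certify the estimator and
machinery under the model's own assumptions, not robustness to real-world
registry pathologies.

## Temporal validation

`predict_for_panel` rolls each patient's trajectory forward from their
diagnosis-year measurements (10% filter by default) and aligns predictions
with observed values up to 3 years after diagnosis (configurable).
`regress_obs_on_pred` fits OLS of observed on predicted and reports the
one-sided p-value for H0: slope ≤ 0 against positive association.
`compare_models` reports RMSE per candidate coefficient set on pooled
patient-year residuals; reports are produced per risk factor, overall and
in the four sex-by-smoking subgroups. No comparator coefficient set ships
with the package; any user-supplied set in the documented YAML schema (for
example re-keyed UKPDS-style equations) can be passed.

## Monte Carlo designs used by the test suite

Problem sizes were chosen as the smallest designs whose Monte Carlo error
is well inside the asserted tolerances:

* **Recovery:** 50 cohorts of n = 2000 patients diagnosed in one year and
  followed 7 years, default noise, no missingness; per equation, mean
  absolute error of α̂ ≤ 0.03 and pooled OLS bias positive and larger.
* **Diagnostic calibration:** 300 cohorts of n = 1200, single equation
  (TC:HDL-like), collapsed instruments; Hansen and AR(2) rejection at the
  5% level within 2–8%, AR(1) ≥ 90%.
* **Validation:** calibration slope approaches 1 as generator noise is
  scaled toward zero; the truth-generating set beats a set with all lag
  coefficients shifted by +0.08 in RMSE in ≥ 95 of 100 replicates
  (n = 120, 3-year horizon).

## Numerical notes and degenerate inputs

* Weighting matrices are inverted by symmetric eigendecomposition with a
  relative eigenvalue cutoff of 1e−12; structurally empty instrument
  columns are dropped before estimation.
* A panel whose longest series is shorter than three waves cannot form any
  differenced moment condition and raises an estimation error, as does an
  instrument count below the parameter count.
* Zero-variance residuals (e.g. noise-free panels), just-identified models,
  and too-short panels for AR(2) raise explicit diagnostic-unavailable
  signals rather than returning numbers.
* `hba1c_monos_to_dcct` accepts 0 (returning the intercept 1.345) and
  rejects negative values; profile baselines must be strictly positive,
  except that non-BMI baselines may be missing (NaN), in which case only
  that factor's trajectory is undefined.

## Known limitations

* Trajectories are deterministic (shocks at their zero mean); there is no
  stochastic simulation of ε draws and no event-risk or cost layer.
* The published equations' numerical coefficients cannot be re-derived
  without the original registry data; the estimator's correctness is
  certified by parameter recovery on synthetic cohorts instead.
* Published validation RMSEs depend on the real 2005 registry cohort and
  are likewise out of reach of synthetic data; the machinery, not those
  numbers, is the deliverable.
* The significance filter operates on the stored star markers (the printed
  information), not on refitted standard errors.
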