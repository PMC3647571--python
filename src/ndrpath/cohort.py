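"""Seeded generator of NDR-like longitudinal panels.

The generator emulates the registry structure the equations were estimated
on: patients newly diagnosed with type 2 diabetes in a staggered window
(default 2001-2004), followed yearly until a fixed end year (default 2008),
with unbalanced follow-up, dropout and per-visit missingness. Risk factors
evolve by the dynamic equation system itself,

    RF_it = alpha RF_{i,t-1} + beta' x_it + mu_i + nu_it,

with a patient-level random effect mu_i ~ N(0, sigma_mu^2) and i.i.d. shocks
nu_it ~ N(0, sigma_nu^2). BMI is simulated first each year and its same-year
value feeds the other four equations, mirroring the deterministic engine.

Baseline covariates are drawn per sex from independent truncated normals
with registry-like means/SDs; smoking status is resolved by a single
possible switch during follow-up so that a configurable share of patients
(default 70% of baseline smokers, 95% of baseline nonsmokers) ends follow-up
with unchanged status. Treatment class is a simple age-dependent categorical
that only exists to exercise the type 2 inclusion filter; it never enters
the equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .equations import CoefficientSet, default_coefficients
from .errors import DomainError
from .panel import MEASUREMENT_COLUMNS, PANEL_COLUMNS, Panel, as_frame

#: Registry-like baseline distributions per sex: mean, SD (public units).
BASELINE_DISTRIBUTIONS = {
    "male": {
        "age": (56.0, 8.8),
        "hba1c": (7.0, 1.4),
        "bmi": (29.8, 4.9),
        "sbp": (138.5, 17.9),
        "tchdl": (4.6, 1.4),
        "ldl": (3.1, 1.0),
        "smoking": 0.21,
    },
    "female": {
        "age": (57.0, 9.0),
        "hba1c": (6.9, 1.3),
        "bmi": (30.7, 5.9),
        "sbp": (138.9, 18.2),
        "tchdl": (4.4, 1.4),
        "ldl": (3.3, 1.0),
        "smoking": 0.22,
    },
}

FEMALE_FRACTION = 2076 / 5043


def default_noise_sds(coeffs: CoefficientSet | None = None):
    """Per-equation (sigma_mu, sigma_nu) defaults, in equation-internal units.

    The between/within variance split is not identified by published
    cross-sectional summaries, so the convention here splits the stationary
    cross-sectional variance of each equation equally between the random
    effect and the accumulated shocks:

        sigma_mu = SD * (1 - alpha) / sqrt(2),
        sigma_nu = SD * sqrt(1 - alpha^2) / sqrt(2),

    where SD is the sex-averaged baseline SD. With baselines drawn at that
    SD, the simulated cross-section then keeps an approximately constant
    spread over follow-up, matching the registry picture of stable
    cross-sectional dispersion.
    """
    coeffs = coeffs or default_coefficients()
    sds = {}
    for rf in MEASUREMENT_COLUMNS:
        male = BASELINE_DISTRIBUTIONS["male"][rf][1]
        female = BASELINE_DISTRIBUTIONS["female"][rf][1]
        sd = (male + female) / 2.0
        if rf == "sbp":
            sd /= 10.0
        alpha = coeffs[rf].lag.value
        sds[rf] = (
            sd * (1.0 - alpha) / math.sqrt(2.0),
            sd * math.sqrt(1.0 - alpha**2) / math.sqrt(2.0),
        )
    return ({rf: v[0] for rf, v in sds.items()}, {rf: v[1] for rf, v in sds.items()})


@dataclass
class CohortParams:
    """Parameters of the synthetic registry cohort."""

    n: int = 5043
    diagnosis_years: tuple = (2001, 2004)
    follow_up_end: int = 2008
    coefficients: CoefficientSet | None = None
    sigma_mu: dict | None = None
    sigma_nu: dict | None = None
    female_fraction: float = FEMALE_FRACTION
    baseline: dict = field(default_factory=lambda: BASELINE_DISTRIBUTIONS)
    age_range: tuple = (20.0, 80.0)
    annual_dropout: float = 0.05
    visit_missingness: float = 0.10
    baseline_missingness: float = 0.03
    smoking_unchanged_smoker: float = 0.70
    smoking_unchanged_nonsmoker: float = 0.95
    #: serial correlation of the idiosyncratic shocks nu_it. The model assumes
    #: 0 (i.i.d. shocks); a nonzero value deliberately violates the moment
    #: conditions, for studying diagnostic power.
    nu_ar1: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for p in (self.annual_dropout, self.visit_missingness, self.baseline_missingness,
                  self.smoking_unchanged_smoker, self.smoking_unchanged_nonsmoker,
                  self.female_fraction):
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"probability parameter {p} outside [0, 1]")
        if self.sigma_mu is not None and any(v < 0 for v in self.sigma_mu.values()):
            raise DomainError("sigma_mu must be non-negative")
        if self.sigma_nu is not None and any(v < 0 for v in self.sigma_nu.values()):
            raise DomainError("sigma_nu must be non-negative")


def _truncated_normal(rng, mean, sd, low, high, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: CohortParams, seed: int | None = None) -> Panel:
    """Simulate a registry-like panel; deterministic given the seed."""
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    coeffs = params.coefficients or default_coefficients()
    sigma_mu, sigma_nu = params.sigma_mu, params.sigma_nu
    if sigma_mu is None or sigma_nu is None:
        d_mu, d_nu = default_noise_sds(coeffs)
        sigma_mu = sigma_mu or d_mu
        sigma_nu = sigma_nu or d_nu

    n = params.n
    female = rng.random(n) < params.female_fraction
    y0, y1 = params.diagnosis_years
    diag_year = rng.integers(y0, y1 + 1, size=n)
    horizon = params.follow_up_end - diag_year          # per-patient max duration
    tmax = int(horizon.max())

    mu = {rf: rng.normal(0.0, sigma_mu[rf], n) if sigma_mu[rf] > 0 else np.zeros(n)
          for rf in MEASUREMENT_COLUMNS}

    # Baselines carry each patient's permanent effect: a patient with random
    # effect mu_i is drawn around mean + mu_i/(1-alpha), their own long-run
    # level. This keeps diagnosis-year deviations from the personal steady
    # state uncorrelated with mu_i — the initial-conditions requirement that
    # validates the levels-equation (system) moment conditions — while the
    # independent residual SD is shrunk so the cross-sectional SD still
    # matches the registry baseline SD.
    age = np.empty(n)
    smoke0 = np.empty(n, dtype=bool)
    base = {rf: np.empty(n) for rf in MEASUREMENT_COLUMNS}
    for sex, mask in (("male", ~female), ("female", female)):
        m = int(mask.sum())
        dist = params.baseline[sex]
        age[mask] = _truncated_normal(rng, *dist["age"], *params.age_range, m)
        smoke0[mask] = rng.random(m) < dist["smoking"]
        for rf in MEASUREMENT_COLUMNS:
            mean, sd = dist[rf]
            scale = 10.0 if rf == "sbp" else 1.0
            alpha = coeffs[rf].lag.value
            mu_public_sd = sigma_mu[rf] * scale / (1.0 - alpha)
            resid_sd = math.sqrt(max(sd**2 - mu_public_sd**2, (0.1 * sd) ** 2))
            draw = mean + mu[rf][mask] * scale / (1.0 - alpha)
            draw = draw + rng.normal(0.0, resid_sd, m)
            base[rf][mask] = np.maximum(draw, 1e-3)  # positive support

    # smoking: at most one status switch, timed uniformly over follow-up, so
    # that the configured share ends follow-up with unchanged status
    p_unchanged = np.where(smoke0, params.smoking_unchanged_smoker,
                           params.smoking_unchanged_nonsmoker)
    switches = rng.random(n) >= p_unchanged
    switch_year = np.where(
        switches & (horizon >= 1), rng.integers(1, np.maximum(horizon, 1) + 1), tmax + 1
    )
    smoking = np.empty((n, tmax + 1))
    for t in range(tmax + 1):
        flipped = switches & (t >= switch_year)
        smoking[:, t] = np.where(flipped, ~smoke0, smoke0).astype(float)

    # treatment class: age-dependent categorical, only for the inclusion filter
    u = rng.random(n)
    p_insulin = np.where(age < 40, 0.25, 0.10)
    treatment = np.where(u < p_insulin, "insulin", np.where(u < p_insulin + 0.35, "diet", "oha"))

    # idiosyncratic shocks, optionally AR(1) with stationary variance sigma_nu^2
    rho = params.nu_ar1
    nu = {}
    for rf in MEASUREMENT_COLUMNS:
        shocks = np.zeros((n, tmax + 1))
        if sigma_nu[rf] > 0:
            shocks[:, 1] = rng.normal(0.0, sigma_nu[rf], n)
            innov_sd = sigma_nu[rf] * math.sqrt(max(1.0 - rho**2, 0.0))
            for t in range(2, tmax + 1):
                shocks[:, t] = rho * shocks[:, t - 1] + rng.normal(0.0, innov_sd, n)
        nu[rf] = shocks

    # forward simulation on equation-internal scales, BMI first each year
    values = {rf: np.empty((n, tmax + 1)) for rf in MEASUREMENT_COLUMNS}
    for rf in MEASUREMENT_COLUMNS:
        values[rf][:, 0] = base[rf] / 10.0 if rf == "sbp" else base[rf]
    age_v = age
    female_v = female.astype(float)

    def step(rf, t, bmi_t):
        eq = coeffs[rf]
        betas = eq.retained(None)
        x = eq.constant.value + eq.lag.value * values[rf][:, t - 1]
        cov = {
            "ln_duration": math.log(t),
            "year1": 1.0 if t == 1 else 0.0,
            "age_at_diagnosis": age_v,
            "female": female_v,
            "smoking": smoking[:, t],
            "bmi": bmi_t,
            "bmi_squared": None if bmi_t is None else bmi_t**2,
        }
        for name, beta in betas.items():
            x = x + beta * cov[name]
        return x + mu[rf] + nu[rf][:, t]

    for t in range(1, tmax + 1):
        bmi_t = step("bmi", t, None)
        values["bmi"][:, t] = bmi_t
        for rf in MEASUREMENT_COLUMNS:
            if rf != "bmi":
                values[rf][:, t] = step(rf, t, bmi_t)

    # dropout: once a patient misses a year they leave the panel for good
    if params.annual_dropout > 0:
        drop = rng.random((n, tmax)) < params.annual_dropout
        first_drop = np.where(drop.any(axis=1), drop.argmax(axis=1) + 1, tmax + 1)
    else:
        first_drop = np.full(n, tmax + 1)
    last_t = np.minimum(horizon, first_drop - 1)

    # assemble long format
    counts = last_t + 1
    pid = np.repeat(np.arange(1, n + 1), counts)
    t_long = np.concatenate([np.arange(c) for c in counts])
    idx = pid - 1

    df = pd.DataFrame({
        "patient_id": pid,
        "year_of_diagnosis": diag_year[idx],
        "calendar_year": diag_year[idx] + t_long,
        "duration": t_long,
        "age_at_diagnosis": age_v[idx],
        "female": female.astype(int)[idx],
        "smoking": smoking[idx, t_long],
        "treatment_class": treatment[idx],
    })
    for rf in MEASUREMENT_COLUMNS:
        v = values[rf][idx, t_long]
        if rf == "sbp":
            v = v * 10.0
        if params.visit_missingness > 0:
            miss = (rng.random(len(v)) < params.visit_missingness) & (t_long >= 1)
            v = np.where(miss, np.nan, v)
        df[rf] = v
    if params.baseline_missingness > 0:
        at_base = t_long == 0
        for col in ("smoking", "bmi"):
            miss = (rng.random(len(df)) < params.baseline_missingness) & at_base
            df.loc[miss, col] = np.nan

    return Panel.from_frame(df[PANEL_COLUMNS])


def apply_inclusion_criteria(
    panel,
    risk_factor: str | None = None,
    diagnosis_years: tuple = (2001, 2004),
) -> Panel:
    """Retain patients meeting the registry study's inclusion rules.

    Criteria: diagnosis year inside the window; age 25-70 at diagnosis; a
    type 2 diagnosis (diet or oral agents at any age, insulin-containing
    treatment only with onset age >= 40); non-missing smoking and BMI in the
    diagnosis year; and, when ``risk_factor`` is given, a measurement at
    diagnosis plus at least two later measurements of that factor (three
    observations being the minimum the dynamic model can use).
    """
    df = as_frame(panel)
    keep = []
    for pid, grp in df.groupby("patient_id", sort=False):
        base_rows = grp[grp["duration"] == 0]
        if base_rows.empty:
            continue
        row = base_rows.iloc[0]
        if "year_of_diagnosis" in grp.columns and pd.notna(row.get("year_of_diagnosis")):
            if not diagnosis_years[0] <= row["year_of_diagnosis"] <= diagnosis_years[1]:
                continue
        if not 25 <= row["age_at_diagnosis"] <= 70:
            continue
        treatment = str(row.get("treatment_class", "diet")).lower()
        if treatment not in ("diet", "oha") and row["age_at_diagnosis"] < 40:
            continue
        if pd.isna(row["smoking"]) or pd.isna(row["bmi"]):
            continue
        if risk_factor is not None:
            if pd.isna(row[risk_factor]):
                continue
            later = grp[(grp["duration"] >= 1) & grp[risk_factor].notna()]
            if len(later) < 2:
                continue
        elif len(grp) < 3:
            continue
        keep.append(pid)
    out = df[df["patient_id"].isin(keep)].reset_index(drop=True)
    return Panel(out)


def yearly_average(frame) -> Panel:
    """Collapse repeated within-year measurements to one record per
    patient-year by arithmetic averaging; no pooling across years."""
    df = as_frame(frame)
    measured = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    agg = {c: "mean" for c in measured}
    for c in df.columns:
        if c not in measured and c not in ("patient_id", "calendar_year"):
            agg[c] = "first"
    out = (
        df.groupby(["patient_id", "calendar_year"], as_index=False, sort=True)
        .agg(agg)
    )
    cols = [c for c in df.columns if c in out.columns]
    return Panel.from_frame(out[cols])
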