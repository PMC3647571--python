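"""Deterministic year-by-year simulation of the coupled risk-factor equations.

The engine iterates the five first-order equations jointly from a baseline
profile. Within each prediction year the BMI equation is advanced first and
the same-year predicted BMI (and its square) feeds the other four equations,
so that the indirect effect of covariates routed through BMI is part of every
prediction. Smoking status is held at its baseline value unless an explicit
smoking path is supplied; duration-dependent covariates are recomputed every
year, while age at diagnosis and sex are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equations import (
    RISK_FACTORS,
    CoefficientSet,
    Equation,
    PatientProfile,
    build_covariates,
    default_coefficients,
    sbp_from_internal,
    sbp_to_internal,
)
from .errors import ContractError, DomainError


@dataclass
class Trajectory:
    """Predicted paths, indexed by years since diagnosis (0 = diagnosis year).

    Values are in public units (SBP in mmHg). ``bmi_path`` and
    ``smoking_path`` are the covariate paths that entered the equations.
    """

    values: dict[str, np.ndarray]
    smoking_path: np.ndarray
    profile: PatientProfile = field(repr=False, default=None)

    @property
    def horizon(self) -> int:
        return len(self.smoking_path) - 1

    @property
    def bmi_path(self) -> np.ndarray:
        return self.values["bmi"]

    def __getitem__(self, risk_factor: str) -> np.ndarray:
        return self.values[risk_factor]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (risk_factor, year, value) table."""
        rows = [
            {"risk_factor": rf, "year": t, "value": self.values[rf][t]}
            for rf in RISK_FACTORS
            for t in range(self.horizon + 1)
        ]
        return pd.DataFrame(rows)


def predict_next(
    equation: Equation,
    previous_value: float,
    covariates: dict[str, float],
    significance_level: float | None = 0.10,
) -> float:
    """One step of a single equation: alpha * previous + beta'x (equation units).

    Raises :class:`ContractError` if a covariate retained at the chosen
    significance level is missing from ``covariates``.
    """
    return equation.lag.value * previous_value + equation.linear_predictor(
        covariates, significance_level
    )


def simulate_path(
    profile: PatientProfile,
    coeffs: CoefficientSet | None = None,
    horizon: int = 5,
    significance_level: float | None = 0.10,
    smoking_path=None,
) -> Trajectory:
    """Simulate all five risk factors for ``horizon`` years after diagnosis.

    ``significance_level`` filters covariates (default 10%, the level used
    for out-of-sample prediction); ``None`` uses every printed coefficient.
    ``smoking_path`` optionally overrides the frozen-at-baseline smoking
    assumption; it must cover years 1..horizon (index 0 is the baseline).
    """
    if horizon < 1:
        raise DomainError(f"horizon must be >= 1, got {horizon}")
    if coeffs is None:
        coeffs = default_coefficients()
    profile.validate()

    if smoking_path is None:
        smoke = np.full(horizon + 1, 1.0 if profile.smoker_at_diagnosis else 0.0)
    else:
        smoke = np.asarray(smoking_path, dtype=float)
        if smoke.shape != (horizon + 1,):
            raise ContractError(
                f"smoking_path must have length horizon+1={horizon + 1}, got {smoke.shape}"
            )

    # state in equation-internal units
    state = {}
    for rf in RISK_FACTORS:
        base = profile.baseline(rf)
        state[rf] = sbp_to_internal(base) if rf == "sbp" else base

    paths = {rf: np.full(horizon + 1, np.nan) for rf in RISK_FACTORS}
    for rf in RISK_FACTORS:
        paths[rf][0] = profile.baseline(rf)

    for t in range(1, horizon + 1):
        # BMI first: its same-year prediction feeds the other equations.
        cov_bmi = build_covariates(profile, t, bmi_current=state["bmi"], smoking_current=smoke[t])
        bmi_t = predict_next(coeffs["bmi"], state["bmi"], cov_bmi, significance_level)
        state["bmi"] = bmi_t
        paths["bmi"][t] = bmi_t

        cov = build_covariates(profile, t, bmi_current=bmi_t, smoking_current=smoke[t])
        for rf in RISK_FACTORS:
            if rf == "bmi":
                continue
            prev = state[rf]
            if not np.isfinite(prev):
                continue
            value = predict_next(coeffs[rf], prev, cov, significance_level)
            state[rf] = value
            paths[rf][t] = sbp_from_internal(value) if rf == "sbp" else value

    return Trajectory(values=paths, smoking_path=smoke, profile=profile)


def long_term_effect(beta: float, alpha: float) -> float:
    """Cumulative effect beta / (1 - alpha) of a sustained one-unit change.

    The short-term coefficient beta acts in the current year; under the
    stable recursion its effect accumulates geometrically to beta/(1-alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError(
            f"lag coefficient {alpha} outside (0, 1): no finite long-term effect"
        )
    return beta / (1.0 - alpha)


def steady_state(
    equation: Equation,
    covariates: dict[str, float],
    significance_level: float | None = 0.10,
) -> float:
    """Fixed point of one equation with frozen covariates (equation units).

    ``predict_next`` applied at this value with the same covariates returns
    it unchanged; with the lag in (0, 1) every trajectory approaches it.
    """
    alpha = equation.lag.value
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"lag coefficient {alpha} outside (0, 1): no steady state")
    return equation.linear_predictor(covariates, significance_level) / (1.0 - alpha)
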