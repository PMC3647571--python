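"""Data model for the five dynamic risk-factor time-path equations.

Each risk factor (HbA1c, systolic BP, TC:HDL, LDL, BMI) follows a first-order
linear dynamic equation

    RF_t = alpha * RF_{t-1} + sum_j beta_j * x_{t,j} + constant,

where t is years since diagnosis of type 2 diabetes and the covariates x are
ln(duration), a first-year indicator, age at diagnosis, sex, current smoking
status, and current BMI (with a quadratic BMI term in the LDL equation).
``alpha`` in (0, 1) makes every equation a stable recursion: individual
differences shrink geometrically and trajectories converge.

Unit conventions
----------------
* HbA1c is carried on the DCCT % scale; :func:`hba1c_monos_to_dcct` converts
  Swedish Mono-S assay values.
* Systolic BP is estimated and iterated on a /10 scale (``public_scale=10``);
  all public interfaces use mmHg.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

from .errors import CoefficientValidationError, ContractError, DomainError, SchemaError

RISK_FACTORS = ("hba1c", "sbp", "tchdl", "ldl", "bmi")

#: Covariates of the equation system, in canonical order.
COVARIATE_NAMES = (
    "ln_duration",
    "year1",
    "age_at_diagnosis",
    "female",
    "smoking",
    "bmi",
    "bmi_squared",
)

#: Marker for "estimated but not significant at the 10% level".
NOT_SIGNIFICANT = "ns"
#: Marker for "covariate not included in the equation".
NOT_INCLUDED = "na"

#: Significance ladder: marker -> nominal level.
SIG_LEVELS = {"1%": 0.01, "5%": 0.05, "10%": 0.10}

_VALID_MARKERS = set(SIG_LEVELS) | {NOT_SIGNIFICANT, NOT_INCLUDED}


@dataclass(frozen=True)
class Coefficient:
    """One coefficient cell: point value (if reported) and significance marker."""

    value: float | None
    sig: str
    endogenous: bool = False

    def __post_init__(self):
        if self.sig not in _VALID_MARKERS:
            raise SchemaError(f"unknown significance marker {self.sig!r}")
        if self.sig == NOT_INCLUDED and self.value is not None:
            raise SchemaError("a not-included coefficient cannot carry a value")

    @property
    def included(self) -> bool:
        """True if the coefficient has a numeric value usable for prediction."""
        return self.value is not None

    def significant_at(self, level: float) -> bool:
        nominal = SIG_LEVELS.get(self.sig)
        return nominal is not None and nominal <= level + 1e-12


@dataclass
class Equation:
    """Coefficients of one risk factor's time-path equation, in equation units."""

    name: str
    constant: Coefficient
    lag: Coefficient
    covariates: dict[str, Coefficient]
    public_scale: float = 1.0
    units: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.lag.value is None:
            raise CoefficientValidationError(f"{self.name}: lag coefficient missing")
        if not 0.0 < self.lag.value < 1.0:
            raise CoefficientValidationError(
                f"{self.name}: lag coefficient {self.lag.value} outside (0, 1); "
                "the dynamic equation would not converge"
            )
        if self.constant.value is None:
            raise CoefficientValidationError(f"{self.name}: constant missing")
        for key in self.covariates:
            if key not in COVARIATE_NAMES:
                raise SchemaError(f"{self.name}: unknown covariate {key!r}")

    def retained(self, level: float | None) -> dict[str, float]:
        """Covariate values used for prediction at a significance threshold.

        ``level=None`` retains every printed coefficient; otherwise only those
        significant at ``level``. Coefficients without a printed value are
        never usable. The constant and the lag are always retained.
        """
        out = {}
        for key, coef in self.covariates.items():
            if not coef.included:
                continue
            if level is None or coef.significant_at(level):
                out[key] = coef.value
        return out

    def linear_predictor(self, covariates: Mapping[str, float], level: float | None) -> float:
        """constant + sum of retained beta_j * x_j (equation units)."""
        acc = self.constant.value
        for key, beta in self.retained(level).items():
            if key not in covariates or covariates[key] is None:
                raise ContractError(
                    f"{self.name}: covariate {key!r} is retained but missing from input"
                )
            acc += beta * covariates[key]
        return acc


@dataclass
class CoefficientSet:
    """A named collection of the five per-risk-factor equations."""

    name: str
    equations: dict[str, Equation]

    def __getitem__(self, risk_factor: str) -> Equation:
        try:
            return self.equations[risk_factor]
        except KeyError:
            raise KeyError(
                f"no equation for {risk_factor!r}; have {sorted(self.equations)}"
            ) from None

    def validate(self) -> None:
        for eq in self.equations.values():
            eq.validate()

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, payload: dict) -> "CoefficientSet":
        if not isinstance(payload, dict) or "equations" not in payload:
            raise SchemaError("coefficient file must contain an 'equations' mapping")
        equations = {}
        for name, raw in payload["equations"].items():
            try:
                equations[name] = Equation(
                    name=name,
                    constant=_parse_coefficient(raw["constant"], f"{name}.constant"),
                    lag=_parse_coefficient(raw["lag"], f"{name}.lag"),
                    covariates={
                        k: _parse_coefficient(v, f"{name}.{k}")
                        for k, v in raw.get("covariates", {}).items()
                    },
                    public_scale=float(raw.get("public_scale", 1.0)),
                    units=raw.get("units", ""),
                    meta=dict(raw.get("meta", {})),
                )
            except KeyError as exc:
                raise SchemaError(f"equation {name!r}: missing field {exc.args[0]!r}") from None
        out = cls(name=payload.get("name", "unnamed"), equations=equations)
        out.validate()
        return out

    def to_dict(self) -> dict:
        payload = {"name": self.name, "equations": {}}
        for name, eq in self.equations.items():
            payload["equations"][name] = {
                "units": eq.units,
                "public_scale": eq.public_scale,
                "constant": _coefficient_to_dict(eq.constant),
                "lag": _coefficient_to_dict(eq.lag),
                "covariates": {k: _coefficient_to_dict(c) for k, c in eq.covariates.items()},
                "meta": dict(eq.meta),
            }
        return payload

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _parse_coefficient(raw, where: str) -> Coefficient:
    if not isinstance(raw, dict):
        raise SchemaError(f"{where}: expected a mapping with 'value'/'sig'")
    sig = raw.get("sig")
    if sig is None:
        raise SchemaError(f"{where}: missing significance marker 'sig'")
    sig = str(sig)
    if sig not in _VALID_MARKERS:
        raise SchemaError(f"{where}: unknown significance marker {sig!r}")
    value = raw.get("value")
    if value is not None:
        value = float(value)
    return Coefficient(value=value, sig=sig, endogenous=bool(raw.get("endogenous", False)))


def _coefficient_to_dict(coef: Coefficient) -> dict:
    out = {"sig": coef.sig}
    if coef.value is not None:
        out["value"] = coef.value
    if coef.endogenous:
        out["endogenous"] = True
    return out


_DEFAULT_SET_NAME = "ndr_table2"
_default_cache: CoefficientSet | None = None


def load_coefficients(source=None) -> CoefficientSet:
    """Load a coefficient set from a YAML file, or the shipped default.

    ``source`` may be ``None`` or ``"ndr_table2"`` for the default NDR set,
    or a filesystem path to a user-supplied set (e.g. a comparator model).
    """
    global _default_cache
    if source is None or source == _DEFAULT_SET_NAME:
        if _default_cache is None:
            text = resources.files("ndrpath.data").joinpath("ndr_table2.yaml").read_text()
            _default_cache = CoefficientSet.from_dict(yaml.safe_load(text))
        return copy.deepcopy(_default_cache)
    with open(source) as fh:
        payload = yaml.safe_load(fh)
    return CoefficientSet.from_dict(payload)


def default_coefficients() -> CoefficientSet:
    """The shipped NDR coefficient set (five equations, see package data)."""
    return load_coefficients(None)


def filter_significant(coeffs: CoefficientSet, level: float = 0.10) -> CoefficientSet:
    """Zero out covariates weaker than ``level`` for prediction.

    The lag coefficient and the constant are always retained. Filtering is
    idempotent: already-zeroed coefficients keep their marker and stay zero.
    """
    if level not in (0.01, 0.05, 0.10):
        raise DomainError(f"significance level must be one of 1%, 5%, 10%; got {level}")
    equations = {}
    for name, eq in coeffs.equations.items():
        covs = {}
        for key, coef in eq.covariates.items():
            if coef.included and not coef.significant_at(level):
                coef = replace(coef, value=0.0)
            covs[key] = coef
        equations[name] = Equation(
            name=eq.name,
            constant=eq.constant,
            lag=eq.lag,
            covariates=covs,
            public_scale=eq.public_scale,
            units=eq.units,
            meta=dict(eq.meta),
        )
    return CoefficientSet(name=f"{coeffs.name}|{level:g}", equations=equations)


@dataclass
class PatientProfile:
    """Baseline characteristics of one (possibly hypothetical) patient.

    Baseline risk-factor values are in public units (SBP in mmHg, HbA1c in
    DCCT %). Baselines other than BMI may be NaN, in which case that factor's
    trajectory is undefined; BMI must always be present because it feeds the
    other four equations.
    """

    age_at_diagnosis: float
    female: bool
    smoker_at_diagnosis: bool
    hba1c: float
    sbp: float
    bmi: float
    tchdl: float
    ldl: float
    year_of_diagnosis: int | None = None

    def baseline(self, risk_factor: str) -> float:
        return getattr(self, risk_factor)

    def validate(self, inclusion: bool = False) -> None:
        if inclusion and not 25 <= self.age_at_diagnosis <= 70:
            raise DomainError(
                f"age at diagnosis {self.age_at_diagnosis} outside the 25-70 inclusion window"
            )
        if not (math.isfinite(self.bmi) and self.bmi > 0):
            raise DomainError("baseline BMI must be a positive number")
        for rf in RISK_FACTORS:
            v = getattr(self, rf)
            if v is not None and math.isfinite(v) and v <= 0:
                raise DomainError(f"baseline {rf} must be strictly positive, got {v}")


def build_covariates(
    profile: PatientProfile,
    duration: int,
    bmi_current: float,
    smoking_current: float | int | None = None,
) -> dict[str, float]:
    """Covariate vector for one prediction year.

    ``duration`` is years since diagnosis (>= 1). Derived features
    (ln_duration, the year-1 indicator, bmi_squared) are computed here;
    smoking defaults to the baseline status.
    """
    if duration < 1:
        raise DomainError(f"duration must be >= 1, got {duration}")
    if smoking_current is None:
        smoking_current = profile.smoker_at_diagnosis
    return {
        "ln_duration": math.log(duration),
        "year1": 1.0 if duration == 1 else 0.0,
        "age_at_diagnosis": float(profile.age_at_diagnosis),
        "female": 1.0 if profile.female else 0.0,
        "smoking": float(smoking_current),
        "bmi": float(bmi_current),
        "bmi_squared": float(bmi_current) ** 2,
    }


def hba1c_monos_to_dcct(value: float) -> float:
    """Convert HbA1c from the Swedish Mono-S assay scale to DCCT %."""
    if value < 0:
        raise DomainError(f"HbA1c must be non-negative, got {value}")
    return 0.923 * value + 1.345


def sbp_to_internal(value_mmhg: float):
    """Map systolic BP from mmHg to the /10 scale the SBP equation uses."""
    return value_mmhg / 10.0


def sbp_from_internal(value):
    """Inverse of :func:`sbp_to_internal`."""
    return value * 10.0
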