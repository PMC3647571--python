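"""Temporal external validation of a coefficient set against a held-out panel.

A later-diagnosed cohort's observed trajectories are compared with the
trajectories the equations predict from each patient's diagnosis-year
values: observed values are regressed on predicted values (one-sided test of
positive association), and root-mean-squared prediction error is computed
per risk factor, overall and in the four sex-by-smoking subgroups, for one
or several candidate coefficient sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .equations import CoefficientSet, PatientProfile
from .errors import ContractError, DomainError
from .panel import MEASUREMENT_COLUMNS, as_frame
from .trajectory import simulate_path

logger = logging.getLogger(__name__)

__all__ = [
    "predict_for_panel",
    "regress_obs_on_pred",
    "rmse",
    "compare_models",
    "validate_panel",
    "ValidationReport",
]


def predict_for_panel(
    panel,
    coeffs: CoefficientSet,
    significance_level: float | None = 0.10,
    horizon: int = 3,
) -> pd.DataFrame:
    """Predicted vs observed values, aligned on patient-years.

    Each patient's trajectory is rolled forward from their diagnosis-year
    (duration 0) measurements and aligned with observed values for durations
    1..``horizon``. Patients without a usable diagnosis-year baseline (BMI
    or smoking missing) are skipped; the skipped count is attached to the
    result as ``.attrs["n_skipped"]`` and logged.

    Returns a tidy frame: patient_id, duration, risk_factor, observed,
    predicted, female, smoker_at_diagnosis.
    """
    df = as_frame(panel)
    records = []
    n_skipped = 0
    for pid, grp in df.groupby("patient_id", sort=True):
        base_rows = grp[grp["duration"] == 0]
        if base_rows.empty:
            n_skipped += 1
            continue
        row = base_rows.iloc[0]
        if pd.isna(row["bmi"]) or pd.isna(row["smoking"]):
            n_skipped += 1
            continue
        profile = PatientProfile(
            age_at_diagnosis=float(row["age_at_diagnosis"]),
            female=bool(row["female"]),
            smoker_at_diagnosis=bool(row["smoking"]),
            hba1c=float(row["hba1c"]) if pd.notna(row["hba1c"]) else float("nan"),
            sbp=float(row["sbp"]) if pd.notna(row["sbp"]) else float("nan"),
            bmi=float(row["bmi"]),
            tchdl=float(row["tchdl"]) if pd.notna(row["tchdl"]) else float("nan"),
            ldl=float(row["ldl"]) if pd.notna(row["ldl"]) else float("nan"),
        )
        traj = simulate_path(profile, coeffs, horizon=horizon,
                             significance_level=significance_level)
        observed = grp[(grp["duration"] >= 1) & (grp["duration"] <= horizon)]
        for obs_row in observed.itertuples():
            t = int(obs_row.duration)
            for rf in MEASUREMENT_COLUMNS:
                obs = getattr(obs_row, rf)
                pred = traj[rf][t]
                if pd.notna(obs) and np.isfinite(pred):
                    records.append(
                        (pid, t, rf, float(obs), float(pred),
                         bool(row["female"]), bool(row["smoking"]))
                    )
    out = pd.DataFrame(
        records,
        columns=["patient_id", "duration", "risk_factor", "observed", "predicted",
                 "female", "smoker_at_diagnosis"],
    )
    out.attrs["n_skipped"] = n_skipped
    if n_skipped:
        logger.info("predict_for_panel: skipped %d patients without usable baselines",
                    n_skipped)
    return out


def regress_obs_on_pred(observed, predicted):
    """OLS of observed on predicted with a one-sided slope test.

    Returns (slope, intercept, one-sided p) for H0: slope <= 0 against
    slope > 0. A well-calibrated model gives slope near 1 and a tiny p.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ContractError("observed and predicted must have equal length")
    if obs.size < 3:
        raise DomainError("need at least 3 paired values to regress")
    if np.std(pred) < 1e-12:
        raise DomainError("predictions have zero variance; slope undefined")
    res = stats.linregress(pred, obs)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    p_one_sided = float(stats.t.sf(t, df=obs.size - 2))
    return float(res.slope), float(res.intercept), p_one_sided


def rmse(observed, predicted) -> float:
    """Root mean squared difference of paired values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ContractError("observed and predicted must have equal length")
    if obs.size == 0:
        raise DomainError("RMSE of an empty sample is undefined")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def compare_models(observed, predictions_by_model: dict) -> pd.DataFrame:
    """RMSE per named prediction set, ordered best first.

    All prediction sets must align with the same observed patient-years.
    """
    if len(predictions_by_model) < 2:
        raise ContractError("compare_models needs at least two named prediction sets")
    obs = np.asarray(observed, dtype=float)
    rows = []
    for name, pred in predictions_by_model.items():
        pred = np.asarray(pred, dtype=float)
        if pred.shape != obs.shape:
            raise ContractError(f"prediction set {name!r} is not aligned with observed values")
        rows.append({"model": name, "rmse": rmse(obs, pred)})
    out = pd.DataFrame(rows).sort_values("rmse", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class ValidationReport:
    """Per risk factor and subgroup: calibration regression and RMSEs."""

    table: pd.DataFrame
    horizon: int
    n_patients: int
    n_skipped: int
    models: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _subgroup_label(female: bool, smoker: bool) -> str:
    sex = "female" if female else "male"
    smoke = "smoker" if smoker else "nonsmoker"
    return f"{sex}_{smoke}"


def validate_panel(
    panel,
    coeffs: CoefficientSet,
    comparators: dict | None = None,
    significance_level: float | None = 0.10,
    horizon: int = 3,
) -> ValidationReport:
    """Full temporal validation of one (or more) coefficient sets.

    ``comparators`` maps model names to additional coefficient sets (for
    example a user-supplied UKPDS-style set); RMSEs are reported for every
    model, the calibration regression for the primary set only.
    """
    models = {"primary": coeffs, **(comparators or {})}
    aligned = {}
    for name, cs in models.items():
        aligned[name] = predict_for_panel(
            panel, cs, significance_level=significance_level, horizon=horizon
        )
    primary = aligned["primary"]

    rows = []
    keys = primary[["patient_id", "duration", "risk_factor"]]
    for rf in MEASUREMENT_COLUMNS:
        sub_rf = primary[primary["risk_factor"] == rf]
        groups = [("all", sub_rf)]
        for female in (False, True):
            for smoker in (False, True):
                part = sub_rf[(sub_rf["female"] == female)
                              & (sub_rf["smoker_at_diagnosis"] == smoker)]
                groups.append((_subgroup_label(female, smoker), part))
        for label, part in groups:
            if part.empty:
                continue
            row = {
                "risk_factor": rf,
                "subgroup": label,
                "n_patients": part["patient_id"].nunique(),
                "n_obs": len(part),
            }
            try:
                slope, intercept, p = regress_obs_on_pred(part["observed"], part["predicted"])
                row.update(slope=slope, intercept=intercept, p_one_sided=p)
            except DomainError:
                row.update(slope=np.nan, intercept=np.nan, p_one_sided=np.nan)
            row["rmse_primary"] = (
                rmse(part["observed"], part["predicted"]) if len(part) else np.nan
            )
            for name, frame in aligned.items():
                if name == "primary":
                    continue
                other = frame[["patient_id", "duration", "risk_factor", "predicted"]]
                merged = part.merge(
                    other, on=["patient_id", "duration", "risk_factor"],
                    suffixes=("", "_cmp"),
                )
                row[f"rmse_{name}"] = (
                    rmse(merged["observed"], merged["predicted_cmp"]) if len(merged) else np.nan
                )
            rows.append(row)

    table = pd.DataFrame(rows)
    return ValidationReport(
        table=table,
        horizon=horizon,
        n_patients=int(keys["patient_id"].nunique()),
        n_skipped=int(primary.attrs.get("n_skipped", 0)),
        models=list(models),
    )
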