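"""File schemas: CSV panels, YAML profiles/parameters, report writing, run logs.

All formats are plain text. Panels are long-format CSV with the documented
header; missing values are empty cells. HbA1c is assumed to be on the DCCT %
scale; pass ``hba1c_standard="mono-s"`` to convert Swedish Mono-S values on
ingestion. SBP is mmHg everywhere on disk.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import metadata

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortParams
from .equations import PatientProfile, hba1c_monos_to_dcct, load_coefficients
from .errors import PanelError, SchemaError
from .panel import PANEL_COLUMNS, Panel

__all__ = [
    "read_panel",
    "write_panel",
    "read_profile",
    "read_cohort_params",
    "write_report",
    "write_run_log",
    "load_coefficients",
]


def read_panel(path, hba1c_standard: str = "dcct") -> Panel:
    """Read a long-format CSV panel and validate its invariants.

    The duration column is cross-checked against calendar_year minus
    year_of_diagnosis; duplicate (patient_id, duration) keys are an error.
    """
    df = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(df.columns) - {"treatment_class"}
    if missing:
        raise PanelError(f"panel file {path} lacks columns: {sorted(missing)}")
    if hba1c_standard not in ("dcct", "mono-s"):
        raise SchemaError(f"hba1c_standard must be 'dcct' or 'mono-s', got {hba1c_standard!r}")
    if hba1c_standard == "mono-s":
        df["hba1c"] = np.where(df["hba1c"].notna(),
                               0.923 * df["hba1c"] + 1.345, np.nan)
    return Panel.from_frame(df)


def write_panel(panel: Panel, path) -> None:
    panel.frame.to_csv(path, index=False, float_format="%.10g")


def read_profile(path) -> PatientProfile:
    """Read a baseline patient profile from YAML (keys as in the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"profile file {path} must contain a mapping")
    monos = raw.pop("hba1c_mono_s", None)
    if monos is not None:
        raw["hba1c"] = hba1c_monos_to_dcct(float(monos))
    try:
        profile = PatientProfile(**raw)
    except TypeError as exc:
        raise SchemaError(f"profile file {path}: {exc}") from None
    profile.validate()
    return profile


def read_cohort_params(path) -> CohortParams:
    """Read simulation parameters from YAML; omitted keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"params file {path} must contain a mapping")
    coeff_source = raw.pop("coefficients", None)
    try:
        params = CohortParams(**{k: _maybe_tuple(v) for k, v in raw.items()})
    except TypeError as exc:
        raise SchemaError(f"params file {path}: {exc}") from None
    if coeff_source is not None:
        params.coefficients = load_coefficients(coeff_source)
    return params


def _maybe_tuple(value):
    return tuple(value) if isinstance(value, list) else value


def write_report(frame: pd.DataFrame, path) -> None:
    """Write a tidy report with deterministic column order and >=6 significant
    digits preserved."""
    frame.to_csv(path, index=False, float_format="%.8g")


def _package_version() -> str:
    try:
        return metadata.version("ndrpath")
    except metadata.PackageNotFoundError:
        return "unknown"


def write_run_log(path, subcommand: str, config: dict, seed=None) -> None:
    """Machine-readable record of one CLI run: config, seed, package version."""
    payload = {
        "package": "ndrpath",
        "version": _package_version(),
        "subcommand": subcommand,
        "seed": seed,
        "config": {k: _jsonable(v) for k, v in config.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(value):
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    if hasattr(value, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(value).items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    return str(value)
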