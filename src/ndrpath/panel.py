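"""Long-format unbalanced longitudinal panel of patient-year records."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PanelError

#: Canonical column order of the panel schema.
PANEL_COLUMNS = [
    "patient_id",
    "year_of_diagnosis",
    "calendar_year",
    "duration",
    "age_at_diagnosis",
    "female",
    "smoking",
    "treatment_class",
    "hba1c",
    "sbp",
    "bmi",
    "tchdl",
    "ldl",
]

MEASUREMENT_COLUMNS = ["hba1c", "sbp", "bmi", "tchdl", "ldl"]


@dataclass
class Panel:
    """A validated long-format panel; one row per patient-year.

    ``duration`` is integer years since diagnosis (0 = diagnosis year).
    Panels may be unbalanced and contain gaps; measurement columns may hold
    NaN for missing values. SBP is stored in mmHg (public units).
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, validate: bool = True) -> "Panel":
        panel = cls(frame=frame.reset_index(drop=True))
        if validate:
            panel.validate()
        return panel

    def validate(self) -> None:
        df = self.frame
        missing = {"patient_id", "duration"} - set(df.columns)
        if missing:
            raise PanelError(f"panel lacks required columns: {sorted(missing)}")
        dur = df["duration"]
        if not np.all(np.isfinite(dur)) or not np.allclose(dur, np.round(dur)):
            raise PanelError("durations must be finite integers")
        if (dur < 0).any():
            raise PanelError("durations must be >= 0")
        dup = df.duplicated(subset=["patient_id", "duration"])
        if dup.any():
            offenders = df.loc[dup, ["patient_id", "duration"]].drop_duplicates()
            raise PanelError(
                "duplicate (patient_id, duration) keys: "
                + ", ".join(f"({r.patient_id}, {int(r.duration)})" for r in offenders.itertuples())
            )
        if {"calendar_year", "year_of_diagnosis"} <= set(df.columns):
            both = df["calendar_year"].notna() & df["year_of_diagnosis"].notna()
            implied = df.loc[both, "calendar_year"] - df.loc[both, "year_of_diagnosis"]
            bad = ~np.isclose(implied, df.loc[both, "duration"])
            if bad.any():
                rows = df.loc[both].loc[bad, "patient_id"].unique()[:5]
                raise PanelError(
                    f"duration inconsistent with calendar_year - year_of_diagnosis "
                    f"for patients {list(rows)}"
                )

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def person_years(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


def as_frame(panel_or_frame) -> pd.DataFrame:
    """Accept either a :class:`Panel` or a bare DataFrame."""
    if isinstance(panel_or_frame, Panel):
        return panel_or_frame.frame
    return panel_or_frame
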