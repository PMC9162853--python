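"""Long-format individual × survey-wave panel container with schema checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every panel must carry
REQUIRED_COLUMNS = [
    "person_id", "city_id", "year", "urrbmi", "lnpcincome",
    "healthy", "outpatient", "hospital", "lnoutself", "lnhosself",
    "age", "age2", "male", "married", "hhnum", "rural",
    "priedu", "secedu", "highedu", "superhigh", "pension", "sanitary", "east",
]

#: mutually exclusive education dummies (the omitted base is "no formal education")
EDU_COLUMNS = ["priedu", "secedu", "highedu", "superhigh"]

#: default covariate set for the factor regressions, in reporting order
DEFAULT_FACTORS = [
    "urrbmi", "age", "age2", "male", "married", "hhnum", "lnpcincome",
    "rural", "priedu", "secedu", "highedu", "superhigh", "pension", "sanitary",
]


class SchemaError(ValueError):
    """A panel violates the required schema or its invariants."""


@dataclass
class PanelDataset:
    """Individual-level panel: one row per person per survey wave.

    ``urrbmi`` is the city-by-year treatment indicator (insurance coverage):
    it must be constant within a (city, year) cell and, because adoption is an
    absorbing state, non-decreasing over time within each city.  The
    out-of-pocket expense outcomes ``lnoutself`` / ``lnhosself`` are defined
    only for users (rows with the corresponding utilization flag set) and are
    missing otherwise.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"panel is missing required columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def waves(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def validate(self) -> "PanelDataset":
        """Check the panel invariants; raise :class:`SchemaError` on violation."""
        df = self.df
        if (df.groupby(["city_id", "year"])["urrbmi"].nunique() > 1).any():
            raise SchemaError("urrbmi must be constant within (city_id, year)")
        per_city = df.drop_duplicates(["city_id", "year"]).sort_values("year")
        if (per_city.groupby("city_id")["urrbmi"].diff().dropna() < 0).any():
            raise SchemaError("adoption must be absorbing: urrbmi non-decreasing per city")
        if not np.allclose(df["age2"], df["age"] ** 2):
            raise SchemaError("age2 must equal age squared")
        if (df[EDU_COLUMNS].sum(axis=1) > 1).any():
            raise SchemaError("education dummies must be mutually exclusive")
        for flag, expense in [("outpatient", "lnoutself"), ("hospital", "lnhosself")]:
            if df.loc[df[flag] == 0, expense].notna().any():
                raise SchemaError(f"{expense} must be missing when {flag} == 0")
        return self

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "PanelDataset":
        return cls(pd.read_csv(path), metadata=metadata or {})
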