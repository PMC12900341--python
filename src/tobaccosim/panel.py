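"""Weighted longitudinal panel of annual tobacco-use observations.

A :class:`PanelDataset` holds one row per person per wave with the
person's fixed demographics, the observed tobacco-use state at that
wave, and the longitudinal survey weight. Waves are numbered 1..n and
are one year apart; ``base_year`` is the calendar year of wave 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .states import TobaccoState

PANEL_COLUMNS = [
    "person_id",
    "wave",
    "age",
    "sex",
    "race_group",
    "poverty",
    "init_age_cat",
    "state",
    "weight",
]


@dataclass
class PanelDataset:
    """Longitudinal panel used for transition estimation."""

    data: pd.DataFrame
    base_year: int = 2014

    def __post_init__(self) -> None:
        missing = set(PANEL_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        self.data = self.data[PANEL_COLUMNS].reset_index(drop=True)

    @property
    def n_waves(self) -> int:
        return int(self.data["wave"].nunique())

    @property
    def n_persons(self) -> int:
        return int(self.data["person_id"].nunique())

    def wave_year(self, wave: int) -> int:
        return self.base_year + (wave - 1)

    def validate_consecutive(self) -> None:
        """Require every person to be observed in waves 1..k with no gaps."""
        counts = self.data.groupby("person_id")["wave"].agg(["min", "max", "count"])
        bad = (counts["min"] != 1) | (counts["count"] != counts["max"])
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} persons have non-consecutive or incomplete waves"
            )

    def weighted_state_share(self, wave: int, states) -> float:
        """Weighted share of the given states at one wave."""
        sub = self.data[self.data["wave"] == wave]
        codes = {int(TobaccoState(s)) for s in states}
        return float(
            sub.loc[sub["state"].isin(codes), "weight"].sum() / sub["weight"].sum()
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, base_year: int = 2014) -> "PanelDataset":
        return cls(pd.read_csv(path, dtype={"person_id": str}), base_year)
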