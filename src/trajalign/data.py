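"""Tidy long-format container for longitudinal observations.

The on-disk schema is plain CSV with one row per observation:
``subject_id, age_months, aligned_age_months, outcome, variant, value,
n_trials`` (``variant`` and ``n_trials`` may be empty for non-behavioral
outcomes).  Unknown extra columns are preserved and ignored.  All ages
are in months; years convert at exactly 12 months/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = [
    "subject_id",
    "age_months",
    "aligned_age_months",
    "outcome",
    "variant",
    "value",
    "n_trials",
]

MONTHS_PER_YEAR = 12.0


@dataclass
class LongitudinalDataset:
    """One or more outcomes in tidy long format."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")

    @property
    def outcomes(self) -> list:
        return sorted(self.df["outcome"].unique().tolist())

    @property
    def subjects(self) -> list:
        return sorted(self.df["subject_id"].unique().tolist())

    def subset(self, outcome: str) -> pd.DataFrame:
        return self.df[self.df["outcome"] == outcome]

    def concat(self, other: "LongitudinalDataset") -> "LongitudinalDataset":
        meta = dict(self.meta)
        meta.update(other.meta)
        return LongitudinalDataset(
            pd.concat([self.df, other.df], ignore_index=True), meta
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "LongitudinalDataset":
        df = pd.read_csv(path)
        return cls(df)
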