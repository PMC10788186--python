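"""Per-patient cohort records and their tabular (CSV/DataFrame) round trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: columns every cohort table carries, in order
_BASE_COLUMNS = [
    "patient_id", "onset_to_ct_h", "stratum", "eligible",
    "hhm_positive", "extend_positive", "nwu_true_pct", "phantom_seed",
]


@dataclass
class CohortRecord:
    """One patient of a (synthetic or real) cohort.

    ``eligible`` and the two classifier calls start unset (``None``) and are
    filled by the labelling / classification stages; ``stratum`` is the
    generator's true group label where known.  ``covariates`` holds baseline
    characteristics (age, sex, comorbidities, NIHSS), possibly missing.
    """

    patient_id: str
    onset_to_ct_h: float
    stratum: str | None = None
    eligible: bool | None = None
    hhm_positive: bool | None = None
    extend_positive: bool | None = None
    nwu_true_pct: float | None = None
    phantom_seed: int | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.onset_to_ct_h < 0:
            raise ValueError("onset_to_ct_h must be >= 0")

    def as_row(self) -> dict:
        row = {col: getattr(self, col) for col in _BASE_COLUMNS}
        row.update(self.covariates)
        return row


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Cohort records as one row per patient, covariates as extra columns."""
    if not records:
        raise ValueError("empty cohort")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("patient_id values must be unique")
    return pd.DataFrame([r.as_row() for r in records])


def frame_to_records(df: pd.DataFrame) -> list[CohortRecord]:
    """Inverse of :func:`records_to_frame` (NaN maps back to None)."""
    records = []
    covariate_cols = [c for c in df.columns if c not in _BASE_COLUMNS]
    for _, row in df.iterrows():
        def get(col, cast=None):
            if col not in row or pd.isna(row[col]):
                return None
            return cast(row[col]) if cast else row[col]

        records.append(CohortRecord(
            patient_id=str(row["patient_id"]),
            onset_to_ct_h=float(row["onset_to_ct_h"]),
            stratum=get("stratum", str),
            eligible=get("eligible", bool),
            hhm_positive=get("hhm_positive", bool),
            extend_positive=get("extend_positive", bool),
            nwu_true_pct=get("nwu_true_pct", float),
            phantom_seed=get("phantom_seed", int),
            covariates={c: (None if pd.isna(row[c]) else row[c])
                        for c in covariate_cols},
        ))
    return records
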