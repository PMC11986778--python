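"""Long-format cohort container and delimited-text I/O.

A :class:`LongCohort` holds one row per person per survey sweep.  Sweeps 1-7
correspond to approximate ages 0.75, 3, 5, 7, 11, 14 and 17 years; the SDQ
outcome is modelled at sweeps 2, 3, 4, 6 and 7 (parent-reported scores; the
teacher-reported age-11 sweep is excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "LongCohort",
    "read_cohort",
    "write_cohort",
    "SWEEP_AGES",
    "MODELED_SWEEPS",
    "MODELED_AGES",
]

#: Age in years at each MCS sweep (9 months coded 0.75).
SWEEP_AGES: dict[int, float] = {1: 0.75, 2: 3.0, 3: 5.0, 4: 7.0, 5: 11.0, 6: 14.0, 7: 17.0}

#: Sweeps with a modelled (parent-reported) SDQ outcome.
MODELED_SWEEPS: tuple[int, ...] = (2, 3, 4, 6, 7)

#: Ages corresponding to the modelled sweeps.
MODELED_AGES: tuple[float, ...] = (3.0, 5.0, 7.0, 14.0, 17.0)

#: Mandatory cohort columns, in canonical order.
COHORT_COLUMNS: tuple[str, ...] = (
    "person_id",
    "sweep",
    "age_years",
    "sdq_total",
    "sex",
    "ethnicity",
    "obesity",
    "longstanding_illness",
    "poverty",
    "maternal_education_nvq",
    "maternal_depression_at_birth",
    "family_structure",
    "lsoa_id",
    "pm25",
    "pm10",
    "no2",
    "ndvi",
    "green_area_ha",
    "imd_decile",
    "urban",
    "country",
    "birth_order_in_multiple",
)

_NUMERIC_COLUMNS = (
    "sweep",
    "age_years",
    "sdq_total",
    "longstanding_illness",
    "poverty",
    "maternal_education_nvq",
    "maternal_depression_at_birth",
    "pm25",
    "pm10",
    "no2",
    "ndvi",
    "green_area_ha",
    "imd_decile",
    "urban",
    "birth_order_in_multiple",
)


@dataclass
class LongCohort:
    """One row per (person, sweep), validated against the cohort invariants.

    Extra columns beyond the mandatory roster (e.g. a latent continuous
    log-outcome from the simulator, cumulative-exposure columns, exclusion
    flags) are carried through untouched.
    """

    df: pd.DataFrame
    #: Optional (lsoa_id, sweep) -> exposure-values table; the stand-in for
    #: the GIS linkage that assigns neighbourhood exposures to an LSOA.
    exposure_lookup: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- container conveniences ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_persons(self) -> int:
        return self.df["person_id"].nunique()

    def modeled_rows(self) -> pd.DataFrame:
        """Rows eligible for the outcome model (modelled sweeps, not excluded)."""
        m = self.df["sweep"].isin(MODELED_SWEEPS)
        if "excluded" in self.df.columns:
            m &= ~self.df["excluded"].fillna(False).astype(bool)
        return self.df.loc[m]

    def copy(self) -> "LongCohort":
        return LongCohort(self.df.copy(), exposure_lookup=self.exposure_lookup)

    # -- validation ------------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort missing mandatory columns: {missing}")
        dup = df.duplicated(subset=["person_id", "sweep"])
        if dup.any():
            pairs = df.loc[dup, ["person_id", "sweep"]].head(3).to_records(index=False)
            raise IntegrityError(f"duplicate (person_id, sweep) rows, e.g. {list(pairs)}")
        sdq = pd.to_numeric(df["sdq_total"], errors="coerce")
        bad = sdq.dropna()
        if len(bad) and (
            (bad < 0).any() or (bad > 40).any() or (bad != np.round(bad)).any()
        ):
            raise IntegrityError("sdq_total must be an integer in [0, 40] when present")
        imd = pd.to_numeric(df["imd_decile"], errors="coerce").dropna()
        if len(imd) and ((imd < 1).any() or (imd > 10).any()):
            raise IntegrityError("imd_decile must be in {1..10} when present")
        ndvi = pd.to_numeric(df["ndvi"], errors="coerce").dropna()
        if len(ndvi) and ((ndvi < 0).any() or (ndvi > 1).any()):
            raise IntegrityError("ndvi must lie in [0, 1]")
        for col in ("pm25", "pm10", "no2", "green_area_ha"):
            v = pd.to_numeric(df[col], errors="coerce").dropna()
            if len(v) and (v < 0).any():
                raise IntegrityError(f"{col} must be nonnegative")
        sw = pd.to_numeric(df["sweep"], errors="coerce")
        if sw.isna().any() or not sw.isin(range(1, 8)).all():
            raise IntegrityError("sweep must be an integer in {1..7}")


def read_cohort(path, codebook=None) -> LongCohort:
    """Read a comma-delimited long-format cohort file.

    Empty cells become missing values.  Unparseable numeric cells are coerced
    to missing with a logged count; structural problems (missing mandatory
    columns, duplicate person-sweep rows, out-of-range SDQ) raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing columns: {missing}")
    n_coerced = 0
    for col in _NUMERIC_COLUMNS:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        n_coerced += int((num.isna() & raw.notna()).sum())
        df[col] = num
    if n_coerced:
        logger.warning("read_cohort: coerced %d unparseable numeric cells to missing", n_coerced)
    df["sweep"] = df["sweep"].astype(int)
    for col in ("sex", "ethnicity", "obesity", "family_structure", "lsoa_id", "country"):
        df[col] = df[col].astype("string")
    return LongCohort(df.reset_index(drop=True))


def write_cohort(cohort: LongCohort, path) -> None:
    """Write the cohort in the same dialect :func:`read_cohort` reads."""
    cohort.df.to_csv(path, index=False)
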