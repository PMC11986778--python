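"""Shared fixtures: hand-built mini-cohorts and design helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neighsdq import GeneratorConfig, LongCohort, generate_cohort
from neighsdq.cohort import COHORT_COLUMNS, SWEEP_AGES
from neighsdq.design import DesignMatrices

__all__ = ["base_row", "make_cohort_df", "empty_design"]


def base_row(person_id: str, sweep: int, **over) -> dict:
    """One fully-populated cohort row with sensible defaults."""
    row = {
        "person_id": person_id,
        "sweep": sweep,
        "age_years": SWEEP_AGES[sweep],
        "sdq_total": 7,
        "sex": "female",
        "ethnicity": "white",
        "obesity": "normal",
        "longstanding_illness": 0,
        "poverty": 0,
        "maternal_education_nvq": 2,
        "maternal_depression_at_birth": 0,
        "family_structure": "couple",
        "lsoa_id": f"LS_{person_id}",
        "pm25": 12.0,
        "pm10": 18.0,
        "no2": 19.0,
        "ndvi": 0.5,
        "green_area_ha": 6.0,
        "imd_decile": 5,
        "urban": 1,
        "country": "England",
        "birth_order_in_multiple": np.nan,
    }
    row.update(over)
    return row


def make_cohort_df(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return df[[c for c in COHORT_COLUMNS if c in df.columns] + [c for c in df.columns if c not in COHORT_COLUMNS]]


def full_person(person_id: str, **over) -> list[dict]:
    return [base_row(person_id, s, **over) for s in range(1, 8)]


def empty_design(y, person_index, person_ids) -> DesignMatrices:
    """A design with no covariate columns (intercept-only fixtures)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return DesignMatrices(
        y=y,
        X=np.empty((n, 0)),
        Z=np.empty((n, 0)),
        x_labels=[],
        z_labels=[],
        z_meta=[],
        z_group=np.empty(0, dtype=int),
        z_group_names=[],
        z_group_pooling=[],
        person_index=np.asarray(person_index, dtype=int),
        person_ids=list(person_ids),
        age_index=np.zeros(n),
        row_keys=[(p, i) for i, p in enumerate(np.asarray(person_index))],
    )


@pytest.fixture(scope="session")
def three_person_cohort() -> LongCohort:
    rows = []
    for pid in ("A", "B", "C"):
        rows += full_person(pid)
    return LongCohort(make_cohort_df(rows))


@pytest.fixture(scope="session")
def small_cohort() -> LongCohort:
    """A simulated 150-person complete cohort (no missingness)."""
    cohort, _ = generate_cohort(GeneratorConfig(n_persons=150, seed=424242))
    return cohort
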