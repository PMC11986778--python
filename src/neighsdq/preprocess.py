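"""Preprocessing rules applied to a cohort before modelling.

Implements residence inference for sweeps with a missing neighbourhood
identifier, the sweep-6 -> sweep-7 carry-forward of income/deprivation,
the analysis-sample filters (England residence, first-born of multiples,
complete residence histories), the outcome transform, deprivation
categorisation, and the variance-inflation-factor collinearity screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import LongCohort
from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "infer_residence",
    "carry_forward_sweep7",
    "filter_analysis_sample",
    "transform_outcome",
    "categorize_imd",
    "compute_vif",
]

#: Columns that are attributes of the LSOA of residence and therefore travel
#: with an inferred lsoa_id when an exposure lookup is available.
LSOA_ATTRIBUTES = ("pm25", "pm10", "no2", "ndvi", "green_area_ha", "imd_decile", "urban")


def infer_residence(cohort: LongCohort, exposure_lookup: pd.DataFrame | None = None):
    """Fill missing neighbourhood identifiers flanked by the same LSOA.

    For each person and each sweep with a missing ``lsoa_id``, if the nearest
    non-missing LSOA before and after that sweep are identical, the gap is
    filled with that LSOA (no relocation inferred).  Leading or trailing
    missing sweeps have no flanking pair and stay missing.  Non-missing
    values are never overwritten, so the operation is idempotent.

    When an exposure lookup table (columns ``lsoa_id``, ``sweep`` plus the
    LSOA attributes) is available — either passed explicitly or attached to
    the cohort — the filled rows also recover their exposure values.

    Returns ``(cohort, n_filled)``; filled rows are marked in a boolean
    ``lsoa_inferred`` column.
    """
    df = cohort.df.copy()
    if "lsoa_inferred" not in df.columns:
        df["lsoa_inferred"] = False
    order = df.sort_values(["person_id", "sweep"]).index
    lsoa = df.loc[order, "lsoa_id"]
    person = df.loc[order, "person_id"]

    # nearest non-missing value before/after within person
    prev = lsoa.groupby(person.values).ffill()
    nxt = lsoa.groupby(person.values).bfill()
    fill = lsoa.isna() & prev.notna() & nxt.notna() & (prev == nxt)
    n_filled = int(fill.sum())
    if n_filled:
        df.loc[order[fill.values], "lsoa_id"] = prev[fill].values
        df.loc[order[fill.values], "lsoa_inferred"] = True

    lookup = exposure_lookup if exposure_lookup is not None else cohort.exposure_lookup
    if n_filled and lookup is not None:
        cols = [c for c in LSOA_ATTRIBUTES if c in lookup.columns]
        keyed = lookup.drop_duplicates(["lsoa_id", "sweep"]).set_index(["lsoa_id", "sweep"])
        filled_idx = order[fill.values]
        keys = list(zip(df.loc[filled_idx, "lsoa_id"], df.loc[filled_idx, "sweep"]))
        present = [k in keyed.index for k in keys]
        hit_idx = filled_idx[np.asarray(present)]
        if len(hit_idx):
            vals = keyed.loc[[k for k, ok in zip(keys, present) if ok], cols]
            df.loc[hit_idx, cols] = vals.values
    logger.info("infer_residence: filled %d missing lsoa cells", n_filled)
    return LongCohort(df, exposure_lookup=lookup), n_filled


def carry_forward_sweep7(cohort: LongCohort) -> LongCohort:
    """Carry income/deprivation from sweep 6 to sweep 7.

    Household income (poverty status) and neighbourhood IMD were not collected
    at sweep 7, so income stability from the previous sweep is assumed and the
    sweep-6 values are assigned uniformly to sweep-7 rows.  Persons whose
    sweep-6 and sweep-7 LSOAs differ (or who are absent at sweep 6) cannot
    inherit a deprivation decile and are flagged ``excluded`` at sweep 7.
    """
    df = cohort.df.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    s6 = df[df["sweep"] == 6].set_index("person_id")
    mask7 = df["sweep"] == 7
    pid7 = df.loc[mask7, "person_id"]

    has6 = pid7.isin(s6.index)
    n_overwritten = int(df.loc[mask7, ["poverty", "imd_decile"]].notna().any(axis=1).sum())
    for col in ("poverty", "imd_decile"):
        df.loc[mask7, col] = pid7.map(s6[col])
    if n_overwritten:
        logger.info(
            "carry_forward_sweep7: %d sweep-7 rows had income/IMD values; "
            "overwritten with sweep-6 values per the carry-forward rule",
            n_overwritten,
        )

    lsoa6 = pid7.map(s6["lsoa_id"])
    lsoa7 = df.loc[mask7, "lsoa_id"]
    moved = has6 & lsoa6.notna() & lsoa7.notna() & (lsoa6 != lsoa7)
    excl = ~has6 | moved
    df.loc[mask7, "excluded"] = df.loc[mask7, "excluded"].astype(bool) | excl
    logger.info("carry_forward_sweep7: %d sweep-7 rows flagged excluded", int(excl.sum()))
    return LongCohort(df, exposure_lookup=cohort.exposure_lookup)


def filter_analysis_sample(cohort: LongCohort, require_complete_residence: bool = True) -> LongCohort:
    """Apply the analysis-sample inclusion rules.

    Retains persons who (a) resided in England at every observed sweep,
    (b) are singletons or the first-born of a multiple birth, and
    (c) — when ``require_complete_residence`` — have a non-missing LSOA at
    all seven sweeps (run :func:`infer_residence` first to expand the sample
    with inferred non-relocations).
    """
    df = cohort.df
    by_person = df.groupby("person_id")

    in_england = by_person["country"].agg(lambda s: bool((s.dropna() == "England").all()))
    firstborn = by_person["birth_order_in_multiple"].agg(
        lambda s: bool(s.dropna().empty or (s.dropna() == 1).all())
    )
    keep = in_england & firstborn
    if require_complete_residence:
        complete = by_person.apply(
            lambda g: bool(g["lsoa_id"].notna().all() and set(g["sweep"]) == set(range(1, 8))),
            include_groups=False,
        )
        keep &= complete

    kept_ids = keep[keep].index
    out = df[df["person_id"].isin(kept_ids)].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_analysis_sample: no persons satisfy the inclusion rules")
    logger.info(
        "filter_analysis_sample: kept %d of %d persons", len(kept_ids), by_person.ngroups
    )
    return LongCohort(out, exposure_lookup=cohort.exposure_lookup)


def transform_outcome(sdq):
    """log(SDQ + 1): the modelled outcome scale.

    The +1 offset makes the transform defined at the observed score 0 and is
    a strictly increasing bijection from {0..40} onto its image.
    """
    arr = np.asarray(sdq, dtype=float)
    if np.any((arr[~np.isnan(arr)] < 0) | (arr[~np.isnan(arr)] > 40)):
        raise DomainError("SDQ total must lie in [0, 40]")
    out = np.log1p(arr)
    return float(out) if np.isscalar(sdq) or arr.ndim == 0 else out


_IMD_CATEGORIES = {
    **{d: "most_deprived" for d in (1, 2, 3)},
    **{d: "moderately_deprived" for d in (4, 5, 6, 7)},
    **{d: "least_deprived" for d in (8, 9, 10)},
}


def categorize_imd(decile):
    """Deprivation category for an IMD decile.

    Deciles 1-3 are the most deprived neighbourhoods, 4-7 moderately
    deprived, 8-10 least deprived.
    """
    if np.isscalar(decile):
        d = int(decile)
        if d != decile or d not in _IMD_CATEGORIES:
            raise DomainError(f"IMD decile must be an integer in 1..10, got {decile!r}")
        return _IMD_CATEGORIES[d]
    return np.array([categorize_imd(d) for d in np.asarray(decile).ravel()])


def compute_vif(design: pd.DataFrame, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factors for the columns of a design matrix.

    For each column j, VIF_j = 1 / (1 - R2_j), with R2_j from a least-squares
    regression of column j on all other columns plus an intercept.  Exactly
    collinear columns are reported as infinite rather than raising.

    Returns a frame indexed by column label with ``vif`` and ``flagged``
    (VIF > ``flag_threshold``) columns.
    """
    X = np.asarray(design, dtype=float)
    cols = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{j}" for j in range(X.shape[1])
    ]
    n, p = X.shape
    if p < 2:
        raise DomainError("VIF needs at least 2 columns")
    if n <= p:
        raise DomainError("VIF needs more rows than columns")
    vifs = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 1e-300:
            vifs[j] = np.inf  # constant column: collinear with the intercept
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    out = pd.DataFrame({"vif": vifs}, index=pd.Index(cols, name="column"))
    out["flagged"] = out["vif"] > flag_threshold
    return out
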