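"""Design-matrix construction from a preprocessed cohort and a model spec."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SWEEP_AGES, MODELED_AGES, LongCohort
from .codebook import CovariateCodebook, default_codebook
from .errors import DataError, SpecError
from .modelspec import ModelSpec
from .preprocess import transform_outcome

__all__ = ["DesignMatrices", "build_design", "make_cumulative"]


@dataclass
class DesignMatrices:
    """Numeric blocks for one model fit.

    y is on the log scale for the Gaussian family and raw counts for the
    Poisson family.  X holds fixed-effect and interaction columns; Z the
    time-varying exposure block, one column per (exposure, age) pair for
    age-specific terms and one column per cumulative term.  z_group maps
    each Z column to its exposure-group index (hierarchical pooling is per
    exposure).
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    x_labels: list[str]
    z_labels: list[str]
    #: per-Z-column (exposure, age-or-None) metadata
    z_meta: list[tuple[str, float | None]]
    #: per-Z-column exposure-group index into z_group_names
    z_group: np.ndarray
    z_group_names: list[str]
    #: per-group pooling mode ("hierarchical" | "independent")
    z_group_pooling: list[str]
    person_index: np.ndarray  # 0..P-1 codes
    person_ids: list
    age_index: np.ndarray
    #: (person_id, sweep) keys per row, for cross-model alignment
    row_keys: list[tuple]
    #: standardisation applied to continuous sources: name -> (mean, sd)
    scaling: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def W(self) -> np.ndarray:
        """Concatenated [X Z] coefficient block."""
        if self.X.size or self.Z.size:
            return np.column_stack([self.X, self.Z])
        return np.empty((self.n_obs, 0))

    @property
    def labels(self) -> list[str]:
        return self.x_labels + self.z_labels

    def to_frame(self) -> pd.DataFrame:
        """Exportable view (debugging aid)."""
        df = pd.DataFrame(self.W, columns=self.labels)
        df.insert(0, "y", self.y)
        df.insert(1, "person_id", [self.person_ids[i] for i in self.person_index])
        df.insert(2, "age", self.age_index)
        return df


def make_cumulative(
    cohort: LongCohort, exposures: list[str], codebook: CovariateCodebook | None = None
) -> LongCohort:
    """Add per-person time-invariant ``cum_<name>`` columns.

    The cumulative exposure is the within-person mean of the exposure across
    that person's observed modelled sweeps; a person with no observed value
    gets a missing cumulative value.
    """
    cb = codebook or default_codebook()
    df = cohort.df.copy()
    modeled = cohort.modeled_rows()
    for name in exposures:
        vals = _exposure_values(modeled, name, cb)
        means = vals.groupby(modeled["person_id"]).mean()
        df[f"cum_{name}"] = df["person_id"].map(means)
    return LongCohort(df, exposure_lookup=cohort.exposure_lookup)


def _exposure_values(df: pd.DataFrame, name: str, cb: CovariateCodebook) -> pd.Series:
    entry = cb[name]
    return entry.expand(df).iloc[:, 0]


def build_design(
    cohort: LongCohort,
    spec: ModelSpec,
    codebook: CovariateCodebook | None = None,
    outcome: str = "sdq",
    keep_keys: set | None = None,
) -> DesignMatrices:
    """Assemble outcome/fixed/time-varying blocks from the modelled rows.

    Rows are the modelled sweeps (ages 3, 5, 7, 14, 17) minus any flagged
    exclusions, restricted to complete cases for the spec's covariates.
    Age-specific exposures expand to one column per (exposure, age): the
    exposure value where the row's age matches, else 0.  Interactions expand
    as modifier-dummy x exposure-value columns in the fixed block.
    Continuous sources marked ``standardize`` in the codebook are centred and
    scaled to unit SD (recorded in ``scaling``).

    outcome="sdq" uses log(SDQ+1) for the Gaussian family and raw counts for
    Poisson; outcome="latent" uses the simulator's continuous log-outcome.
    """
    cb = codebook or default_codebook()
    rows = cohort.modeled_rows().copy()
    if keep_keys is not None:
        key = list(zip(rows["person_id"], rows["sweep"]))
        rows = rows[[k in keep_keys for k in key]]
    if rows.empty:
        raise DataError("no modelled rows available")

    # outcome
    if outcome == "latent":
        if "log_sdq_latent" not in rows.columns:
            raise DataError("cohort has no latent log-outcome column")
        y = pd.to_numeric(rows["log_sdq_latent"], errors="coerce")
    elif outcome == "sdq":
        sdq = pd.to_numeric(rows["sdq_total"], errors="coerce")
        if spec.family == "poisson":
            y = sdq
        else:
            y = pd.Series(
                np.where(sdq.notna(), transform_outcome(sdq.fillna(0)), np.nan),
                index=rows.index,
            )
    else:
        raise SpecError(f"unknown outcome source {outcome!r}")

    age = rows["sweep"].map(SWEEP_AGES).astype(float)

    # fixed block
    x_parts, x_labels = [], []
    for term in spec.fixed_terms:
        block = cb[term].expand(rows)
        x_parts.append(block)
        x_labels.extend(block.columns)

    scaling: dict[str, tuple[float, float]] = {}

    def exposure_series(name: str) -> pd.Series:
        entry = cb[name]
        vals = _exposure_values(rows, name, cb)
        if entry.kind == "continuous" and entry.standardize:
            m, s = float(vals.mean()), float(vals.std(ddof=0))
            s = s if s > 0 else 1.0
            scaling[name] = (m, s)
            vals = (vals - m) / s
        return vals

    # time-varying block
    z_parts, z_labels, z_meta = [], [], []
    z_group, z_group_names, z_group_pooling = [], [], []
    for gi, term in enumerate(spec.time_varying):
        z_group_names.append(term.name)
        z_group_pooling.append(term.pooling)
        if term.mode == "age_specific":
            vals = exposure_series(term.name)
            for a in MODELED_AGES:
                # exposure value where the row's age matches, else 0; a
                # missing exposure invalidates only rows at its own age
                col = np.where(age.values == a, vals.values, 0.0)
                z_parts.append(pd.Series(col, index=rows.index))
                z_labels.append(f"{term.name}@age{a:g}")
                z_meta.append((term.name, a))
                z_group.append(gi)
        else:  # cumulative: within-person mean over observed modelled sweeps
            col_name = f"cum_{term.name}"
            if col_name in rows.columns:
                vals = pd.to_numeric(rows[col_name], errors="coerce")
            else:
                modeled = cohort.modeled_rows()
                src = _exposure_values(modeled, term.name, cb)
                means = src.groupby(modeled["person_id"]).mean()
                vals = rows["person_id"].map(means)
            entry = cb[term.name]
            if entry.kind == "continuous" and entry.standardize:
                m, s = float(vals.mean()), float(vals.std(ddof=0))
                s = s if s > 0 else 1.0
                scaling[col_name] = (m, s)
                vals = (vals - m) / s
            z_parts.append(vals)
            z_labels.append(f"{term.name}_cum")
            z_meta.append((term.name, None))
            z_group.append(gi)

    # interaction columns (part of the fixed block, flat priors)
    for mod, exp_name in spec.interactions:
        mod_cols = cb[mod].expand(rows)
        if mod_cols.shape[1] != 1:
            raise SpecError(f"interaction modifier {mod!r} must be binary")
        vals = exposure_series(exp_name)
        x_parts.append((mod_cols.iloc[:, 0] * vals).to_frame(f"{mod}:{exp_name}"))
        x_labels.append(f"{mod}:{exp_name}")

    X = pd.concat(x_parts, axis=1) if x_parts else pd.DataFrame(index=rows.index)
    Zdf = pd.concat(z_parts, axis=1) if z_parts else pd.DataFrame(index=rows.index)

    # complete cases: outcome, fixed/interaction columns, and — for
    # age-specific terms — the exposure value at the row's own age
    ok = y.notna()
    if len(x_labels):
        ok &= X.notna().all(axis=1)
    if len(z_labels):
        ok &= Zdf.notna().all(axis=1)

    rows_ok = rows[ok]
    if rows_ok.empty:
        raise DataError("zero usable rows after complete-case filtering")

    person_ids = list(pd.unique(rows_ok["person_id"]))
    code = {p: i for i, p in enumerate(person_ids)}
    person_index = rows_ok["person_id"].map(code).to_numpy()
    n = int(ok.sum())

    return DesignMatrices(
        y=y[ok].to_numpy(dtype=float),
        X=X.loc[ok].to_numpy(dtype=float).reshape(n, len(x_labels)),
        Z=Zdf.loc[ok].to_numpy(dtype=float).reshape(n, len(z_labels)),
        x_labels=list(x_labels),
        z_labels=list(z_labels),
        z_meta=z_meta,
        z_group=np.asarray(z_group, dtype=int),
        z_group_names=z_group_names,
        z_group_pooling=z_group_pooling,
        person_index=person_index,
        person_ids=person_ids,
        age_index=age[ok].to_numpy(dtype=float),
        row_keys=list(zip(rows_ok["person_id"], rows_ok["sweep"])),
        scaling=scaling,
    )
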