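"""Synthetic MCS-like cohort generator with known ground truth.

The generator emulates the analysis sample of the real cohort: ~3595
children followed over seven sweeps (ages 0.75, 3, 5, 7, 11, 14, 17), with
declining neighbourhood air-pollution trends, a deprivation gradient that
drifts toward less-deprived categories over time, slowly-varying individual
and household covariates, residential relocation, and block-wise
missingness/attrition.  The outcome is generated from the same hierarchical
model the inference module fits (individual random intercepts, fixed
individual/household effects, age-specific neighbourhood-exposure
coefficients), so parameter-recovery tests have an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import SWEEP_AGES, MODELED_SWEEPS, LongCohort
from .codebook import CovariateCodebook, default_codebook
from .errors import ConfigError

__all__ = ["GeneratorConfig", "TruthRecord", "default_truth", "generate_cohort", "inject_missingness", "simulate_study_cohort"]

_SWEEPS = np.arange(1, 8)
_AGES = np.array([SWEEP_AGES[s] for s in _SWEEPS])

# Per-sweep exposure means/SDs (sweeps 1..7).  Sweeps 2..7 follow the cohort's
# descriptive statistics; sweep 1 (age 9 months, year ~2001) extrapolates the
# declining pollution trend one step back.
_EXPOSURE_MEANS = {
    "pm25": [15.0, 14.1, 12.0, 11.1, 11.1, 9.3, 9.4],
    "pm10": [22.5, 21.4, 18.1, 16.7, 15.1, 13.9, 14.4],
    "no2": [21.0, 20.7, 19.9, 18.6, 17.9, 14.8, 13.9],
    "ndvi": [0.5, 0.5, 0.5, 0.5, 0.5, 0.6, 0.5],
    "green_area_ha": [5.8, 5.8, 6.2, 5.9, 6.2, 6.4, 6.4],
}
_EXPOSURE_SDS = {
    "pm25": [2.4, 2.3, 2.0, 1.9, 1.6, 1.3, 1.8],
    "pm10": [3.4, 3.3, 3.0, 2.4, 2.0, 2.0, 2.5],
    "no2": [8.0, 8.0, 7.5, 7.2, 6.5, 6.2, 5.7],
    "ndvi": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
    "green_area_ha": [30.1, 30.1, 30.8, 22.2, 20.1, 22.8, 22.8],
}

# Deprivation category shares per sweep: (most deprived 1-3, least deprived 8-10).
_IMD_SHARES = {
    "most": [0.275, 0.275, 0.262, 0.250, 0.232, 0.228, 0.222],
    "least": [0.323, 0.323, 0.340, 0.352, 0.367, 0.376, 0.380],
}

# Time-varying covariate prevalences per sweep (persistent within person via a
# shared latent uniform, so prevalence drift implies few within-person flips).
_COVARIATE_RATES = {
    "longstanding_illness": [0.10, 0.154, 0.190, 0.185, 0.135, 0.167, 0.170],
    "overweight": [0.171, 0.171, 0.155, 0.139, 0.200, 0.182, 0.182],
    "obese": [0.048, 0.048, 0.041, 0.046, 0.0535, 0.063, 0.089],
    "family_single": [0.080, 0.086, 0.112, 0.127, 0.165, 0.178, 0.218],
    "poverty": [0.180, 0.176, 0.183, 0.159, 0.107, 0.138, 0.133],
}

# Per-sweep outcome missingness at the modelled sweeps (1 - n_sweep / 3595).
_OUTCOME_MISSING = {2: 0.067, 3: 0.008, 4: 0.007, 6: 0.038, 7: 0.056}


@dataclass
class TruthRecord:
    """Generating parameter values for a synthetic cohort."""

    mu_alpha: float
    sigma2_alpha: float
    beta: dict[str, float]
    #: age x exposure matrix of time-varying coefficients (index = modelled ages)
    gamma: pd.DataFrame
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma2: float = 0.2
    family: str = "gaussian_log"


def default_truth() -> TruthRecord:
    """Default generating values, mirroring the headline effect pattern:
    a PM2.5 effect confined to age 3, a protective deprivation contrast that
    grows through adolescence, and null green-space effects."""
    ages = [3.0, 5.0, 7.0, 14.0, 17.0]
    gamma = pd.DataFrame(
        {
            "pm25": [0.15, 0.0, 0.0, 0.0, 0.0],
            "ndvi": [0.0] * 5,
            "green_area": [0.0] * 5,
            "imd_4_10": [0.10, -0.25, -0.43, -0.58, -0.72],
        },
        index=ages,
    )
    beta = {
        "sex_male": 0.12,
        "ethnicity_other": 0.02,
        "obesity_overweight": 0.05,
        "obesity_obese": 0.10,
        "longstanding_illness": 0.20,
        "poverty_below": 0.12,
        "maternal_education_2": -0.05,
        "maternal_education_3": -0.10,
        "maternal_education_4": -0.15,
        "maternal_education_5": -0.20,
        "maternal_depression": 0.15,
        "family_single": 0.02,
        "urban": 0.05,
    }
    return TruthRecord(mu_alpha=0.2, sigma2_alpha=0.16, beta=beta, gamma=gamma, sigma2=0.2)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_persons: int = 3595
    seed: int = 0
    truth: TruthRecord | None = None
    exposure_means: dict = field(default_factory=lambda: {k: list(v) for k, v in _EXPOSURE_MEANS.items()})
    exposure_sds: dict = field(default_factory=lambda: {k: list(v) for k, v in _EXPOSURE_SDS.items()})
    imd_shares: dict = field(default_factory=lambda: {k: list(v) for k, v in _IMD_SHARES.items()})
    covariate_rates: dict = field(default_factory=lambda: {k: list(v) for k, v in _COVARIATE_RATES.items()})
    female_share: float = 0.505
    white_share: float = 0.838
    maternal_education_probs: tuple = (0.105, 0.379, 0.120, 0.338, 0.058)
    maternal_depression_share: float = 0.795  # printed Table-1 marginal
    urban_share: float = 0.8
    autocorr: float = 0.8  # within-person exposure autocorrelation
    relocation_rate: float = 0.05  # per between-sweep transition
    england_share: float = 1.0
    second_born_multiple_share: float = 0.0
    multiple_birth_share: float = 0.015
    # missingness block rates
    outcome_missing: dict = field(default_factory=lambda: dict(_OUTCOME_MISSING))
    lsoa_missing_rate: float = 0.03
    covariate_missing_rate: float = 0.01
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        rates = [
            self.female_share, self.white_share, self.maternal_depression_share,
            self.urban_share, self.autocorr, self.relocation_rate,
            self.england_share, self.second_born_multiple_share,
            self.multiple_birth_share, self.lsoa_missing_rate,
            self.covariate_missing_rate, self.dropout_rate,
            *self.outcome_missing.values(),
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        for name, sds in self.exposure_sds.items():
            if any(s < 0 for s in sds):
                raise ConfigError(f"negative SD for exposure {name!r}")


def _persistent_anchor(rng, reloc: np.ndarray, draw) -> np.ndarray:
    """(P,7) latent that is redrawn only at relocation sweeps."""
    P, T = reloc.shape
    fresh = draw((P, T))
    out = np.empty((P, T))
    out[:, 0] = fresh[:, 0]
    for t in range(1, T):
        out[:, t] = np.where(reloc[:, t], fresh[:, t], out[:, t - 1])
    return out


# exposures whose truth column maps to a raw cohort column
_EXPOSURE_SOURCE = {
    "pm25": "pm25",
    "pm10": "pm10",
    "no2": "no2",
    "ndvi": "ndvi",
    "green_area": "green_area_ha",
    "imd_4_10": None,  # derived indicator imd_decile >= 4
}


def generate_cohort(config: GeneratorConfig) -> tuple[LongCohort, TruthRecord]:
    """Draw a complete cohort (no missingness) plus its generating truth.

    The linear predictor follows the outcome model exactly:
    mu_it = alpha_i + sum_p beta_p x_itp + sum_k gamma_{t,k} z_itk
    (+ interactions), with alpha_i ~ N(mu_alpha, sigma2_alpha) and, for the
    Gaussian family, log-outcome ~ N(mu_it, sigma2).  Integer SDQ scores are
    obtained by exponentiating, subtracting the +1 offset, rounding and
    clamping to [0, 40]; the continuous log-outcome is retained in a
    ``log_sdq_latent`` column so recovery tests can bypass discretisation.
    """
    truth = config.truth if config.truth is not None else default_truth()
    rng = np.random.default_rng(config.seed)
    P, T = config.n_persons, 7
    rho = config.autocorr

    # ---- person-level attributes ------------------------------------------
    sex = np.where(rng.random(P) < config.female_share, "female", "male")
    ethnicity = np.where(rng.random(P) < config.white_share, "white", "other")
    mat_edu = rng.choice(np.arange(1, 6), size=P, p=list(config.maternal_education_probs))
    mat_dep = (rng.random(P) < config.maternal_depression_share).astype(float)
    urban = (rng.random(P) < config.urban_share).astype(float)
    country = np.where(rng.random(P) < config.england_share, "England", "Wales")
    is_multiple = rng.random(P) < config.multiple_birth_share
    second_born = rng.random(P) < config.second_born_multiple_share
    birth_order = np.where(is_multiple, np.where(second_born, 2.0, 1.0), np.nan)
    alpha = truth.mu_alpha + np.sqrt(truth.sigma2_alpha) * rng.standard_normal(P)

    # persistent latents for slowly-varying covariates
    u_ill, u_ob, u_single, u_pov = (rng.random(P) for _ in range(4))
    rates = config.covariate_rates
    ill = np.stack([(u_ill < rates["longstanding_illness"][t]) for t in range(T)], axis=1)
    obese = np.stack([(u_ob < rates["obese"][t]) for t in range(T)], axis=1)
    overw = np.stack(
        [(~obese[:, t]) & (u_ob < rates["obese"][t] + rates["overweight"][t]) for t in range(T)],
        axis=1,
    )
    single = np.stack([(u_single < rates["family_single"][t]) for t in range(T)], axis=1)
    poverty = np.stack([(u_pov < rates["poverty"][t]) for t in range(T)], axis=1)

    # ---- residence spells and exposures -----------------------------------
    reloc = np.zeros((P, T), dtype=bool)
    reloc[:, 1:] = rng.random((P, T - 1)) < config.relocation_rate
    spell = np.cumsum(reloc, axis=1)
    lsoa = np.array(
        [[f"L{p:05d}_{spell[p, t]}" for t in range(T)] for p in range(P)], dtype=object
    )

    normal_draw = lambda shape: rng.standard_normal(shape)
    anchors = {
        "pollution": _persistent_anchor(rng, reloc, normal_draw),
        "ndvi": _persistent_anchor(rng, reloc, normal_draw),
        "green_area_ha": _persistent_anchor(rng, reloc, normal_draw),
    }
    exposures: dict[str, np.ndarray] = {}
    for name in ("pm25", "pm10", "no2", "ndvi"):
        m = np.asarray(config.exposure_means[name])
        s = np.asarray(config.exposure_sds[name])
        a = anchors["pollution"] if name in ("pm25", "pm10", "no2") else anchors["ndvi"]
        eps = rng.standard_normal((P, T))
        z = m + s * (np.sqrt(rho) * a + np.sqrt(1 - rho) * eps)
        exposures[name] = (
            np.clip(z, 0.01, 0.99) if name == "ndvi" else np.clip(z, 0.1, None)
        )
    # green-space area is strongly right-skewed: lognormal matching mean/SD
    m = np.asarray(config.exposure_means["green_area_ha"], dtype=float)
    s = np.asarray(config.exposure_sds["green_area_ha"], dtype=float)
    with np.errstate(divide="ignore"):
        sig2 = np.log1p((s / m) ** 2)
    mu_ln = np.log(m) - sig2 / 2
    eps = rng.standard_normal((P, T))
    exposures["green_area_ha"] = np.exp(
        mu_ln + np.sqrt(sig2) * (np.sqrt(rho) * anchors["green_area_ha"] + np.sqrt(1 - rho) * eps)
    )

    # deprivation: per-spell latent mapped through drifting category shares
    u_imd = _persistent_anchor(rng, reloc, lambda shape: rng.random(shape))
    v_imd = _persistent_anchor(rng, reloc, lambda shape: rng.random(shape))
    p_most = np.asarray(config.imd_shares["most"])
    p_least = np.asarray(config.imd_shares["least"])
    most = u_imd < p_most
    least = u_imd > 1.0 - p_least
    decile = np.where(
        most,
        1 + np.floor(v_imd * 3),
        np.where(least, 8 + np.floor(v_imd * 3), 4 + np.floor(v_imd * 4)),
    ).astype(int)
    decile = np.clip(decile, 1, 10)

    # ---- linear predictor and outcome -------------------------------------
    xcols = {
        "sex_male": np.repeat((sex == "male").astype(float)[:, None], T, axis=1),
        "ethnicity_other": np.repeat((ethnicity == "other").astype(float)[:, None], T, axis=1),
        "obesity_overweight": overw.astype(float),
        "obesity_obese": obese.astype(float),
        "longstanding_illness": ill.astype(float),
        "poverty_below": poverty.astype(float),
        "maternal_depression": np.repeat(mat_dep[:, None], T, axis=1),
        "family_single": single.astype(float),
        "urban": np.repeat(urban[:, None], T, axis=1),
    }
    for lev in (2, 3, 4, 5):
        xcols[f"maternal_education_{lev}"] = np.repeat(
            (mat_edu == lev).astype(float)[:, None], T, axis=1
        )

    mu = np.repeat(alpha[:, None], T, axis=1)
    for name, b in truth.beta.items():
        if name not in xcols:
            raise ConfigError(f"truth.beta names unknown covariate {name!r}")
        mu = mu + b * xcols[name]

    zvals = {}
    for exp_name in truth.gamma.columns:
        if exp_name == "imd_4_10":
            zvals[exp_name] = (decile >= 4).astype(float)
        else:
            src = _EXPOSURE_SOURCE.get(exp_name, exp_name)
            zvals[exp_name] = exposures[src]
    for t, sweep in enumerate(_SWEEPS):
        if sweep in MODELED_SWEEPS:
            age = SWEEP_AGES[sweep]
            for exp_name in truth.gamma.columns:
                mu[:, t] += truth.gamma.loc[age, exp_name] * zvals[exp_name][:, t]
    for (mod, exp_name), coef in truth.interactions.items():
        mu = mu + coef * xcols[mod] * zvals[exp_name]

    modeled_mask = np.isin(_SWEEPS, MODELED_SWEEPS)
    latent = np.full((P, T), np.nan)
    sdq = np.full((P, T), np.nan)
    if truth.family == "gaussian_log":
        noise = rng.standard_normal((P, T))
        latent[:, modeled_mask] = (mu + np.sqrt(truth.sigma2) * noise)[:, modeled_mask]
        sdq[:, modeled_mask] = np.clip(
            np.round(np.expm1(latent[:, modeled_mask])), 0, 40
        )
    elif truth.family == "poisson":
        counts = rng.poisson(np.exp(np.clip(mu, None, 20.0)))
        sdq[:, modeled_mask] = np.clip(counts, 0, 40)[:, modeled_mask]
    else:
        raise ConfigError(f"unknown outcome family {truth.family!r}")

    # ---- assemble the long table ------------------------------------------
    pid = np.repeat([f"P{p:05d}" for p in range(P)], T)
    df = pd.DataFrame(
        {
            "person_id": pid,
            "sweep": np.tile(_SWEEPS, P),
            "age_years": np.tile(_AGES, P),
            "sdq_total": sdq.ravel(),
            "sex": np.repeat(sex, T),
            "ethnicity": np.repeat(ethnicity, T),
            "obesity": np.where(
                obese.ravel(), "obese", np.where(overw.ravel(), "overweight", "normal")
            ),
            "longstanding_illness": ill.astype(float).ravel(),
            "poverty": poverty.astype(float).ravel(),
            "maternal_education_nvq": np.repeat(mat_edu.astype(float), T),
            "maternal_depression_at_birth": np.repeat(mat_dep, T),
            "family_structure": np.where(single.ravel(), "single", "couple"),
            "lsoa_id": lsoa.ravel(),
            "pm25": exposures["pm25"].ravel(),
            "pm10": exposures["pm10"].ravel(),
            "no2": exposures["no2"].ravel(),
            "ndvi": exposures["ndvi"].ravel(),
            "green_area_ha": exposures["green_area_ha"].ravel(),
            "imd_decile": decile.astype(float).ravel(),
            "urban": np.repeat(urban, T),
            "country": np.repeat(country, T),
            "birth_order_in_multiple": np.repeat(birth_order, T),
            "log_sdq_latent": latent.ravel(),
        }
    )
    lookup = df.loc[
        :, ["lsoa_id", "sweep", "pm25", "pm10", "no2", "ndvi", "green_area_ha", "imd_decile", "urban"]
    ].drop_duplicates(["lsoa_id", "sweep"])
    return LongCohort(df, exposure_lookup=lookup), truth


def inject_missingness(cohort: LongCohort, config: GeneratorConfig) -> LongCohort:
    """Blank cells completely at random at the configured block rates.

    Outcome cells go missing at per-sweep rates; an LSOA cell going missing
    also blanks the LSOA-derived exposure columns (exposure assignment is
    keyed on the neighbourhood of residence); covariate cells go missing at a
    shared rate.  Dropout, once triggered at a sweep, removes all later rows
    for that person.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7919]))
    df = cohort.df.copy()
    n = len(df)

    # outcome block
    for sweep, rate in config.outcome_missing.items():
        mask = (df["sweep"] == sweep).values & (rng.random(n) < rate)
        df.loc[mask, ["sdq_total", "log_sdq_latent"]] = np.nan

    # residence block (lsoa and its attributes)
    mask = rng.random(n) < config.lsoa_missing_rate
    df.loc[mask, "lsoa_id"] = pd.NA
    df.loc[mask, ["pm25", "pm10", "no2", "ndvi", "green_area_ha", "imd_decile", "urban"]] = np.nan

    # covariate block
    for col in ("obesity", "longstanding_illness", "poverty", "family_structure"):
        mask = rng.random(n) < config.covariate_missing_rate
        df.loc[mask, col] = pd.NA if df[col].dtype == object else np.nan

    # monotone dropout
    if config.dropout_rate > 0:
        trig = rng.random(n) < config.dropout_rate
        trig &= (df["sweep"] >= 2).values
        drop_from = (
            df.assign(_trig=np.where(trig, df["sweep"], np.inf))
            .groupby("person_id")["_trig"]
            .min()
        )
        keep = df["sweep"] <= df["person_id"].map(drop_from)
        df = df[keep].reset_index(drop=True)

    return LongCohort(df, exposure_lookup=cohort.exposure_lookup)


def simulate_study_cohort(config: GeneratorConfig) -> tuple[LongCohort, TruthRecord]:
    """Convenience: generate a cohort and apply the missingness mechanism."""
    cohort, truth = generate_cohort(config)
    return inject_missingness(cohort, config), truth
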