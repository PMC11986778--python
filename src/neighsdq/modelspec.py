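"""Declarative model specification for the hierarchical outcome model."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import SpecError

__all__ = ["PriorSpec", "TimeVaryingTerm", "ModelSpec", "default_model_spec"]

FAMILIES = ("gaussian_log", "poisson")

#: Default fixed-effect roster: individual + household covariates and the
#: urban/rural indicator.
DEFAULT_FIXED_TERMS = (
    "sex_male",
    "ethnicity_other",
    "obesity",
    "longstanding_illness",
    "poverty_below",
    "maternal_education",
    "maternal_depression",
    "family_single",
    "urban",
)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Fixed effects and interaction coefficients get Normal(beta_mean, beta_var);
    the hyper-means mu_alpha and mu_gamma_k get Normal(0, hyper_var); every
    precision tau = 1/sigma2 gets Gamma(prec_shape, prec_rate) — i.e. an
    inverse-gamma prior on the variance.  The 1000 in Normal(0, 1000) is read
    as a variance.
    """

    beta_mean: float = 0.0
    beta_var: float = 1000.0
    hyper_var: float = 1000.0
    prec_shape: float = 1.0
    prec_rate: float = 0.01


@dataclass(frozen=True)
class TimeVaryingTerm:
    """One neighbourhood exposure entering the time-varying block.

    mode ``age_specific`` expands to one coefficient per modelled age;
    ``cumulative`` collapses to a single coefficient on the within-person
    mean across observed modelled sweeps.  pooling ``hierarchical`` places
    gamma_{t,k} ~ N(mu_gamma_k, sigma2_gamma_k); ``independent`` uses flat
    N(0, beta_var) priors per coefficient.
    """

    name: str
    mode: str = "age_specific"
    pooling: str = "hierarchical"

    def __post_init__(self):
        if self.mode not in ("age_specific", "cumulative"):
            raise SpecError(f"unknown mode {self.mode!r} for {self.name!r}")
        if self.pooling not in ("hierarchical", "independent"):
            raise SpecError(f"unknown pooling {self.pooling!r} for {self.name!r}")


@dataclass
class ModelSpec:
    family: str = "gaussian_log"
    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    time_varying: tuple[TimeVaryingTerm, ...] = ()
    #: (modifier, exposure) pairs; modifier must be a binary fixed term
    interactions: tuple[tuple[str, str], ...] = ()
    priors: PriorSpec = field(default_factory=PriorSpec)
    #: residual variance pinned to a constant (None = sampled); gaussian only
    fixed_sigma2: float | None = None
    #: individual random intercepts; when False the model has a single
    #: global intercept mu_alpha
    random_intercept: bool = True
    name: str = "model"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        self.fixed_terms = tuple(self.fixed_terms)
        self.time_varying = tuple(
            t if isinstance(t, TimeVaryingTerm) else TimeVaryingTerm(**t) if isinstance(t, dict) else TimeVaryingTerm(t)
            for t in self.time_varying
        )
        self.interactions = tuple((m, e) for m, e in self.interactions)
        names = list(self.fixed_terms) + [t.name for t in self.time_varying]
        if len(names) != len(set(names)):
            raise SpecError("duplicate term in model specification")
        tv_names = {t.name for t in self.time_varying}
        for mod, exp in self.interactions:
            if mod not in self.fixed_terms:
                raise SpecError(f"interaction modifier {mod!r} not among fixed terms")
            if exp not in tv_names:
                raise SpecError(f"interaction exposure {exp!r} not among time-varying terms")

    def with_(self, **changes) -> "ModelSpec":
        return replace(self, **changes)


def default_model_spec(
    pollutant: str = "pm25",
    mode: str = "age_specific",
    pooling: str = "hierarchical",
) -> ModelSpec:
    """The main combined model: one pollutant, both green-space metrics and
    the deprivation contrast (IMD deciles 4-10 vs the most deprived 1-3),
    each with age-specific coefficients, over the full fixed-effect roster."""
    tv = tuple(
        TimeVaryingTerm(name, mode=mode, pooling=pooling)
        for name in (pollutant, "ndvi", "green_area", "imd_4_10")
    )
    return ModelSpec(time_varying=tv, name=f"main_{pollutant}_{mode}")
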