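"""Exact evaluation of log-likelihood, log-prior and log-posterior.

The outcome model is

    Y_it ~ Normal(mu_it, sigma2)            (Gaussian family, log-scale y)
    Y_it ~ Poisson(exp(mu_it))              (Poisson family, raw counts)
    mu_it = alpha_i + sum_p beta_p x_itp + sum_k gamma_tk z_itk (+ interactions)
    alpha_i ~ N(mu_alpha, sigma2_alpha)
    gamma_tk ~ N(mu_gamma_k, sigma2_gamma_k)       (hierarchical pooling)

with Normal(0, 1000) priors on the fixed effects, interactions and hyper-
means, and Gamma(1, 0.01) priors on each precision tau = 1/sigma2 (an
inverse-gamma(1, 0.01) on the variance).  Interaction coefficients live in
the beta vector, aligned to the X columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .design import DesignMatrices
from .errors import DomainError
from .modelspec import ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["ParameterState", "log_likelihood", "log_prior", "log_posterior"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ParameterState:
    """One point in parameter space, aligned to a DesignMatrices object.

    beta covers the full X block (fixed effects and interaction columns, in
    X-column order); gamma aligns to the Z columns.  Hyperparameters that a
    model variant does not contain (e.g. sigma2_alpha without random
    intercepts, mu_gamma for independent pooling) are None/empty.
    """

    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu_alpha: float | None = None
    sigma2_alpha: float | None = None
    #: per-exposure-group hyper-means/variances (hierarchical groups only -> None entries otherwise)
    mu_gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2_gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2: float | None = None

    def linear_predictor(self, design: DesignMatrices) -> np.ndarray:
        eta = np.zeros(design.n_obs)
        if self.alpha.size:
            eta += self.alpha[design.person_index]
        elif self.mu_alpha is not None:
            eta += self.mu_alpha
        if self.beta.size:
            eta += design.X @ self.beta
        if self.gamma.size:
            eta += design.Z @ self.gamma
        return eta


def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + np.log(var)) - 0.5 * (np.asarray(x) - mean) ** 2 / var


def _gamma_logpdf(tau, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(tau) - rate * tau


def log_likelihood(state: ParameterState, design: DesignMatrices, family: str = "gaussian_log") -> float:
    """Sum of per-observation log-densities at the given parameter state."""
    if design.n_obs == 0:
        return 0.0
    eta = state.linear_predictor(design)
    if not np.all(np.isfinite(eta)):
        logger.warning("non-finite linear predictor; log-likelihood is non-finite")
    if family == "gaussian_log":
        if state.sigma2 is None or state.sigma2 <= 0:
            raise DomainError("gaussian family needs sigma2 > 0")
        return float(np.sum(_norm_logpdf(design.y, eta, state.sigma2)))
    if family == "poisson":
        y = design.y
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))
    raise DomainError(f"unknown family {family!r}")


def log_prior(state: ParameterState, spec: ModelSpec, design: DesignMatrices) -> float:
    """Sum of log prior densities for every parameter present in the state.

    Precision priors are evaluated as Gamma(shape, rate) densities of
    tau = 1/sigma2 (the stated parameterisation of the variance priors).
    """
    pr = spec.priors
    for v in (state.sigma2, state.sigma2_alpha, *np.atleast_1d(state.sigma2_gamma)):
        if v is not None and not (v > 0 or np.isnan(v)):
            raise DomainError("variances must be positive")
    total = 0.0
    if state.beta.size:
        total += float(np.sum(_norm_logpdf(state.beta, pr.beta_mean, pr.beta_var)))
    if state.mu_alpha is not None:
        total += float(_norm_logpdf(state.mu_alpha, 0.0, pr.hyper_var))
    if state.alpha.size:
        if state.sigma2_alpha is None:
            raise DomainError("alpha present but sigma2_alpha missing")
        total += float(np.sum(_norm_logpdf(state.alpha, state.mu_alpha, state.sigma2_alpha)))
        total += float(_gamma_logpdf(1.0 / state.sigma2_alpha, pr.prec_shape, pr.prec_rate))
    if state.gamma.size:
        for gi, pooling in enumerate(design.z_group_pooling):
            cols = np.flatnonzero(design.z_group == gi)
            g = state.gamma[cols]
            if pooling == "hierarchical":
                mu_k = state.mu_gamma[gi]
                s2_k = state.sigma2_gamma[gi]
                total += float(_norm_logpdf(mu_k, 0.0, pr.hyper_var))
                total += float(np.sum(_norm_logpdf(g, mu_k, s2_k)))
                total += float(_gamma_logpdf(1.0 / s2_k, pr.prec_shape, pr.prec_rate))
            else:
                total += float(np.sum(_norm_logpdf(g, pr.beta_mean, pr.beta_var)))
    if spec.family == "gaussian_log" and spec.fixed_sigma2 is None and state.sigma2 is not None:
        total += float(_gamma_logpdf(1.0 / state.sigma2, pr.prec_shape, pr.prec_rate))
    return total


def log_posterior(state: ParameterState, design: DesignMatrices, spec: ModelSpec) -> float:
    """log-likelihood + log-prior, up to the normalising constant."""
    return log_likelihood(state, design, spec.family) + log_prior(state, spec, design)
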