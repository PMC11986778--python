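"""WAIC computation and the iterative model-comparison workflow.

Model fit is compared with the Watanabe-Akaike information criterion,
WAIC = -2 (lppd - p_waic), where lppd is the log pointwise predictive
density and p_waic the effective number of parameters (sum of per-
observation posterior variances of the log-density).  Lower is better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .design import DesignMatrices, build_design
from .diagnostics import summarize_posterior
from .errors import DataError, SpecError
from .modelspec import ModelSpec
from .sampler import PosteriorDraws, SamplerConfig, run_mcmc

logger = logging.getLogger(__name__)

__all__ = ["WaicResult", "pointwise_loglik", "compute_waic", "compare_models", "ModelComparison"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    #: per-observation (lppd_i, p_waic_i) contributions
    pointwise: pd.DataFrame

    def __post_init__(self):
        assert np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic))


def pointwise_loglik(
    draws: PosteriorDraws, design: DesignMatrices, spec: ModelSpec, thin: int = 1
) -> np.ndarray:
    """(draw, observation) matrix of log-densities under the fitted family.

    Uses the stored intercept draws (conditional log-density given the
    individual random effects).  ``thin`` subsamples the saved draws to
    bound memory on large fits.
    """
    if draws.alpha_draws is None:
        raise SpecError("pointwise_loglik needs stored intercept draws (save_alpha)")
    labels = draws.labels
    coef_labels = design.labels
    if labels[: len(coef_labels)] != coef_labels:
        raise SpecError("draw labels do not match design columns")
    W = design.W
    y = design.y
    mats = []
    for c in range(draws.n_chains):
        theta = draws.draws[c, ::thin, : len(coef_labels)]
        alpha = draws.alpha_draws[c, ::thin, :]
        eta = alpha[:, design.person_index]
        if len(coef_labels):
            eta = eta + theta @ W.T
        if spec.family == "gaussian_log":
            s2_idx = labels.index("sigma2")
            if spec.fixed_sigma2 is not None:
                s2 = np.full(eta.shape[0], float(spec.fixed_sigma2))
            else:
                s2 = draws.draws[c, ::thin, s2_idx]
            ll = -0.5 * (_LOG2PI + np.log(s2)[:, None]) - 0.5 * (y - eta) ** 2 / s2[:, None]
        else:
            ll = y * eta - np.exp(np.clip(eta, None, 50.0)) - gammaln(y + 1.0)
        mats.append(ll)
    return np.concatenate(mats, axis=0)


def compute_waic(pointwise: np.ndarray) -> WaicResult:
    """WAIC from a (draw x observation) log-likelihood matrix.

    lppd_i = log mean_s exp(loglik_si) via a stable log-sum-exp;
    p_waic_i = sample variance over draws (denominator S-1).
    """
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2 or ll.size == 0:
        raise DataError("pointwise matrix must be (draws x observations), non-empty")
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    if S == 1:
        warnings.warn("single draw: p_waic is zero", stacklevel=2)
        p_i = np.zeros(ll.shape[1])
    else:
        p_i = ll.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(
        lppd=lppd,
        p_waic=p_waic,
        waic=-2.0 * (lppd - p_waic),
        pointwise=pd.DataFrame({"lppd_i": lppd_i, "p_waic_i": p_i}),
    )


@dataclass
class ModelComparison:
    """Ranked WAIC table plus per-model artefacts."""

    table: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    draws: dict[str, PosteriorDraws]
    waics: dict[str, WaicResult]
    n_obs: int


def compare_models(
    cohort,
    specs: list[ModelSpec],
    cfg: SamplerConfig,
    codebook=None,
    outcome: str = "sdq",
    loglik_thin: int = 5,
) -> ModelComparison:
    """Fit several specs on a common row set and rank them by WAIC.

    All models are fitted on the intersection of their complete-case rows so
    the WAIC values are comparable; a hard error is raised if the aligned
    row sets still differ.  The returned table is ordered by ascending WAIC.
    """
    if len(specs) < 2:
        raise SpecError("compare_models needs at least 2 specs")
    designs = [build_design(cohort, sp, codebook=codebook, outcome=outcome) for sp in specs]
    common = set.intersection(*(set(d.row_keys) for d in designs))
    if not common:
        raise DataError("no common complete-case rows across specs")
    designs = [
        build_design(cohort, sp, codebook=codebook, outcome=outcome, keep_keys=common)
        for sp in specs
    ]
    key_sets = {frozenset(d.row_keys) for d in designs}
    if len(key_sets) != 1:
        raise DataError("row sets differ after alignment; WAIC is not comparable")

    names, rows = [], []
    summaries, all_draws, waics = {}, {}, {}
    for sp, ds in zip(specs, designs):
        name = sp.name
        draws = run_mcmc(ds, sp, cfg)
        ll = pointwise_loglik(draws, ds, sp, thin=loglik_thin)
        res = compute_waic(ll)
        names.append(name)
        rows.append({"model": name, "lppd": res.lppd, "p_waic": res.p_waic, "waic": res.waic})
        summaries[name] = summarize_posterior(draws)
        all_draws[name] = draws
        waics[name] = res
        logger.info("compare_models: %s waic=%.2f (n=%d)", name, res.waic, ds.n_obs)

    table = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ModelComparison(
        table=table,
        summaries=summaries,
        draws=all_draws,
        waics=waics,
        n_obs=designs[0].n_obs,
    )
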