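"""Bespoke MCMC for the hierarchical outcome model.

Gaussian family: blocked conjugate Gibbs.  The coefficient block
(beta, gamma, interactions) is drawn jointly from its multivariate-normal
full conditional; individual intercepts, hyper-means, and precisions all
have closed-form conditionals.  Poisson family: random-walk Metropolis
within Gibbs for the coefficients and intercepts (adaptive proposal scales
during burn-in, frozen afterwards) with the same conjugate hyperparameter
updates.

Covariate columns are centred before sampling — this removes the
near-nonidentifiability between the global mean mu_alpha and the dummy
blocks — and the intercept draws are shifted back to the raw-covariate
scale when recorded, so reported draws always refer to the model as
specified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .design import DesignMatrices
from .errors import ConfigError, DataError
from .modelspec import ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "PosteriorDraws", "run_mcmc"]


@dataclass
class SamplerConfig:
    n_chains: int = 2
    n_burnin: int = 10_000
    n_postburn: int = 10_000
    thin: int = 1
    seed: int = 0
    init: str = "prior_scaled"  # or "fixed_zero"
    proposal_scale: float = 0.1  # Poisson family initial RW scale
    adapt_interval: int = 50
    #: store individual random-intercept draws (needed for WAIC); None = auto
    save_alpha: bool | None = None

    def __post_init__(self):
        if self.n_chains < 1 or self.n_postburn < 1 or self.thin < 1:
            raise ConfigError("n_chains >= 1, n_postburn >= 1, thin >= 1 required")
        if self.init not in ("prior_scaled", "fixed_zero"):
            raise ConfigError(f"unknown init strategy {self.init!r}")


@dataclass
class PosteriorDraws:
    """Per-chain, per-iteration draws of the model parameters.

    ``draws`` has shape (n_chains, n_saved, n_params) with ``labels`` naming
    the last axis: coefficient labels in design order followed by the
    hyperparameters.  Individual intercepts are kept separately in
    ``alpha_draws`` (n_chains, n_saved, n_persons) when stored.
    """

    draws: np.ndarray
    labels: list[str]
    alpha_draws: np.ndarray | None
    person_ids: list
    config: SamplerConfig
    family: str
    spec_name: str = "model"
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_saved(self) -> int:
        return self.draws.shape[1]

    @property
    def all_labels(self) -> list[str]:
        """Every sampled parameter symbol, including stored intercepts."""
        extra = [f"alpha[{p}]" for p in self.person_ids] if self.alpha_draws is not None else []
        return list(self.labels) + extra

    def param(self, label: str) -> np.ndarray:
        """(n_chains, n_saved) array for one labelled parameter."""
        return self.draws[:, :, self.labels.index(label)]

    def stacked(self) -> np.ndarray:
        """(n_chains * n_saved, n_params) pooled post-burn-in draws."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        long = self.stacked()
        df = pd.DataFrame(long, columns=self.labels)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_saved))
        df.insert(1, "iteration", np.tile(np.arange(self.n_saved), self.n_chains))
        return df

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            draws=self.draws,
            labels=np.array(self.labels),
            alpha_draws=self.alpha_draws if self.alpha_draws is not None else np.empty(0),
            person_ids=np.array([str(p) for p in self.person_ids]),
            family=self.family,
            spec_name=self.spec_name,
        )

    @classmethod
    def load(cls, path, config: SamplerConfig | None = None) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            alpha = z["alpha_draws"]
            return cls(
                draws=z["draws"],
                labels=[str(s) for s in z["labels"]],
                alpha_draws=alpha if alpha.size else None,
                person_ids=[str(s) for s in z["person_ids"]],
                config=config or SamplerConfig(),
                family=str(z["family"]),
                spec_name=str(z["spec_name"]),
            )


# --------------------------------------------------------------------------
# shared machinery


class _ModelLayout:
    """Precomputed quantities shared by both family samplers."""

    def __init__(self, design: DesignMatrices, spec: ModelSpec):
        self.design = design
        self.spec = spec
        self.n = design.n_obs
        self.P = design.n_persons
        self.y = design.y
        self.person = design.person_index
        self.n_i = np.bincount(self.person, minlength=self.P).astype(float)
        W = design.W
        self.ncol = W.shape[1]
        self.w_mean = W.mean(axis=0) if self.ncol else np.empty(0)
        self.Wc = W - self.w_mean
        self.p_x = len(design.x_labels)
        self.q = len(design.z_labels)
        # hierarchical exposure groups: (group index, Z-column offsets into theta)
        self.hier_groups = []
        for gi, pooling in enumerate(design.z_group_pooling):
            if pooling == "hierarchical":
                cols = self.p_x + np.flatnonzero(design.z_group == gi)
                self.hier_groups.append((gi, cols))
        pr = spec.priors
        # fixed prior precision/mean for non-hierarchical coefficients
        self.pinned = np.zeros(self.ncol, dtype=bool)  # beta_var == 0 point mass
        self.base_prec = np.empty(self.ncol)
        self.base_mean = np.full(self.ncol, pr.beta_mean)
        if pr.beta_var == 0:
            self.pinned[: self.p_x] = True
            self.base_prec[: self.p_x] = np.inf
        else:
            self.base_prec[: self.p_x] = 1.0 / pr.beta_var
        for gi, pooling in enumerate(design.z_group_pooling):
            cols = self.p_x + np.flatnonzero(design.z_group == gi)
            if pooling == "independent":
                if pr.beta_var == 0:
                    self.pinned[cols] = True
                    self.base_prec[cols] = np.inf
                else:
                    self.base_prec[cols] = 1.0 / pr.beta_var
            else:
                self.base_prec[cols] = np.nan  # filled per iteration
        self.free = ~self.pinned
        self.WtW = self.Wc[:, self.free].T @ self.Wc[:, self.free] if self.free.any() else None

    def hyper_labels(self) -> list[str]:
        labels = ["mu_alpha"]
        if self.spec.random_intercept:
            labels.append("sigma2_alpha")
        for gi, _ in self.hier_groups:
            name = self.design.z_group_names[gi]
            labels += [f"mu_gamma[{name}]", f"sigma2_gamma[{name}]"]
        if self.spec.family == "gaussian_log" and self.spec.fixed_sigma2 is None:
            labels.append("sigma2")
        return labels


def _init_state(lay: _ModelLayout, cfg: SamplerConfig, rng: np.random.Generator):
    pr = lay.spec.priors
    theta = np.array(lay.base_mean, dtype=float)
    if cfg.init == "prior_scaled":
        # overdispersed but shrunk x0.01 in variance: Normal(0,1000) draws
        # would overflow exp-link models
        sd = np.sqrt(pr.beta_var * 0.01) if pr.beta_var > 0 else 0.0
        if lay.spec.family == "poisson":
            sd = min(sd, 0.1)  # exp-link overflow guard
        theta[lay.free] = pr.beta_mean + sd * rng.standard_normal(int(lay.free.sum()))
        mu_a = float(np.sqrt(pr.hyper_var * 0.01) * rng.standard_normal())
        if lay.spec.family == "poisson":
            mu_a = float(np.log1p(np.mean(lay.y)) + 0.5 * rng.standard_normal())
        s2, s2a = float(np.exp(rng.standard_normal())), float(np.exp(rng.standard_normal()))
        s2g = {gi: float(np.exp(rng.standard_normal())) for gi, _ in lay.hier_groups}
        mu_g = {gi: float(np.sqrt(pr.hyper_var * 0.01) * rng.standard_normal()) for gi, _ in lay.hier_groups}
    else:
        mu_a, s2, s2a = 0.0, 1.0, 1.0
        s2g = {gi: 1.0 for gi, _ in lay.hier_groups}
        mu_g = {gi: 0.0 for gi, _ in lay.hier_groups}
    if lay.spec.fixed_sigma2 is not None:
        s2 = float(lay.spec.fixed_sigma2)
    alpha = mu_a + np.sqrt(max(s2a, 1e-12)) * rng.standard_normal(lay.P) * 0.5
    if not lay.spec.random_intercept:
        alpha = np.full(lay.P, mu_a)
    return theta, alpha, mu_a, s2a, mu_g, s2g, s2


def _conjugate_hyper_updates(lay, rng, alpha, theta, mu_a, s2a, mu_g, s2g):
    """mu_alpha, sigma2_alpha, mu_gamma_k, sigma2_gamma_k full conditionals."""
    pr = lay.spec.priors
    if lay.spec.random_intercept:
        prec = lay.P / s2a + 1.0 / pr.hyper_var
        mean = (alpha.sum() / s2a) / prec
        mu_a = mean + rng.standard_normal() / np.sqrt(prec)
        rate = pr.prec_rate + 0.5 * float(np.sum((alpha - mu_a) ** 2))
        s2a = 1.0 / rng.gamma(pr.prec_shape + 0.5 * lay.P, 1.0 / rate)
    for gi, cols in lay.hier_groups:
        g = theta[cols]
        prec = len(g) / s2g[gi] + 1.0 / pr.hyper_var
        mean = (g.sum() / s2g[gi]) / prec
        mu_g[gi] = mean + rng.standard_normal() / np.sqrt(prec)
        rate = pr.prec_rate + 0.5 * float(np.sum((g - mu_g[gi]) ** 2))
        s2g[gi] = 1.0 / rng.gamma(pr.prec_shape + 0.5 * len(g), 1.0 / rate)
    return mu_a, s2a, mu_g, s2g


# --------------------------------------------------------------------------
# Gaussian family: blocked conjugate Gibbs


def _run_chain_gaussian(lay: _ModelLayout, cfg: SamplerConfig, rng, store_alpha: bool):
    spec, pr = lay.spec, lay.spec.priors
    n, P = lay.n, lay.P
    y, person = lay.y, lay.person
    free = lay.free
    nfree = int(free.sum())
    theta, alpha, mu_a, s2a, mu_g, s2g, s2 = _init_state(lay, cfg, rng)
    a_rows = alpha[person] if spec.random_intercept else np.full(n, mu_a)

    n_saved = cfg.n_postburn // cfg.thin
    hyper_labels = lay.hyper_labels()
    out = np.empty((n_saved, lay.ncol + len(hyper_labels)))
    out_alpha = np.empty((n_saved, P)) if store_alpha else None
    ridge_warned = False
    si = 0

    total = cfg.n_burnin + cfg.n_postburn
    for it in range(total):
        # 1. joint (beta, gamma, interactions) block
        if nfree:
            prior_prec = lay.base_prec.copy()
            prior_mean = lay.base_mean.copy()
            for gi, cols in lay.hier_groups:
                prior_prec[cols] = 1.0 / s2g[gi]
                prior_mean[cols] = mu_g[gi]
            pp, pm = prior_prec[free], prior_mean[free]
            A = lay.WtW / s2 + np.diag(pp)
            part = y - a_rows
            if lay.pinned.any():
                part = part - lay.Wc[:, lay.pinned] @ theta[lay.pinned]
            rhs = lay.Wc[:, free].T @ part / s2 + pp * pm
            try:
                L = sla.cholesky(A, lower=True)
            except sla.LinAlgError:
                if not ridge_warned:
                    logger.warning("singular conditional covariance; ridge-stabilizing")
                    ridge_warned = True
                A = A + np.eye(nfree) * (1e-8 * np.trace(A) / nfree + 1e-12)
                L = sla.cholesky(A, lower=True)
            mean = sla.cho_solve((L, True), rhs)
            z = rng.standard_normal(nfree)
            theta[free] = mean + sla.solve_triangular(L, z, lower=True, trans="T")
        resid = y - lay.Wc @ theta if lay.ncol else y.copy()

        # 2. intercepts
        if spec.random_intercept:
            s_i = np.bincount(person, weights=resid, minlength=P)
            prec_i = lay.n_i / s2 + 1.0 / s2a
            mean_i = (s_i / s2 + mu_a / s2a) / prec_i
            alpha = mean_i + rng.standard_normal(P) / np.sqrt(prec_i)
            a_rows = alpha[person]
        else:
            prec = n / s2 + 1.0 / pr.hyper_var
            mean = (resid.sum() / s2) / prec
            mu_a = mean + rng.standard_normal() / np.sqrt(prec)
            a_rows = np.full(n, mu_a)
            alpha = np.full(P, mu_a)

        # 3./4. hyperparameters
        mu_a, s2a, mu_g, s2g = _conjugate_hyper_updates(
            lay, rng, alpha, theta, mu_a, s2a, mu_g, s2g
        )

        # 5. residual variance
        if spec.fixed_sigma2 is None:
            eps = resid - a_rows
            rate = pr.prec_rate + 0.5 * float(eps @ eps)
            s2 = 1.0 / rng.gamma(pr.prec_shape + 0.5 * n, 1.0 / rate)

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and si < n_saved:
            shift = float(lay.w_mean @ theta) if lay.ncol else 0.0
            hyper = [mu_a - shift]
            if spec.random_intercept:
                hyper.append(s2a)
            for gi, _ in lay.hier_groups:
                hyper += [mu_g[gi], s2g[gi]]
            if spec.fixed_sigma2 is None:
                hyper.append(s2)
            out[si, : lay.ncol] = theta
            out[si, lay.ncol:] = hyper
            if store_alpha:
                out_alpha[si] = alpha - shift
            si += 1
    return out, out_alpha, {}


# --------------------------------------------------------------------------
# Poisson family: random-walk Metropolis within Gibbs


def _run_chain_poisson(lay: _ModelLayout, cfg: SamplerConfig, rng, store_alpha: bool):
    spec, pr = lay.spec, lay.spec.priors
    n, P = lay.n, lay.P
    y, person = lay.y, lay.person
    theta, alpha, mu_a, s2a, mu_g, s2g, _ = _init_state(lay, cfg, rng)
    if not spec.random_intercept:
        alpha = np.full(P, mu_a)
    a_rows = alpha[person]
    eta = a_rows + (lay.Wc @ theta if lay.ncol else 0.0)
    exp_eta = np.exp(np.clip(eta, None, 50.0))

    scales = np.full(lay.ncol, cfg.proposal_scale)
    scale_a = cfg.proposal_scale
    acc_theta = np.zeros(lay.ncol)
    acc_alpha = 0.0
    post_acc_theta = np.zeros(lay.ncol)
    post_acc_alpha = 0.0
    n_saved = cfg.n_postburn // cfg.thin
    hyper_labels = lay.hyper_labels()
    out = np.empty((n_saved, lay.ncol + len(hyper_labels)))
    out_alpha = np.empty((n_saved, P)) if store_alpha else None
    si = 0
    target = 0.44

    def col_prior(j):
        """(mean, var) of coefficient j's conditional prior."""
        for gi, cols in lay.hier_groups:
            if j in cols:
                return mu_g[gi], s2g[gi]
        return pr.beta_mean, pr.beta_var

    total = cfg.n_burnin + cfg.n_postburn
    for it in range(total):
        # coefficients: scalar random-walk Metropolis
        for j in range(lay.ncol):
            if lay.pinned[j]:
                continue
            step = scales[j] * rng.standard_normal()
            d_eta = lay.Wc[:, j] * step
            new_eta = eta + d_eta
            new_exp = np.exp(np.clip(new_eta, None, 50.0))
            dll = float(y @ d_eta - (new_exp.sum() - exp_eta.sum()))
            pm, pv = col_prior(j)
            old, new = theta[j], theta[j] + step
            dlp = -0.5 * ((new - pm) ** 2 - (old - pm) ** 2) / pv
            if np.log(rng.random()) < dll + dlp:
                theta[j] = new
                eta, exp_eta = new_eta, new_exp
                acc_theta[j] += 1
                if it >= cfg.n_burnin:
                    post_acc_theta[j] += 1

        # intercepts: simultaneous per-person Metropolis (independent given theta)
        step_a = scale_a * rng.standard_normal(P)
        d_eta = step_a[person]
        new_eta = eta + d_eta
        new_exp = np.exp(np.clip(new_eta, None, 50.0))
        dll_i = np.bincount(person, weights=y * d_eta - (new_exp - exp_eta), minlength=P)
        if spec.random_intercept:
            dlp_i = -0.5 * ((alpha + step_a - mu_a) ** 2 - (alpha - mu_a) ** 2) / s2a
        else:
            # single global intercept: propose one common step instead
            step_a = np.full(P, scale_a * rng.standard_normal())
            d_eta = step_a[person]
            new_eta = eta + d_eta
            new_exp = np.exp(np.clip(new_eta, None, 50.0))
            dll_i = np.array([float(y @ d_eta - (new_exp.sum() - exp_eta.sum()))])
            dlp_i = np.array(
                [-0.5 * ((mu_a + step_a[0]) ** 2 - mu_a**2) / pr.hyper_var]
            )
        if spec.random_intercept:
            accept = np.log(rng.random(P)) < dll_i + dlp_i
            if accept.any():
                alpha = np.where(accept, alpha + step_a, alpha)
                rows_acc = accept[person]
                eta = np.where(rows_acc, new_eta, eta)
                exp_eta = np.where(rows_acc, new_exp, exp_eta)
            rate_now = float(accept.mean())
        else:
            ok = np.log(rng.random()) < float(dll_i[0] + dlp_i[0])
            if ok:
                mu_a = mu_a + step_a[0]
                alpha = np.full(P, mu_a)
                eta, exp_eta = new_eta, new_exp
            rate_now = float(ok)
        acc_alpha += rate_now
        if it >= cfg.n_burnin:
            post_acc_alpha += rate_now

        # conjugate hyperparameters
        mu_a, s2a, mu_g, s2g = _conjugate_hyper_updates(
            lay, rng, alpha, theta, mu_a, s2a, mu_g, s2g
        )

        # adapt proposal scales during burn-in only (frozen afterwards)
        if it < cfg.n_burnin and (it + 1) % cfg.adapt_interval == 0:
            rates = acc_theta / cfg.adapt_interval
            scales *= np.exp(0.7 * (rates - target))
            scales = np.clip(scales, 1e-5, 50.0)
            acc_theta[:] = 0.0
            scale_a *= float(np.exp(0.7 * (acc_alpha / cfg.adapt_interval - target)))
            scale_a = float(np.clip(scale_a, 1e-5, 50.0))
            acc_alpha = 0.0

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and si < n_saved:
            shift = float(lay.w_mean @ theta) if lay.ncol else 0.0
            hyper = [mu_a - shift]
            if spec.random_intercept:
                hyper.append(s2a)
            for gi, _ in lay.hier_groups:
                hyper += [mu_g[gi], s2g[gi]]
            out[si, : lay.ncol] = theta
            out[si, lay.ncol:] = hyper
            if store_alpha:
                out_alpha[si] = alpha - shift
            si += 1

    meta = {
        "accept_rate_theta": (post_acc_theta / max(cfg.n_postburn, 1)).tolist(),
        "accept_rate_alpha": post_acc_alpha / max(cfg.n_postburn, 1),
        "proposal_scales": scales.tolist(),
    }
    return out, out_alpha, meta


# --------------------------------------------------------------------------


def run_mcmc(design: DesignMatrices, spec: ModelSpec, cfg: SamplerConfig) -> PosteriorDraws:
    """Run the family-appropriate sampler; reproducible given cfg.seed.

    Chains are initialised overdispersed (per cfg.init) from independent
    streams spawned from the seed.  Raises on a divergent (non-finite) state.
    """
    if design.n_obs == 0:
        raise DataError("empty design")
    lay = _ModelLayout(design, spec)
    store_alpha = cfg.save_alpha
    if store_alpha is None:
        store_alpha = True  # needed for WAIC; caller may disable at scale
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(cfg.n_chains)

    chains, alpha_chains, metas = [], [], []
    runner = _run_chain_gaussian if spec.family == "gaussian_log" else _run_chain_poisson
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        out, out_alpha, meta = runner(lay, cfg, rng, store_alpha)
        if not np.all(np.isfinite(out)):
            raise DataError(f"chain {c} reached a non-finite state")
        chains.append(out)
        alpha_chains.append(out_alpha)
        metas.append(meta)

    labels = design.labels + lay.hyper_labels()
    draws = np.stack(chains)
    alpha_draws = np.stack(alpha_chains) if store_alpha else None
    return PosteriorDraws(
        draws=draws,
        labels=labels,
        alpha_draws=alpha_draws,
        person_ids=list(design.person_ids),
        config=cfg,
        family=spec.family,
        spec_name=spec.name,
        meta={"chains": metas, "w_mean": lay.w_mean.tolist(), "seed": cfg.seed},
    )
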