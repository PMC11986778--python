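"""Config-driven study orchestration.

Runs the full workflow — simulate or load a cohort, preprocess (residence
inference, sweep-7 carry-forward, sample filters, collinearity screen), fit
the main hierarchical model, summarize coefficients with convergence
diagnostics, compute WAIC — and the sensitivity battery (Poisson outcome,
alternative hyperpriors, urban-only, complete-LSOA-only, independent
time-varying coefficients, cumulative exposure).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codebook import CovariateCodebook, default_codebook
from .cohort import LongCohort, read_cohort
from .design import build_design
from .diagnostics import summarize_posterior
from .errors import ConfigError, ConvergenceError, DataError
from .modelspec import ModelSpec, PriorSpec, TimeVaryingTerm, default_model_spec
from .preprocess import carry_forward_sweep7, compute_vif, filter_analysis_sample, infer_residence
from .sampler import PosteriorDraws, SamplerConfig, run_mcmc
from .simulate import GeneratorConfig, simulate_study_cohort
from .waic import compute_waic, pointwise_loglik

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "sensitivity_battery", "preprocess_cohort"]

SENSITIVITY_TOGGLES = (
    "poisson_family",
    "alt_hyperpriors",
    "urban_only",
    "complete_lsoa_only",
    "independent_gamma",
    "cumulative_exposure",
)

#: Default alternative-hyperprior settings: half-width changes to the
#: fixed-effect variance and a flatter precision gamma.
DEFAULT_ALT_HYPERPRIORS = (
    {"beta_var": 100.0},
    {"beta_var": 10_000.0},
    {"prec_shape": 0.1, "prec_rate": 0.1},
)


@dataclass
class StudyConfig:
    """One study run: exactly one input source, a model, a sampler, toggles."""

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    model: ModelSpec = field(default_factory=default_model_spec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    sensitivity: dict = field(default_factory=dict)
    outdir: str | None = None
    strict: bool = False
    emit_plots: bool = False
    outcome: str = "sdq"
    rhat_threshold: float = 1.1
    alt_hyperpriors: tuple = DEFAULT_ALT_HYPERPRIORS

    def __post_init__(self):
        if (self.generator is None) == (self.cohort_path is None):
            raise ConfigError("exactly one of generator / cohort_path must be set")
        unknown = set(self.sensitivity) - set(SENSITIVITY_TOGGLES)
        if unknown:
            raise ConfigError(f"unknown sensitivity toggles: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = None
        if raw.get("cohort_path") is None:
            gkw = dict(raw.get("generator") or {})
            if seed is not None:
                gkw["seed"] = seed
            gen = GeneratorConfig(**gkw)
        m = dict(raw.get("model") or {})
        if {"pollutant", "mode", "pooling"} & set(m):
            spec = default_model_spec(
                pollutant=m.get("pollutant", "pm25"),
                mode=m.get("mode", "age_specific"),
                pooling=m.get("pooling", "hierarchical"),
            )
            if m.get("family"):
                spec = spec.with_(family=m["family"])
            if m.get("interactions"):
                spec = spec.with_(interactions=tuple(tuple(p) for p in m["interactions"]))
        elif m:
            if "priors" in m:
                m["priors"] = PriorSpec(**m["priors"])
            if "time_varying" in m:
                m["time_varying"] = tuple(
                    TimeVaryingTerm(**t) if isinstance(t, dict) else TimeVaryingTerm(t)
                    for t in m["time_varying"]
                )
            spec = ModelSpec(**m)
        else:
            spec = default_model_spec()
        skw = dict(raw.get("sampler") or {})
        if seed is not None:
            skw["seed"] = seed
        return cls(
            generator=gen,
            cohort_path=raw.get("cohort_path"),
            model=spec,
            sampler=SamplerConfig(**skw),
            sensitivity=dict(raw.get("sensitivity") or {}),
            outdir=raw.get("outdir"),
            strict=bool(raw.get("strict", False)),
            emit_plots=bool(raw.get("emit_plots", False)),
            outcome=raw.get("outcome", "sdq"),
        )


@dataclass
class StudyReport:
    cohort: LongCohort
    design: object
    draws: PosteriorDraws
    coefficients: pd.DataFrame
    waic: object
    vif: pd.DataFrame
    manifest: dict
    sensitivity: dict = field(default_factory=dict)


def preprocess_cohort(cohort: LongCohort) -> tuple[LongCohort, dict]:
    """The preprocessing chain: residence inference -> sweep-7 carry-forward
    -> analysis-sample filters.  Returns the cohort plus a step log."""
    cohort, n_filled = infer_residence(cohort)
    cohort = carry_forward_sweep7(cohort)
    n_before = cohort.n_persons
    cohort = filter_analysis_sample(cohort)
    steps = {
        "lsoa_cells_inferred": int(n_filled),
        "persons_before_filter": int(n_before),
        "persons_after_filter": int(cohort.n_persons),
    }
    return cohort, steps


def _manifest(config: StudyConfig, design, coef: pd.DataFrame, steps: dict, max_rhat: float) -> dict:
    coef_bytes = coef.to_csv().encode()
    echo = {
        "model": config.model.name,
        "family": config.model.family,
        "seed": config.sampler.seed,
        "n_chains": config.sampler.n_chains,
        "n_burnin": config.sampler.n_burnin,
        "n_postburn": config.sampler.n_postburn,
        "thin": config.sampler.thin,
        "outcome": config.outcome,
        "generator_seed": config.generator.seed if config.generator else None,
        "cohort_path": config.cohort_path,
    }
    return {
        "package_version": __version__,
        "config": echo,
        "preprocess": steps,
        "n_obs": int(design.n_obs),
        "n_persons": int(design.n_persons),
        "max_rhat": float(max_rhat),
        "coefficients_sha256": hashlib.sha256(coef_bytes).hexdigest(),
    }


def _emit_trace_plots(draws: PosteriorDraws, outdir: Path, max_params: int = 16) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for lab in draws.labels[:max_params]:
        fig, ax = plt.subplots(figsize=(6, 2.2))
        for c in range(draws.n_chains):
            ax.plot(draws.param(lab)[c], lw=0.5)
        ax.set_title(lab)
        fig.tight_layout()
        fig.savefig(outdir / f"trace_{lab.replace('/', '_').replace(':', '_')}.png", dpi=80)
        plt.close(fig)


def run_study(config: StudyConfig, codebook: CovariateCodebook | None = None) -> StudyReport:
    """Execute the study end to end; deterministic given the config seeds.

    In strict mode an R-hat above the threshold raises
    :class:`ConvergenceError` after the report is assembled.
    """
    cb = codebook or default_codebook()
    if config.generator is not None:
        cohort, _truth = simulate_study_cohort(config.generator)
    else:
        cohort = read_cohort(config.cohort_path, cb)
    cohort, steps = preprocess_cohort(cohort)

    design = build_design(cohort, config.model, codebook=cb, outcome=config.outcome)
    vif = (
        compute_vif(pd.DataFrame(design.X, columns=design.x_labels))
        if len(design.x_labels) >= 2
        else pd.DataFrame(columns=["vif", "flagged"])
    )
    flagged = vif.index[vif["flagged"]].tolist() if len(vif) else []
    if flagged:
        logger.warning("VIF screen flagged collinear columns: %s", flagged)

    draws = run_mcmc(design, config.model, config.sampler)
    coef = summarize_posterior(draws)
    waic = compute_waic(pointwise_loglik(draws, design, config.model, thin=5))
    max_rhat = float(np.nanmax(coef["rhat"].values)) if len(coef) else float("nan")
    manifest = _manifest(config, design, coef, steps, max_rhat)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        coef.to_csv(outdir / "coefficients.csv")
        vif.to_csv(outdir / "vif.csv")
        pd.DataFrame(
            [{"model": config.model.name, "lppd": waic.lppd, "p_waic": waic.p_waic, "waic": waic.waic}]
        ).to_csv(outdir / "waic.csv", index=False)
        draws.save(outdir / "draws.npz")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if config.emit_plots:
            _emit_trace_plots(draws, outdir)

    sens = {}
    if any(config.sensitivity.get(t) for t in SENSITIVITY_TOGGLES):
        sens = sensitivity_battery(
            cohort,
            config.model,
            config.sampler,
            config.sensitivity,
            codebook=cb,
            outcome=config.outcome,
            base_summary=coef,
            alt_hyperpriors=config.alt_hyperpriors,
        )
        if config.outdir:
            for name, res in sens.items():
                res["comparison"].to_csv(Path(config.outdir) / f"sensitivity_{name}.csv")

    report = StudyReport(
        cohort=cohort,
        design=design,
        draws=draws,
        coefficients=coef,
        waic=waic,
        vif=vif,
        manifest=manifest,
        sensitivity=sens,
    )
    if max_rhat > config.rhat_threshold:
        msg = f"max R-hat {max_rhat:.3f} exceeds {config.rhat_threshold}"
        if config.strict:
            raise ConvergenceError(msg)
        logger.warning("convergence warning: %s", msg)
        report.manifest["convergence_warning"] = msg
    return report


def _side_by_side(base: pd.DataFrame, variant: pd.DataFrame) -> pd.DataFrame:
    return base[["mean", "lower", "upper"]].join(
        variant[["mean", "lower", "upper"]], how="outer", lsuffix="_base", rsuffix="_variant"
    )


def sensitivity_battery(
    cohort: LongCohort,
    base: ModelSpec,
    cfg: SamplerConfig,
    toggles: dict,
    codebook: CovariateCodebook | None = None,
    outcome: str = "sdq",
    base_summary: pd.DataFrame | None = None,
    alt_hyperpriors: tuple = DEFAULT_ALT_HYPERPRIORS,
) -> dict:
    """Fit enabled model/sample variants and compare them to the base fit.

    Each result maps a variant name to ``{"summary": ..., "comparison": ...}``.
    Variants with zero usable rows are skipped with a logged reason.
    """
    cb = codebook or default_codebook()
    variants: list[tuple[str, ModelSpec, LongCohort, str]] = []

    if toggles.get("poisson_family"):
        variants.append(("poisson", base.with_(family="poisson", name=f"{base.name}_poisson"), cohort, "sdq"))
    if toggles.get("alt_hyperpriors"):
        for i, over in enumerate(alt_hyperpriors):
            pri = replace(base.priors, **over)
            tag = "_".join(f"{k}{v:g}" for k, v in over.items())
            variants.append(
                (f"hyperprior_{tag}", base.with_(priors=pri, name=f"{base.name}_prior{i}"), cohort, outcome)
            )
    if toggles.get("urban_only"):
        sub = cohort.df[cohort.df["urban"] == 1]
        if sub.empty:
            logger.warning("sensitivity urban_only skipped: no urban rows")
        else:
            variants.append(
                ("urban_only", base.with_(name=f"{base.name}_urban"), LongCohort(sub.reset_index(drop=True)), outcome)
            )
    if toggles.get("complete_lsoa_only"):
        if "lsoa_inferred" in cohort.df.columns:
            inferred = cohort.df.groupby("person_id")["lsoa_inferred"].any()
            keep = inferred[~inferred].index
            sub = cohort.df[cohort.df["person_id"].isin(keep)]
        else:
            sub = cohort.df
        if sub.empty:
            logger.warning("sensitivity complete_lsoa_only skipped: no complete-record persons")
        else:
            variants.append(
                ("complete_lsoa_only", base.with_(name=f"{base.name}_complete"), LongCohort(sub.reset_index(drop=True)), outcome)
            )
    if toggles.get("independent_gamma"):
        tv = tuple(replace(t, pooling="independent") for t in base.time_varying)
        variants.append(("independent_gamma", base.with_(time_varying=tv, name=f"{base.name}_indep"), cohort, outcome))
    if toggles.get("cumulative_exposure"):
        tv = tuple(replace(t, mode="cumulative") for t in base.time_varying)
        variants.append(("cumulative", base.with_(time_varying=tv, name=f"{base.name}_cum"), cohort, outcome))

    results = {}
    for name, spec, data, outc in variants:
        try:
            design = build_design(data, spec, codebook=cb, outcome=outc)
        except DataError as exc:
            logger.warning("sensitivity %s skipped: %s", name, exc)
            continue
        draws = run_mcmc(design, spec, cfg)
        summary = summarize_posterior(draws)
        comparison = (
            _side_by_side(base_summary, summary) if base_summary is not None else summary
        )
        results[name] = {"summary": summary, "comparison": comparison, "n_obs": design.n_obs}
        logger.info("sensitivity %s: fitted on %d rows", name, design.n_obs)
    return results
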