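"""Design construction and exact log-likelihood / log-prior / log-posterior."""

import math

import numpy as np
import pandas as pd
import pytest

from neighsdq import (
    GeneratorConfig,
    ModelSpec,
    ParameterState,
    TimeVaryingTerm,
    build_design,
    generate_cohort,
    log_likelihood,
    log_posterior,
    log_prior,
    make_cumulative,
)
from neighsdq.errors import SpecError

from conftest import base_row, empty_design, make_cohort_df
from neighsdq.cohort import LongCohort


@pytest.fixture(scope="module")
def cohort150(small_cohort):
    return small_cohort


class TestBuildDesign:
    def test_sweep_to_age_mapping(self, cohort150):
        spec = ModelSpec(time_varying=(TimeVaryingTerm("pm25"),))
        ds = build_design(cohort150, spec)
        keys = dict(zip(ds.row_keys, ds.age_index))
        sweep6 = [a for (p, s), a in keys.items() if s == 6]
        assert set(sweep6) == {14.0}
        assert set(ds.age_index) == {3.0, 5.0, 7.0, 14.0, 17.0}

    def test_age_specific_exposure_expands_to_five_columns(self, cohort150):
        spec = ModelSpec(time_varying=(TimeVaryingTerm("pm25"),))
        ds = build_design(cohort150, spec)
        assert ds.z_labels == [
            "pm25@age3", "pm25@age5", "pm25@age7", "pm25@age14", "pm25@age17",
        ]
        # each column is the raw exposure at its own age, 0 elsewhere
        col3 = ds.Z[:, 0]
        at3 = ds.age_index == 3.0
        assert np.all(col3[~at3] == 0.0)
        assert np.all(col3[at3] > 0.0)

    def test_empty_time_varying_gives_zero_z_columns(self, cohort150):
        ds = build_design(cohort150, ModelSpec())
        assert ds.Z.shape[1] == 0 and ds.z_labels == []

    def test_unknown_covariate_is_spec_error(self, cohort150):
        spec = ModelSpec(fixed_terms=("sex_male", "nonexistent"))
        with pytest.raises(SpecError):
            build_design(cohort150, spec)

    def test_interaction_column_is_dummy_times_exposure(self, cohort150):
        spec = ModelSpec(
            time_varying=(TimeVaryingTerm("ndvi"),),
            interactions=(("sex_male", "ndvi"),),
        )
        ds = build_design(cohort150, spec)
        j = ds.x_labels.index("sex_male:ndvi")
        male = ds.X[:, ds.x_labels.index("sex_male")]
        # NDVI is standardised; reconstruct its value from the Z columns
        ndvi_std = ds.Z.sum(axis=1)
        assert np.allclose(ds.X[:, j], male * ndvi_std)


class TestCumulative:
    def _tiny(self, values):
        rows = []
        for s, v in zip((2, 3, 4, 6, 7), values):
            rows.append(base_row("A", s, pm25=v))
        return LongCohort(make_cohort_df(rows))

    def test_constant_exposure_mean_is_itself(self):
        out = make_cumulative(self._tiny([10, 10, 10, 10, 10]), ["pm25"])
        assert (out.df["cum_pm25"] == 10).all()

    def test_arithmetic_mean(self):
        out = make_cumulative(self._tiny([14, 12, 10, 9, 9]), ["pm25"])
        assert np.allclose(out.df["cum_pm25"], 10.8)

    def test_single_observed_sweep(self):
        rows = [base_row("A", 2, pm25=13.7)]
        out = make_cumulative(LongCohort(make_cohort_df(rows)), ["pm25"])
        assert (out.df["cum_pm25"] == 13.7).all()

    def test_cumulative_design_equals_replicated_time_invariant_column(self, cohort150):
        spec = ModelSpec(time_varying=(TimeVaryingTerm("pm25", mode="cumulative"),))
        ds = build_design(cohort150, spec)
        modeled = cohort150.modeled_rows()
        means = modeled.groupby("person_id")["pm25"].mean()
        expected = np.array([means[p] for (p, s) in ds.row_keys])
        assert np.allclose(ds.Z[:, 0], expected)


class TestLogLikelihood:
    def test_gaussian_zero_residuals(self):
        ds = empty_design([1.5, 1.5, 1.5], [0, 0, 0], ["p"])
        st = ParameterState(alpha=np.array([1.5]), mu_alpha=1.5, sigma2_alpha=1.0, sigma2=1.0)
        assert log_likelihood(st, ds, "gaussian_log") == pytest.approx(
            -1.5 * math.log(2 * math.pi)
        )

    def test_empty_design_is_zero(self):
        ds = empty_design([], [], [])
        st = ParameterState(mu_alpha=0.0, sigma2=1.0)
        assert log_likelihood(st, ds, "gaussian_log") == 0.0

    def test_poisson_single_row(self):
        ds = empty_design([3.0], [0], ["p"])
        st = ParameterState(alpha=np.array([1.0]), mu_alpha=1.0, sigma2_alpha=1.0)
        expected = 3.0 * 1.0 - math.e - math.log(math.factorial(3))
        assert log_likelihood(st, ds, "poisson") == pytest.approx(expected)

    def test_gaussian_maximized_at_mean_squared_residual(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50) + 2.0
        ds = empty_design(y, np.zeros(50, dtype=int), ["p"])
        msr = float(np.mean((y - 1.0) ** 2))

        def ll(s2):
            st = ParameterState(alpha=np.array([1.0]), mu_alpha=1.0, sigma2_alpha=1.0, sigma2=s2)
            return log_likelihood(st, ds, "gaussian_log")

        assert ll(msr) > ll(msr * 1.1)
        assert ll(msr) > ll(msr * 0.9)


class TestLogPrior:
    def _spec(self):
        return ModelSpec(fixed_terms=(), time_varying=(), random_intercept=False)

    def test_single_beta_at_prior_mean(self):
        ds = empty_design([0.0], [0], ["p"])
        st = ParameterState(beta=np.array([0.0]))
        expected = -0.5 * math.log(2 * math.pi * 1000)
        assert log_prior(st, self._spec(), ds) == pytest.approx(expected)

    def test_precision_gamma_density_at_one(self):
        # gamma(shape 1, rate 0.01) at tau = 1: log(0.01) - 0.01
        ds = empty_design([0.0], [0], ["p"])
        spec = ModelSpec(fixed_terms=(), time_varying=())
        st = ParameterState(
            alpha=np.array([]),
            mu_alpha=None,
            sigma2=1.0,
        )
        assert log_prior(st, spec, ds) == pytest.approx(math.log(0.01) - 0.01)

    def test_additivity_of_zero_valued_beta(self):
        ds = empty_design([0.0], [0], ["p"])
        one = log_prior(ParameterState(beta=np.zeros(1)), self._spec(), ds)
        two = log_prior(ParameterState(beta=np.zeros(2)), self._spec(), ds)
        assert two - one == pytest.approx(-0.5 * math.log(2 * math.pi * 1000))


def brute_force_log_posterior(state, design, spec):
    """Independent straight-line re-implementation (loops + math)."""
    pr = spec.priors
    total = 0.0
    n = design.n_obs
    for i in range(n):
        eta = 0.0
        if state.alpha.size:
            eta += state.alpha[design.person_index[i]]
        elif state.mu_alpha is not None:
            eta += state.mu_alpha
        for j in range(design.X.shape[1]):
            eta += design.X[i, j] * state.beta[j]
        for j in range(design.Z.shape[1]):
            eta += design.Z[i, j] * state.gamma[j]
        if spec.family == "gaussian_log":
            total += (
                -0.5 * math.log(2 * math.pi * state.sigma2)
                - (design.y[i] - eta) ** 2 / (2 * state.sigma2)
            )
        else:
            total += design.y[i] * eta - math.exp(eta) - math.lgamma(design.y[i] + 1)

    def norm(x, m, v):
        return -0.5 * math.log(2 * math.pi * v) - (x - m) ** 2 / (2 * v)

    for b in state.beta:
        total += norm(b, pr.beta_mean, pr.beta_var)
    if state.mu_alpha is not None:
        total += norm(state.mu_alpha, 0.0, pr.hyper_var)
    if state.alpha.size:
        for a in state.alpha:
            total += norm(a, state.mu_alpha, state.sigma2_alpha)
        tau = 1.0 / state.sigma2_alpha
        total += math.log(pr.prec_rate) - pr.prec_rate * tau  # shape 1
    for gi, pooling in enumerate(design.z_group_pooling):
        cols = [j for j, g in enumerate(design.z_group) if g == gi]
        if pooling == "hierarchical":
            total += norm(state.mu_gamma[gi], 0.0, pr.hyper_var)
            for j in cols:
                total += norm(state.gamma[j], state.mu_gamma[gi], state.sigma2_gamma[gi])
            tau = 1.0 / state.sigma2_gamma[gi]
            total += math.log(pr.prec_rate) - pr.prec_rate * tau
        else:
            for j in cols:
                total += norm(state.gamma[j], pr.beta_mean, pr.beta_var)
    if spec.family == "gaussian_log" and spec.fixed_sigma2 is None and state.sigma2 is not None:
        tau = 1.0 / state.sigma2
        total += math.log(pr.prec_rate) - pr.prec_rate * tau
    return total


@pytest.fixture(scope="module")
def fixture10():
    cohort, _ = generate_cohort(GeneratorConfig(n_persons=2, seed=99))
    spec = ModelSpec(
        fixed_terms=("sex_male", "poverty_below"),
        time_varying=(TimeVaryingTerm("pm25"), TimeVaryingTerm("ndvi", pooling="independent")),
    )
    ds = build_design(cohort, spec)
    assert ds.n_obs == 10
    rng = np.random.default_rng(7)
    st = ParameterState(
        beta=rng.standard_normal(2) * 0.3,
        gamma=rng.standard_normal(10) * 0.1,
        alpha=rng.standard_normal(2),
        mu_alpha=0.4,
        sigma2_alpha=0.7,
        mu_gamma=np.array([0.05, 0.0]),  # independent-group slots unused
        sigma2_gamma=np.array([0.2, 1.0]),
        sigma2=0.3,
    )
    return st, ds, spec


class TestLogPosterior:

    def test_matches_brute_force_to_1e10(self, fixture10):
        st, ds, spec = fixture10
        ours = log_posterior(st, ds, spec)
        oracle = brute_force_log_posterior(st, ds, spec)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_is_sum_of_likelihood_and_prior(self, fixture10):
        st, ds, spec = fixture10
        assert log_posterior(st, ds, spec) == pytest.approx(
            log_likelihood(st, ds, spec.family) + log_prior(st, spec, ds)
        )

    def test_invariant_under_row_permutation(self, fixture10):
        st, ds, spec = fixture10
        rng = np.random.default_rng(1)
        perm = rng.permutation(ds.n_obs)
        ds2 = empty_design(ds.y[perm], ds.person_index[perm], ds.person_ids)
        ds2.X, ds2.Z = ds.X[perm], ds.Z[perm]
        ds2.x_labels, ds2.z_labels = ds.x_labels, ds.z_labels
        ds2.z_group, ds2.z_group_pooling = ds.z_group, ds.z_group_pooling
        ds2.z_group_names = ds.z_group_names
        assert log_posterior(st, ds2, spec) == pytest.approx(
            log_posterior(st, ds, spec), rel=1e-12
        )
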