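import numpy as np
import pytest
from scipy import stats

import corrbf
from corrbf.data_model import Dataset, VariableSpec
from corrbf.posterior_sampler import (
    ConvergenceWarning,
    CorrelationDraws,
    SamplerError,
    compute_rhat,
    export_traceplot_data,
    pd_interval,
    run_mcmc,
    sample_prior_gibbs,
)
from corrbf.synthetic_data import discretize, exact_corr_values

from .oracles import grid_posterior_moments


class TestPdInterval:
    def test_bivariate_support_is_full_interval(self):
        lo, hi = pd_interval(np.eye(2), 0, 1)
        assert (lo, hi) == pytest.approx((-1.0, 1.0), abs=1e-9)

    @pytest.mark.parametrize("r13,r23", [(0.8, 0.8), (0.5, -0.7), (0.0, 0.9)])
    def test_trivariate_support_matches_closed_form(self, r13, r23):
        R = np.eye(3)
        R[0, 2] = R[2, 0] = r13
        R[1, 2] = R[2, 1] = r23
        lo, hi = pd_interval(R, 0, 1)
        center = r13 * r23
        width = np.sqrt((1 - r13**2) * (1 - r23**2))
        assert lo == pytest.approx(max(center - width, -1.0), abs=1e-8)
        assert hi == pytest.approx(min(center + width, 1.0), abs=1e-8)


class TestPriorOnlyRun:
    def test_bivariate_prior_marginal_uniform(self):
        d = sample_prior_gibbs(2, 50_000, seed=7)
        p = stats.kstest(d[:, 0], stats.uniform(-0.999, 2 * 0.999).cdf).pvalue
        assert p > 0.01

    def test_trivariate_prior_marginals_stretched_beta(self):
        d = sample_prior_gibbs(3, 20_000, seed=8, thin=10)
        for k in range(3):
            p = stats.kstest(d[:, k], lambda x: stats.beta.cdf((x + 1) / 2, 1.5, 1.5)).pvalue
            assert p > 0.01


class TestContinuousPosterior:
    def test_matches_grid_oracle(self, bivariate_dataset, bivariate_draws):
        """Posterior of rho vs direct numerical integration of the likelihood."""
        mean, sd, _, _ = grid_posterior_moments(bivariate_dataset.values)
        pooled = bivariate_draws.pooled()[:, 0]
        assert pooled.mean() == pytest.approx(mean, abs=0.05 * sd + 0.01)
        assert pooled.std() == pytest.approx(sd, rel=0.05)

    def test_posterior_interval_for_bmi_pa(self, bivariate_draws):
        lo, hi = np.quantile(bivariate_draws.pooled()[:, 0], [0.025, 0.975])
        assert lo == pytest.approx(-0.587, abs=0.03)
        assert hi == pytest.approx(-0.076, abs=0.03)

    def test_independent_data_centered_at_zero(self, rng):
        Y = exact_corr_values(400, np.eye(3), seed=31)
        ds = Dataset([VariableSpec(f"v{i}", "continuous") for i in range(3)], Y)
        d = run_mcmc(ds, iterations=2000, chains=1, seed=5)
        assert np.all(np.abs(d.pooled().mean(axis=0)) < 0.05)


class TestMixedScales:
    @pytest.mark.parametrize(
        "scales",
        [("continuous", "ordinal"), ("continuous", "binary"),
         ("ordinal", "binary"), ("ordinal", "ordinal"), ("binary", "binary")],
    )
    def test_latent_recovery_each_pair_type(self, scales):
        """Polyserial/biserial/polychoric/tetrachoric parameter recovery."""
        rho = 0.6
        X = exact_corr_values(500, np.array([[1, rho], [rho, 1]]), seed=hash(scales) % 2**31)
        cols, specs = [], []
        cuts = {"ordinal": (-0.8, -0.2, 0.4, 1.0), "binary": (0.15,)}
        for k, sc in enumerate(scales):
            if sc == "continuous":
                cols.append(X[:, k])
                specs.append(VariableSpec(f"v{k}", "continuous"))
            else:
                codes = discretize(X[:, k], cuts[sc])
                cols.append(codes)
                specs.append(VariableSpec(f"v{k}", sc, tuple(range(1, len(cuts[sc]) + 2))))
        ds = Dataset(specs, np.column_stack(cols))
        d = run_mcmc(ds, iterations=1500, chains=1, seed=9, nugget=0.99)
        assert d.pooled().mean() == pytest.approx(rho, abs=0.1)

    def test_threshold_recovery(self):
        cuts = (-1.0, 0.0, 0.8)
        X = exact_corr_values(2000, np.array([[1, 0.3], [0.3, 1]]), seed=12)
        ds = Dataset(
            [VariableSpec("c", "continuous"), VariableSpec("o", "ordinal", (1, 2, 3, 4))],
            np.column_stack([X[:, 0], discretize(X[:, 1], cuts)]),
        )
        d = run_mcmc(ds, iterations=1200, chains=1, seed=13)
        means = d.threshold_draws.reshape(-1, 3).mean(axis=0)
        assert np.allclose(means, cuts, atol=0.1)
        # strict monotonicity holds draw by draw
        assert np.all(np.diff(d.threshold_draws, axis=2) > 0)

    def test_degenerate_category_error(self):
        vals = np.column_stack([np.random.default_rng(0).normal(size=20), np.ones(20)])
        ds = Dataset.__new__(Dataset)  # bypass Dataset's own validation
        ds.variables = [VariableSpec("c", "continuous"), VariableSpec("b", "binary", (1, 2))]
        ds.values = vals
        ds.group = None
        ds.covariates = None
        ds.covariate_names = []
        with pytest.raises(SamplerError, match="'b'"):
            run_mcmc(ds, iterations=1000, chains=1, seed=1)


class TestUpdateSteps:
    """Contracts of the individual Gibbs updates."""

    @pytest.fixture()
    def mixed_sampler(self):
        from corrbf.posterior_sampler import _GroupSampler

        X = exact_corr_values(60, np.array([[1, 0.4], [0.4, 1]]), seed=50)
        ds = Dataset(
            [VariableSpec("c", "continuous"), VariableSpec("o", "ordinal", (1, 2, 3, 4, 5))],
            np.column_stack([X[:, 0], discretize(X[:, 1], (-1.0, -0.3, 0.3, 1.0))]),
        )
        sampler = _GroupSampler(ds, np.arange(60), grid_size=200, nugget=0.999)
        rng = np.random.default_rng(51)
        return sampler, sampler.init_state(rng), rng, ds

    def test_latent_scores_respect_category_intervals(self, mixed_sampler):
        sampler, state, rng, ds = mixed_sampler
        for _ in range(5):
            sampler.update_latent_scores(state, rng)
            tau = np.concatenate([[-np.inf], state.thresholds[1], [np.inf]])
            codes = ds.values[:, 1].astype(int)
            w = state.W[:, 1]
            assert np.all(w > tau[codes - 1]) and np.all(w <= tau[codes])

    def test_thresholds_stay_ordered_and_separate_categories(self, mixed_sampler):
        sampler, state, rng, ds = mixed_sampler
        for _ in range(5):
            sampler.update_latent_scores(state, rng)
            sampler.update_thresholds(state, rng)
            tau = state.thresholds[1]
            assert len(tau) == 4  # K - 1 cutpoints
            assert np.all(np.diff(tau) > 0)

    def test_correlation_update_stays_in_support(self, mixed_sampler):
        sampler, state, rng, _ = mixed_sampler
        for _ in range(10):
            sampler.update_correlations(state, rng)
            assert abs(state.R[0, 1]) < 0.999
            assert np.linalg.eigvalsh(state.R).min() > 0


class TestDrawsContract:
    def test_nugget_bound_and_shapes(self, bivariate_draws):
        assert bivariate_draws.draws.shape == (2, 6000, 1)
        assert np.all(np.abs(bivariate_draws.pooled()) < 0.999)

    def test_seeded_reproducibility(self, bivariate_dataset):
        a = run_mcmc(bivariate_dataset, iterations=1000, chains=1, seed=42)
        b = run_mcmc(bivariate_dataset, iterations=1000, chains=1, seed=42)
        assert np.array_equal(a.draws, b.draws)

    def test_argument_validation(self, bivariate_dataset):
        with pytest.raises(ValueError):
            run_mcmc(bivariate_dataset, iterations=100)
        with pytest.raises(ValueError):
            run_mcmc(bivariate_dataset, iterations=1000, nugget=0.5)


class TestRhat:
    def _draws(self, arr):
        from corrbf.data_model import ParameterIndex

        params = ParameterIndex(names=("r",), entries=((0, 1, 0),))
        return CorrelationDraws(
            draws=arr, parameters=params, seed=0, nugget=0.999, burnin=0
        )

    def test_identical_distributions_near_one(self, rng):
        base = np.tanh(rng.normal(0, 0.3, size=4000))
        arr = np.stack([base, rng.permutation(base)])[:, :, None]
        vals = compute_rhat(self._draws(arr))
        assert vals["r"] < 1.01

    def test_stuck_chain_warns(self, rng):
        stuck = np.full(2000, -0.98) + rng.normal(0, 1e-4, 2000)
        mixing = np.tanh(rng.normal(0, 0.3, size=2000))
        arr = np.stack([stuck, mixing])[:, :, None]
        with pytest.warns(ConvergenceWarning):
            vals = compute_rhat(self._draws(arr))
        assert vals["r"] > 1.05

    def test_requires_two_chains(self, rng):
        arr = np.tanh(rng.normal(0, 0.3, size=(1, 2000, 1)))
        with pytest.raises(ValueError, match="2 chains"):
            compute_rhat(self._draws(arr))

    def test_healthy_run_converges(self, bivariate_draws):
        assert all(v < 1.05 for v in compute_rhat(bivariate_draws).values())


class TestTraceplotExport:
    def test_series_shape(self, bivariate_draws):
        df = export_traceplot_data(bivariate_draws, "pa_with_bmi")
        assert len(df) == 2 * 6000
        assert set(df["chain"]) == {1, 2}
        assert df["value"].abs().max() < 0.999

    def test_unknown_parameter(self, bivariate_draws):
        with pytest.raises(KeyError):
            export_traceplot_data(bivariate_draws, "nope")
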