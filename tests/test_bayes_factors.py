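import numpy as np
import pytest

import corrbf
from corrbf.bayes_factors import (
    DegenerateHypothesisError,
    TestResult,
    bf_vs_unconstrained,
    evidence_matrix,
    manual_test,
    posterior_hypothesis_probs,
    standard_test,
)
from corrbf.data_model import Dataset, VariableSpec
from corrbf.hypotheses import HypothesisSet, build_complement, parse
from corrbf.synthetic_data import exact_corr_values

from .oracles import grid_bf10


@pytest.fixture(scope="module")
def null_constraint(bivariate_params):
    return parse("pa_with_bmi = 0", bivariate_params)


class TestEvidenceMatrix:
    def test_arithmetic(self):
        mat = evidence_matrix([2.0, 0.5])
        assert np.allclose(mat, [[1, 4], [0.25, 1]])

    def test_transitivity(self):
        bf = np.array([3.1, 0.2, 12.0, 0.7])
        mat = evidence_matrix(bf)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert np.log(mat[i, j]) + np.log(mat[j, k]) == pytest.approx(
                        np.log(mat[i, k]), abs=1e-10
                    )

    def test_single_hypothesis(self):
        assert evidence_matrix([5.0]).tolist() == [[1.0]]


class TestPosteriorProbs:
    def test_two_sided_example(self):
        # BF 4.353 for the alternative with equal priors -> .813 / .187
        p = posterior_hypothesis_probs([1.0, 4.353], [0.5, 0.5])
        assert p == pytest.approx([0.187, 0.813], abs=0.001)

    def test_equal_bfs_uniform(self):
        p = posterior_hypothesis_probs([2.0, 2.0, 2.0], [1 / 3] * 3)
        assert np.allclose(p, 1 / 3)

    def test_prior_weights_move_posterior_not_bf(self, bivariate_prior, bivariate_posterior, null_constraint):
        bf_a = bf_vs_unconstrained(null_constraint, bivariate_prior, bivariate_posterior, seed=1)
        bf_b = bf_vs_unconstrained(null_constraint, bivariate_prior, bivariate_posterior, seed=1)
        assert bf_a == bf_b  # BF has no dependence on weights at all
        pa = posterior_hypothesis_probs([bf_a, 1.0], [0.5, 0.5])
        pb = posterior_hypothesis_probs([bf_a, 1.0], [0.9, 0.1])
        assert not np.allclose(pa, pb)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            posterior_hypothesis_probs([1.0], [0.5, 0.5])


class TestBfVsUnconstrained:
    def test_unconstrained_is_one(self, bivariate_params, bivariate_prior, bivariate_posterior):
        from corrbf.hypotheses import ConstraintSet

        c = ConstraintSet(
            names=bivariate_params.names,
            R_E=np.zeros((0, 1)), r_E=[], R_O=np.zeros((0, 1)), r_O=[],
        )
        assert bf_vs_unconstrained(c, bivariate_prior, bivariate_posterior) == 1.0

    def test_two_sided_bf_matches_paper(self, bivariate_prior, bivariate_posterior, null_constraint):
        """n=44, exact r=-0.38: BF(complement, null) = 4.353."""
        bf_0u = bf_vs_unconstrained(null_constraint, bivariate_prior, bivariate_posterior, seed=1)
        comp = build_complement([null_constraint])
        bf_cu = bf_vs_unconstrained(comp, bivariate_prior, bivariate_posterior, seed=1)
        assert bf_cu == 1.0  # only an equality stated: complement == unconstrained
        assert bf_cu / bf_0u == pytest.approx(4.353, rel=0.10)

    def test_savage_dickey_matches_marginal_likelihood_oracle(self):
        """Toy continuous data, n=12: BF within 10% of grid integration."""
        Y = exact_corr_values(12, np.array([[1, 0.3], [0.3, 1]]), seed=9)
        ds = Dataset([VariableSpec("a", "continuous"), VariableSpec("b", "continuous")], Y)
        draws = corrbf.run_mcmc(ds, iterations=8000, chains=2, seed=10)
        post = corrbf.fit_posterior_normal_approx(draws)
        params = corrbf.name_parameters(ds)
        prior = corrbf.fit_prior_normal_approx(2, params, m=50_000, seed=11)
        bf_0u = bf_vs_unconstrained(parse("b_with_a = 0", params), prior, post, seed=12)
        assert 1.0 / bf_0u == pytest.approx(grid_bf10(Y), rel=0.10)

    def test_exhaustive_orders_leave_no_complement(self, bivariate_params, bivariate_prior, bivariate_posterior):
        neg = parse("pa_with_bmi < 0", bivariate_params)
        pos = parse("pa_with_bmi > 0", bivariate_params)
        comp = build_complement([neg, pos])
        with pytest.raises(DegenerateHypothesisError, match="zero prior mass"):
            bf_vs_unconstrained(comp, bivariate_prior, bivariate_posterior, seed=3)


class TestStandardTest:
    def test_bmi_pa_probabilities_and_bfs(self, bivariate_prior, bivariate_posterior):
        res = standard_test(bivariate_prior, bivariate_posterior)["pa_with_bmi"]
        assert res.posterior_probs == pytest.approx([0.187, 0.808, 0.006], abs=0.03)
        assert res.evidence[1, 0] == pytest.approx(8.653, rel=0.10)
        assert res.evidence[1, 2] == pytest.approx(163.8, rel=0.25)
        assert res.best == 1

    def test_one_sided_decomposition(self, bivariate_prior, bivariate_posterior):
        # prior one-sided masses are exactly 1/2, so BF(-,u) + BF(+,u) = 2
        res = standard_test(bivariate_prior, bivariate_posterior)["pa_with_bmi"]
        assert res.bf_iu[1] + res.bf_iu[2] == pytest.approx(2.0, abs=1e-12)

    def test_transitivity_identity(self, bivariate_prior, bivariate_posterior):
        res = standard_test(bivariate_prior, bivariate_posterior)["pa_with_bmi"]
        lhs = np.log(res.evidence[1, 0]) + np.log(res.evidence[0, 2])
        assert lhs == pytest.approx(np.log(res.evidence[1, 2]), abs=1e-10)

    def test_symmetric_at_zero_correlation(self):
        Y = exact_corr_values(200, np.eye(2), seed=4)
        ds = Dataset([VariableSpec("a", "continuous"), VariableSpec("b", "continuous")], Y)
        draws = corrbf.run_mcmc(ds, iterations=4000, chains=2, seed=6)
        post = corrbf.fit_posterior_normal_approx(draws)
        params = corrbf.name_parameters(ds)
        prior = corrbf.fit_prior_normal_approx(2, params, m=50_000, seed=7)
        res = standard_test(prior, post)["b_with_a"]
        assert res.posterior_probs[1] == pytest.approx(res.posterior_probs[2], abs=0.05)

    def test_weight_validation(self, bivariate_prior, bivariate_posterior):
        with pytest.raises(ValueError):
            standard_test(bivariate_prior, bivariate_posterior, weights=(1, 1))


class TestManualTest:
    def test_result_invariants(self, bivariate_prior, bivariate_posterior, bivariate_params, null_constraint):
        hs = HypothesisSet(
            hypotheses=[("H1", null_constraint), ("H2", build_complement([null_constraint]))],
            prior_weights=[1, 1],
        )
        res = manual_test(hs, bivariate_prior, bivariate_posterior, seed=2)
        assert isinstance(res, TestResult)
        assert res.posterior_probs.sum() == pytest.approx(1.0)
        assert np.allclose(np.diag(res.evidence), 1.0)
        assert res.legend["H2"] == "complement"
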