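"""Likelihood, link and prior computations of the DM regression model."""

import itertools

import numpy as np
import pytest
from scipy.stats import multinomial

import dmreg
from dmreg.model import Z_MAX


def _compositions(total, parts):
    """All non-negative integer vectors of length `parts` summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


class TestDmLogPmf:
    def test_single_category_is_certain(self):
        assert dmreg.dm_log_pmf(np.array([5]), np.array([2.0])) == pytest.approx(0.0)

    def test_uniform_two_outcomes(self):
        lp = dmreg.dm_log_pmf(np.array([1, 0]), np.array([1.0, 1.0]))
        assert lp == pytest.approx(np.log(0.5), abs=1e-12)

    def test_normalizes_over_compositions(self):
        gamma = np.array([0.5, 1.0, 2.0])
        total = sum(
            np.exp(dmreg.dm_log_pmf(np.array(y), gamma))
            for y in _compositions(4, 3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("J,ytot,seed", [(2, 6, 0), (3, 5, 1), (4, 4, 2), (4, 6, 3)])
    def test_normalization_property(self, J, ytot, seed):
        """The pmf sums to one over all compositions for random gamma.

        This pins down the per-taxon numerator Gamma(y_j + gamma_j): the
        variant with Gamma(y_j + gamma_+) does not normalize.
        """
        gamma = np.random.default_rng(seed).uniform(0.2, 3.0, size=J)
        total = sum(
            np.exp(dmreg.dm_log_pmf(np.array(y), gamma))
            for y in _compositions(ytot, J)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dmreg.dm_log_pmf(np.array([1, 1]), np.array([1.0, -0.5]))
        with pytest.raises(ValueError):
            dmreg.dm_log_pmf(np.array([1.5, 1.0]), np.array([1.0, 1.0]))

    def test_overdispersion_variance_factor(self):
        """For J=2 the DM variance is the multinomial variance times
        (y+ + g+)/(1 + g+)."""
        gamma = np.array([1.3, 2.1])
        n_tot = 12
        pis = gamma[0] / gamma.sum()
        probs = np.array(
            [
                np.exp(dmreg.dm_log_pmf(np.array([y1, n_tot - y1]), gamma))
                for y1 in range(n_tot + 1)
            ]
        )
        ys = np.arange(n_tot + 1)
        var_dm = np.sum(probs * ys**2) - np.sum(probs * ys) ** 2
        var_mult = n_tot * pis * (1 - pis)
        factor = (n_tot + gamma.sum()) / (1 + gamma.sum())
        assert var_dm == pytest.approx(var_mult * factor, rel=1e-10)

    def test_multinomial_limit(self):
        """With gamma scaled x1e6 at fixed composition, the DM pmf
        approaches the multinomial pmf."""
        gamma = np.array([0.5, 1.0, 2.0])
        y = np.array([2, 1, 3])
        big = gamma * 1e6
        lp_dm = dmreg.dm_log_pmf(y, big)
        lp_mult = multinomial.logpmf(y, n=y.sum(), p=gamma / gamma.sum())
        assert lp_dm == pytest.approx(lp_mult, abs=1e-3)


class TestComputeGamma:
    def test_zero_state_gives_ones(self):
        X = dmreg.CovariateTable(np.random.default_rng(0).normal(size=(4, 3)),
                                 ["a", "b", "c"])
        state = dmreg.RegressionState(np.zeros(2), np.zeros((3, 2)),
                                      np.zeros((3, 2), dtype=np.uint8))
        assert np.allclose(dmreg.compute_gamma(state, X), 1.0)

    def test_intercept_only(self):
        X = dmreg.CovariateTable(np.zeros((3, 1)), ["a"])
        state = dmreg.RegressionState(np.log([2.0, 3.0]), np.zeros((1, 2)),
                                      np.zeros((1, 2), dtype=np.uint8))
        assert np.allclose(dmreg.compute_gamma(state, X), [[2.0, 3.0]] * 3)

    def test_single_covariate_effect(self):
        X = dmreg.CovariateTable(np.array([[1.0]]), ["a"])
        state = dmreg.RegressionState(
            np.zeros(2), np.array([[0.5, 0.0]]), np.array([[1, 0]], dtype=np.uint8)
        )
        g = dmreg.compute_gamma(state, X)
        assert g[0, 0] == pytest.approx(np.exp(0.5))

    def test_clipping_guards_overflow(self):
        X = dmreg.CovariateTable(np.array([[1000.0]]), ["a"])
        state = dmreg.RegressionState(
            np.zeros(2), np.array([[2.0, 0.0]]), np.array([[1, 0]], dtype=np.uint8)
        )
        g = dmreg.compute_gamma(state, X)
        assert np.isfinite(g).all() and g[0, 0] == pytest.approx(np.exp(Z_MAX))

    def test_dimension_mismatch(self):
        X = dmreg.CovariateTable(np.zeros((3, 2)), ["a", "b"])
        state = dmreg.RegressionState(np.zeros(2), np.zeros((1, 2)),
                                      np.zeros((1, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            dmreg.compute_gamma(state, X)


class TestLogLikelihood:
    def test_single_sample_equals_pmf(self):
        Y = dmreg.TaxaCountTable(np.array([[3, 1, 2]]), ["s0"], ["t0", "t1", "t2"])
        X = dmreg.CovariateTable(np.array([[0.4]]), ["a"])
        state = dmreg.RegressionState(
            np.array([0.1, -0.2, 0.3]),
            np.array([[0.5, 0.0, -0.3]]),
            np.array([[1, 0, 1]], dtype=np.uint8),
        )
        gamma = dmreg.compute_gamma(state, X)[0]
        assert dmreg.log_likelihood(state, Y, X) == pytest.approx(
            dmreg.dm_log_pmf(Y.counts[0], gamma), abs=1e-10
        )

    def test_doubling_rows_doubles_loglik(self, small_dataset):
        Y, X, truth, cfg = small_dataset
        state = dmreg.RegressionState.initial(Y, cfg.P)
        ll1 = dmreg.log_likelihood(state, Y, X)
        Y2 = dmreg.TaxaCountTable(
            np.vstack([Y.counts, Y.counts]),
            Y.sample_ids + [s + "_b" for s in Y.sample_ids],
            Y.taxon_ids,
        )
        X2 = dmreg.CovariateTable(np.vstack([X.values, X.values]), X.covariate_ids)
        assert dmreg.log_likelihood(state, Y2, X2) == pytest.approx(2 * ll1, rel=1e-12)

    def test_incremental_matches_full(self, rng):
        """Single-column delta agrees with full recomputation within 1e-8."""
        n, J, P = 5, 4, 3
        Y = dmreg.TaxaCountTable(
            rng.integers(0, 30, size=(n, J)), [f"s{i}" for i in range(n)],
            [f"t{j}" for j in range(J)],
        )
        X = dmreg.CovariateTable(rng.normal(size=(n, P)), list("abc"))
        beta = np.zeros((P, J))
        xi = np.zeros((P, J), dtype=np.uint8)
        beta[1, 2], xi[1, 2] = 0.7, 1
        state = dmreg.RegressionState(rng.normal(size=J) * 0.5, beta, xi)
        gamma = dmreg.compute_gamma(state, X)
        ll_old = dmreg.log_likelihood(state, Y, X)
        for j in range(J):
            new_state = state.copy()
            new_state.beta[0, j] = 0.4
            new_state.xi[0, j] = 1
            gamma_new = dmreg.compute_gamma(new_state, X)
            delta = dmreg.log_likelihood_delta(
                j, gamma[:, j], gamma_new[:, j], gamma.sum(axis=1), Y
            )
            full = dmreg.log_likelihood(new_state, Y, X) - ll_old
            assert delta == pytest.approx(full, abs=1e-8)


class TestLogPrior:
    def test_empty_model_closed_form(self):
        J, P = 3, 4
        hyp = dmreg.Hyperparameters.from_mean_inclusion(0.01)
        state = dmreg.RegressionState(np.zeros(J), np.zeros((P, J)),
                                      np.zeros((P, J), dtype=np.uint8))
        expected = J * (-0.5 * np.log(2 * np.pi * 10.0)) + P * J * np.log(0.99)
        assert dmreg.log_prior(state, hyp) == pytest.approx(expected, rel=1e-12)

    def test_marginal_inclusion_probability(self):
        hyp = dmreg.Hyperparameters(beta_a=0.02, beta_b=1.98)
        assert hyp.prior_mean_inclusion == pytest.approx(0.01)
        assert dmreg.Hyperparameters.from_mean_inclusion(0.3).prior_mean_inclusion == (
            pytest.approx(0.3)
        )

    def test_coupling_violation_raises(self):
        state = dmreg.RegressionState(np.zeros(2), np.zeros((2, 2)),
                                      np.zeros((2, 2), dtype=np.uint8))
        state.beta[0, 0] = 0.5  # xi still 0: violates the invariant
        with pytest.raises(ValueError):
            dmreg.log_prior(state, dmreg.Hyperparameters())

    def test_posterior_invariant_to_taxon_permutation(self, small_dataset, rng):
        Y, X, truth, cfg = small_dataset
        state = dmreg.RegressionState(
            truth.alpha_true, truth.beta_true, truth.xi_true
        )
        hyp = dmreg.Hyperparameters()
        before = dmreg.log_likelihood(state, Y, X) + dmreg.log_prior(state, hyp)
        perm = rng.permutation(Y.n_taxa)
        Yp = dmreg.TaxaCountTable(Y.counts[:, perm], Y.sample_ids,
                                  [Y.taxon_ids[j] for j in perm])
        state_p = dmreg.RegressionState(
            state.alpha[perm], state.beta[:, perm], state.xi[:, perm]
        )
        after = dmreg.log_likelihood(state_p, Yp, X) + dmreg.log_prior(state_p, hyp)
        assert after == pytest.approx(before, rel=1e-12)
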