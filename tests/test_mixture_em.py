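"""Mixture likelihood, E/M steps and the multi-start EM fit."""

import numpy as np
import pytest
from scipy.stats import norm

from aneuqtl import (
    ConfigurationModel,
    FitConstraints,
    ParentalDuplicationRates,
    PhenotypeSample,
    e_step,
    fit_mixture,
    loglik,
    m_step,
    reference_scenario,
    simulate_sample,
)
from aneuqtl.mixture_em import _EMKernel


@pytest.fixture()
def toy_sample():
    # Six subjects spanning all four genotypes.
    k = np.array([1, 1, 2, 3, 4, 4])
    y = np.array([2.1, 0.3, 1.0, -0.2, -0.9, -1.4])
    return PhenotypeSample(k, y)


@pytest.fixture()
def toy_model():
    means = np.array([[1.7, -0.1], [1.5, -0.5], [1.2, -0.4], [-0.3, -1.3]])
    return ConfigurationModel(means, sigma2=0.8)


class TestLoglik:
    def test_matches_per_subject_brute_force(self, toy_sample, toy_model):
        rates = ParentalDuplicationRates(0.3, 0.4)
        expected = 0.0
        for k, y in zip(toy_sample.genotype_k, toy_sample.y):
            w = 0.3 if k <= 2 else 0.4
            dens = w * norm.pdf(y, toy_model.means[k - 1, 0], np.sqrt(0.8)) + (
                1 - w
            ) * norm.pdf(y, toy_model.means[k - 1, 1], np.sqrt(0.8))
            expected += np.log(dens)
        assert loglik(toy_sample, rates, toy_model) == pytest.approx(expected)

    def test_single_component_collapse(self, toy_sample, toy_model):
        rates = ParentalDuplicationRates(1.0, 1.0)
        expected = sum(
            norm.logpdf(y, toy_model.means[k - 1, 0], np.sqrt(0.8))
            for k, y in zip(toy_sample.genotype_k, toy_sample.y)
        )
        assert loglik(toy_sample, rates, toy_model) == pytest.approx(expected)

    def test_equal_means_make_weights_irrelevant(self, toy_sample):
        means = np.tile(np.array([[1.0], [0.5], [0.0], [-0.5]]), (1, 2))
        model = ConfigurationModel(means, sigma2=1.0)
        lls = {
            loglik(toy_sample, ParentalDuplicationRates(u, v), model)
            for u, v in [(0.1, 0.9), (0.5, 0.5), (0.99, 0.01)]
        }
        assert max(lls) - min(lls) < 1e-12


class TestESstep:
    def test_degenerate_prior(self, toy_sample, toy_model):
        omega = e_step(toy_sample, ParentalDuplicationRates(1.0, 1.0), toy_model)
        assert np.allclose(omega[:, 0], 1.0)

    def test_uninformative_likelihood_returns_prior(self, toy_sample):
        means = np.tile(np.array([[1.0], [0.5], [0.0], [-0.5]]), (1, 2))
        model = ConfigurationModel(means, sigma2=1.0)
        omega = e_step(toy_sample, ParentalDuplicationRates(0.3, 0.4), model)
        expected = np.where(toy_sample.genotype_k <= 2, 0.3, 0.4)
        assert np.allclose(omega[:, 0], expected)

    def test_midpoint_symmetry(self):
        sample = PhenotypeSample(np.array([1]), np.array([0.5]))
        model = ConfigurationModel(
            np.vstack([[1.0, 0.0]] * 4), sigma2=1.0
        )
        omega = e_step(sample, ParentalDuplicationRates(0.5, 0.5), model)
        assert np.allclose(omega, 0.5)

    def test_rows_sum_to_one(self, toy_sample, toy_model):
        omega = e_step(toy_sample, ParentalDuplicationRates(0.3, 0.4), toy_model)
        assert np.allclose(omega.sum(axis=1), 1.0)
        assert np.all((omega >= 0) & (omega <= 1))


class TestMStep:
    def test_hard_assignment_gives_stratum_means(self, toy_sample):
        omega = np.column_stack([np.ones(6), np.zeros(6)])
        rates, model = m_step(toy_sample, omega)
        assert rates.u == 1.0 and rates.v == 1.0
        y, k = toy_sample.y, toy_sample.genotype_k
        for g in range(4):
            assert model.means[g, 0] == pytest.approx(y[k == g + 1].mean())

    def test_symmetric_posterior_ties_components(self, toy_sample):
        omega = np.full((6, 2), 0.5)
        _, model = m_step(toy_sample, omega)
        assert np.allclose(model.means[:, 0], model.means[:, 1])

    def test_matches_hand_weighted_means(self, toy_sample):
        rng = np.random.default_rng(7)
        w1 = rng.uniform(0.1, 0.9, size=6)
        omega = np.column_stack([w1, 1 - w1])
        rates, model = m_step(toy_sample, omega)
        y, k = toy_sample.y, toy_sample.genotype_k
        # Spreadsheet-style oracle.
        u_exp = w1[k <= 2].sum() / (k <= 2).sum()
        v_exp = w1[k > 2].sum() / (k > 2).sum()
        assert rates.u == pytest.approx(u_exp)
        assert rates.v == pytest.approx(v_exp)
        ss = 0.0
        for g in range(4):
            sel = k == g + 1
            for j, wj in enumerate((w1, 1 - w1)):
                mean_exp = (wj[sel] * y[sel]).sum() / wj[sel].sum()
                assert model.means[g, j] == pytest.approx(mean_exp)
                ss += (wj[sel] * (y[sel] - mean_exp) ** 2).sum()
        assert model.sigma2 == pytest.approx(ss / 6)


class TestKernelConsistency:
    def test_one_sweep_matches_public_steps(self, toy_sample, toy_model):
        rates = ParentalDuplicationRates(0.3, 0.4)
        omega = e_step(toy_sample, rates, toy_model)
        rates_ref, model_ref = m_step(toy_sample, omega, old_model=toy_model)
        kernel = _EMKernel(toy_sample, None, 0.0)
        u, v, means, sigma2, trace, _ = kernel.run(
            0.3, 0.4, toy_model.means.copy(), toy_model.sigma2, tol=0.0, max_iter=1
        )
        assert u == pytest.approx(rates_ref.u)
        assert v == pytest.approx(rates_ref.v)
        assert np.allclose(means, model_ref.means)
        assert sigma2 == pytest.approx(model_ref.sigma2)
        assert trace[0] == pytest.approx(loglik(toy_sample, rates, toy_model))


class TestFitMixture:
    def test_loglik_trace_is_monotone(self, small_cohort):
        fit = fit_mixture(small_cohort.sample, seed=3)
        assert np.all(np.diff(fit.trace) > -1e-8)

    def test_reported_loglik_matches_parameters(self, small_cohort):
        fit = fit_mixture(small_cohort.sample, seed=3)
        assert fit.loglik == pytest.approx(
            loglik(small_cohort.sample, fit.rates, fit.config_model)
        )

    def test_well_separated_single_component_recovery(self):
        # u = v = 1 data: each stratum is a single well-separated normal.
        # The within-stratum component split is then a flat direction of the
        # likelihood, so only the mixture-weighted stratum mean (and the
        # residual variance) are identified — those must match the data.
        rng = np.random.default_rng(42)
        k = rng.integers(1, 5, size=2000)
        true_means = np.array([6.0, 2.0, -2.0, -6.0])
        y = true_means[k - 1] + rng.normal(0, 0.5, size=2000)
        fit = fit_mixture(PhenotypeSample(k, y), seed=0)
        w1 = configuration_weight_first(fit)
        weighted = (
            w1 * fit.config_model.means[:, 0]
            + (1 - w1) * fit.config_model.means[:, 1]
        )
        stratum_means = np.array([y[k == g + 1].mean() for g in range(4)])
        assert np.allclose(weighted, stratum_means, atol=0.1)
        # sigma2 can trade off against the (flat) component split, but stays
        # in the neighbourhood of the generating 0.25.
        assert 0.15 < fit.config_model.sigma2 < 0.3

    def test_constrained_fit_never_beats_unconstrained(self, small_cohort):
        alt = fit_mixture(small_cohort.sample, seed=5)
        null = fit_mixture(
            small_cohort.sample,
            constraints=FitConstraints(fixed_effects={"lam": 0.0}),
            seed=5,
        )
        # Slack covers the EM stopping rule (1e-8 relative on |loglik| ~ 1e3).
        assert null.loglik <= alt.loglik + 1e-3
        assert null.effects.lam == pytest.approx(0.0, abs=1e-12)

    def test_null_true_constraint_costs_little(self):
        # Data generated with lam = 0: constraining lam to 0 loses only
        # sampling noise worth of log-likelihood.
        from aneuqtl import simulate_null_sample

        sim = simulate_null_sample(
            reference_scenario(n=1000, h2=0.2, seed=77), null="no_imprinting"
        )
        alt = fit_mixture(sim.sample, seed=6)
        null = fit_mixture(
            sim.sample,
            constraints=FitConstraints(
                fixed_effects={
                    "lam": 0.0, "I_a_lam": 0.0, "I_d_lam": 0.0, "I_dprime_lam": 0.0
                }
            ),
            seed=6,
        )
        assert alt.loglik - null.loglik < 15.0

    def test_flat_direction_when_components_tied(self, small_cohort):
        # With all means tied across configurations, (u, v) cannot move the
        # likelihood.
        sample = small_cohort.sample
        constraints = FitConstraints(
            fixed_effects={
                "lam": 0.0, "I_a_lam": 0.0, "I_d_lam": 0.0, "I_dprime_lam": 0.0
            }
        )
        fit = fit_mixture(sample, constraints=constraints, seed=1)
        for u, v in [(0.2, 0.8), (0.7, 0.3)]:
            ll = loglik(sample, ParentalDuplicationRates(u, v), fit.config_model)
            assert ll == pytest.approx(fit.loglik, abs=1e-8)

    def test_fixed_rate_constraint_is_respected(self, small_cohort):
        fit = fit_mixture(
            small_cohort.sample, constraints=FitConstraints(fixed_u=1.0), seed=2
        )
        assert fit.rates.u == 1.0

    def test_constant_phenotypes_rejected(self):
        sample = PhenotypeSample(np.array([1, 2, 3, 4]), np.zeros(4))
        with pytest.raises(ValueError):
            fit_mixture(sample, seed=0)


def configuration_weight_first(fit):
    """Dominant-component weight per genotype row (u, u, v, v)."""
    return np.array([fit.rates.u, fit.rates.u, fit.rates.v, fit.rates.v])
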