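"""Random histogram prior: conjugacy, marginals, projections, consistency."""

import math
import warnings

import numpy as np
import pytest

from hellbayes.disparity import hellinger_distance, make_grid
from hellbayes.families import Normal1D
from hellbayes.histprior import (DataMap, HistogramSpec, KPrior, bin_counts,
                                 expected_posterior_density,
                                 fit_histogram_posterior, kn_rate,
                                 log_marginal_k, posterior_update,
                                 practical_k, project_density,
                                 sample_posterior_density)


class TestBinCounts:
    def test_basic_binning(self):
        np.testing.assert_array_equal(
            bin_counts([0.1, 0.2, 0.7], 2), [2, 1])

    def test_right_edge_in_last_bin(self):
        np.testing.assert_array_equal(bin_counts([1.0], 4), [0, 0, 0, 1])

    def test_empty_data(self):
        np.testing.assert_array_equal(bin_counts([], 3), [0, 0, 0])

    def test_out_of_range_identified(self):
        with pytest.raises(ValueError, match="1.5"):
            bin_counts([0.2, 1.5], 2)


class TestConjugateUpdate:
    def test_posterior_parameters(self):
        spec = HistogramSpec(2, [1.0, 1.0])
        np.testing.assert_array_equal(posterior_update(spec, [2, 1]), [3, 2])

    def test_no_data_returns_prior(self):
        spec = HistogramSpec(3, [2.0, 1.0, 0.5])
        np.testing.assert_array_equal(posterior_update(spec, [0, 0, 0]),
                                      spec.alpha)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            posterior_update(HistogramSpec(2, [1, 1]), [-1, 2])

    def test_posterior_mean_weights(self):
        spec = HistogramSpec(2, [1.0, 1.0])
        a = posterior_update(spec, [2, 1])
        np.testing.assert_allclose(a / a.sum(), [0.6, 0.4])


class TestLogMarginal:
    def test_one_bin_is_uniform_likelihood(self):
        spec = HistogramSpec(1, [2.0])
        assert log_marginal_k(spec, [7], 7) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_single_point(self):
        spec = HistogramSpec(2, [1.0, 1.0])
        assert log_marginal_k(spec, [1, 0], 1) == pytest.approx(0.0,
                                                               abs=1e-12)

    def test_monte_carlo_prior_predictive_oracle(self):
        """Brute-force prior-predictive sampling matches the closed form."""
        rng = np.random.default_rng(42)
        data = np.array([0.05, 0.3, 0.31, 0.62, 0.9])
        k, alpha = 4, np.array([0.8, 1.0, 1.2, 1.0])
        spec = HistogramSpec(k, alpha)
        counts = bin_counts(data, k)
        exact = math.exp(log_marginal_k(spec, counts, 5))
        omegas = rng.dirichlet(alpha, size=100_000)
        idx = np.minimum((data * k).astype(int), k - 1)
        lik = (k ** 5) * np.prod(omegas[:, idx], axis=1)
        mc, se = lik.mean(), lik.std(ddof=1) / math.sqrt(len(lik))
        assert abs(mc - exact) < 3 * se


class TestFitPosterior:
    def test_dirac_composition(self):
        post = fit_histogram_posterior(
            np.array([0.1, 0.2, 0.7]), KPrior.dirac(2), data_map=DataMap())
        assert len(post.records) == 1
        np.testing.assert_array_equal(post.records[0]["alpha_post"], [3, 2])
        np.testing.assert_allclose(post.k_weights, [1.0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_histogram_posterior(np.array([]), KPrior.dirac(2))

    def test_k_mixture_weights_match_hand_computation(self):
        data = np.array([0.1, 0.2, 0.7])
        kp = KPrior.pmf([1, 2], [0.4, 0.6])
        post = fit_histogram_posterior(data, kp, data_map=DataMap())
        m1 = math.exp(log_marginal_k(HistogramSpec(1, [1.0]), [3], 3))
        m2 = math.exp(log_marginal_k(HistogramSpec(2, [1.0, 1.0]), [2, 1], 3))
        expect = np.array([0.4 * m1, 0.6 * m2])
        expect /= expect.sum()
        np.testing.assert_allclose(post.k_weights, expect, rtol=1e-12)


class TestExpectedDensity:
    def test_closed_form_heights(self):
        post = fit_histogram_posterior(
            np.array([0.1, 0.2, 0.7]), KPrior.dirac(2), data_map=DataMap())
        g = expected_posterior_density(post)
        np.testing.assert_allclose(g(np.array([0.25, 0.75])), [1.2, 0.8],
                                   rtol=1e-14)

    def test_integrates_to_one_exactly(self):
        rng = np.random.default_rng(0)
        post = fit_histogram_posterior(rng.normal(size=40), KPrior.dirac(7))
        g = expected_posterior_density(post)
        edges = g.bin_edges_original()
        widths = np.diff(edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        assert float(g(mids) @ widths) == pytest.approx(1.0, abs=1e-12)

    def test_l1_consistency_trend(self):
        """g*_n approaches the truth as n grows (fixed smooth truth)."""
        fam = Normal1D()
        rng = np.random.default_rng(7)
        errs = []
        for n in (100, 1000, 10000):
            data = rng.normal(0.0, 1.0, size=n)
            post = fit_histogram_posterior(data,
                                           KPrior.dirac(practical_k(n)))
            g = expected_posterior_density(post)
            edges = g.bin_edges_original()
            grid = make_grid((edges[0], edges[-1]), breakpoints=edges,
                             order=6)
            truth = fam.pdf((0.0, 1.0), grid.nodes)
            errs.append(grid.integrate(np.abs(g(grid.nodes) - truth)))
        assert errs[0] > errs[1] > errs[2]


class TestSampleDensities:
    def test_draw_weights_on_simplex(self):
        rng = np.random.default_rng(3)
        post = fit_histogram_posterior(rng.normal(size=25), KPrior.dirac(5))
        draws = sample_posterior_density(post, 50, seed=11)
        for d in draws:
            assert d.omega.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(d.omega >= 0)

    def test_draw_mean_matches_dirichlet_mean(self):
        post = fit_histogram_posterior(
            np.array([0.1, 0.2, 0.7]), KPrior.dirac(2), data_map=DataMap())
        draws = sample_posterior_density(post, 10_000, seed=5)
        w1 = np.array([d.omega[0] for d in draws])
        se = w1.std(ddof=1) / math.sqrt(len(w1))
        assert abs(w1.mean() - 0.6) < 3 * se

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        post = fit_histogram_posterior(rng.normal(size=25), KPrior.dirac(5))
        d1 = sample_posterior_density(post, 10, seed=123)
        d2 = sample_posterior_density(post, 10, seed=123)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.omega, b.omega)

    def test_nonpositive_draws_rejected(self):
        rng = np.random.default_rng(3)
        post = fit_histogram_posterior(rng.normal(size=25), KPrior.dirac(5))
        with pytest.raises(ValueError):
            sample_posterior_density(post, 0)


class TestProjection:
    def test_uniform_is_fixed_point(self):
        f = lambda x: np.ones_like(x)
        for k in (1, 3, 5):
            proj = project_density(f, k)
            np.testing.assert_allclose(proj(np.linspace(0.05, 0.95, 9)),
                                       1.0, rtol=1e-9)

    def test_linear_density_two_bins(self):
        f = lambda x: 2.0 * x
        proj = project_density(f, 2)
        np.testing.assert_allclose(proj.omega, [0.25, 0.75], rtol=1e-9)
        np.testing.assert_allclose(proj(np.array([0.2, 0.8])), [0.5, 1.5],
                                   rtol=1e-9)

    def test_l2_error_decreases_in_k(self):
        f = lambda x: 2.0 * x
        errs = []
        for k in (1, 2, 4, 8):
            proj = project_density(f, k)
            grid = make_grid((0.0, 1.0),
                             breakpoints=np.linspace(0, 1, k + 1), order=6)
            diff = f(grid.nodes) - proj(grid.nodes)
            errs.append(grid.integrate(diff * diff))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestKPriors:
    def test_kn_rate_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert kn_rate(500) == 1

    def test_poisson_prior_tail_envelope(self):
        """The Poisson-type default obeys the sub-exponential bracket
        e^(-b1 k log k) <= p_k(k) <= e^(-b2 k log k) up to normalization."""
        kp = KPrior.poisson(10.0, 100_000)
        ks = kp.support.astype(float)
        logp = np.log(kp.probs)
        big = ks >= 30
        t = ks[big] * np.log(ks[big])
        ratio = -logp[big] / t
        assert np.all(ratio > 0.05) and np.all(ratio < 20.0)

    def test_pmf_must_normalise(self):
        with pytest.raises(ValueError):
            KPrior.pmf([1, 2], [0.5, 0.4])
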