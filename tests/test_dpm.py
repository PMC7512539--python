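"""DP normal-mixture Gibbs sampler and its density draws."""

import math
from math import lgamma

import numpy as np
import pytest
from scipy.integrate import quad

from hellbayes.disparity import make_grid
from hellbayes.dpm import (DPMDensityDraw, DPMHyper, DPMState,
                           _AverageDensity, default_hyper, density_draw,
                           dpm_gibbs, eap_density, update_concentration)


@pytest.fixture(scope="module")
def tight_chain():
    x = np.random.default_rng(0).normal(0.0, 0.1, size=50)
    hyper = default_hyper(x)
    return x, hyper, dpm_gibbs(x, hyper, n_iter=400, burnin=100, thin=3,
                               seed=1)


class TestGibbs:
    def test_single_tight_cluster(self, tight_chain):
        _, _, chain = tight_chain
        occ = [s.cluster_sizes.size for s in chain]
        assert np.bincount(occ).argmax() == 1

    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(20, 1, 50)])
        truth = np.array([0] * 50 + [1] * 50)
        chain = dpm_gibbs(x, default_hyper(x), n_iter=400, burnin=100,
                          thin=3, seed=2)
        purity = []
        for s in chain:
            agree = 0
            for c in np.unique(s.assignments):
                sub = truth[s.assignments == c]
                agree += max((sub == 0).sum(), (sub == 1).sum())
            purity.append(agree / 100)
        assert np.mean(purity) > 0.95

    def test_seed_determinism(self):
        x = np.random.default_rng(5).normal(size=(40, 2))
        hyper = default_hyper(x)
        c1 = dpm_gibbs(x, hyper, n_iter=150, burnin=50, thin=2, seed=9)
        c2 = dpm_gibbs(x, hyper, n_iter=150, burnin=50, thin=2, seed=9)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.assignments, b.assignments)
            np.testing.assert_array_equal(a.cluster_means, b.cluster_means)

    def test_input_validation(self):
        hyper = DPMHyper(dim=1, m2=[0.0], s2=[[1000.0]], psi1=[[1.0]])
        with pytest.raises(ValueError):
            dpm_gibbs(np.array([1.0]), hyper)
        with pytest.raises(ValueError):
            dpm_gibbs(np.array([1.0, 2.0]), hyper, n_iter=10, burnin=10)

    def test_exchangeability_of_cluster_counts(self):
        """Permuting the rows leaves occupied-cluster behaviour unchanged."""
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(8, 1, 30)])
        means = []
        for perm_seed in (1, 2):
            xp = np.random.default_rng(perm_seed).permutation(x)
            chain = dpm_gibbs(xp, default_hyper(xp), n_iter=500, burnin=200,
                              thin=3, seed=7)
            means.append(np.mean([s.cluster_sizes.size for s in chain]))
        assert abs(means[0] - means[1]) < 0.75


class TestConcentrationUpdate:
    def test_stationary_law_matches_quadrature_oracle(self):
        """The auxiliary-variable update's stationary distribution is
        pi(alpha | C, n) propto alpha^(a0+C-1) e^(-b0 alpha)
        Gamma(alpha)/Gamma(alpha+n)."""
        C, n, a0, b0 = 3, 50, 1.0, 1.0

        def dens(a):
            return np.exp((a0 + C - 1) * np.log(a) - b0 * a + lgamma(a)
                          - lgamma(a + n))

        target = quad(lambda a: a * dens(a), 0, 60)[0] / \
            quad(dens, 0, 60)[0]
        rng = np.random.default_rng(1)
        a, draws = 1.0, []
        for _ in range(8000):
            a = update_concentration(rng, a, C, n, a0, b0)
            draws.append(a)
        draws = np.array(draws[500:])
        batch = draws[:7500].reshape(25, -1).mean(axis=1)
        se = batch.std(ddof=1) / math.sqrt(len(batch))
        assert abs(draws.mean() - target) < 3 * se


class TestDensityDraws:
    def test_weights_sum_to_one_and_mass(self, tight_chain):
        _, hyper, chain = tight_chain
        d = density_draw(chain[-1], hyper)
        assert d.weights.sum() == pytest.approx(1.0, abs=1e-12)
        # window scaled to the draw's own widest component
        sd = math.sqrt(max(c[0, 0] for c in d.covs))
        m = float(d.means[:-1].mean())
        grid = make_grid((m - 10 * sd, m + 10 * sd), order=10, n_panels=24)
        assert grid.integrate(d(grid.nodes)) > 0.999

    def test_vanishing_concentration_reduces_to_single_normal(self):
        """alpha -> 0+ with one cluster: the draw is that cluster's normal."""
        state = DPMState(
            assignments=np.zeros(50, dtype=int),
            cluster_sizes=np.array([50]),
            cluster_means=np.array([[1.0]]),
            cluster_covs=np.array([[[0.25]]]),
            m1=np.array([0.0]), k0=1.0, psi1=np.array([[1.0]]),
            alpha=1e-8, iteration=0)
        hyper = DPMHyper(dim=1, m2=[0.0], s2=[[1000.0]], psi1=[[1.0]])
        d = density_draw(state, hyper)
        grid = make_grid((-5, 7), order=10, n_panels=16)
        ref = np.exp(-0.5 * ((grid.nodes - 1.0) / 0.5) ** 2) / (
            0.5 * math.sqrt(2 * math.pi))
        assert grid.integrate(np.abs(d(grid.nodes) - ref)) < 0.05

    def test_eap_of_identical_states(self, tight_chain):
        _, hyper, chain = tight_chain
        single = density_draw(chain[0], hyper)
        avg = eap_density([chain[0], chain[0], chain[0]], hyper)
        x = np.linspace(-1, 1, 50)
        np.testing.assert_allclose(avg(x), single(x), rtol=1e-12)

    def test_eap_integrates_to_one(self, tight_chain):
        # window/panels must resolve both the tight cluster and the diffuse
        # base-predictive component some states carry (k0 can be tiny)
        _, hyper, chain = tight_chain
        g = eap_density(chain, hyper)
        grid = make_grid((-400, 400), order=10,
                         breakpoints=np.linspace(-2, 2, 81), n_panels=80)
        assert grid.integrate(g(grid.nodes)) == pytest.approx(1.0, abs=1e-3)

    def test_empty_chain_rejected(self, tight_chain):
        _, hyper, _ = tight_chain
        with pytest.raises(ValueError):
            eap_density([], hyper)

    def test_density_estimation_accuracy(self):
        """EAP density close to a smooth truth in L1 (n=200 from N(3, 4))."""
        x = np.random.default_rng(12).normal(3, 2.0, size=200)
        hyper = default_hyper(x)
        chain = dpm_gibbs(x, hyper, n_iter=3000, burnin=1000, thin=10,
                          seed=3)
        g = eap_density(chain, hyper)
        grid = make_grid((-15, 21), order=8, n_panels=24)
        truth = np.exp(-0.5 * ((grid.nodes - 3) / 2) ** 2) / (
            2 * math.sqrt(2 * math.pi))
        assert grid.integrate(np.abs(g(grid.nodes) - truth)) < 0.1


def test_univariate_matches_degenerate_bivariate():
    """With a near-constant second coordinate, the first-coordinate marginal
    of the 2-D fit agrees with the plain 1-D fit."""
    rng = np.random.default_rng(21)
    x = rng.normal(0, 1, 100)
    x2 = np.column_stack([x, rng.normal(0, 0.05, 100)])
    h1, h2 = default_hyper(x), default_hyper(x2)
    c1 = dpm_gibbs(x, h1, n_iter=600, burnin=200, thin=4, seed=5)
    c2 = dpm_gibbs(x2, h2, n_iter=600, burnin=200, thin=4, seed=5)
    g1 = eap_density(c1, h1)
    marg = _AverageDensity([
        DPMDensityDraw(weights=d.weights, means=d.means[:, :1],
                       covs=d.covs[:, :1, :1], base_df=d.base_df, dim=1)
        for d in (density_draw(s, h2) for s in c2)])
    grid = make_grid((-6, 6), order=8, n_panels=16)
    assert grid.integrate(np.abs(g1(grid.nodes) - marg(grid.nodes))) < 0.2
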