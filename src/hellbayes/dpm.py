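"""Dirichlet-process mixture of normals with a conjugate NIW base.

Model (1-D or 2-D observations)::

    y_i | mu_i, Sigma_i ~ N(mu_i, Sigma_i)
    (mu_i, Sigma_i) | G ~ G,   G | alpha, G0 ~ DP(alpha G0)
    G0 = N(mu | m1, Sigma / k0) IW(Sigma | nu1, psi1)

with independent hyperpriors m1 ~ N(m2, S2) and k0 ~ Gamma(tau1/2, tau2/2).
The DP concentration alpha is fixed (default 1) with an optional
auxiliary-variable update, and the base scale psi1 is fixed by default
(typically at the empirical covariance of the data) with an optional
conjugate Wishart update.

Inference is collapsed Gibbs over cluster assignments (cluster parameters
marginalised, predictive probabilities are multivariate-t), followed each
sweep by an explicit (mu_c, Sigma_c) refresh from the normal-inverse-Wishart
full conditionals, which feeds the m1 / k0 updates.

A retained state is converted to a density draw as the conditional mixture

    sum_c n_c/(n+alpha) N(. | mu_c, Sigma_c) + alpha/(n+alpha) t_base(.)

where ``t_base`` is the heavy-tailed Student-t predictive induced by the NIW
base; this finite mixture is the surrogate for a draw from the posterior over
densities that the BMH pushforward consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma, log, pi, sqrt
from typing import Sequence

import numpy as np

__all__ = ["DPMHyper", "DPMState", "DPMDensityDraw", "dpm_gibbs",
           "density_draw", "eap_density", "default_hyper"]


@dataclass
class DPMHyper:
    """Hyperparameters and hyperprior settings for the DPM sampler."""

    dim: int
    m2: np.ndarray          # prior mean for m1
    s2: np.ndarray          # prior covariance for m1
    tau1: float = 1.0       # k0 ~ Gamma(tau1/2, rate=tau2/2)
    tau2: float = 100.0
    nu1: float | None = None  # base IW df; default dim + 2
    nu2: float = 2.0        # psi1 hyperprior df (optional update)
    psi2: np.ndarray | None = None
    psi1: np.ndarray | None = None  # fixed base scale; default empirical cov
    alpha: float = 1.0      # DP concentration (fixed unless update_alpha)
    a0: float = 1.0
    b0: float = 1.0
    update_alpha: bool = False
    update_psi1: bool = False

    def __post_init__(self):
        d = self.dim
        self.m2 = np.asarray(self.m2, dtype=float).reshape(d)
        self.s2 = np.atleast_2d(np.asarray(self.s2, dtype=float))
        if self.nu1 is None:
            self.nu1 = d + 2.0
        if self.nu1 <= d - 1:
            raise ValueError("nu1 must exceed dim - 1")
        if self.psi2 is None:
            self.psi2 = np.eye(d)
        else:
            self.psi2 = np.atleast_2d(np.asarray(self.psi2, dtype=float))
        for name in ("tau1", "tau2", "nu2", "alpha", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_hyper(data, dim: int | None = None, **overrides) -> DPMHyper:
    """Demo defaults: m2 = 0, S2 = diag(1000), tau = (1, 100), nu2 = 2,
    psi2 = I, psi1 = empirical covariance of the data, alpha = 1 fixed."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d = dim or x.shape[1]
    emp = np.atleast_2d(np.cov(x.T, ddof=1)) + 1e-12 * np.eye(d)
    kw = dict(dim=d, m2=np.zeros(d), s2=1000.0 * np.eye(d), psi1=emp)
    kw.update(overrides)
    return DPMHyper(**kw)


@dataclass
class DPMState:
    """One retained Gibbs state."""

    assignments: np.ndarray
    cluster_sizes: np.ndarray
    cluster_means: np.ndarray   # (C, d)
    cluster_covs: np.ndarray    # (C, d, d)
    m1: np.ndarray
    k0: float
    psi1: np.ndarray
    alpha: float
    iteration: int


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _rwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Wishart draw via the Bartlett decomposition."""
    d = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.normal()
    LA = L @ A
    return LA @ LA.T


def _rinvwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw: inverse of a Wishart(df, scale^-1) draw."""
    return np.linalg.inv(_rwishart(rng, df, np.linalg.inv(scale)))


def _mvt_logconst(v: float, d: int) -> float:
    return lgamma((v + d) / 2.0) - lgamma(v / 2.0) - 0.5 * d * log(v * pi)


class _Suff:
    """Per-cluster sufficient statistics, kept as scalars for speed.

    1-D: (n, sx, sxx); 2-D additionally (sy, sxy, syy).
    """

    __slots__ = ("n", "sx", "sy", "sxx", "sxy", "syy")

    def __init__(self):
        self.n = 0
        self.sx = self.sy = 0.0
        self.sxx = self.sxy = self.syy = 0.0

    def add1(self, x):
        self.n += 1
        self.sx += x
        self.sxx += x * x

    def remove1(self, x):
        self.n -= 1
        self.sx -= x
        self.sxx -= x * x

    def add2(self, x, y):
        self.n += 1
        self.sx += x
        self.sy += y
        self.sxx += x * x
        self.sxy += x * y
        self.syy += y * y

    def remove2(self, x, y):
        self.n -= 1
        self.sx -= x
        self.sy -= y
        self.sxx -= x * x
        self.sxy -= x * y
        self.syy -= y * y

    def mean_vec(self, d):
        if self.n == 0:
            return np.zeros(d)
        if d == 1:
            return np.array([self.sx / self.n])
        return np.array([self.sx / self.n, self.sy / self.n])


def _niw_posterior(stats: _Suff | None, m1, k0, nu1, psi1, d):
    """(kappa, m, nu, Psi) of the NIW posterior given cluster members.

    ``m1`` is a length-d array; ``psi1`` a (d, d) array.  Returns arrays.
    """
    if stats is None or stats.n == 0:
        return k0, m1, nu1, psi1
    n = stats.n
    kappa = k0 + n
    nu = nu1 + n
    if d == 1:
        xbar = stats.sx / n
        m = np.array([(k0 * m1[0] + stats.sx) / kappa])
        scatter = stats.sxx - n * xbar * xbar
        dev = xbar - m1[0]
        psi = np.array([[psi1[0, 0] + scatter
                         + (k0 * n / kappa) * dev * dev]])
        return kappa, m, nu, psi
    xbar = stats.sx / n
    ybar = stats.sy / n
    m = np.array([(k0 * m1[0] + stats.sx) / kappa,
                  (k0 * m1[1] + stats.sy) / kappa])
    sxx = stats.sxx - n * xbar * xbar
    sxy = stats.sxy - n * xbar * ybar
    syy = stats.syy - n * ybar * ybar
    dx = xbar - m1[0]
    dy = ybar - m1[1]
    w = k0 * n / kappa
    psi = np.array([
        [psi1[0, 0] + sxx + w * dx * dx, psi1[0, 1] + sxy + w * dx * dy],
        [psi1[0, 1] + sxy + w * dx * dy, psi1[1, 1] + syy + w * dy * dy]])
    return kappa, m, nu, psi


def _log_predictive_1d(x, stats, m10, k0, nu1, p11):
    """Scalar-arithmetic Student-t predictive (1-D)."""
    if stats is None or stats.n == 0:
        kappa, m, nu, psi = k0, m10, nu1, p11
    else:
        n = stats.n
        kappa = k0 + n
        nu = nu1 + n
        m = (k0 * m10 + stats.sx) / kappa
        xbar = stats.sx / n
        dev = xbar - m10
        psi = p11 + (stats.sxx - n * xbar * xbar) \
            + (k0 * n / kappa) * dev * dev
    v = nu  # nu - d + 1 with d = 1
    s = psi * (kappa + 1.0) / (kappa * v)
    dx = x - m
    return (_mvt_logconst(v, 1) - 0.5 * log(s)
            - 0.5 * (v + 1.0) * log(1.0 + dx * dx / (s * v)))


def _log_predictive_2d(x, y, stats, m10, m11, k0, nu1, p11, p12, p22):
    """Scalar-arithmetic Student-t predictive (2-D)."""
    if stats is None or stats.n == 0:
        kappa, nu = k0, nu1
        mx, my = m10, m11
        a, b, c = p11, p12, p22
    else:
        n = stats.n
        kappa = k0 + n
        nu = nu1 + n
        mx = (k0 * m10 + stats.sx) / kappa
        my = (k0 * m11 + stats.sy) / kappa
        xbar = stats.sx / n
        ybar = stats.sy / n
        dx = xbar - m10
        dy = ybar - m11
        w = k0 * n / kappa
        a = p11 + (stats.sxx - n * xbar * xbar) + w * dx * dx
        b = p12 + (stats.sxy - n * xbar * ybar) + w * dx * dy
        c = p22 + (stats.syy - n * ybar * ybar) + w * dy * dy
    v = nu - 1.0  # nu - d + 1 with d = 2
    factor = (kappa + 1.0) / (kappa * v)
    a *= factor
    b *= factor
    c *= factor
    det = a * c - b * b
    dx = x - mx
    dy = y - my
    q = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return (_mvt_logconst(v, 2) - 0.5 * log(det)
            - 0.5 * (v + 2.0) * log(1.0 + q / v))


def update_concentration(rng, alpha: float, n_clusters: int, n: int,
                         a0: float, b0: float) -> float:
    """Auxiliary-variable update of the DP concentration (Escobar & West).

    Draws eta ~ Beta(alpha+1, n), then alpha from the two-component Gamma
    mixture whose stationary law is the exact conditional
    pi(alpha | C, n) propto alpha^(a0+C-1) e^(-b0 alpha)
    Gamma(alpha) / Gamma(alpha+n).
    """
    eta = rng.beta(alpha + 1.0, n)
    odds = (a0 + n_clusters - 1.0) / (n * (b0 - log(eta)))
    shape = a0 + n_clusters if rng.random() < odds / (1.0 + odds) \
        else a0 + n_clusters - 1.0
    return float(rng.gamma(shape, 1.0 / (b0 - log(eta))))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def dpm_gibbs(data, hyper: DPMHyper, n_iter: int = 6000, burnin: int = 1000,
              thin: int = 10, seed=None, progress: bool = False) -> list:
    """Collapsed Gibbs chain; returns the retained post-burnin states.

    Assignments are resampled one observation at a time from the conjugate
    multivariate-t predictives; each sweep then refreshes (mu_c, Sigma_c)
    from the NIW full conditionals and updates m1 and k0 (and optionally
    psi1 / alpha) from theirs.  Reproducible given ``seed``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least two observations")
    if d != hyper.dim:
        raise ValueError(f"data dim {d} != hyper dim {hyper.dim}")
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    psi1 = (np.atleast_2d(hyper.psi1) if hyper.psi1 is not None
            else np.atleast_2d(np.cov(x.T, ddof=1))).copy()
    m1 = hyper.m2.copy()
    k0 = hyper.tau1 / hyper.tau2  # prior mean of Gamma(tau1/2, tau2/2)
    if k0 <= 0:
        k0 = 1.0
    alpha = hyper.alpha
    nu1 = float(hyper.nu1)
    s2_inv = np.linalg.inv(hyper.s2)
    s2_inv_m2 = s2_inv @ hyper.m2

    # initial assignment: single cluster
    z = np.zeros(n, dtype=int)
    clusters = [_Suff()]
    xs = x[:, 0].tolist()
    ys = x[:, 1].tolist() if d == 2 else [0.0] * n
    for xi, yi in zip(xs, ys):
        if d == 1:
            clusters[0].add1(xi)
        else:
            clusters[0].add2(xi, yi)

    states: list[DPMState] = []
    log_alpha = log(alpha)
    for it in range(1, n_iter + 1):
        # --- assignments -------------------------------------------------
        m10 = m1[0]
        m11 = m1[1] if d == 2 else 0.0
        p11 = psi1[0, 0]
        p12 = psi1[0, 1] if d == 2 else 0.0
        p22 = psi1[1, 1] if d == 2 else 0.0
        uniforms = rng.random(n)
        for i in range(n):
            xi = xs[i]
            yi = ys[i]
            ci = z[i]
            st = clusters[ci]
            if d == 1:
                st.remove1(xi)
            else:
                st.remove2(xi, yi)
            if st.n == 0:
                clusters.pop(ci)
                z[z > ci] -= 1
            logp = []
            if d == 1:
                for st in clusters:
                    logp.append(log(st.n) + _log_predictive_1d(
                        xi, st, m10, k0, nu1, p11))
                logp.append(log_alpha + _log_predictive_1d(
                    xi, None, m10, k0, nu1, p11))
            else:
                for st in clusters:
                    logp.append(log(st.n) + _log_predictive_2d(
                        xi, yi, st, m10, m11, k0, nu1, p11, p12, p22))
                logp.append(log_alpha + _log_predictive_2d(
                    xi, yi, None, m10, m11, k0, nu1, p11, p12, p22))
            mx = max(logp)
            probs = [math.exp(v - mx) for v in logp]
            target = uniforms[i] * sum(probs)
            acc = 0.0
            new_c = len(probs) - 1
            for c, pv in enumerate(probs):
                acc += pv
                if target <= acc:
                    new_c = c
                    break
            if new_c == len(clusters):
                clusters.append(_Suff())
            if d == 1:
                clusters[new_c].add1(xi)
            else:
                clusters[new_c].add2(xi, yi)
            z[i] = new_c

        # --- explicit cluster parameters ---------------------------------
        C = len(clusters)
        mus = np.empty((C, d))
        covs = np.empty((C, d, d))
        for c, st in enumerate(clusters):
            kappa, m, nu, psi = _niw_posterior(st, m1, k0, nu1, psi1, d)
            try:
                cov = _rinvwishart(rng, nu, psi)
            except np.linalg.LinAlgError:
                import warnings as _w
                _w.warn("non-PD scatter; jittering by 1e-8 I")
                cov = _rinvwishart(rng, nu, psi + 1e-8 * np.eye(d))
            mu = rng.multivariate_normal(m, cov / kappa)
            mus[c] = mu
            covs[c] = cov

        # --- hyperparameter updates --------------------------------------
        prec_sum = np.zeros((d, d))
        prec_mu_sum = np.zeros(d)
        quad = 0.0
        cov_invs = []
        for c in range(C):
            ci = np.linalg.inv(covs[c])
            cov_invs.append(ci)
            prec_sum += ci
            prec_mu_sum += ci @ mus[c]
        post_prec = s2_inv + k0 * prec_sum
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (s2_inv_m2 + k0 * prec_mu_sum)
        m1 = rng.multivariate_normal(post_mean,
                                     0.5 * (post_cov + post_cov.T))
        for c in range(C):
            dev = mus[c] - m1
            quad += float(dev @ cov_invs[c] @ dev)
        shape = 0.5 * hyper.tau1 + 0.5 * C * d
        rate = 0.5 * hyper.tau2 + 0.5 * quad
        k0 = float(rng.gamma(shape, 1.0 / rate))
        if hyper.update_psi1:
            # conjugate Wishart full conditional (psi1 ~ W(nu2, psi2) read)
            w_df = hyper.nu2 + C * nu1
            w_scale = np.linalg.inv(np.linalg.inv(hyper.psi2) + prec_sum)
            psi1 = _rwishart(rng, w_df, w_scale)
        if hyper.update_alpha:
            alpha = update_concentration(rng, alpha, C, n, hyper.a0,
                                         hyper.b0)
            log_alpha = log(alpha)

        if it > burnin and (it - burnin) % thin == 0:
            states.append(DPMState(
                assignments=z.copy(),
                cluster_sizes=np.array([st.n for st in clusters]),
                cluster_means=mus.copy(), cluster_covs=covs.copy(),
                m1=m1.copy(), k0=k0, psi1=psi1.copy(), alpha=alpha,
                iteration=it))
    return states


# ---------------------------------------------------------------------------
# density draws
# ---------------------------------------------------------------------------


@dataclass
class DPMDensityDraw:
    """Finite-mixture density associated with a posterior state.

    Normal components for occupied clusters plus one Student-t
    base-predictive component with weight alpha / (n + alpha).
    """

    weights: np.ndarray
    means: np.ndarray       # (C+1, d); last row is the base mean
    covs: np.ndarray        # (C+1, d, d); last is the base t scale
    base_df: float          # df of the trailing t component
    dim: int

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.dim == 1:
            x = x.reshape(-1, 1)
        elif x.ndim == 1:
            x = x[None, :]
        out = np.zeros(x.shape[0])
        ncomp = len(self.weights)
        for j in range(ncomp):
            mu = self.means[j]
            cov = self.covs[j]
            dev = x - mu
            prec = np.linalg.inv(cov)
            det = np.linalg.det(cov)
            q = np.einsum("ni,ij,nj->n", dev, prec, dev)
            d = self.dim
            if j < ncomp - 1:
                out += self.weights[j] * np.exp(-0.5 * q) / (
                    (2 * pi) ** (d / 2.0) * sqrt(det))
            else:
                v = self.base_df
                logc = _mvt_logconst(v, d) - 0.5 * log(det)
                out += self.weights[j] * np.exp(
                    logc - 0.5 * (v + d) * np.log1p(q / v))
        return out


def density_draw(state: DPMState, hyper: DPMHyper) -> DPMDensityDraw:
    """Conditional-mixture density draw for one Gibbs state."""
    d = hyper.dim
    n = state.assignments.size
    C = state.cluster_sizes.size
    alpha = state.alpha
    weights = np.empty(C + 1)
    weights[:C] = state.cluster_sizes / (n + alpha)
    weights[C] = alpha / (n + alpha)
    means = np.vstack([state.cluster_means, state.m1[None, :]])
    v = hyper.nu1 - d + 1.0
    base_scale = state.psi1 * (state.k0 + 1.0) / (state.k0 * v)
    covs = np.concatenate([state.cluster_covs, base_scale[None, :, :]])
    return DPMDensityDraw(weights=weights, means=means, covs=covs,
                          base_df=v, dim=d)


class _AverageDensity:
    """Pointwise average of density draws (the DPM expected posterior)."""

    def __init__(self, draws):
        if not draws:
            raise ValueError("empty chain")
        self.draws = draws

    def __call__(self, x):
        out = self.draws[0](x)
        for dr in self.draws[1:]:
            out = out + dr(x)
        return out / len(self.draws)


def eap_density(chain: Sequence[DPMState], hyper: DPMHyper):
    """Expected a posteriori density: average of per-state density draws."""
    if not chain:
        raise ValueError("empty chain")
    return _AverageDensity([density_draw(s, hyper) for s in chain])
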