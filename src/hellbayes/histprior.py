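"""Random histogram prior on densities over [0, 1].

A density is modelled as a regular k-bin histogram ``f_{omega,k}(x) =
k * sum_j omega_j 1{x in I_j}`` with ``I_j = [(j-1)/k, j/k)`` (last bin
right-closed) and Dirichlet weights ``omega ~ D(alpha_1, ..., alpha_k)``;
``k`` itself carries either a Dirac prior or a pmf with sub-exponential tails
(``exp(-b1 k log k) <= p_k(k) <= exp(-b2 k log k)``), satisfied by the
Poisson distribution.

Because the likelihood of a sample is multinomial in ``omega``, the posterior
is conjugate: ``omega | X ~ D(alpha + counts)`` with marginal likelihood
``k^n B(alpha + counts) / B(alpha)``.  The expected a posteriori density
(the MHB input) is therefore available in closed form, and posterior density
draws (the BMH input) are cheap Dirichlet draws.

Raw data on the real line are carried to [0, 1] by an affine map recorded in
the fit; all densities returned here evaluate on the original scale with the
Jacobian applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson as _poisson

__all__ = [
    "HistogramSpec", "KPrior", "HistogramPosterior", "HistogramDensity",
    "DataMap", "kn_rate", "bin_counts", "posterior_update", "log_marginal_k",
    "fit_histogram_posterior", "expected_posterior_density",
    "sample_posterior_density", "project_density", "practical_k",
]


def kn_rate(n: int) -> int:
    """Dirac bin-count rate K_n = n^(1/2) (log n)^(-2), clamped to >= 1.

    For every practically sized n this is below 1 (the rate targets very
    large samples); we clamp and warn, and callers normally override k.
    """
    kn = math.sqrt(n) / math.log(n) ** 2 if n > 1 else 1.0
    if kn < 1.0:
        warnings.warn(
            f"K_n rate = {kn:.3f} < 1 at n={n}; clamping to 1 "
            "(choose k explicitly for finite-sample work)", stacklevel=2)
    return max(1, round(kn))


def practical_k(n: int) -> int:
    """Finite-sample default bin count: the Rice rule, 2 * n^(1/3).

    The asymptotic rate :func:`kn_rate` is the theoretically efficient
    choice but degenerates to one bin at practical n; the Rice rule is the
    standard histogram default at simulation scale.
    """
    return max(1, round(2.0 * n ** (1.0 / 3.0)))


@dataclass
class DataMap:
    """Affine map x -> (x - offset) / scale carrying data into [0, 1]."""

    offset: float = 0.0
    scale: float = 1.0

    def to01(self, x):
        return (np.asarray(x, dtype=float) - self.offset) / self.scale

    def from01(self, u):
        return np.asarray(u, dtype=float) * self.scale + self.offset

    @classmethod
    def auto(cls, data, padding: float = 0.05) -> "DataMap":
        data = np.asarray(data, dtype=float)
        lo, hi = data.min(), data.max()
        rng = hi - lo
        if rng == 0.0:
            rng = max(abs(lo), 1.0)
        return cls(offset=lo - padding * rng, scale=rng * (1 + 2 * padding))


@dataclass
class HistogramSpec:
    """Bin count and Dirichlet concentration for one histogram model."""

    k: int
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(-1)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha.size != self.k:
            raise ValueError("alpha must have length k")
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    def check_bracket(self, a: float, c1: float, c2: float) -> bool:
        """Warn unless c1 * k^(-a) <= alpha_j <= c2 for all j."""
        lo = c1 * self.k ** (-a)
        ok = bool(np.all((self.alpha >= lo) & (self.alpha <= c2)))
        if not ok:
            warnings.warn(
                f"alpha outside the bracket [{lo:.3g}, {c2:.3g}] "
                f"(a={a}, c1={c1}, c2={c2})", stacklevel=2)
        return ok


@dataclass
class KPrior:
    """Prior on the bin count k: a Dirac mass or an explicit pmf."""

    kind: str  # "dirac" | "pmf"
    k_fixed: int | None = None
    support: np.ndarray | None = None
    probs: np.ndarray | None = None

    @classmethod
    def dirac(cls, k: int) -> "KPrior":
        if k < 1:
            raise ValueError("k must be >= 1")
        return cls(kind="dirac", k_fixed=int(k))

    @classmethod
    def poisson(cls, lam: float, n: int) -> "KPrior":
        """Zero-truncated Poisson(lam) restricted to {1..floor(n/log(n)^2)}."""
        kmax = max(1, int(n / math.log(max(n, 3)) ** 2))
        ks = np.arange(1, kmax + 1)
        p = _poisson.pmf(ks, lam)
        keep = p > 0.0  # drop the underflowed far tail
        ks, p = ks[keep], p[keep]
        if p.size == 0:
            raise ValueError("empty k-prior support")
        return cls(kind="pmf", support=ks, probs=p / p.sum())

    @classmethod
    def pmf(cls, support, probs) -> "KPrior":
        support = np.asarray(support, dtype=int)
        probs = np.asarray(probs, dtype=float)
        if support.size == 0:
            raise ValueError("empty k-prior support")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("k pmf must sum to 1")
        return cls(kind="pmf", support=support, probs=probs)

    def items(self):
        if self.kind == "dirac":
            return [(self.k_fixed, 1.0)]
        return list(zip(self.support.tolist(), self.probs.tolist()))


def bin_counts(data01, k: int) -> np.ndarray:
    """Counts over I_j = [(j-1)/k, j/k), with x = 1 in the last bin."""
    x = np.asarray(data01, dtype=float).reshape(-1)
    if x.size and (x.min() < 0.0 or x.max() > 1.0):
        bad = x[(x < 0) | (x > 1)][0]
        raise ValueError(f"data point {bad} outside [0, 1]")
    idx = np.minimum((x * k).astype(int), k - 1)
    return np.bincount(idx, minlength=k)


def posterior_update(spec: HistogramSpec, counts) -> np.ndarray:
    """Conjugate Dirichlet update: alpha + counts."""
    c = np.asarray(counts, dtype=float).reshape(-1)
    if c.size != spec.k:
        raise ValueError("counts length must equal k")
    if np.any(c < 0):
        raise ValueError("negative counts")
    return spec.alpha + c


def _log_dirichlet_norm(a: np.ndarray) -> float:
    return float(gammaln(a).sum() - gammaln(a.sum()))


def log_marginal_k(spec: HistogramSpec, counts, n: int) -> float:
    """log m(X | k) = n log k + log B(alpha + counts) - log B(alpha)."""
    c = np.asarray(counts, dtype=float).reshape(-1)
    if int(c.sum()) != n:
        raise ValueError("counts must sum to n")
    return (n * math.log(spec.k)
            + _log_dirichlet_norm(spec.alpha + c)
            - _log_dirichlet_norm(spec.alpha))


@dataclass
class HistogramDensity:
    """A single histogram density draw, evaluable on the original scale."""

    k: int
    omega: np.ndarray
    data_map: DataMap

    def __call__(self, x):
        u = self.data_map.to01(x)
        inside = (u >= 0.0) & (u <= 1.0)
        idx = np.minimum((np.clip(u, 0.0, 1.0) * self.k).astype(int),
                         self.k - 1)
        vals = self.k * self.omega[idx] / self.data_map.scale
        return np.where(inside, vals, 0.0)

    def bin_edges_original(self) -> np.ndarray:
        return self.data_map.from01(np.linspace(0.0, 1.0, self.k + 1))


@dataclass
class HistogramPosterior:
    """Per-k conjugate posteriors with posterior weights over k."""

    records: list  # of dict(k, spec, counts, alpha_post, log_marginal)
    k_weights: np.ndarray
    data_map: DataMap
    n: int

    def bin_edges_original(self) -> np.ndarray:
        edges = [self.data_map.from01(np.linspace(0, 1, r["k"] + 1))
                 for r in self.records]
        return np.unique(np.concatenate(edges))


def _default_alpha_rule(k: int) -> np.ndarray:
    return np.ones(k)


def fit_histogram_posterior(data, kprior: KPrior,
                            alpha_rule: Callable[[int], np.ndarray] | None = None,
                            data_map="auto",
                            padding: float = 0.05) -> HistogramPosterior:
    """Conjugate fit: per-k Dirichlet posteriors and posterior k-weights.

    ``k_weights(k) propto p_k(k) * m(X | k)``; Dirac priors give a point
    mass.  ``data_map`` is either "auto" (data range with 5% padding per
    side) or an explicit :class:`DataMap`.
    """
    data = np.asarray(data, dtype=float).reshape(-1)
    n = data.size
    if n < 1:
        raise ValueError("need at least one observation")
    if alpha_rule is None:
        alpha_rule = _default_alpha_rule
    dmap = DataMap.auto(data, padding) if data_map == "auto" else data_map
    u = dmap.to01(data)
    records = []
    log_w = []
    for k, pk in kprior.items():
        spec = HistogramSpec(k, alpha_rule(k))
        if spec.alpha.sum() > n / 10:
            warnings.warn(
                f"sum(alpha)={spec.alpha.sum():.1f} is large relative to "
                f"n={n}; the prior may dominate", stacklevel=2)
        counts = bin_counts(u, k)
        lm = log_marginal_k(spec, counts, n)
        records.append({
            "k": k, "spec": spec, "counts": counts,
            "alpha_post": posterior_update(spec, counts),
            "log_marginal": lm,
        })
        log_w.append(math.log(pk) + lm)
    log_w = np.asarray(log_w)
    k_weights = np.exp(log_w - logsumexp(log_w))
    return HistogramPosterior(records=records, k_weights=k_weights,
                              data_map=dmap, n=n)


@dataclass
class _HistogramMixtureDensity:
    """Mixture over k of closed-form posterior-mean histograms (g*_n)."""

    posterior: HistogramPosterior

    def __post_init__(self):
        self._parts = []
        for rec, w in zip(self.posterior.records,
                          self.posterior.k_weights):
            a = rec["alpha_post"]
            self._parts.append(
                (w, HistogramDensity(rec["k"], a / a.sum(),
                                     self.posterior.data_map)))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape)
        for w, part in self._parts:
            out += w * part(x)
        return out

    def bin_edges_original(self) -> np.ndarray:
        return self.posterior.bin_edges_original()


def expected_posterior_density(post: HistogramPosterior):
    """The expected a posteriori density g*_n (closed form, integrates to 1).

    Bin j of the k-component has height k * (alpha_j + n_j) / (sum alpha + n)
    on the [0, 1] scale, Jacobian-corrected to the original scale.
    """
    return _HistogramMixtureDensity(post)


def sample_posterior_density(post: HistogramPosterior, n_draws: int,
                             seed=None) -> list:
    """Draws g ~ pi(. | X): k ~ k_weights, omega ~ D(alpha_post(k))."""
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    ks = rng.choice(len(post.records), size=n_draws, p=post.k_weights)
    draws = []
    for ki in ks:
        rec = post.records[ki]
        omega = rng.dirichlet(rec["alpha_post"])
        draws.append(HistogramDensity(rec["k"], omega, post.data_map))
    return draws


def project_density(f, k: int, data_map: DataMap | None = None
                    ) -> HistogramDensity:
    """L2 projection f[k] of a density on [0,1]: bin value k * int_{I_j} f."""
    from scipy.integrate import quad

    edges = np.linspace(0.0, 1.0, k + 1)
    masses = np.empty(k)
    for j in range(k):
        val, err = quad(lambda t: float(np.asarray(f(np.array([t])))[0]),
                        edges[j], edges[j + 1], limit=100)
        if not np.isfinite(val):
            raise RuntimeError(f"quadrature failed on bin {j}")
        masses[j] = val
    return HistogramDensity(k, masses, data_map or DataMap())
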