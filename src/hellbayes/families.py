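"""Parametric families with square-root density machinery.

The minimum-Hellinger functional ``T`` maps a density ``g`` to the parameter
``theta`` whose family member ``f_theta`` is closest to ``g`` in Hellinger
distance.  Its asymptotic analysis runs through the square root
``s_theta = f_theta ** (1/2)`` and its parameter derivatives:

* Fisher information ``I(theta) = 4 * int s_dot s_dot^T dx``;
* efficient influence function
  ``T~(x) = -[int s_ddot(x) g0(x)**0.5 dx]^{-1} . s_dot(x) / (2 g0(x)**0.5)``,
  whose centred L2(g0) norm equals ``I(theta)^{-1}`` when ``g0 = f_theta``.

Built-in families are the univariate normal ``(mu, sigma)`` and the bivariate
normal ``(mu1, mu2, S11, S12, S22)``; the latter is optimised internally in
Cholesky coordinates so iterates stay positive definite.  Unbounded parameter
spaces can be embedded in a compact rectangle with :func:`compactify`, which
applies ``arctan`` coordinate-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParametricFamily",
    "SqrtDensityBundle",
    "Normal1D",
    "BivariateNormal",
    "get_family",
    "sqrt_density",
    "sqrt_density_derivatives",
    "fisher_information",
    "efficient_influence",
    "compactify",
]


class DomainError(ValueError):
    """Parameter outside its admissible open interval."""


def _as_theta(theta, dim: int) -> np.ndarray:
    th = np.asarray(theta, dtype=float).reshape(-1)
    if th.size != dim:
        raise ValueError(f"expected {dim} parameters, got {th.size}")
    return th


@dataclass
class ParametricFamily:
    """A smooth family {f_theta} on a common support.

    ``param_bounds`` are open intervals; densities evaluate to 0 off
    ``support``.  ``mle`` is used only for optimizer initialisation and as a
    non-robust benchmark column.
    """

    name: str
    param_dim: int
    data_dim: int
    param_names: tuple
    param_bounds: tuple  # per-coordinate (lo, hi), open
    support: tuple  # (lo, hi) in 1-D, ((lo,hi),(lo,hi)) in 2-D

    def pdf(self, theta, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def logpdf(self, theta, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(theta, x))

    def mle(self, sample):  # pragma: no cover - abstract
        raise NotImplementedError

    def sample(self, theta, n, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- parameter validation ------------------------------------------------
    def check_theta(self, theta, interior: bool = False) -> np.ndarray:
        th = _as_theta(theta, self.param_dim)
        for j, (lo, hi) in enumerate(self.param_bounds):
            v = th[j]
            bad = not (lo < v < hi)
            if interior and (v == lo or v == hi):
                bad = True
            if bad:
                raise DomainError(
                    f"parameter '{self.param_names[j]}'={v} outside open "
                    f"interval ({lo}, {hi}) of family '{self.name}'"
                )
        self._check_extra(th)
        return th

    def _check_extra(self, theta: np.ndarray) -> None:
        """Joint constraints beyond per-coordinate boxes (e.g. PD-ness)."""

    # -- internal (optimizer) coordinates ------------------------------------
    # Identity by default; BivariateNormal overrides with Cholesky coords.
    def to_internal(self, theta) -> np.ndarray:
        return _as_theta(theta, self.param_dim)

    def from_internal(self, z) -> np.ndarray:
        return _as_theta(z, self.param_dim)

    def internal_bounds(self):
        return self.param_bounds

    # -- analytic sqrt-density derivatives (optional) -------------------------
    def sdot(self, theta, x):
        return None

    def sddot(self, theta, x):
        return None

    def fisher_closed_form(self, theta):
        return None


@dataclass
class SqrtDensityBundle:
    """``s_theta`` and its first/second parameter derivatives at fixed theta.

    ``s_dot(x)`` has shape ``(n, p)`` and ``s_ddot(x)`` shape ``(n, p, p)``
    for ``n`` evaluation points and ``p`` parameters.
    """

    family: ParametricFamily
    theta: np.ndarray
    s: Callable
    s_dot: Callable
    s_ddot: Callable
    mode: str  # "analytic" | "finite-difference"


def sqrt_density(family: ParametricFamily, theta, x) -> np.ndarray:
    """``f_theta(x) ** 0.5``; zero off the support."""
    th = family.check_theta(theta)
    return np.sqrt(family.pdf(th, x))


def _fd_steps(theta: np.ndarray, h: float) -> np.ndarray:
    return h * (1.0 + np.abs(theta))


def sqrt_density_derivatives(
    family: ParametricFamily, theta, h: float = 1e-5
) -> SqrtDensityBundle:
    """First/second derivatives of ``s_theta`` in theta.

    Analytic forms are used when the family provides them; otherwise central
    finite differences with per-coordinate step ``h * (1 + |theta_j|)``.
    """
    th = family.check_theta(theta, interior=True)
    p = family.param_dim

    def s(x):
        return np.sqrt(family.pdf(th, x))

    a_dot = family.sdot(th, None)
    if a_dot is not None:

        def s_dot(x):
            return family.sdot(th, x)

        def s_ddot(x):
            return family.sddot(th, x)

        return SqrtDensityBundle(family, th, s, s_dot, s_ddot, "analytic")

    steps = _fd_steps(th, h)

    def s_at(t, x):
        return np.sqrt(family.pdf(t, x))

    def s_dot(x):
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        out = np.empty((n, p))
        for j in range(p):
            e = np.zeros(p)
            e[j] = steps[j]
            out[:, j] = (s_at(th + e, x) - s_at(th - e, x)) / (2 * steps[j])
        return out

    def s_ddot(x):
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        out = np.empty((n, p, p))
        s0 = s_at(th, x)
        for j in range(p):
            ej = np.zeros(p)
            ej[j] = steps[j]
            out[:, j, j] = (
                s_at(th + ej, x) - 2 * s0 + s_at(th - ej, x)
            ) / steps[j] ** 2
            for l in range(j + 1, p):
                el = np.zeros(p)
                el[l] = steps[l]
                mixed = (
                    s_at(th + ej + el, x)
                    - s_at(th + ej - el, x)
                    - s_at(th - ej + el, x)
                    + s_at(th - ej - el, x)
                ) / (4 * steps[j] * steps[l])
                out[:, j, l] = mixed
                out[:, l, j] = mixed
        return out

    return SqrtDensityBundle(family, th, s, s_dot, s_ddot, "finite-difference")


def fisher_information(family: ParametricFamily, theta, grid=None) -> np.ndarray:
    """Fisher information ``I(theta) = 4 int s_dot s_dot^T dx``.

    Uses the family's closed form when available, else quadrature over
    ``grid`` (a :class:`~hellbayes.disparity.QuadratureGrid`).
    """
    th = family.check_theta(theta, interior=True)
    closed = family.fisher_closed_form(th)
    if closed is not None:
        return closed
    if grid is None:
        grid = _default_grid(family, th)
    bundle = sqrt_density_derivatives(family, th)
    sd = bundle.s_dot(grid.nodes)
    info = 4.0 * np.einsum("n,ni,nj->ij", grid.weights, sd, sd)
    info = 0.5 * (info + info.T)
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "numerically singular Fisher information; consider "
            "reparametrizing the family"
        )
    return info


def efficient_influence(
    family: ParametricFamily, theta, g0, grid=None
) -> Callable:
    """Efficient influence function of the minimum-Hellinger functional.

    At ``g0`` with ``theta = T(g0)``::

        T~(x) = -A^{-1} . s_dot(x) / (2 g0(x)**0.5),
        A = int s_ddot(x) g0(x)**0.5 dx

    (the vanishing remainder is set to zero).  At the model ``g0 = f_theta``
    this reduces to ``I(theta)^{-1}`` times the score.  Raises on evaluation
    where ``g0(x) = 0`` but ``s_dot(x) != 0`` (unbounded influence).
    """
    th = family.check_theta(theta, interior=True)
    if grid is None:
        grid = _default_grid(family, th)
    bundle = sqrt_density_derivatives(family, th)
    sqrt_g0 = np.sqrt(np.asarray(g0(grid.nodes), dtype=float))
    sdd = bundle.s_ddot(grid.nodes)
    a_mat = np.einsum("n,nij->ij", grid.weights * sqrt_g0, sdd)
    a_inv = np.linalg.inv(a_mat)

    def influence(x):
        x = np.asarray(x, dtype=float)
        gx = np.sqrt(np.asarray(g0(x), dtype=float))
        sd = bundle.s_dot(x)
        zero = gx == 0.0
        if np.any(zero & np.any(sd != 0.0, axis=-1)):
            raise ZeroDivisionError(
                "influence function unbounded: g0(x)=0 with s_dot(x)!=0"
            )
        gx = np.where(zero, 1.0, gx)
        return -(sd / (2.0 * gx[:, None])) @ a_inv.T

    return influence


def _default_grid(family: ParametricFamily, theta):
    """A wide quadrature window for the built-in normal families."""
    from .disparity import make_grid

    if isinstance(family, Normal1D):
        mu, sig = theta
        return make_grid((mu - 10 * sig, mu + 10 * sig), n_panels=20, order=12)
    if isinstance(family, BivariateNormal):
        m1, m2, s11, s12, s22 = theta
        a, b = math.sqrt(s11), math.sqrt(s22)
        return make_grid(
            ((m1 - 8 * a, m1 + 8 * a), (m2 - 8 * b, m2 + 8 * b)),
            n_panels=12,
            order=10,
        )
    raise ValueError(
        "no default quadrature window for custom families; pass grid="
    )


# ---------------------------------------------------------------------------
# Built-in families
# ---------------------------------------------------------------------------

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Normal1D(ParametricFamily):
    """Univariate normal, parametrized by (mu, sigma) with sigma the sd."""

    def __init__(self):
        super().__init__(
            name="normal1d",
            param_dim=2,
            data_dim=1,
            param_names=("mu", "sigma"),
            param_bounds=((-np.inf, np.inf), (0.0, np.inf)),
            support=(-np.inf, np.inf),
        )

    def pdf(self, theta, x):
        mu, sig = _as_theta(theta, 2)
        x = np.asarray(x, dtype=float)
        z = (x - mu) / sig
        return _INV_SQRT_2PI / sig * np.exp(-0.5 * z * z)

    def mle(self, sample):
        s = np.asarray(sample, dtype=float).reshape(-1)
        return np.array([s.mean(), s.std(ddof=0)])

    def sample(self, theta, n, rng):
        mu, sig = _as_theta(theta, 2)
        return rng.normal(mu, sig, size=n)

    # analytic sqrt-density derivatives:
    #   s = (2 pi sig^2)^(-1/4) exp(-(x-mu)^2 / (4 sig^2))
    def _s(self, theta, x):
        mu, sig = theta
        x = np.asarray(x, dtype=float)
        return (2 * math.pi * sig**2) ** -0.25 * np.exp(
            -((x - mu) ** 2) / (4 * sig**2)
        )

    def sdot(self, theta, x):
        if x is None:
            return True  # signal availability
        mu, sig = theta
        x = np.asarray(x, dtype=float)
        s = self._s(theta, x)
        d = x - mu
        dmu = d / (2 * sig**2) * s
        dsig = (-1.0 / (2 * sig) + d * d / (2 * sig**3)) * s
        return np.stack([dmu, dsig], axis=-1)

    def sddot(self, theta, x):
        mu, sig = theta
        x = np.asarray(x, dtype=float)
        s = self._s(theta, x)
        d = x - mu
        a_mu = d / (2 * sig**2)
        a_sig = -1.0 / (2 * sig) + d * d / (2 * sig**3)
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = (a_mu * a_mu - 1.0 / (2 * sig**2)) * s
        out[..., 1, 1] = (
            a_sig * a_sig + 1.0 / (2 * sig**2) - 3 * d * d / (2 * sig**4)
        ) * s
        mixed = (a_mu * a_sig - d / sig**3) * s
        out[..., 0, 1] = mixed
        out[..., 1, 0] = mixed
        return out

    def fisher_closed_form(self, theta):
        _, sig = theta
        return np.diag([1.0 / sig**2, 2.0 / sig**2])


class BivariateNormal(ParametricFamily):
    """Bivariate normal, theta = (mu1, mu2, S11, S12, S22).

    Positive definiteness of Sigma is preserved during optimisation by an
    internal Cholesky parametrization (L11, L21, L22) with L11, L22 > 0.
    """

    def __init__(self):
        super().__init__(
            name="normal2d",
            param_dim=5,
            data_dim=2,
            param_names=("mu1", "mu2", "S11", "S12", "S22"),
            param_bounds=(
                (-np.inf, np.inf),
                (-np.inf, np.inf),
                (0.0, np.inf),
                (-np.inf, np.inf),
                (0.0, np.inf),
            ),
            support=((-np.inf, np.inf), (-np.inf, np.inf)),
        )

    def _check_extra(self, theta):
        _, _, s11, s12, s22 = theta
        if s11 * s22 - s12 * s12 <= 0.0:
            raise DomainError(
                f"covariance [[{s11},{s12}],[{s12},{s22}]] is not positive "
                "definite"
            )

    def pdf(self, theta, x):
        m1, m2, s11, s12, s22 = _as_theta(theta, 5)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        det = s11 * s22 - s12 * s12
        d1 = x[:, 0] - m1
        d2 = x[:, 1] - m2
        q = (s22 * d1 * d1 - 2 * s12 * d1 * d2 + s11 * d2 * d2) / det
        return np.exp(-0.5 * q) / (2 * math.pi * math.sqrt(det))

    def mle(self, sample):
        s = np.atleast_2d(np.asarray(sample, dtype=float))
        mu = s.mean(axis=0)
        c = np.cov(s.T, ddof=0)
        return np.array([mu[0], mu[1], c[0, 0], c[0, 1], c[1, 1]])

    def sample(self, theta, n, rng):
        m1, m2, s11, s12, s22 = _as_theta(theta, 5)
        return rng.multivariate_normal(
            [m1, m2], [[s11, s12], [s12, s22]], size=n
        )

    # Cholesky internal coordinates ------------------------------------------
    def to_internal(self, theta):
        m1, m2, s11, s12, s22 = self.check_theta(theta)
        l11 = math.sqrt(s11)
        l21 = s12 / l11
        l22 = math.sqrt(s22 - l21 * l21)
        return np.array([m1, m2, l11, l21, l22])

    def from_internal(self, z):
        m1, m2, l11, l21, l22 = _as_theta(z, 5)
        return np.array(
            [m1, m2, l11 * l11, l11 * l21, l21 * l21 + l22 * l22]
        )

    def internal_bounds(self):
        eps = 1e-8
        return (
            (-np.inf, np.inf),
            (-np.inf, np.inf),
            (eps, np.inf),
            (-np.inf, np.inf),
            (eps, np.inf),
        )

    def fisher_closed_form(self, theta):
        m1, m2, s11, s12, s22 = theta
        sigma = np.array([[s11, s12], [s12, s22]])
        prec = np.linalg.inv(sigma)
        info = np.zeros((5, 5))
        info[:2, :2] = prec
        basis = [
            np.array([[1.0, 0.0], [0.0, 0.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, 1.0]]),
        ]
        for a in range(3):
            for b in range(3):
                info[2 + a, 2 + b] = 0.5 * np.trace(
                    prec @ basis[a] @ prec @ basis[b]
                )
        return info


# ---------------------------------------------------------------------------
# Compactification (arctan reparametrization)
# ---------------------------------------------------------------------------


class CompactifiedFamily(ParametricFamily):
    """A family re-indexed by t = arctan(theta) coordinate-wise.

    Location coordinates map to (-pi/2, pi/2), positive scale coordinates to
    (0, pi/2); coordinates that are already bounded keep the identity map.
    The Hellinger geometry is untouched: pdf(t, x) = base.pdf(atan^-1 t, x).
    """

    def __init__(self, base: ParametricFamily):
        self.base = base
        maps = []
        bounds = []
        for lo, hi in base.param_bounds:
            if np.isinf(lo) or np.isinf(hi):
                maps.append(True)
                bounds.append(
                    (math.atan(lo) if np.isfinite(lo) else -math.pi / 2,
                     math.atan(hi) if np.isfinite(hi) else math.pi / 2)
                )
            else:
                maps.append(False)
                bounds.append((lo, hi))
        self._arctan = maps
        super().__init__(
            name=base.name + "_arctan",
            param_dim=base.param_dim,
            data_dim=base.data_dim,
            param_names=tuple("t_" + n for n in base.param_names),
            param_bounds=tuple(bounds),
            support=base.support,
        )

    def compactify_theta(self, theta):
        th = _as_theta(theta, self.param_dim)
        return np.array(
            [math.atan(v) if m else v for v, m in zip(th, self._arctan)]
        )

    def uncompactify_theta(self, t):
        t = _as_theta(t, self.param_dim)
        return np.array(
            [math.tan(v) if m else v for v, m in zip(t, self._arctan)]
        )

    def _check_extra(self, t):
        self.base._check_extra(self.uncompactify_theta(t))

    def pdf(self, t, x):
        return self.base.pdf(self.uncompactify_theta(t), x)

    def mle(self, sample):
        return self.compactify_theta(self.base.mle(sample))

    def sample(self, t, n, rng):
        return self.base.sample(self.uncompactify_theta(t), n, rng)


def compactify(family: ParametricFamily) -> CompactifiedFamily:
    """Embed an unbounded parameter space in a compact rectangle.

    Identity on coordinates whose bounds are already finite.
    """
    return CompactifiedFamily(family)


_REGISTRY = {}


def register_family(name: str, factory: Callable[[], ParametricFamily]):
    _REGISTRY[name] = factory


register_family("normal1d", Normal1D)
register_family("normal2d", BivariateNormal)


def get_family(name: str) -> ParametricFamily:
    """Look up a built-in or registered family by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown family '{name}'; available: {sorted(_REGISTRY)}"
        ) from None
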