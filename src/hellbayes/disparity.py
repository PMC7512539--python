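"""Hellinger distance, quadrature grids, and the minimum-Hellinger functional.

The Hellinger distance between densities ``f`` and ``g`` is

    h(f, g) = [ int (f**0.5 - g**0.5)**2 dx ]**0.5
            = sqrt(2 - 2 * A(f, g)),        A(f, g) = int (f*g)**0.5 dx,

with ``A`` the Bhattacharyya affinity; ``0 <= h <= sqrt(2)``.  The functional
``T(g) = argmin_theta h(f_theta, g)`` is computed by maximising the affinity
with a multi-start Nelder-Mead search (``T`` may be multi-valued; ties within
1e-8 in distance are broken by the lexicographically smallest theta).

All integrals use composite Gauss-Legendre panels.  Histogram integrands are
exact provided their bin edges are supplied as panel breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

__all__ = ["QuadratureGrid", "TResult", "make_grid", "hellinger_distance",
           "minimize_hellinger"]


@dataclass
class QuadratureGrid:
    """Gauss-Legendre nodes/weights over a 1-D interval or 2-D rectangle."""

    dimension: int
    nodes: np.ndarray  # (n,) in 1-D, (n, 2) in 2-D
    weights: np.ndarray  # (n,)
    window: tuple

    def integrate(self, values) -> float:
        return float(self.weights @ np.asarray(values, dtype=float))


def _panel_nodes(breakpoints: np.ndarray, order: int):
    xs, ws = np.polynomial.legendre.leggauss(order)
    lo = breakpoints[:-1]
    hi = breakpoints[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = (mid[:, None] + half[:, None] * xs[None, :]).ravel()
    weights = (half[:, None] * ws[None, :]).ravel()
    return nodes, weights


def _axis_breakpoints(lo, hi, breakpoints, n_panels):
    edges = np.linspace(lo, hi, n_panels + 1)
    if breakpoints is not None:
        bp = np.asarray(breakpoints, dtype=float)
        if np.any(np.diff(bp) < 0):
            raise ValueError("breakpoints must be sorted")
        bp = bp[(bp > lo) & (bp < hi)]
        edges = np.unique(np.concatenate([edges, bp]))
    if edges.size < 2:
        raise ValueError("degenerate window")
    return edges


def make_grid(window, breakpoints=None, order: int = 10,
              n_panels: int = 16) -> QuadratureGrid:
    """Composite Gauss-Legendre grid.

    1-D: ``window=(lo, hi)``; panels between consecutive breakpoints (or
    ``n_panels`` equal panels).  2-D: ``window=((x0,x1),(y0,y1))`` with a
    tensor product of per-axis rules; ``breakpoints`` may be a pair of
    per-axis sequences.

    Callers holding histogram densities must pass the bin edges as
    breakpoints, so that no panel straddles a jump.
    """
    win = np.asarray(window, dtype=float)
    if win.ndim == 1:
        lo, hi = win
        if not hi > lo:
            raise ValueError("degenerate window")
        edges = _axis_breakpoints(lo, hi, breakpoints, n_panels)
        nodes, weights = _panel_nodes(edges, order)
        return QuadratureGrid(1, nodes, weights, (lo, hi))
    (x0, x1), (y0, y1) = win
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate window")
    bpx, bpy = (None, None) if breakpoints is None else breakpoints
    ex = _axis_breakpoints(x0, x1, bpx, n_panels)
    ey = _axis_breakpoints(y0, y1, bpy, n_panels)
    nx, wx = _panel_nodes(ex, order)
    ny, wy = _panel_nodes(ey, order)
    xx, yy = np.meshgrid(nx, ny, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    weights = np.outer(wx, wy).ravel()
    return QuadratureGrid(2, nodes, weights, ((x0, x1), (y0, y1)))


def _eval_density(f, grid: QuadratureGrid, name: str) -> np.ndarray:
    vals = np.asarray(f(grid.nodes), dtype=float)
    if np.any(vals < 0):
        xbad = grid.nodes[np.argmin(vals)]
        raise ValueError(f"density '{name}' is negative at x={xbad}")
    return vals


def hellinger_distance(f, g, grid: QuadratureGrid,
                       mass_tol: float = 1e-6) -> float:
    """h(f, g) = sqrt(max(0, 2 - 2 * int sqrt(f g))); symmetric.

    Warns when the grid window captures less than ``1 - mass_tol`` of either
    density's mass.
    """
    fv = _eval_density(f, grid, "f")
    gv = _eval_density(g, grid, "g")
    for name, v in (("f", fv), ("g", gv)):
        mass = grid.integrate(v)
        if mass < 1.0 - mass_tol:
            warnings.warn(
                f"quadrature window captures only {mass:.6f} of the mass of "
                f"'{name}'", stacklevel=2)
    affinity = grid.integrate(np.sqrt(fv * gv))
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * affinity)))


@dataclass
class TResult:
    """Outcome of the minimum-Hellinger search T(g)."""

    theta_hat: np.ndarray
    hellinger: float
    affinity: float
    n_starts: int
    converged: bool
    all_local_optima: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "theta_hat": [float(v) for v in self.theta_hat],
            "hellinger": self.hellinger,
            "affinity": self.affinity,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "provenance": self.provenance,
        }


def _grid_moments(g_vals, grid: QuadratureGrid):
    w = grid.weights * g_vals
    mass = max(w.sum(), 1e-300)
    if grid.dimension == 1:
        x = grid.nodes
        mu = float((w * x).sum() / mass)
        var = float((w * (x - mu) ** 2).sum() / mass)
        return mu, max(var, 1e-12)
    x = grid.nodes
    mu = (w[:, None] * x).sum(axis=0) / mass
    d = x - mu
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / mass
    return mu, cov


def _auto_starts(family, g_vals, grid: QuadratureGrid):
    """Moment-matched, robust (median/IQR), and mid-bounds starting points."""
    starts = []
    if grid.dimension == 1:
        mu, var = _grid_moments(g_vals, grid)
        sd = float(np.sqrt(var))
        # quantiles of g from the grid CDF for a robust start
        order = np.argsort(grid.nodes)
        x = grid.nodes[order]
        cdf = np.cumsum((grid.weights * g_vals)[order])
        cdf /= max(cdf[-1], 1e-300)
        med = float(np.interp(0.5, cdf, x))
        q1 = float(np.interp(0.25, cdf, x))
        q3 = float(np.interp(0.75, cdf, x))
        riqr = max((q3 - q1) / 1.349, 1e-6)
        if family.param_dim == 2:
            starts.append(np.array([mu, sd]))
            starts.append(np.array([med, riqr]))
            lo, hi = grid.window
            starts.append(np.array([0.5 * (lo + hi), 0.25 * (hi - lo)]))
    else:
        mu, cov = _grid_moments(g_vals, grid)
        cov = cov + 1e-10 * np.eye(2)
        starts.append(np.array([mu[0], mu[1], cov[0, 0], cov[0, 1],
                                cov[1, 1]]))
        shrunk = 0.5 * cov + 0.5 * np.diag(np.diag(cov)) * 0.5
        starts.append(np.array([mu[0], mu[1], shrunk[0, 0], shrunk[0, 1],
                                shrunk[1, 1]]))
    if not starts:
        raise ValueError("cannot build auto starts for this family; pass "
                         "explicit starts")
    return starts


_BOUND_MARGIN = 1e-8


def _clip_to_bounds(z, bounds):
    z = np.array(z, dtype=float)
    for j, (lo, hi) in enumerate(bounds):
        if np.isfinite(lo):
            z[j] = max(z[j], lo + _BOUND_MARGIN)
        if np.isfinite(hi):
            z[j] = min(z[j], hi - _BOUND_MARGIN)
    return z


def minimize_hellinger(family, g, grid: QuadratureGrid, starts="auto",
                       xatol: float = 1e-7, fatol: float = 1e-12,
                       check_mass: bool = False) -> TResult:
    """T(g): the family member closest to ``g`` in Hellinger distance.

    Maximises the affinity ``int sqrt(f_theta * g)`` by Nelder-Mead from each
    start (in the family's internal coordinates, e.g. Cholesky factors for
    the bivariate normal).  All local optima found are reported; the returned
    ``theta_hat`` is the best, with distance ties within 1e-8 broken by the
    lexicographically smallest theta.
    """
    g_vals = _eval_density(g, grid, "g")
    if check_mass:
        mass = grid.integrate(g_vals)
        if mass < 1.0 - 1e-6:
            warnings.warn(f"window captures only {mass:.6f} of g's mass",
                          stacklevel=2)
    wsg = grid.weights * np.sqrt(g_vals)
    bounds = family.internal_bounds()

    def neg_affinity(z):
        zc = _clip_to_bounds(z, bounds)
        theta = family.from_internal(zc)
        try:
            family.check_theta(theta)
        except Exception:
            return 2.0  # worse than any affinity
        fv = family.pdf(theta, grid.nodes)
        return -float(wsg @ np.sqrt(np.maximum(fv, 0.0)))

    if isinstance(starts, str) and starts == "auto":
        starts = _auto_starts(family, g_vals, grid)
    optima = []
    any_converged = False
    for th0 in starts:
        z0 = _clip_to_bounds(family.to_internal(np.asarray(th0, float)),
                             bounds)
        res = _scipy_minimize(
            neg_affinity, z0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 4000})
        if not np.isfinite(res.fun) or res.fun >= 2.0:
            continue
        any_converged = any_converged or res.success
        theta = family.from_internal(_clip_to_bounds(res.x, bounds))
        optima.append((theta, float(res.fun)))
    if not optima:
        raise RuntimeError(
            f"minimize_hellinger: no start converged (starts={starts})")

    # dedupe local optima; lexicographic tie-break within 1e-8 in distance
    optima.sort(key=lambda t: (t[1], tuple(t[0])))
    distinct = []
    for theta, fval in optima:
        if not any(np.allclose(theta, t0, atol=1e-6) for t0, _ in distinct):
            distinct.append((theta, fval))
    fbest = distinct[0][1]
    tied = [t for t in distinct if t[1] <= fbest + 1e-8]
    tied.sort(key=lambda t: tuple(t[0]))
    best_theta, best_f = tied[0]
    affinity = -best_f
    hell = float(np.sqrt(max(0.0, 2.0 - 2.0 * affinity)))
    all_opt = [(t, float(np.sqrt(max(0.0, 2.0 - 2.0 * (-f)))))
               for t, f in distinct]
    return TResult(
        theta_hat=best_theta, hellinger=hell, affinity=affinity,
        n_starts=len(starts), converged=any_converged,
        all_local_optima=all_opt)
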