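"""Seeded generators for the demonstration designs.

Three generators cover everything the test-suite and the worked examples
need without external downloads:

* :func:`gen_contaminated_bivariate` -- 100 bivariate points, 90 from the main
  Gaussian N((10,5), [[3,1],[1,2]]) and exactly five from each of two
  contaminating Gaussians at (-2,5) and (10,14) (10% asymmetric
  contamination, exact counts);
* :func:`gen_newcomb_like` -- a synthetic stand-in for the historical
  light-speed measurements: 64 inliers from N(27.75, 5.08^2) plus two fixed
  gross negative outliers (-44, -2), 66 values in all.  It exercises the
  same code path as the real data but carries no numeric claims about it;
* :func:`gen_parametric` -- clean i.i.d. draws from a built-in family.

All generators are pure functions of (spec, seed) using numpy's PCG64
generator, so output is reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .families import ParametricFamily

__all__ = ["MixtureSpec", "CONTAMINATED_BIVARIATE_MIXTURE", "gen_mixture",
           "gen_contaminated_bivariate", "gen_newcomb_like", "gen_parametric"]


@dataclass
class MixtureSpec:
    """A finite Gaussian mixture with optional exact per-component counts."""

    weights: np.ndarray
    means: np.ndarray        # (C, d)
    covs: np.ndarray         # (C, d, d)
    exact_counts: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        for c in self.covs:
            if not np.allclose(c, c.T) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be symmetric PD")

    def counts(self, n: int) -> np.ndarray:
        """Exact component counts: minor components rounded, the first
        (dominant) component absorbs the remainder."""
        k = np.round(self.weights[1:] * n).astype(int)
        return np.concatenate([[n - k.sum()], k])

    def mean(self) -> np.ndarray:
        return self.weights @ self.means

    def cov(self) -> np.ndarray:
        mu = self.mean()
        second = sum(w * (c + np.outer(m, m)) for w, m, c in
                     zip(self.weights, self.means, self.covs))
        return second - np.outer(mu, mu)


# The bivariate demonstration mixture: 90% main component, two 5%
# contaminants.  Main covariance [[3,1],[1,2]] (Sigma22 = 2 per the
# generating-parameter table).
CONTAMINATED_BIVARIATE_MIXTURE = MixtureSpec(
    weights=[0.9, 0.05, 0.05],
    means=[[10.0, 5.0], [-2.0, 5.0], [10.0, 14.0]],
    covs=[
        [[3.0, 1.0], [1.0, 2.0]],
        [[0.5, 0.1], [0.1, 0.5]],
        [[0.4, -0.1], [-0.1, 0.4]],
    ],
)


def gen_mixture(spec: MixtureSpec, n: int, seed=None,
                return_labels: bool = False):
    """Sample a Gaussian mixture, honoring exact counts, rows shuffled."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if spec.exact_counts:
        counts = spec.counts(n)
    else:
        counts = rng.multinomial(n, spec.weights)
    parts = []
    labels = []
    for ci, (m, c, k) in enumerate(zip(spec.means, spec.covs, counts)):
        parts.append(rng.multivariate_normal(m, c, size=int(k)))
        labels.append(np.full(int(k), ci))
    x = np.vstack(parts)
    lab = np.concatenate(labels)
    perm = rng.permutation(n)
    x, lab = x[perm], lab[perm]
    return (x, lab) if return_labels else x


def gen_contaminated_bivariate(n: int = 100, seed=None,
                           return_labels: bool = False):
    """The contaminated bivariate normal demonstration sample.

    n=100 gives 90/5/5 points from the three components (counts scale
    proportionally for other n, minimum 10).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    return gen_mixture(CONTAMINATED_BIVARIATE_MIXTURE, n, seed=seed,
                       return_labels=return_labels)


NEWCOMB_LIKE_OUTLIERS = (-44.0, -2.0)


def gen_newcomb_like(seed=None) -> np.ndarray:
    """Synthetic 66-value light-speed-style sample with 2 gross outliers.

    64 inliers ~ N(27.75, 5.08^2), matched to the outlier-free moments of
    the historical data, plus the two fixed negative outliers.  Shuffled.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    inliers = rng.normal(27.75, 5.08, size=64)
    sample = np.concatenate([inliers, NEWCOMB_LIKE_OUTLIERS])
    rng.shuffle(sample)
    return sample


def gen_parametric(family: ParametricFamily, theta, n: int,
                   seed=None) -> np.ndarray:
    """Clean i.i.d. draws from f_theta."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return family.sample(family.check_theta(theta), n, rng)
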