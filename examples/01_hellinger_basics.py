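"""Hellinger distance and the minimum-Hellinger functional T.

Builds a small histogram density, measures its Hellinger distance to a
normal, and finds the Hellinger-closest normal by multi-start optimisation.
"""

import math

import numpy as np

from hellbayes import (DataMap, Normal1D, hellinger_distance, make_grid,
                       minimize_hellinger)
from hellbayes.histprior import HistogramDensity

fam = Normal1D()
grid = make_grid((-10, 10), order=12, n_panels=20)

# closed form: h(N(0,1), N(mu,1)) = sqrt(2 - 2 exp(-mu^2/8))
f = lambda x: fam.pdf((0.0, 1.0), x)
g = lambda x: fam.pdf((1.0, 1.0), x)
h = hellinger_distance(f, g, grid)
print(f"h(N(0,1), N(1,1)) = {h:.5f}  (closed form "
      f"{math.sqrt(2 - 2 * math.exp(-1 / 8)):.5f})")

# T(g): the normal closest to a staircase histogram on [0, 1]
hist = HistogramDensity(4, np.array([0.1, 0.2, 0.3, 0.4]), DataMap())
hgrid = make_grid((0, 1), breakpoints=hist.bin_edges_original(), order=8)
res = minimize_hellinger(fam, hist, hgrid)
print(f"T(histogram) = mu {res.theta_hat[0]:.4f}, sigma "
      f"{res.theta_hat[1]:.4f}; achieved distance {res.hellinger:.4f}")
print("The fitted normal concentrates where the histogram puts its mass "
      "(upper bins); the residual distance reflects the staircase shape no "
      "normal can match.")
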