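# hellbayes

Robust *and* efficient Bayesian parameter estimation by combining the
minimum Hellinger distance method with Bayesian nonparametric density
posteriors.

## The problem

Likelihood-based estimates of a parametric model `f_θ` are efficient when
the model is right and fragile when it is not: a handful of gross outliers
drags the normal MLE arbitrarily far. Classical minimum-Hellinger-distance
estimation fixes this by first estimating the density nonparametrically and
then choosing the family member closest in Hellinger distance,

    h(f, g) = [ ∫ (√f − √g)² dx ]^{1/2} = √(2 − 2 ∫ √(f·g) dx),

which rejects isolated contamination while losing no asymptotic precision
at the model. `hellbayes` replaces the classical kernel density with a
**Bayesian nonparametric posterior over densities** and provides two
estimators built on the functional `T(g) = argmin_θ h(f_θ, g)`:

* **MHB** — apply `T` to the expected a posteriori density `g*_n` (a point
  estimate);
* **BMH** — push the whole posterior `π(g | X)` through `T`, giving a
  posterior `π(θ | X) = π(T(g) | X)` over the parameter.

Both achieve the Cramér–Rao bound when the data really come from `f_θ0`
(the BMH posterior satisfies a Bernstein–von-Mises theorem with variance
`I(θ0)^{-1}/n`), and both reject gross errors: under the contamination
model `(1−α) f_θ + α·U(z−ε, z+ε)` the estimates return to `θ` as the
spike location `z` moves out, while the MLE diverges linearly.

Two density posteriors are implemented:

* a **random histogram prior** on `[0,1]` (k equal bins, Dirichlet weights,
  fixed or random k) — fully conjugate, closed-form `g*_n`, cheap draws;
* a **Dirichlet-process mixture of normals** (1-D/2-D) with conjugate
  normal–inverse-Wishart base and hyperpriors, sampled by collapsed Gibbs.

## A worked example

100 bivariate points, 90 from N((10,5), [[3,1],[1,2]]) plus five each from
two contaminating Gaussians at (−2,5) and (10,14):

```python
import numpy as np
from hellbayes import gen_contaminated_bivariate
from hellbayes.pipelines import dpm_bmh_bivariate

x, lab = gen_contaminated_bivariate(100, seed=1, return_labels=True)
post = dpm_bmh_bivariate(x, seed=101)          # DPM Gibbs -> 500 T(g) draws
print(np.round(post.eap, 2), np.round(post.post_sd, 2))
```

Output (order `mu1 mu2 S11 S12 S22`; see `examples/03_bivariate_dpm_bmh.py`):

```
contaminated-sample estimates: [9.53 5.49 9.34 0.74 5.28]
outlier-removed estimates:     [10.18  5.02  2.55  1.09  1.64]
BMH eap (mu1 mu2 S11 S12 S22): [10.18  5.03  2.62  1.07  1.67]
BMH posterior sd:              [0.17 0.15 0.38 0.23 0.24]
```

The raw moments are wrecked by the 10% contamination (S11 is 9.3 instead
of ~3); the BMH posterior lands on the outlier-removed values to within a
few hundredths — without ever seeing the labels.

The `examples/` directory has one short script per capability (Hellinger
basics, histogram-prior robustness on an outlier-laden 1-D sample,
the bivariate demonstration, robustness curves, BvM diagnostics). A thin
CLI mirrors the pipelines:

```sh
hellbayes simulate newcomb-like --seed 3 --out d.csv
hellbayes mhb --data d.csv --k 100 --alpha 0.01
hellbayes robustness --alpha 0.1 --z 2,4,6,8,10 --n 400 --estimator mhb
```

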