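"""Metalog fits for non-Gaussian marginals.

The 2-term metalog is exactly the logistic distribution, so fitting one to
logistic samples recovers location and scale; a 7-term fit can follow a
bimodal mixture closely enough that resampled data is statistically
indistinguishable from the source.
"""

import numpy as np
from scipy.stats import ks_2samp

import hcsim as H

rng = np.random.default_rng(0)
u = rng.uniform(1e-9, 1 - 1e-9, 5000)
logistic = 3.0 + 2.0 * np.log(u / (1 - u))
fit2 = H.metalog_fit(logistic, n_terms=2)
print(f"logistic(3, 2) sample -> a1 = {fit2.coefficients[0]:.3f}, "
      f"a2 = {fit2.coefficients[1]:.3f}  (location and scale)")

comp = rng.uniform(size=5000) < 0.5
bimodal = np.where(comp, rng.normal(-2, 1, 5000), rng.normal(2, 1, 5000))
fit7 = H.metalog_fit(bimodal, n_terms=7)
resampled = H.metalog_sample(fit7, 5000, seed=1)
print(f"bimodal mixture, {fit7.n_terms}-term fit: "
      f"KS(resampled, source) = {ks_2samp(bimodal, resampled).statistic:.3f}")
print("KS well below 0.05 means inverse-transform samples from the fitted "
      "quantile function replicate the two-mode shape.")
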