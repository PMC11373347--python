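"""Why the variance-matching noise step matters for network topology.

Weighted correlation networks (edge weight = squared correlation) built
from noiseless PC reconstructions have inflated clustering coefficients;
adding back per-variable residual noise restores the reference topology.
"""

import numpy as np

import hcsim as H

X, _ = H.generate_hierarchical_blocks(H.default_block_spec(n_samples=500), seed=1)
model = H.hcr_fit(X, f_E=0.9, k=1, g_max=2, seed=1)
sig = np.setdiff1d(np.arange(X.n_variables), model.noise_indices)

cc_ref = H.clustering_coefficient(H.adjacency(X.values[:, sig]))
print(f"reference: median cc = {np.median(cc_ref):.3f}")

for add_noise, label in ((False, "noiseless"), (True, "noisified")):
    sim = H.hcs_simulate(model, variant="normal", seed=7, add_noise=add_noise)
    cc = H.clustering_coefficient(H.adjacency(sim.values[:, sig]))
    ks = H.topology_ks(cc_ref, cc)
    print(f"HCS(n) {label}: median cc = {np.median(cc):.3f}, "
          f"KS vs reference = {ks:.3f}")
print("the noiseless simulation's clustering coefficients are far above the "
      "reference (large KS); the noisified variant sits close to it.")
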