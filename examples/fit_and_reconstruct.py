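"""Fit a hierarchical decomposition and inspect its variance ledger.

Generates a small two-level block-correlated dataset (3 parent modules with
11 child sub-modules, 70% signal variance), fits the decomposition with one
PC per cluster over two levels, and prints what the model explains.
"""

import numpy as np

import hcsim as H

X, truth = H.generate_hierarchical_blocks(H.default_block_spec(n_samples=500), seed=1)
print(f"data: {X.n_samples} samples x {X.n_variables} variables")

model = H.hcr_fit(X, f_E=0.9, k=1, g_max=2, seed=1)
for i, level in enumerate(model.levels, start=1):
    print(f"level {i}: {level.partition.n_clusters} clusters, "
          f"V_E = {level.v_explained_after:.3f}")
print(f"noise subset C0: {len(model.noise_indices)} variables")
print(f"PC accounting: {H.pc_count_summary(model)}")

# the variance ledger is exact: Var(X) = Var(X^R) + Var(E) per variable
XR = H.reconstruct(model)
gap = np.abs(XR.var(axis=0, ddof=1) + model.residual_variances
             - model.original_variances)
print(f"max |Var(X) - Var(X^R) - Var(E)| = {gap.max():.2e}")
print("V_E near 0.7 means the fit recovered the planted signal fraction; "
      "the ledger gap is numerical zero because reconstruction and residual "
      "are orthogonal by construction.")
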