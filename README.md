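# hcsim — hierarchical clustering-based reconstruction and simulation of omics data

Benchmarking feature-selection and machine-learning pipelines on omics data
needs datasets that *look* like real gene-expression matrices — thousands of
correlated variables, modular co-expression structure, heavy noise — but
where the ground truth is known. `hcsim` builds such datasets from a real
(or synthetic) reference in two steps:

**HCR (reconstruction).** Variables are clustered by squared Pearson
correlation (Markov clustering, with very small clusters relegated to a
noise subset C0); each cluster is summarized by its leading *k* principal
components; the residuals E = X − X¹ are clustered again (complete linkage
on 1 − cor(Eᵢ,Eⱼ)², cut at the sub-cluster count maximizing the normalized
entropy of the split) and decomposed again, for *g* levels. Every variable
becomes a linear combination of at most *g·k* PCs,

    Xᵢᴿ = Σ_j βᵢⱼ · PCⱼ ,   Var(Xᵢ) = Var(Xᵢᴿ) + Var(Eᵢ)

and the exact variance ledger above drives the convergence criterion
V_E = Σ Var(Xᴿ) / Σ Var(X).

**HCS (simulation).** The retained PCs' correlation matrix is estimated,
repaired to positive definite, and used to draw *synthetic* PCs — Gaussian
(HCS(n)) or with metalog-fitted marginals coupled by a Gaussian copula
(HCS(f)). Pushing them through the same β coefficients, and adding
per-variable noise with exactly the residual variance, yields new samples
that are statistically independent of the originals while replicating their
correlation structure and weighted-network topology (degree, clustering
coefficient, topological overlap).

## Worked example

```sh
python examples/fit_and_reconstruct.py
```

prints

```
data: 500 samples x 140 variables
level 1: 3 clusters, V_E = 0.467
level 2: 12 clusters, V_E = 0.694
noise subset C0: 7 variables
PC accounting: {'total_pcs': 15, 'max_pcs_per_variable': 2}
max |Var(X) - Var(X^R) - Var(E)| = 1.18e-14
```

The fixture plants 3 parent modules (variance share 0.4) containing 11
child sub-modules (share 0.3) plus pure-noise variables: the fit finds the
3 parents at level 1, the children at level 2, and V_E ≈ 0.7 — the planted
signal fraction — with the per-variable variance ledger exact to machine
precision. `examples/simulate_new_dataset.py` then shows that simulated
data has maximal squared cross-correlation with the reference at the level
of an independent control (≈ 0.03 at n = 500) while the RMSE between the
two correlation matrices is ~5× smaller than the control's, and
`examples/network_topology.py` reproduces the topology contrast: without
the variance-matching noise step the simulated clustering coefficients are
roughly double the reference's; with it they match.

The same flows are scriptable from the shell:

```sh
hcs synth --spec blocks.json --seed 1 --out X.tsv
hcs fit --input X.tsv --fe 0.9 --k 1 --gmax 2 --seed 1 --out model.hcd
hcs simulate --model model.hcd --variant f --seed 7 --out XS.tsv
hcs evaluate --ref X.tsv --query XS.tsv --out metrics.json
```

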