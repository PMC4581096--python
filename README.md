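# bnggm

Inference of gene-regulatory networks from expression data with Gaussian
Bayesian networks, sampled by structure MCMC and optionally *guided* by a
graphical Gaussian model (GGM) through a hierarchical Bayesian prior.

## Who this is for

Systems-biology practitioners who want posterior edge probabilities for a
small-to-moderate regulatory network (tens of genes) from steady-state
expression measurements, and methods researchers who need a clean,
fully-tested reference implementation of BGe-scored structure MCMC, the
GGM-guided Gibbs structure prior with a sampled inverse temperature, and
the accompanying accuracy/convergence evaluation machinery.

## The model

A Bayesian network factorizes the joint density over variables
`X_1, …, X_N` according to a DAG `G`:
`P(X_1,…,X_N) = ∏_i P(X_i | X_{π_i(G)})`.  Structures are scored by the
BGe metric — the closed-form marginal likelihood
`P(D|G) = ∫ P(D|q,G) P(q|G) dq` under a conjugate Normal-Wishart prior —
and sampled by Metropolis-Hastings moves (edge add / delete / reverse)
in DAG space.

The guided sampler (**BNGGM**) additionally estimates, from the same data,
a shrinkage partial-correlation matrix `ρ`, rescales it to
`τ_ik = (|ρ_ik| − min|ρ|)/(max|ρ| − min|ρ|) ∈ [0,1]`, and places a Gibbs
prior over structures

    P(G | β) = exp(−β E(G)) / Z(β),      E(G) = Σ_{i≠k} |τ_ik − g_ik|,

with the inverse temperature `β` sampled under a uniform prior on [0, 30]
via a second Metropolis-Hastings sub-move (the intractable `Z` is replaced
by a polynomial edge-factorized upper bound, consistently in both terms of
the ratio).  Guidance speeds up mixing and convergence of the chain; at
`β = 0` the sampler reduces exactly to the classical flat-prior MCMC.

Accuracy is reported as ROC AUC of the posterior edge probabilities
against a gold-standard network; convergence as `c_rms`, the RMS spread of
two independent chains' paired edge posteriors around the line `y = x`.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from bnggm import (
    benchmark_dag, simulate_gaussian, GaussianSimConfig, compute_tau,
    run_chain, SamplerConfig, edge_posterior, roc_auc, c_rms,
)

dag = benchmark_dag()                       # 10 genes, 12 edges
data = simulate_gaussian(dag, GaussianSimConfig(seed=1))  # 100 obs, sigma^2=0.01
tau = compute_tau(data)                     # GGM guidance from the data itself

guided = run_chain(data, SamplerConfig(n_steps=10_000, mode="bnggm", seed=1), tau=tau)
plain = run_chain(data, SamplerConfig(n_steps=10_000, mode="bn", seed=2))

print("AUC guided :", round(roc_auc(edge_posterior(guided), dag.adjacency), 3))
print("AUC plain  :", round(roc_auc(edge_posterior(plain), dag.adjacency), 3))
```

Output:

```
AUC guided : 1.0
AUC plain  : 0.99
```

Both samplers recover essentially the whole benchmark network from one
simulated data set (AUC 1.0 = perfect ranking of true edges above absent
ones, 0.5 = random).  The advantage of the guided sampler shows up in
convergence: across replicate data sets, the mean final `c_rms` between
two independently initialized guided chains is lower than between two
plain chains at the same number of steps (run the experiment grid below to
measure it).

The same workflow is available from the shell:

```
bnggm simulate --nodes 10 --edges 12 --seed 1 --out-data data.tsv --out-dag dag.tsv
bnggm ggm --in data.tsv --out-tau tau.tsv
bnggm run --data data.tsv --mode bnggm --tau tau.tsv --seed 1 --out trace.npz
bnggm evaluate --trace trace.npz --truth dag.tsv --out report.tsv
bnggm experiment --plan plan.yaml --out results/
```

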