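# Methods

## Problem and model

`bnggm` infers gene-regulatory network structure from steady-state
expression-style data.  The generative model is a Gaussian Bayesian
network: a DAG `G` over variables `X_1..X_N` together with linear-Gaussian
conditionals, so the joint density factorizes as
`P(X_1..X_N) = prod_i P(X_i | X_parents(i))`.  Structures are scored by the
BGe marginal likelihood `P(D|G)` — the integral of the likelihood over a
conjugate Normal-Wishart parameter prior — and the posterior over
structures is explored by Metropolis-Hastings MCMC in DAG space with
single-edge moves (add, delete, reverse) proposed uniformly from the
acyclicity-valid neighborhood, with the `|N(G)|/|N(G')|` Hastings
correction.

The package's core contribution is the guided variant (`bnggm` mode).  A
graphical Gaussian model is fitted to the same data: a Schafer-Strimmer
shrinkage covariance, its inverse, partial correlations
`rho_ik = -C^-1_ik / sqrt(C^-1_ii C^-1_kk)`, and the min-max rescaled
matrix `tau = (|rho| - min|rho|) / (max|rho| - min|rho|)` over off-diagonal
entries.  `tau_ik > 0.5` is soft evidence for an edge between `i` and `k`,
`tau_ik < 0.5` against.  A Gibbs prior over structures,

    P(G | beta) = exp(-beta * E(G)) / Z(beta),
    E(G) = sum_{i != k} |tau_ik - g_ik|,

couples the sampler to this evidence.  The inverse temperature `beta` is a
hyperparameter with a uniform prior on [0, 30], sampled jointly with the
structure: each MCMC step performs one structure sub-move (at fixed beta)
and one beta sub-move (at fixed structure, symmetric reflected uniform
proposal).  At beta = 0 the prior is flat and the guided sampler is
*identical* to the baseline (this is tested bitwise); as beta grows the
prior concentrates on minimum-energy structures.

`Z(beta)` sums over all DAGs and is intractable.  Relaxing acyclicity
makes the sum factorize over the `N(N-1)` directed slots,
`prod_{i != k} [exp(-beta tau_ik) + exp(-beta |tau_ik - 1|)]`, an upper
bound on the true partition function computable in `O(N^2)`.  The same
bound is used in the numerator and denominator of the beta acceptance
ratio, so the approximation enters only through the ratio
`Z_bound(beta)/Z_bound(beta')`.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `edge_weight w` | 1 | linear interaction strength per present edge |
| `noise_variance sigma^2` | 0.01 | dynamic noise of the generator (near-deterministic) |
| `n_samples` | 100 | observations per simulated data set |
| `n_steps` | 10^4 | MCMC steps; one structure (+ one beta) proposal each |
| `thin` | 10 | recording interval; trace length = n_steps / thin |
| `burn_in_fraction` | 0.5 | leading fraction of samples discarded |
| `beta` bounds | [0, 30] | support of the uniform prior on the inverse temperature |
| `beta_half_width` | 0.5 | reflected-uniform proposal half-width |
| `alpha_mu` | 1 | Normal-Wishart mean-precision weight |
| `alpha_w` | N + 2 | Wishart degrees of freedom |
| `T0` | `alpha_mu (alpha_w - N - 1)/(alpha_mu + 1) * I` | parametric prior scale (equivalent-sample-size construction) |
| `mu0` | column means | prior mean vector |

The sub-move interleaving ratio (1:1) and the beta proposal width are
design choices of this package — the hierarchical scheme only requires
that the two sub-moves be iterated — and both are exposed in
`SamplerConfig`.  Chains start from the empty graph with `beta = 0`, the
uninformative end of the prior, so that early exploration is data-driven
and the guidance strength is annealed in by the beta sub-move itself.
This default matters: starting hot (beta drawn uniformly from [0, 30],
also available as `initial_beta="prior"`) lets the orientation-blind
guidance lock arbitrary edge directions into place before the data term
can resolve them, and such chains were observed to dwell in wrongly
oriented near-optimal modes for the whole run.  Both the initial graph
(`run_chain(initial_dag=...)`) and the initial beta are overridable and
seed-controlled.

## Standardization before scoring

Data columns are z-scored inside `BGeScorer` by default
(`BGeHyperparams.standardize`).  The identity-scale Wishart prior above is
calibrated for unit-variance data; with the default generator
(`w = 1, sigma^2 = 0.01`) raw column variances lie in 0.01–0.1, and at
that prior/data scale mismatch the marginal likelihood rewards spurious
parents (empirically, nearly every single spurious addition to the true
benchmark graph raised the raw-data score, and neither sampler could
recover the network).  After per-column standardization the true structure
dominates and both samplers recover it reliably.  Standardization is a
per-column affine map, so likelihood equivalence is untouched; tests that
validate the closed form against numerical integration disable it to score
raw values.

## Synthetic data

`simulate_gaussian` draws nodes in topological order:
`X_i ~ N(sum_parents w * x_k, sigma^2)`, root nodes from `N(0, sigma^2)`
(the empty parent sum).  This is exactly the multivariate Gaussian implied
by the DAG, i.e. the model family the BGe score assumes — passing tests on
it demonstrates correctness of the machinery under a well-specified model,
*not* robustness to the nonlinearity, measurement noise, hidden
confounders or non-Gaussianity of real expression data.  External data is
instead rank-transformed by `quantile_normalize`: value of averaged rank
`r` maps to `Phi^-1((r - 0.5)/n)`.  The half-offset rule is chosen over
`r/n` because the extreme rank would otherwise map to `Phi^-1(1) =
infinity`; it is symmetric, finite, and idempotent on tie-free data.
Constant columns map to 0 with a warning.

The default gold standard is a fixed synthetic 10-gene cascade with 12
edges (`benchmark_dag`); an 11-node consensus Raf-pathway topology
reconstructed from the signalling literature ships as `raf_pathway` for
use with externally produced data.

## Evaluation

Edge posteriors are the element-wise mean of post-burn-in sampled
adjacencies.  Accuracy is ROC AUC over ordered off-diagonal pairs (exact
trapezoid with tied scores grouped); gold standards are treated as
directed by default, with an option to symmetrize the truth so an
undirected edge counts as the superposition of both directions.  The AUC
trajectory re-applies the run protocol prefix-wise: the value at step `s`
is the AUC the run would have produced had it stopped at `s` (first half
of the available samples discarded).

Convergence of two independently seeded chains is summarized by

    c_rms = sqrt( mean_{i != k} (r_a,ik - r_b,ik)^2 / 2 ),

the RMS perpendicular distance of paired edge posteriors from the line
y = x — zero iff the chains agree exactly, bounded by 1/sqrt(2).  Any
monotone variant of this statistic would order samplers identically; the
perpendicular form is the literal "spread around y = x" and is what this
package reports.

## Numerical choices

- All scores, priors and acceptance ratios live in log-space; determinants
  via Cholesky (a non-positive-definite posterior scale raises, never
  returns NaN).
- BGe local scores are cached per (node, parent-set) through a
  subset-marginal cache; cached values are bit-identical to recomputation
  (asserted in tests along whole traces).
- Acyclicity during sampling uses a boolean transitive closure for
  additions and a DFS path test for reversals; every stored sample is
  re-checked acyclic in tests.
- `rescale_tau` requires at least two distinct off-diagonal |rho| values;
  the degenerate all-equal case raises and suggests the uninformative
  fallback `tau = 0.5` everywhere.
- The tau matrix is symmetric: a GGM cannot orient edges, so both
  directions receive identical guidance, and reversal moves are exactly
  prior-neutral.  Guidance therefore accelerates finding the right
  skeleton but contributes nothing to orientation.

## Problem sizes

The shipped experiment grid follows the study conditions end to end:
5 data sets x 2 modes x 2 chains at 10^4 steps on the 10-node benchmark
(~1–2 minutes total).  Exactness checks run 10^5-step chains on 3 nodes
against full 25-DAG enumeration; the beta sub-move is validated against a
1-D quadrature of its conditional density; the BGe closed form is checked
against direct numerical integration of the 1-D and 2-D marginal
likelihood.

## Known limitations

- Sampling is plain single-edge structure MCMC; on near-deterministic
  data individual chains (either mode) can dwell in a wrongly-oriented
  near-optimal mode (a few log units below the best) for many steps,
  which is precisely what the c_rms diagnostic is designed to expose.
  Order-MCMC and the new-edge-reversal move are deliberately out of scope.
- The guidance cuts both ways once beta has risen: it speeds the approach
  to high-scoring regions (its advantage is largest mid-run), but escaping
  a wrong mode through deletion of a strong-tau edge is prior-penalized by
  about `exp(beta * (2 tau - 1))`.  At the default 10-node / 5-data-set
  scale the final-step c_rms comparison between the guided and plain
  samplers is therefore a modest, replicate-dependent effect; the mid-run
  c_rms comparison and the accuracy comparison are the more stable
  summaries, and both are recomputed alongside the final values by
  `scripts/acceptance.py`.
- The partition-function bound relaxes acyclicity; beta values are
  therefore sampled under a slightly misspecified normalizer (consistently
  in all ratios).  The bound is exact at N = 2 and verified to dominate
  the DAG-only sum at N = 3.
- Enumeration-based exactness checks are limited to 4 nodes or fewer.
- GGM guidance is undirected and estimated from the same data being
  analysed; it sharpens and speeds convergence but cannot add information
  the data does not contain.
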