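# graphmr

Total and direct causal networks among complex traits from GWAS summary
statistics.

Pairwise Mendelian randomization (MR) answers "does trait A causally affect
trait B?" using genetic variants as instruments, but the effect it estimates
is the *total* one — direct plus everything mediated through other traits.
`graphmr` implements a two-stage framework for many traits at once:

1. **Total causal graph.** For every ordered pair of traits, a
   constrained-maximum-likelihood MR estimator fits the bivariate model

       (beta_x_i, beta_y_i) ~ N2( (b_Xi, theta b_Xi + r_i),
                                  [[sx_i^2, rho sx_i sy_i],
                                   [rho sx_i sy_i, sy_i^2]] )

   selecting the set of invalid instruments (r_i != 0) by BIC, with the
   correlation `rho` accounting for overlapping GWAS samples. A
   matrix-normal data-perturbation scheme, E ~ MN(0, R, P) over the whole
   SNP-by-trait Z-score matrix (R = SNP LD, P = trait-overlap correlation),
   rebuilds the entire graph on each of B perturbed datasets to get
   standard errors that include model-selection uncertainty.
2. **Direct causal graph.** Network deconvolution inverts
   G_tot = G_dir (I - G_dir)^{-1} as G_dir = G_tot (I + G_tot)^{-1}
   (valid when the direct graph's spectral radius is below 1, cycles
   allowed), with either a zero diagonal ("d0", exact for acyclic graphs)
   or an iteratively estimated diagonal ("d1", for cyclic graphs). Edge
   significance uses Bonferroni at the eigenvalue-based effective number
   of tests.

Everything — estimators, perturbation, deconvolution, the two synthetic
study designs, screening and reporting — is importable from `graphmr`;
a thin `graphmr` command-line wrapper covers the common workflows.
See `docs/methods.md` for the model details and `examples/` for runnable
walkthroughs.

## Worked example

Two traits with a one-way causal effect of 0.2 and fully overlapping GWAS
samples (N = 25000 each):

```python
from graphmr import estimate_rho_null_z, mrcml_dp, select_bic
from graphmr.simulate import PairSimConfig, simulate_pair_overlap

cfg = PairSimConfig(theta=0.2, overlap_frac=1.0, rng_seed=7)
pair, truth = simulate_pair_overlap(cfg)
rho = estimate_rho_null_z(truth["z_null_x"], truth["z_null_y"], None)
sel = select_bic(pair.with_rho(rho))
dp = mrcml_dp(pair.with_rho(rho), B=500, rng_seed=1)
print(f"rho_hat = {rho:.3f}")
print(f"BIC:  theta = {sel.fit.theta:.3f} (SE {sel.se_fisher:.3f}), K_hat = {sel.k_hat}")
print(f"DP:   theta = {dp.theta_dp:.3f} (SE {dp.se_dp:.3f}), p = {dp.pvalue:.2e}")
```

prints

```
rho_hat = 0.652
BIC:  theta = 0.141 (SE 0.040), K_hat = 0
DP:   theta = 0.137 (SE 0.042), p = 1.15e-03
```

`rho_hat` is the estimate correlation induced by the shared participants
(equal to the phenotypic correlation here, since the overlap is complete);
the causal effect is recovered within 1.5 standard errors of the true 0.2
on this single replicate (across 200 replicates the mean estimate is
unbiased to < 0.01), `K_hat = 0` correctly reports no invalid instruments,
and the perturbation SE agrees with the Fisher SE because instrument
selection is stable on these data.

`examples/02_total_and_direct_graph.py` runs the full six-trait pipeline:
simulated summary matrix -> perturbed total graph -> deconvolved direct
graph -> adjusted edge calls.

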