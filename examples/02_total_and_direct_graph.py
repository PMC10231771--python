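"""Full pipeline: six-trait summary matrix -> total graph -> direct graph.

Simulates GWAS summary statistics from a known cyclic direct graph (each
trait with 30-50 strong instruments at biobank-scale standard errors),
estimates the total causal graph under 200 joint matrix-normal
perturbations, deconvolves it into the direct graph with the iterative
diagonal (d1), and calls edges at the eigenvalue-adjusted Bonferroni level.
"""

import numpy as np

from graphmr import (
    assemble_report,
    deconvolve_dp,
    effective_tests,
    estimate_total_graph,
    make_random_direct_graph,
)
from graphmr.simulate import make_graph_sim_config, simulate_graph_summary

D_true = make_random_direct_graph(
    6, edge_density=0.3, effect_range=(0.15, 0.3), allow_cycles=True,
    max_radius=0.6, rng_seed=42,
)
cfg = make_graph_sim_config(D_true, rng_seed=42)
gwas, registry, truth = simulate_graph_summary(cfg)
print("true direct graph (rows = source, cols = target):")
print(np.round(D_true, 2))

total = estimate_total_graph(
    gwas, truth["model"], registry, B=200, rng_seed=7, k_grid=range(0, 16)
)
direct = deconvolve_dp(total, variant="d1")
tests = effective_tests(total.stack, total.zero_mask)
report = assemble_report(total, direct, tests, manifest={"seed": 7})

print(f"\nm_eff = {tests.m_eff:.1f} over {tests.n_edges} edges "
      f"-> adjusted alpha = {tests.alpha_adjusted:.2e}")
print("estimated direct graph:")
print(np.round(direct.effects, 2))
sig = report.significant_direct[report.significant_direct["significant"]]
print(f"\nsignificant direct edges ({len(sig)}):")
for row in sig.itertuples(index=False):
    print(f"  {row.source} -> {row.target}: {row.effect:+.3f} "
          f"(SE {row.se:.3f}, p = {row.pvalue:.1e})")
print(
    f"\nall {total.B} perturbed direct graphs kept spectral radius < 1: "
    f"{direct.frac_radius_ge_1 == 0.0}; d1 converged in "
    f"{100 * direct.d1_converged_per_b.mean():.0f}% of perturbations."
)
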