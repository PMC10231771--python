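"""Bivariate MR with overlapping GWAS samples and invalid instruments.

Simulates individual-level data for an exposure and an outcome measured on
the *same* 25000 people (100% overlap), with 30% of the 20 instruments
carrying correlated pleiotropy, estimates the estimate-correlation rho from
null SNPs, and compares the naive working-independence analysis with the
overlap-aware one.
"""

from graphmr import estimate_rho_null_z, mrcml_dp, select_bic
from graphmr.simulate import PairSimConfig, simulate_pair_overlap

cfg = PairSimConfig(
    theta=0.2, overlap_frac=1.0, frac_invalid=0.3, phi_max=0.01, rng_seed=11
)
pair, truth = simulate_pair_overlap(cfg)

rho = estimate_rho_null_z(truth["z_null_x"], truth["z_null_y"], None)
print(f"estimated rho from {cfg.n_null_snps} null SNPs: {rho:.3f}")
print(f"truly invalid instruments: {sorted(map(int, truth['invalid_idx']))}")

for label, r in [("working independence (rho=0)", 0.0), ("overlap-aware", rho)]:
    sel = select_bic(pair.with_rho(r))
    dp = mrcml_dp(pair.with_rho(r), B=500, rng_seed=3)
    print(
        f"{label:>30}: theta = {dp.theta_dp:+.3f} (DP SE {dp.se_dp:.3f}), "
        f"K_hat = {sel.k_hat}, flagged = {sorted(map(int, sel.fit.invalid_set))}"
    )

print(
    "\nThe true causal effect is 0.2. The overlap-aware fit uses the estimated\n"
    "rho in both the likelihood and the perturbation covariance; the flagged\n"
    "set shows which instruments the BIC selection deems pleiotropic."
)
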