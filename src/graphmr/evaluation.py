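"""Replication studies at desk scale.

These drive the package's own generators through the full estimation
pipelines and summarize operating characteristics (type-I error, bias,
power, spectral-radius diagnostics).  They are used by the test suite and
the reproduction script, and are available to users who want to rerun the
calibration experiments at other settings.
"""

from __future__ import annotations

import numpy as np

from .deconv import deconvolve_dp, spectral_radius, total_from_direct
from .graph_total import effective_tests, estimate_total_graph
from .gwas_data import estimate_rho_null_z
from .pair_inference import mrcml_dp
from .simulate import (
    PairSimConfig,
    make_graph_sim_config,
    make_random_direct_graph,
    simulate_graph_summary,
    simulate_pair_overlap,
)

__all__ = ["pair_overlap_study", "graph_recovery_study", "deconvolution_roundtrip_study"]


def _child_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def pair_overlap_study(
    theta: float,
    overlap_frac: float,
    frac_invalid: float = 0.0,
    phi_max: float = 0.0,
    n_reps: int = 200,
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Replicated two-trait study: data perturbation MR with sample overlap.

    Each replicate simulates individual-level data (20 instruments, MAF
    0.3, strength 0.08, N1 = N2 = 25000 by default), estimates rho from
    the null-SNP Z-scores, and runs the BIC-selected constrained MLE under
    B perturbations.  Returns the empirical rejection rate at ``alpha``
    and the moments of the perturbation point estimates.
    """
    rejections = 0
    estimates = np.empty(n_reps)
    rho_hats = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = PairSimConfig(
            theta=theta,
            overlap_frac=overlap_frac,
            frac_invalid=frac_invalid,
            phi_max=phi_max,
            rng_seed=_child_seed(seed, 1, rep),
        )
        pair, truth = simulate_pair_overlap(cfg)
        rho = estimate_rho_null_z(truth["z_null_x"], truth["z_null_y"], None)
        res = mrcml_dp(pair.with_rho(rho), B=B, rng_seed=_child_seed(seed, 2, rep))
        rejections += res.pvalue < alpha
        estimates[rep] = res.theta_dp
        rho_hats[rep] = rho
    return {
        "n_reps": n_reps,
        "rejection_rate": rejections / n_reps,
        "n_rejections": int(rejections),
        "mean_theta": float(estimates.mean()),
        "sd_theta": float(estimates.std(ddof=1)),
        "bias": float(estimates.mean() - theta),
        "mean_rho_hat": float(rho_hats.mean()),
    }


def graph_recovery_study(
    allow_cycles: bool,
    n_reps: int = 20,
    B: int = 200,
    seed: int = 0,
    n_traits: int = 6,
    edge_density: float = 0.3,
    effect_range: tuple[float, float] = (0.15, 0.3),
    max_radius: float = 0.6,
    n_iv_range: tuple[int, int] = (30, 50),
    k_max: int = 15,
    variant: str = "d1",
    alpha: float = 0.05,
) -> dict:
    """Replicated end-to-end direct-network recovery study.

    Each replicate draws a random direct graph (edge magnitudes in
    ``effect_range``), simulates a summary matrix with strong instruments
    at biobank-scale SEs, runs the perturbed total-graph estimation,
    deconvolves, and tests every free edge at the eigenvalue-adjusted
    Bonferroni level.  Detection rates are pooled over replicates.
    """
    true_hits = true_total = 0
    null_hits = null_total = 0
    radius_ge_1 = 0
    d1_conv = []
    for rep in range(n_reps):
        D = make_random_direct_graph(
            n_traits, edge_density, effect_range=effect_range,
            allow_cycles=allow_cycles, max_radius=max_radius,
            rng_seed=_child_seed(seed, 10, rep),
        )
        cfg = make_graph_sim_config(
            D, n_iv_range=n_iv_range, rng_seed=_child_seed(seed, 11, rep)
        )
        gwas, registry, truth = simulate_graph_summary(cfg)
        total = estimate_total_graph(
            gwas, truth["model"], registry, B=B,
            rng_seed=_child_seed(seed, 12, rep), k_grid=range(0, k_max + 1),
        )
        direct = deconvolve_dp(total, variant=variant)
        tests = effective_tests(total.stack, total.zero_mask, alpha=alpha)
        sig = direct.pvalues < tests.alpha_adjusted
        off = ~np.eye(n_traits, dtype=bool)
        true_edges = (D != 0) & off
        null_edges = (D == 0) & off
        true_hits += int(sig[true_edges].sum())
        true_total += int(true_edges.sum())
        null_hits += int(sig[null_edges].sum())
        null_total += int(null_edges.sum())
        radius_ge_1 += int(np.nanmax(direct.spectral_radius_per_b) >= 1)
        d1_conv.append(float(direct.d1_converged_per_b.mean()))
    return {
        "n_reps": n_reps,
        "true_edge_detection": true_hits / max(true_total, 1),
        "null_edge_rejection": null_hits / max(null_total, 1),
        "n_true_edges": true_total,
        "n_null_edges": null_total,
        "n_reps_with_radius_ge_1": radius_ge_1,
        "mean_d1_convergence": float(np.mean(d1_conv)),
    }


def deconvolution_roundtrip_study(
    n_graphs: int = 500, n_traits: int = 6, max_radius: float = 0.9, seed: int = 0
) -> dict:
    """Round-trip error of deconvolution over random direct graphs."""
    from .deconv import deconvolve_d0, deconvolve_d1

    max_err_d0 = 0.0
    max_err_d1 = 0.0
    n_d1_converged = 0
    for k in range(n_graphs):
        D = make_random_direct_graph(
            n_traits, 0.4, effect_range=(0.05, 0.3), allow_cycles=True,
            max_radius=max_radius, rng_seed=_child_seed(seed, 20, k),
        )
        T = total_from_direct(D)
        max_err_d0 = max(max_err_d0, float(np.max(np.abs(deconvolve_d0(T) - D))))
        T_off = T.copy()
        np.fill_diagonal(T_off, 0.0)
        D1, t_diag, conv = deconvolve_d1(T_off)
        if conv:
            n_d1_converged += 1
            max_err_d1 = max(max_err_d1, float(np.max(np.abs(D1 - D))))
    return {
        "n_graphs": n_graphs,
        "max_roundtrip_error_d0": max_err_d0,
        "max_roundtrip_error_d1_converged": max_err_d1,
        "n_d1_converged": n_d1_converged,
    }
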