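"""Network deconvolution: total causal graph -> direct causal graph.

Under linear causal relations, the total-effect matrix G_tot (entry
(i, j) = total effect of trait i on trait j) and the direct-effect matrix
G_dir satisfy

    G_tot = G_dir + G_dir^2 + G_dir^3 + ... = G_dir (I - G_dir)^{-1},

the series converging iff the spectral radius of G_dir is below 1, hence

    G_dir = G_tot (I + G_tot)^{-1}.

Only off-diagonal totals are estimable by pairwise MR.  The d0 policy
sets the unknown diagonal of G_tot to zero (exact when the direct graph
is acyclic); the d1 policy estimates the diagonal from the cycle identity
T_ii = sum_{j != i} D_ij T_ji by alternating it with the inversion until
the diagonal stabilizes, falling back to the initial completion
T_ii = sum_{j != i} T_ij T_ji when the sweep does not converge.
No scaling, thresholding, or symmetrization is applied; the matrix in the
inversion step is inverted directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import InferenceUnreliableError, ParameterError
from .graph_total import TotalGraph

__all__ = [
    "DirectGraph",
    "total_from_direct",
    "deconvolve_d0",
    "deconvolve_d1",
    "spectral_radius",
    "deconvolve_dp",
]


@dataclass
class DirectGraph:
    """T x T direct causal effects with per-perturbation diagnostics."""

    traits: list[str]
    effects: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    stack: np.ndarray
    spectral_radius_per_b: np.ndarray
    frac_radius_ge_1: float
    variant: str
    d1_converged_per_b: np.ndarray
    zero_mask: np.ndarray
    t_diag: np.ndarray | None = None  # mean estimated total-graph diagonal (d1)


def spectral_radius(M: np.ndarray) -> float:
    """Largest modulus over all (possibly complex) eigenvalues."""
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ParameterError("spectral_radius: non-finite entries")
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def total_from_direct(D: np.ndarray) -> np.ndarray:
    """Total-effect matrix D (I - D)^{-1}; requires spectral radius < 1."""
    D = np.asarray(D, dtype=float)
    if spectral_radius(D) >= 1:
        raise ParameterError(
            "total_from_direct: spectral radius >= 1, the effect series diverges"
        )
    t = D.shape[0]
    return D @ np.linalg.inv(np.eye(t) - D)


def deconvolve_d0(T_tot: np.ndarray) -> np.ndarray:
    """Direct effects G_tot (I + G_tot)^{-1} with the matrix as given.

    Callers following the d0 policy pass a zero diagonal; when the true
    diagonal is supplied the inversion recovers the direct graph exactly.
    """
    T_tot = np.asarray(T_tot, dtype=float)
    t = T_tot.shape[0]
    A = np.eye(t) + T_tot
    try:
        return T_tot @ np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("deconvolve_d0: I + G_tot is singular") from exc


def deconvolve_d1(
    T_offdiag: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Deconvolution with iterative estimation of the total-graph diagonal.

    Initializes T_ii = sum_{j != i} T_ij T_ji, then alternates
    (a) D = G_tot (I + G_tot)^{-1} on the completed matrix and
    (b) T_ii = sum_{j != i} D_ij T_ji,
    stopping when the diagonal moves by less than ``tol``.  On
    non-convergence (or a singular iterate) the initial-diagonal solution
    is returned with ``converged=False``.  The returned D has its diagonal
    forced to exactly zero (no self-loops by assumption).
    """
    T_off = np.asarray(T_offdiag, dtype=float).copy()
    t = T_off.shape[0]
    np.fill_diagonal(T_off, 0.0)

    t_init = np.einsum("ij,ji->i", T_off, T_off)  # sum_{j != i} T_ij T_ji

    def solve(diag):
        M = T_off.copy()
        M[np.diag_indices(t)] = diag
        D = deconvolve_d0(M)
        np.fill_diagonal(D, 0.0)
        return D

    t_diag = t_init.copy()
    try:
        for _ in range(max_iter):
            D = solve(t_diag)
            t_new = np.einsum("ij,ji->i", D, T_off)
            if np.max(np.abs(t_new - t_diag)) < tol:
                return solve(t_new), t_new, True
            t_diag = t_new
    except ParameterError:
        pass  # singular iterate: fall back below
    try:
        return solve(t_init), t_init, False
    except ParameterError as exc:
        raise ParameterError("deconvolve_d1: initial completion is singular") from exc


def deconvolve_dp(
    total: TotalGraph,
    variant: str = "d1",
    tol: float = 1e-8,
    max_iter: int = 1000,
    max_fail_frac: float = 0.2,
) -> DirectGraph:
    """Deconvolve every perturbed total graph and summarize elementwise.

    Each slice of ``total.stack`` (masked edges kept at 0) is deconvolved
    with the chosen variant; per-slice spectral radius and (for d1)
    convergence are recorded, along with the fraction of slices whose
    direct graph has spectral radius >= 1.  Effects/SEs are the
    elementwise mean/SD over successful slices with two-sided normal
    p-values; masked edges are re-zeroed after inversion so constraints
    survive deconvolution.
    """
    if variant not in ("d0", "d1"):
        raise ParameterError(f"variant must be 'd0' or 'd1', got {variant!r}")
    B, t, _ = total.stack.shape
    zero_mask = total.zero_mask
    stack = np.full((B, t, t), np.nan)
    radius = np.full(B, np.nan)
    d1_conv = np.ones(B, dtype=bool)
    t_diag_acc = np.zeros((B, t))
    n_failed = 0
    for b in range(B):
        T_b = total.stack[b].copy()
        if np.isnan(T_b).any():
            n_failed += 1
            continue
        np.fill_diagonal(T_b, 0.0)
        try:
            if variant == "d0":
                D = deconvolve_d0(T_b)
                np.fill_diagonal(D, 0.0)
                t_diag_acc[b] = 0.0
            else:
                D, t_diag_b, conv = deconvolve_d1(T_b, tol=tol, max_iter=max_iter)
                d1_conv[b] = conv
                t_diag_acc[b] = t_diag_b
        except ParameterError:
            n_failed += 1
            continue
        D[zero_mask] = 0.0
        stack[b] = D
        radius[b] = spectral_radius(D)
    if n_failed > max_fail_frac * B:
        raise InferenceUnreliableError(
            f"{n_failed}/{B} perturbed deconvolutions failed"
        )

    ok = ~np.isnan(radius)
    frac_ge_1 = float(np.mean(radius[ok] >= 1)) if ok.any() else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        effects = np.nanmean(stack, axis=0)
        se = np.nanstd(stack, axis=0, ddof=1)
    free = ~zero_mask & ~np.eye(t, dtype=bool)
    effects[~free] = 0.0
    se[~free] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, effects / se, 0.0)
    pvalues = 2.0 * norm.sf(np.abs(z))
    pvalues[se == 0] = np.where(effects[se == 0] == 0, 1.0, 0.0)
    pvalues[~free] = 1.0
    return DirectGraph(
        traits=list(total.traits),
        effects=effects,
        se=se,
        pvalues=pvalues,
        stack=stack,
        spectral_radius_per_b=radius,
        frac_radius_ge_1=frac_ge_1,
        variant=variant,
        d1_converged_per_b=d1_conv,
        zero_mask=zero_mask,
        t_diag=t_diag_acc[ok].mean(axis=0) if ok.any() else None,
    )
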