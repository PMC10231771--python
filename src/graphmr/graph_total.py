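"""Joint perturbation of the SNP-by-trait matrix and the total causal graph.

The T-trait extension perturbs the whole Z-score matrix at once with
matrix-normal noise E ~ MN(0, R, P): R is the SNP-side LD correlation and
P the trait-side correlation from overlapping GWAS samples, so
vec(E) ~ N(0, P kron R).  This captures, in one draw, both the reuse of
each trait across many pairs and LD between the instrument sets of
different pairs.  Each perturbed matrix is analyzed by bidirectional
BIC-selected constrained-ML MR on every unmasked ordered pair, and the
per-perturbation graphs are summarized elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.stats import norm

from .cml_core import _select_bic_batch
from .exceptions import ParameterError
from .gwas_data import (
    GwasMatrix,
    IVRegistry,
    LDStructure,
    TraitCorrelation,
    repair_psd,
)

__all__ = [
    "PerturbationModel",
    "TotalGraph",
    "EdgeTestSummary",
    "sample_noise",
    "perturb_gwas_matrix",
    "estimate_total_graph",
    "effective_tests",
    "li_ji_meff",
]


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Square-root factor L with L L^T = M (after PSD repair), via eigh."""
    M = repair_psd(M)
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


@dataclass
class PerturbationModel:
    """Factorized matrix-normal noise model MN(0, R, P).

    The Kronecker covariance P kron R is never formed: separate factors
    L_P and L_R (L L^T reconstructing each matrix to < 1e-8 after PSD
    repair) let an m x T draw be computed as L_R V L_P^T with V iid
    standard normal, which is algebraically identical to drawing vec(E)
    with covariance P kron R.
    """

    P: TraitCorrelation
    R: LDStructure
    factor_P: np.ndarray = field(init=False)
    factor_R: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.factor_P = _psd_factor(self.P.P)
        self.factor_R = _psd_factor(self.R.R)
        for factor, target, name in (
            (self.factor_P, self.P.P, "P"),
            (self.factor_R, self.R.R, "R"),
        ):
            err = np.max(np.abs(factor @ factor.T - repair_psd(target)))
            if err >= 1e-8:
                raise ParameterError(f"factorization of {name} failed (error {err:.2e})")


def sample_noise(model: PerturbationModel, rng_seed) -> np.ndarray:
    """Draw one m x T matrix-normal noise matrix E ~ MN(0, R, P)."""
    rng = np.random.default_rng(rng_seed)
    m = model.factor_R.shape[0]
    t = model.factor_P.shape[0]
    V = rng.standard_normal((m, t))
    return model.factor_R @ V @ model.factor_P.T


def _sample_noise_stack(model: PerturbationModel, B: int, rng) -> np.ndarray:
    """B independent matrix-normal draws, shape (B, m, T)."""
    m = model.factor_R.shape[0]
    t = model.factor_P.shape[0]
    V = rng.standard_normal((B, m, t))
    return np.einsum("ij,bjk,lk->bil", model.factor_R, V, model.factor_P, optimize=True)


def perturb_gwas_matrix(gwas: GwasMatrix, model: PerturbationModel, rng_seed) -> GwasMatrix:
    """Perturb observed cells of the GWAS matrix: B(b) = (Z + E(b)) * S.

    Noise is generated for the full m x T grid but applied only to
    observed cells, so the joint covariance of the observed cells is
    exactly as specified; S and the missingness mask are unchanged.
    """
    E = sample_noise(model, rng_seed)
    obs = gwas.observed
    B_new = gwas.B_hat.copy()
    B_new[obs] = (gwas.Z[obs] + E[obs]) * gwas.S[obs]
    return GwasMatrix(
        list(gwas.snp_ids), list(gwas.trait_names),
        B_new, gwas.S.copy(), gwas.n_by_trait.copy(),
    )


@dataclass
class TotalGraph:
    """T x T total causal effects with per-edge perturbation inference.

    Entry (i, j) is the total effect of trait i on trait j.  ``stack``
    holds the per-perturbation estimates (NaN where a fit failed);
    ``effects``/``se`` are the elementwise mean/SD over successes and
    masked or diagonal entries are exactly 0 with p-value 1.
    """

    traits: list[str]
    effects: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    stack: np.ndarray
    zero_mask: np.ndarray
    n_failed: np.ndarray
    diag_policy: str = "d0"

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def B(self) -> int:
        return self.stack.shape[0]

    def free_edges(self) -> np.ndarray:
        """Boolean T x T mask of estimated (unmasked, off-diagonal) edges."""
        t = self.n_traits
        return ~self.zero_mask & ~np.eye(t, dtype=bool)


@dataclass
class EdgeTestSummary:
    """Effective number of independent edge tests and the adjusted level."""

    m_eff: float
    alpha: float
    alpha_adjusted: float
    n_edges: int


def estimate_total_graph(
    gwas: GwasMatrix,
    model: PerturbationModel,
    ivs: IVRegistry,
    zero_mask: np.ndarray | None = None,
    B: int = 2000,
    rng_seed=None,
    k_grid=None,
    n_starts: int = 1,
    tol: float = 1e-7,
    max_iter: int = 200,
    max_fail_frac: float = 0.2,
) -> TotalGraph:
    """Estimate the total causal graph under B joint matrix perturbations.

    For each perturbation, every unmasked ordered pair (i, j) is fit by
    BIC-selected constrained MLE using the registry's instruments for the
    pair and rho = P[i, j]; effects and SEs are the elementwise mean and
    SD of the per-perturbation stack, with two-sided normal p-values.
    All noise is drawn up front from one seeded stream, so results do not
    depend on the order in which pairs are processed.
    """
    t = gwas.n_traits
    if model.factor_R.shape[0] != gwas.m or model.factor_P.shape[0] != t:
        raise ParameterError("perturbation model dimensions do not match the GWAS matrix")
    if zero_mask is None:
        zero_mask = np.zeros((t, t), dtype=bool)
    zero_mask = np.asarray(zero_mask, dtype=bool)
    ivs.validate_against(gwas)

    rng = np.random.default_rng(rng_seed)
    E = _sample_noise_stack(model, B, rng)          # (B, m, T)
    Z = gwas.Z
    S = gwas.S

    stack = np.full((B, t, t), np.nan)
    n_failed = np.zeros((t, t), dtype=int)
    free = ~zero_mask & ~np.eye(t, dtype=bool)
    for i in range(t):
        for j in range(t):
            if not free[i, j]:
                continue
            key = (gwas.trait_names[i], gwas.trait_names[j])
            rows = np.asarray(ivs[key], dtype=int)
            if rows.size < 3:
                raise ParameterError(f"pair {key}: fewer than 3 registered instruments")
            sx, sy = S[rows, i], S[rows, j]
            bx = (Z[rows, i] + E[:, rows, i]) * sx
            by = (Z[rows, j] + E[:, rows, j]) * sy
            rho = float(model.P.P[i, j])
            n_eff = int(min(gwas.n_by_trait[i], gwas.n_by_trait[j]))
            pair_rng = np.random.SeedSequence(
                [0 if rng_seed is None else int(rng_seed), 7, i, j]
            )
            theta, _, _, conv = _select_bic_batch(
                bx, sx, by, sy, rho, n_eff,
                k_grid=k_grid, n_starts=n_starts, rng=pair_rng,
                tol=tol, max_iter=max_iter,
            )
            stack[:, i, j] = np.where(conv, theta, np.nan)
            n_failed[i, j] = int(B - conv.sum())
            if n_failed[i, j] > max_fail_frac * B:
                warnings.warn(
                    f"pair {key}: {n_failed[i, j]}/{B} perturbation fits failed",
                    stacklevel=2,
                )

    stack[:, ~free] = np.where(np.isnan(stack[:, ~free]), 0.0, stack[:, ~free])
    stack[:, zero_mask] = 0.0
    for d in range(t):
        stack[:, d, d] = 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        effects = np.nanmean(stack, axis=0)
        se = np.nanstd(stack, axis=0, ddof=1)
    effects[~free] = 0.0
    se[~free] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = np.where(se > 0, effects / se, 0.0)
    pvalues = 2.0 * norm.sf(np.abs(zscores))
    pvalues[~free] = 1.0
    pvalues[se == 0] = np.where(effects[se == 0] == 0, 1.0, 0.0)
    pvalues[~free] = 1.0
    return TotalGraph(
        list(gwas.trait_names), effects, se, pvalues, stack, zero_mask, n_failed
    )


def li_ji_meff(eigvals: np.ndarray) -> float:
    """Effective number of independent tests from correlation eigenvalues.

    Each eigenvalue contributes I(lambda >= 1) + (lambda - floor(lambda)).
    Eigenvalues within 1e-9 of an integer are snapped to it first: floor()
    is discontinuous there and eigensolver noise would otherwise flip a
    whole unit of the count (e.g. rank-one correlation matrices).
    """
    lam = np.abs(np.asarray(eigvals, dtype=float))
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) < 1e-9, near, lam)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def effective_tests(
    stack: np.ndarray,
    zero_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> EdgeTestSummary:
    """Bonferroni adjustment with the effective number of independent tests.

    Flattens the unmasked off-diagonal edges of the B x T x T stack into a
    B x E matrix, takes the eigenvalues of its correlation matrix, and
    applies the Li-Ji estimator; constant edge columns are dropped with a
    warning.  m_eff is clipped to [1, E].
    """
    stack = np.asarray(stack, dtype=float)
    B, t, _ = stack.shape
    if B < 100:
        raise ParameterError("need at least 100 perturbations to estimate m_eff")
    if zero_mask is None:
        zero_mask = np.zeros((t, t), dtype=bool)
    free = ~np.asarray(zero_mask, dtype=bool) & ~np.eye(t, dtype=bool)
    X = stack[:, free]                     # (B, E)
    n_edges = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(X, axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} constant edge column(s) from m_eff")
        X = X[:, keep]
    if X.shape[1] == 0:
        return EdgeTestSummary(1.0, alpha, alpha, n_edges)
    # pairwise-complete correlation; NaNs only arise from failed fits
    if np.isnan(X).any():
        import pandas as pd

        C = pd.DataFrame(X).corr().to_numpy()
    else:
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    lam = np.linalg.eigvalsh(0.5 * (C + C.T))
    m_eff = li_ji_meff(lam)
    m_eff = float(min(max(m_eff, 1.0), n_edges))
    return EdgeTestSummary(m_eff, alpha, alpha / m_eff, n_edges)
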