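"""Generators for the two study designs used throughout the package.

``simulate_pair_overlap`` builds individual-level two-trait data with a
configurable fraction of shared participants between the exposure and
outcome GWAS: a confounder U loads on both traits, instruments act on the
exposure, and invalid instruments get direct (uncorrelated, alpha) and/or
confounder-mediated (correlated, phi) pleiotropic effects.  Marginal
per-SNP GWAS estimates are computed by closed-form simple regression on
the two (overlapping) sample windows, and a panel of null SNPs provides
Z-scores for estimating the between-study correlation rho.

``simulate_graph_summary`` builds multi-trait GWAS summary matrices from
a direct causal graph: each SNP's direct effect on its assigned trait
propagates along all directed paths, B = Gamma (I - D)^{-1}, and the
estimates are B + S * E with matrix-normal noise E ~ MN(0, R, P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deconv import spectral_radius, total_from_direct
from .exceptions import SimulationConfigError
from .graph_total import PerturbationModel, _sample_noise_stack
from .gwas_data import GwasMatrix, IVRegistry, LDStructure, SummaryPair, TraitCorrelation

__all__ = [
    "PairSimConfig",
    "GraphSimConfig",
    "simulate_pair_overlap",
    "simulate_graph_summary",
    "make_random_direct_graph",
    "make_graph_sim_config",
    "implied_rho",
]


@dataclass
class PairSimConfig:
    """Generative parameters for the two-trait overlapping-sample design.

    Defaults reproduce the reference design: 20 instruments of strength
    0.08 at MAF 0.3, GWAS sample sizes 25000 each, uncorrelated pleiotropy
    alpha ~ N(0.04, 0.05^2) and correlated pleiotropy phi ~ Unif(0, phi_max)
    on the invalid fraction, unit confounder loadings, and 1000 null SNPs
    for estimating rho.
    """

    m_iv: int = 20
    maf: float = 0.3
    gamma: float = 0.08
    frac_invalid: float = 0.0
    alpha_mean: float = 0.04
    alpha_sd: float = 0.05
    phi_max: float = 0.0
    theta: float = 0.0
    n1: int = 25000
    n2: int = 25000
    overlap_frac: float = 0.0
    n_null_snps: int = 1000
    beta_xu: float = 1.0
    beta_yu: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_frac <= 1.0):
            raise SimulationConfigError("overlap_frac must lie in [0, 1]")
        if not (0.0 < self.maf <= 0.5):
            raise SimulationConfigError("maf must lie in (0, 0.5]")
        if self.alpha_sd < 0:
            raise SimulationConfigError("alpha_sd must be >= 0")
        if not (0.0 <= self.frac_invalid < 1.0):
            raise SimulationConfigError("frac_invalid must lie in [0, 1)")
        self.n0 = int(round(self.overlap_frac * min(self.n1, self.n2)))
        if self.n1 - self.n0 + self.n2 > self.n1 + self.n2:
            raise SimulationConfigError("overlap window exceeds available individuals")


# reusable genotype-matrix buffers, keyed by shape: replicate loops would
# otherwise pay large-allocation page faults on every call
_GENO_BUFFERS: dict[tuple, tuple] = {}


def _binomial2(rng: np.random.Generator, maf: float, shape) -> np.ndarray:
    """Genotype draws Binomial(2, maf) via the inverse CDF of one uniform.

    Returns a float32 matrix (0/1/2 are exact in float32, and all
    downstream sums stay below the float32 exact-integer range).
    """
    shape = tuple(shape)
    if shape not in _GENO_BUFFERS:
        if len(_GENO_BUFFERS) > 2:
            _GENO_BUFFERS.clear()
        _GENO_BUFFERS[shape] = (
            np.empty(shape, np.float32),
            np.empty(shape, bool),
            np.empty(shape, np.uint8),
            np.empty(shape, np.float32),
        )
    u, b, g8, G = _GENO_BUFFERS[shape]
    p0 = np.float32((1.0 - maf) ** 2)
    p01 = np.float32((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))
    rng.random(dtype=np.float32, out=u)
    np.greater(u, p0, out=b)
    np.copyto(g8, b, casting="unsafe")
    np.greater(u, p01, out=b)
    np.add(g8, b, out=g8)
    np.copyto(G, g8, casting="unsafe")
    return G


def _marginal_regressions(G: np.ndarray, y: np.ndarray):
    """Per-SNP simple linear regression of y on each genotype column.

    Closed-form slope, SE and normal p-value, vectorized across SNPs.
    """
    from scipy.stats import norm

    n = y.shape[0]
    y32 = y.astype(np.float32)
    sg = G.sum(axis=0, dtype=np.float64)
    sgg = np.einsum("ij,ij->j", G, G).astype(np.float64)
    sy = float(y.sum())
    syy = float(y @ y)
    sgy = (G.T @ y32).astype(np.float64)
    sxx = sgg - sg * sg / n
    sxy = sgy - sg * sy / n
    syy_c = syy - sy * sy / n
    beta = sxy / sxx
    rss = np.maximum(syy_c - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    z = beta / se
    pval = 2.0 * norm.sf(np.abs(z))
    return beta, se, pval


def simulate_pair_overlap(cfg: PairSimConfig) -> tuple[SummaryPair, dict]:
    """Generate one two-trait summary dataset with overlapping samples.

    The exposure GWAS uses individuals [0, n1); the outcome GWAS uses the
    shifted window [n1 - n0, n1 - n0 + n2), overlapping in n0 individuals.
    Returns the instrument-level SummaryPair (rho unset) and a truth
    record with the causal effect, the invalid-instrument index set, the
    true marginal instrument effects b_X = gamma + beta_XU * phi, and the
    null-SNP Z-scores for estimating rho.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n0 = cfg.n0
    n_tot = cfg.n1 + cfg.n2 - n0
    m = cfg.m_iv
    m_tot = m + cfg.n_null_snps

    n_invalid = int(round(cfg.frac_invalid * m))
    invalid_idx = np.arange(n_invalid)
    alpha = np.zeros(m)
    phi = np.zeros(m)
    if n_invalid:
        alpha[invalid_idx] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=n_invalid)
        if cfg.phi_max > 0:
            phi[invalid_idx] = rng.uniform(0.0, cfg.phi_max, size=n_invalid)

    G = _binomial2(rng, cfg.maf, (n_tot, m_tot))
    G_iv = G[:, :m]
    U = G_iv @ phi + rng.standard_normal(n_tot)
    X = G_iv @ np.full(m, cfg.gamma) + cfg.beta_xu * U + rng.standard_normal(n_tot)
    Y = cfg.theta * X + G_iv @ alpha + cfg.beta_yu * U + rng.standard_normal(n_tot)

    rows_x = slice(0, cfg.n1)
    rows_y = slice(cfg.n1 - n0, cfg.n1 - n0 + cfg.n2)
    beta_x, se_x, pval_x = _marginal_regressions(G[rows_x], X[rows_x])
    beta_y, se_y, pval_y = _marginal_regressions(G[rows_y], Y[rows_y])

    snp_ids = [f"iv{i:04d}" for i in range(m)] + [
        f"null{i:04d}" for i in range(cfg.n_null_snps)
    ]
    pair = SummaryPair(
        snp_ids[:m],
        beta_x[:m], se_x[:m], beta_y[:m], se_y[:m],
        float("nan"), cfg.n1, cfg.n2,
    )
    truth = {
        "theta": cfg.theta,
        "invalid_idx": invalid_idx,
        "b_x_true": cfg.gamma + cfg.beta_xu * phi,
        "r_true": cfg.beta_yu * phi + alpha,
        "alpha": alpha,
        "phi": phi,
        "z_null_x": beta_x[m:] / se_x[m:],
        "z_null_y": beta_y[m:] / se_y[m:],
        "pval_x": pval_x[:m],
        "pval_y": pval_y[:m],
        "n0": n0,
    }
    return pair, truth


def implied_rho(cfg: PairSimConfig, truth: dict) -> float:
    """Model-implied estimate correlation (N0 / sqrt(N1 N2)) * corr(X, Y).

    The phenotypic moments follow from the generative structural
    equations with the realized pleiotropy draws in ``truth``.
    """
    vg = 2.0 * cfg.maf * (1.0 - cfg.maf)
    phi, alpha = truth["phi"], truth["alpha"]
    b_x = cfg.gamma + cfg.beta_xu * phi
    b_y = cfg.theta * b_x + cfg.beta_yu * phi + alpha
    # residual (non-genetic) loadings: X gets beta_xu*eU + eX; Y gets
    # (theta*beta_xu + beta_yu)*eU + theta*eX + eY
    var_x = float(np.sum(b_x**2) * vg + cfg.beta_xu**2 + 1.0)
    ay_u = cfg.theta * cfg.beta_xu + cfg.beta_yu
    var_y = float(np.sum(b_y**2) * vg + ay_u**2 + cfg.theta**2 + 1.0)
    cov = float(np.sum(b_x * b_y) * vg + cfg.beta_xu * ay_u + cfg.theta)
    r_xy = cov / np.sqrt(var_x * var_y)
    return truth["n0"] / np.sqrt(cfg.n1 * cfg.n2) * r_xy


@dataclass
class GraphSimConfig:
    """Generative parameters for the multi-trait summary-matrix design."""

    D_true: np.ndarray
    iv_effects: np.ndarray            # m x T direct SNP-to-trait effects Gamma
    S: np.ndarray                     # m x T standard errors
    P: TraitCorrelation
    R: LDStructure
    trait_names: list[str] = field(default_factory=list)
    n_by_trait: np.ndarray | None = None
    frac_invalid_per_pair: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.D_true = np.asarray(self.D_true, dtype=float)
        self.iv_effects = np.asarray(self.iv_effects, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        t = self.D_true.shape[0]
        if np.any(np.diag(self.D_true) != 0):
            raise SimulationConfigError("D_true must have a zero diagonal")
        if spectral_radius(self.D_true) >= 1:
            raise SimulationConfigError("spectral radius of D_true must be < 1")
        if np.any(self.S <= 0):
            raise SimulationConfigError("S must be strictly positive")
        if not self.trait_names:
            self.trait_names = [f"T{i}" for i in range(t)]
        if self.n_by_trait is None:
            self.n_by_trait = np.full(t, 200_000)
        self.n_by_trait = np.asarray(self.n_by_trait, dtype=int)


def simulate_graph_summary(cfg: GraphSimConfig) -> tuple[GwasMatrix, IVRegistry, dict]:
    """Generate a SNP-by-trait summary matrix from a direct causal graph.

    True marginal effects propagate along all directed paths,
    B = Gamma (I - D)^{-1}; estimates add matrix-normal noise scaled by S.
    The registry assigns each ordered pair the instruments of the source
    trait (the SNPs whose primary Gamma entry is on that trait).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    Gamma = cfg.iv_effects
    m, t = Gamma.shape
    D = cfg.D_true
    M = np.linalg.inv(np.eye(t) - D)
    B_true = Gamma @ M
    model = PerturbationModel(cfg.P, cfg.R)
    E = _sample_noise_stack(model, 1, rng)[0]
    B_hat = B_true + cfg.S * E

    assignment = np.argmax(np.abs(Gamma), axis=1)
    snp_ids = [f"snp{i:05d}" for i in range(m)]
    gwas = GwasMatrix(snp_ids, list(cfg.trait_names), B_hat, cfg.S.copy(), cfg.n_by_trait)
    pairs = {}
    for i in range(t):
        rows = list(np.flatnonzero(assignment == i))
        for j in range(t):
            if i != j:
                pairs[(cfg.trait_names[i], cfg.trait_names[j])] = rows
    registry = IVRegistry(pairs)
    truth = {
        "D_true": D,
        "G_tot": total_from_direct(D),
        "B_true": B_true,
        "assignment": assignment,
        "model": model,
    }
    return gwas, registry, truth


def make_graph_sim_config(
    D_true: np.ndarray,
    n_iv_range: tuple[int, int] = (30, 50),
    n_gwas: int = 200_000,
    beta_range: tuple[float, float] = (0.02, 0.05),
    p_overlap: float = 0.3,
    n_overlap_pairs: int = 2,
    frac_invalid_per_trait: float = 0.0,
    pleiotropy_scale: float = 0.02,
    rng_seed: int | None = None,
) -> GraphSimConfig:
    """Assemble a realistic desk-scale configuration around a direct graph.

    Each trait gets a uniform number of instruments in ``n_iv_range`` with
    signed effects in ``beta_range`` (strongly significant at GWAS sample
    size ``n_gwas``, where SEs are ~1/sqrt(n)); ``n_overlap_pairs``
    consecutive trait pairs share samples with estimate correlation
    ``p_overlap``.  ``frac_invalid_per_trait`` of each trait's instruments
    get an extra pleiotropic effect on one random other trait.
    """
    rng = np.random.default_rng(rng_seed)
    D_true = np.asarray(D_true, dtype=float)
    t = D_true.shape[0]
    counts = rng.integers(n_iv_range[0], n_iv_range[1] + 1, size=t)
    m = int(counts.sum())
    Gamma = np.zeros((m, t))
    row = 0
    for i in range(t):
        k = counts[i]
        mags = rng.uniform(beta_range[0], beta_range[1], size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        Gamma[row : row + k, i] = mags * signs
        if frac_invalid_per_trait > 0:
            n_bad = int(round(frac_invalid_per_trait * k))
            for b in range(n_bad):
                other = int(rng.choice([x for x in range(t) if x != i]))
                Gamma[row + b, other] = rng.normal(0.0, pleiotropy_scale)
        row += k
    S = np.full((m, t), 1.0 / np.sqrt(n_gwas))
    P = np.eye(t)
    for k in range(min(n_overlap_pairs, t // 2)):
        P[2 * k, 2 * k + 1] = P[2 * k + 1, 2 * k] = p_overlap
    return GraphSimConfig(
        D_true=D_true,
        iv_effects=Gamma,
        S=S,
        P=TraitCorrelation(P),
        R=LDStructure(np.eye(m)),
        n_by_trait=np.full(t, n_gwas),
        frac_invalid_per_pair=frac_invalid_per_trait,
        rng_seed=None if rng_seed is None else int(rng_seed) + 1,
    )


def make_random_direct_graph(
    T: int,
    edge_density: float,
    effect_range: tuple[float, float] = (0.15, 0.3),
    allow_cycles: bool = True,
    max_radius: float = 0.6,
    rng_seed: int | None = None,
    max_draws: int = 1000,
) -> np.ndarray:
    """Rejection-sample a random direct-effect matrix with bounded radius.

    Signed effect magnitudes are uniform on ``effect_range``; the zero
    diagonal is enforced, and in acyclic mode the matrix is strictly
    triangular under a random trait permutation.
    """
    if not (0 <= max_radius < 1):
        raise SimulationConfigError("max_radius must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_draws):
        D = np.zeros((T, T))
        if allow_cycles:
            mask = rng.random((T, T)) < edge_density
            np.fill_diagonal(mask, False)
        else:
            perm = rng.permutation(T)
            mask = np.zeros((T, T), dtype=bool)
            for a in range(T):
                for b in range(a + 1, T):
                    mask[perm[a], perm[b]] = rng.random() < edge_density
        k = int(mask.sum())
        if k:
            D[mask] = rng.uniform(effect_range[0], effect_range[1], size=k) * rng.choice(
                [-1.0, 1.0], size=k
            )
        if spectral_radius(D) < max_radius:
            return D
    raise SimulationConfigError(
        f"no draw with spectral radius < {max_radius} in {max_draws} attempts; "
        "reduce edge_density or effect sizes"
    )
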