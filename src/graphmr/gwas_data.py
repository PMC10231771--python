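"""Data model and I/O for GWAS summary statistics.

This module holds the containers the rest of the package operates on:
per-SNP summary records, the bivariate per-pair view (``SummaryPair``),
the SNP-by-trait matrix view (``GwasMatrix``), trait-correlation and LD
matrices, and the registry mapping each ordered trait pair to its
instrument SNPs.  It also implements estimation of the between-study
correlation ``rho`` from null Z-scores, shrinkage of small trait
correlations, and eigenvalue repair of nearly-PSD matrices.

Conventions
-----------
* Effect sizes are per-allele on the trait scale (or logOR for binary
  traits); standard errors are strictly positive.
* Missing cells in matrix views are ``NaN`` in both the effect and SE
  matrices, with identical missingness patterns.
* Genomic coordinates are 1-based and carried as metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: strand-ambiguous (palindromic) allele pairs, dropped during harmonization
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: default column map for the common exposure/outcome summary-stat layout
DEFAULT_COLUMNS = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}


@dataclass(frozen=True)
class SnpRecord:
    """One SNP-trait association from a GWAS summary-statistics table."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ParameterError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.pval <= 1.0):
            raise ParameterError(f"{self.snp_id}: pval outside [0, 1]: {self.pval}")
        if not self.effect_allele or not self.other_allele:
            raise ParameterError(f"{self.snp_id}: alleles must be non-empty")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC


@dataclass
class SummaryPair:
    """Aligned per-SNP bivariate GWAS estimates for one ordered trait pair.

    ``rho`` is the correlation between the exposure and outcome estimates
    induced by overlapping samples; ``NaN`` means unset.
    """

    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    rho: float = float("nan")
    n_x: int = 0
    n_y: int = 0

    def __post_init__(self) -> None:
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        m = len(self.snp_ids)
        if m < 1:
            raise ParameterError("SummaryPair needs at least one SNP")
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if getattr(self, name).shape != (m,):
                raise ParameterError(f"{name} must have shape ({m},)")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ParameterError("standard errors must be strictly positive")
        if np.isfinite(self.rho) and not abs(self.rho) < 1:
            raise ParameterError(f"|rho| must be < 1, got {self.rho}")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def rho_is_set(self) -> bool:
        return bool(np.isfinite(self.rho))

    def with_rho(self, rho: float) -> "SummaryPair":
        return SummaryPair(
            list(self.snp_ids),
            self.beta_x.copy(),
            self.se_x.copy(),
            self.beta_y.copy(),
            self.se_y.copy(),
            float(rho),
            self.n_x,
            self.n_y,
        )

    def reversed(self) -> "SummaryPair":
        """Swap the exposure and outcome roles."""
        return SummaryPair(
            list(self.snp_ids),
            self.beta_y.copy(),
            self.se_y.copy(),
            self.beta_x.copy(),
            self.se_x.copy(),
            self.rho,
            self.n_y,
            self.n_x,
        )


@dataclass
class GwasMatrix:
    """m x T matrices of GWAS effect estimates and standard errors.

    Missing cells are NaN in both ``B_hat`` and ``S`` (identical masks);
    ``Z = B_hat / S`` is well defined on observed cells.
    """

    snp_ids: list[str]
    trait_names: list[str]
    B_hat: np.ndarray
    S: np.ndarray
    n_by_trait: np.ndarray

    def __post_init__(self) -> None:
        self.B_hat = np.asarray(self.B_hat, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.n_by_trait = np.asarray(self.n_by_trait, dtype=int)
        m, t = len(self.snp_ids), len(self.trait_names)
        if self.B_hat.shape != (m, t) or self.S.shape != (m, t):
            raise ParameterError(f"B_hat and S must have shape ({m}, {t})")
        if self.n_by_trait.shape != (t,):
            raise ParameterError(f"n_by_trait must have length {t}")
        mask_b = np.isnan(self.B_hat)
        mask_s = np.isnan(self.S)
        if not np.array_equal(mask_b, mask_s):
            raise DataError("missingness masks of B_hat and S differ")
        if np.any(self.S[~mask_s] <= 0):
            raise DataError("S must be strictly positive wherever observed")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.B_hat)

    @property
    def Z(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.B_hat / self.S

    def trait_index(self, name: str) -> int:
        try:
            return self.trait_names.index(name)
        except ValueError as exc:
            raise DataError(f"unknown trait {name!r}") from exc

    def extract_pair(self, rows, source: str, target: str, rho: float) -> SummaryPair:
        """Build the bivariate view for ``source -> target`` over SNP ``rows``."""
        rows = np.asarray(rows, dtype=int)
        i, j = self.trait_index(source), self.trait_index(target)
        bx, by = self.B_hat[rows, i], self.B_hat[rows, j]
        sx, sy = self.S[rows, i], self.S[rows, j]
        if np.isnan(bx).any() or np.isnan(by).any():
            raise DataError(f"pair ({source}, {target}): unobserved cells in IV rows")
        return SummaryPair(
            [self.snp_ids[r] for r in rows],
            bx, sx, by, sy,
            rho,
            int(self.n_by_trait[i]),
            int(self.n_by_trait[j]),
        )


@dataclass
class TraitCorrelation:
    """T x T symmetric trait-correlation matrix with unit diagonal."""

    P: np.ndarray
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        t = self.P.shape[0]
        if self.P.shape != (t, t):
            raise ParameterError("P must be square")
        if not np.allclose(self.P, self.P.T, atol=1e-8):
            raise ParameterError("P must be symmetric")
        if not np.allclose(np.diag(self.P), 1.0, atol=1e-8):
            raise ParameterError("P must have unit diagonal")


@dataclass
class LDStructure:
    """m x m LD correlation matrix, possibly block-diagonal with named blocks.

    Cross-block entries are exactly zero, mirroring the use of approximately
    independent LD blocks.
    """

    R: np.ndarray
    snp_ids: list[str] | None = None
    block_assignment: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        m = self.R.shape[0]
        if self.R.shape != (m, m):
            raise ParameterError("R must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ParameterError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ParameterError("R must have unit diagonal")

    @classmethod
    def from_blocks(
        cls, blocks: dict[str, tuple[list[str], np.ndarray]]
    ) -> "LDStructure":
        """Assemble a block-diagonal LD matrix from per-block matrices.

        ``blocks`` maps a block id to ``(snp_ids, R_block)``.  Cross-block
        LD is exactly zero by construction.
        """
        snp_ids: list[str] = []
        assignment: dict[str, str] = {}
        mats = []
        for block_id, (ids, mat) in blocks.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(ids), len(ids)):
                raise ParameterError(f"block {block_id}: matrix/id length mismatch")
            snp_ids.extend(ids)
            assignment.update({s: block_id for s in ids})
            mats.append(mat)
        m = len(snp_ids)
        R = np.zeros((m, m))
        off = 0
        for mat in mats:
            k = mat.shape[0]
            R[off : off + k, off : off + k] = mat
            off += k
        return cls(R, snp_ids, assignment)


@dataclass
class IVRegistry:
    """Map from ordered trait pair (source, target) to instrument SNP rows."""

    pairs: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, rows in self.pairs.items():
            if len(set(rows)) != len(rows):
                raise DataError(f"duplicate IV rows for pair {key}")

    def __getitem__(self, key: tuple[str, str]) -> list[int]:
        return self.pairs[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.pairs

    def validate_against(self, gwas: GwasMatrix) -> None:
        obs = gwas.observed
        for (src, tgt), rows in self.pairs.items():
            i, j = gwas.trait_index(src), gwas.trait_index(tgt)
            rows = np.asarray(rows, dtype=int)
            if rows.size and (rows.min() < 0 or rows.max() >= gwas.m):
                raise DataError(f"pair ({src}, {tgt}): IV row index out of range")
            if not (obs[rows, i].all() and obs[rows, j].all()):
                raise DataError(f"pair ({src}, {tgt}): IV rows not observed for both traits")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_summary_stats(path, column_map: dict[str, str] | None = None) -> list[SnpRecord]:
    """Read a delimited GWAS summary-statistics table into SnpRecords.

    ``column_map`` maps the internal field names (keys of
    :data:`DEFAULT_COLUMNS`, optionally ``chrom``/``pos``) to the column
    names in the file.  Rows with non-positive SE or missing beta are
    dropped; the drop count is logged.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        with open(path) as fh:
            header = fh.readline()
    except OSError as exc:
        raise FormatError(f"{path}: unreadable") from exc
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        # C engine with round_trip parsing so written floats re-read exactly
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: empty or unparseable file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    required = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[SnpRecord] = []
    dropped = 0
    has_chrom = cmap.get("chrom") in df.columns
    has_pos = cmap.get("pos") in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict()
        beta = row[cmap["beta"]]
        se = row[cmap["se"]]
        if pd.isna(beta) or pd.isna(se) or se <= 0:
            dropped += 1
            continue
        records.append(
            SnpRecord(
                snp_id=str(row[cmap["snp_id"]]),
                chrom=str(row[cmap["chrom"]]) if has_chrom else "NA",
                pos=int(row[cmap["pos"]]) if has_pos else 0,
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(beta),
                se=float(se),
                pval=float(row[cmap["pval"]]),
                n=int(row[cmap["n"]]),
            )
        )
    if dropped:
        logger.info("read_summary_stats(%s): dropped %d unusable row(s)", path, dropped)
    read_summary_stats.last_dropped = dropped  # introspectable drop count
    return records


def write_summary_stats(records: list[SnpRecord], path) -> None:
    """Write SnpRecords as a TSV that round-trips numeric fields exactly."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pval for r in records],
            "samplesize": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Read a square delimited matrix with a name header row (and index)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix_tsv(M: np.ndarray, names: list[str], path) -> None:
    pd.DataFrame(M, index=names, columns=names).to_csv(path, sep="\t", float_format="%.17g")


def read_ld_matrix(path) -> LDStructure:
    """Read one dense whitespace-delimited LD matrix with a SNP-id header."""
    M, ids = read_matrix_tsv(path)
    return LDStructure(M, ids)


def read_ld_blocks(directory, assignment_path) -> LDStructure:
    """Read per-block LD matrices plus a block-assignment table.

    ``assignment_path`` is a two-column TSV (snp_id, block); each block id
    must match a file ``<block>.tsv`` in ``directory`` holding that
    block's square matrix.  Cross-block LD is exactly zero.
    """
    from pathlib import Path

    adf = pd.read_csv(assignment_path, sep="\t")
    for col in ("snp_id", "block"):
        if col not in adf.columns:
            raise FormatError(f"{assignment_path}: missing column {col!r}")
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    directory = Path(directory)
    for block_id, group in adf.groupby("block", sort=False):
        M, ids = read_matrix_tsv(directory / f"{block_id}.tsv")
        expected = [str(s) for s in group["snp_id"]]
        if ids != expected:
            raise FormatError(
                f"block {block_id}: SNP order in matrix header does not match assignment"
            )
        blocks[str(block_id)] = (ids, M)
    return LDStructure.from_blocks(blocks)


def read_trait_correlation(path) -> TraitCorrelation:
    M, names = read_matrix_tsv(path)
    return TraitCorrelation(M, names)


def read_iv_registry(path) -> IVRegistry:
    """Read a three-column TSV (source, target, snp_row) into an IVRegistry."""
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "snp_row"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    pairs: dict[tuple[str, str], list[int]] = {}
    for row in df.itertuples(index=False):
        pairs.setdefault((str(row.source), str(row.target)), []).append(int(row.snp_row))
    return IVRegistry(pairs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def harmonize_pair(
    records_x: list[SnpRecord], records_y: list[SnpRecord]
) -> SummaryPair:
    """Align two per-trait record lists on shared SNPs and effect alleles.

    SNPs present in both lists are kept; when the effect/other alleles are
    swapped between the traits, the trait-Y beta is sign-flipped.
    Strand-ambiguous (A/T, C/G) SNPs and allele-mismatched SNPs are
    dropped.  Output order is sorted snp_id; ``rho`` is left unset.
    """
    by_id_x = {r.snp_id: r for r in records_x}
    by_id_y = {r.snp_id: r for r in records_y}
    shared = sorted(set(by_id_x) & set(by_id_y))
    if not shared:
        raise DataError("harmonize_pair: no shared SNPs between the two traits")

    ids, bx, sx, by, sy, nx, ny = [], [], [], [], [], [], []
    for snp in shared:
        rx, ry = by_id_x[snp], by_id_y[snp]
        if rx.is_palindromic or ry.is_palindromic:
            continue
        if (rx.effect_allele, rx.other_allele) == (ry.effect_allele, ry.other_allele):
            flip = 1.0
        elif (rx.effect_allele, rx.other_allele) == (ry.other_allele, ry.effect_allele):
            flip = -1.0
        else:
            continue  # allele mismatch, not resolvable without frequencies
        ids.append(snp)
        bx.append(rx.beta)
        sx.append(rx.se)
        by.append(flip * ry.beta)
        sy.append(ry.se)
        nx.append(rx.n)
        ny.append(ry.n)
    if not ids:
        raise DataError("harmonize_pair: no SNPs survived allele harmonization")
    return SummaryPair(
        ids,
        np.array(bx), np.array(sx), np.array(by), np.array(sy),
        float("nan"),
        int(np.median(nx)),
        int(np.median(ny)),
    )


def estimate_rho_null_z(
    z_x: np.ndarray,
    z_y: np.ndarray,
    null_threshold: float | None = 2.0,
    min_snps: int = 50,
) -> float:
    """Estimate the between-study correlation from null Z-scores.

    SNPs with ``|z| < null_threshold`` in *both* traits are treated as null
    and their Pearson correlation is returned.  ``null_threshold=None``
    uses all supplied SNPs (appropriate when the inputs are known nulls,
    e.g. from a simulation).
    """
    z_x = np.asarray(z_x, dtype=float)
    z_y = np.asarray(z_y, dtype=float)
    if z_x.shape != z_y.shape:
        raise ParameterError("z_x and z_y must have the same length")
    if null_threshold is not None:
        if null_threshold <= 0:
            raise ParameterError("null_threshold must be positive")
        keep = (np.abs(z_x) < null_threshold) & (np.abs(z_y) < null_threshold)
        z_x, z_y = z_x[keep], z_y[keep]
    if z_x.size < min_snps:
        raise InsufficientDataError(
            f"only {z_x.size} null SNPs survive (need >= {min_snps}); supply rho directly"
        )
    return float(np.corrcoef(z_x, z_y)[0, 1])


def shrink_small_rho(P: TraitCorrelation, cutoff: float = 0.1) -> TraitCorrelation:
    """Zero out off-diagonal trait correlations smaller than ``cutoff``.

    Small estimated correlations contribute mostly noise; results are
    robust to ignoring them, so they are set to exactly zero.
    """
    if cutoff >= 1:
        raise ParameterError("cutoff must be < 1")
    M = P.P.copy()
    off = ~np.eye(M.shape[0], dtype=bool)
    M[off & (np.abs(M) < cutoff)] = 0.0
    M = 0.5 * (M + M.T)
    return TraitCorrelation(M, P.trait_names)


def repair_psd(M: np.ndarray, sym_tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Returns the input unchanged when it is already PSD; idempotent.
    """
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=sym_tol):
        raise ParameterError("repair_psd: input is not symmetric")
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    if w.min() >= 0:
        return M
    w = np.clip(w, 0.0, None)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)
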