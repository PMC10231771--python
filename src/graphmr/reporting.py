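"""Inference assembly and export for total and direct causal graphs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deconv import DirectGraph
from .exceptions import ParameterError
from .graph_total import EdgeTestSummary, TotalGraph
from .gwas_data import write_matrix_tsv

__all__ = ["GraphReport", "assemble_report", "write_report"]


@dataclass
class GraphReport:
    """Joint report over the total and direct graphs.

    Significant edges are exactly those unmasked edges with
    p < alpha / m_eff; an optional looser "suggestive" tier can be added
    for display purposes (off by default).
    """

    total: TotalGraph
    direct: DirectGraph
    tests: EdgeTestSummary
    alpha: float
    significant_total: pd.DataFrame
    significant_direct: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _edge_table(
    traits: list[str],
    effects: np.ndarray,
    se: np.ndarray,
    pvalues: np.ndarray,
    free: np.ndarray,
    alpha_adjusted: float,
    suggestive_alpha: float | None,
) -> pd.DataFrame:
    rows = []
    t = len(traits)
    for i in range(t):
        for j in range(t):
            if not free[i, j]:
                continue
            p = pvalues[i, j]
            tier = "significant" if p < alpha_adjusted else (
                "suggestive" if suggestive_alpha is not None and p < suggestive_alpha else ""
            )
            rows.append(
                {
                    "source": traits[i],
                    "target": traits[j],
                    "effect": effects[i, j],
                    "se": se[i, j],
                    "pvalue": p,
                    "significant": p < alpha_adjusted,
                    "tier": tier,
                }
            )
    return pd.DataFrame(rows, columns=["source", "target", "effect", "se", "pvalue", "significant", "tier"])


def assemble_report(
    total: TotalGraph,
    direct: DirectGraph,
    tests: EdgeTestSummary,
    alpha: float = 0.05,
    suggestive_alpha: float | None = None,
    manifest: dict | None = None,
) -> GraphReport:
    """Deterministic report: every call on the same inputs is identical.

    Each significance call is re-derivable from the stored p-values and
    alpha / m_eff.
    """
    if list(total.traits) != list(direct.traits):
        raise ParameterError("total and direct graphs have different trait orders")
    alpha_adj = alpha / tests.m_eff
    free_t = total.free_edges()
    free_d = ~direct.zero_mask & ~np.eye(len(direct.traits), dtype=bool)
    sig_total = _edge_table(
        total.traits, total.effects, total.se, total.pvalues, free_t, alpha_adj, suggestive_alpha
    )
    sig_direct = _edge_table(
        direct.traits, direct.effects, direct.se, direct.pvalues, free_d, alpha_adj, suggestive_alpha
    )
    man = dict(manifest or {})
    man.update(
        {
            "n_traits": len(total.traits),
            "B": total.B,
            "alpha": alpha,
            "m_eff": tests.m_eff,
            "alpha_adjusted": alpha_adj,
            "deconv_variant": direct.variant,
            "frac_radius_ge_1": direct.frac_radius_ge_1,
        }
    )
    payload = json.dumps(man, sort_keys=True, default=str).encode()
    man["config_hash"] = hashlib.sha256(payload).hexdigest()[:16]
    return GraphReport(total, direct, tests, alpha, sig_total, sig_direct, man)


def write_report(report: GraphReport, outdir, prefix: str = "graphmr") -> list[Path]:
    """Write matrices, tidy edge lists, and the JSON manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = report.total.traits
    written = []

    def _mat(name, M):
        path = outdir / f"{prefix}_{name}.tsv"
        write_matrix_tsv(M, traits, path)
        written.append(path)

    _mat("total_effects", report.total.effects)
    _mat("total_se", report.total.se)
    _mat("total_pvalues", report.total.pvalues)
    _mat("direct_effects", report.direct.effects)
    _mat("direct_se", report.direct.se)
    _mat("direct_pvalues", report.direct.pvalues)

    for name, table in (
        ("total_edges", report.significant_total),
        ("direct_edges", report.significant_direct),
    ):
        path = outdir / f"{prefix}_{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.17g")
        written.append(path)

    path = outdir / f"{prefix}_manifest.json"
    path.write_text(json.dumps(report.manifest, indent=2, sort_keys=True, default=str))
    written.append(path)
    return written
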