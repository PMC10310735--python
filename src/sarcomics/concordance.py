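"""Proteome-transcriptome concordance for paired cohorts.

Per-gene Spearman correlation between protein and mRNA rows with BH-FDR
classes, dual-layer univariable hazard screening with the HR > 2 / < 0.5
rule, the all-endpoint overlap between layers, and detection of genes
whose protein and transcript point in opposite prognostic directions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .survival import ENDPOINTS, screen_features

logger = logging.getLogger(__name__)


@dataclass
class PairedOmics:
    protein: pd.DataFrame
    mrna: pd.DataFrame
    dropped_genes: list[str]
    dropped_samples: list[str]

    @property
    def n_shared_genes(self) -> int:
        return self.protein.shape[0]

    @property
    def n_shared_samples(self) -> int:
        return self.protein.shape[1]


def pair_layers(
    protein_matrix: pd.DataFrame, mrna_matrix: pd.DataFrame
) -> PairedOmics:
    """Restrict both layers to shared genes and samples, same ordering."""
    genes = protein_matrix.index.intersection(mrna_matrix.index)
    samples = protein_matrix.columns.intersection(mrna_matrix.columns)
    if len(genes) == 0:
        raise ValueError("no shared gene identifiers between the layers")
    if len(samples) == 0:
        raise ValueError("no shared samples between the layers")
    dropped_genes = sorted(
        set(protein_matrix.index).symmetric_difference(mrna_matrix.index)
    )
    dropped_samples = sorted(
        set(protein_matrix.columns).symmetric_difference(mrna_matrix.columns)
    )
    if dropped_genes:
        logger.info("%d identifiers present in only one layer", len(dropped_genes))
    return PairedOmics(
        protein=protein_matrix.loc[genes, samples],
        mrna=mrna_matrix.loc[genes, samples],
        dropped_genes=dropped_genes,
        dropped_samples=dropped_samples,
    )


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration."""
    base = np.arange(n, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    bc = base - base.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    null = (pc @ bc) / np.sqrt((pc**2).sum(axis=1) * (bc**2).sum())
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


# full enumeration is cheap up to 8 samples (40320 permutations)
_EXACT_N_MAX = 8


def correlate_layers(paired: PairedOmics, fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene Spearman correlation with FDR classes.

    p-values are exact (full rank-permutation enumeration) for very small
    cohorts and use the t approximation otherwise. Classes:
    positive-significant / negative-significant (BH FDR below threshold)
    or non-significant; constant rows are flagged non-significant.
    """
    n = paired.n_shared_samples
    if n < 5:
        raise ValueError("need at least 5 shared samples")
    rhos, ps, flagged = [], [], []
    for gene in paired.protein.index:
        x = paired.protein.loc[gene].to_numpy(float)
        y = paired.mrna.loc[gene].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rhos.append(np.nan)
            ps.append(1.0)
            flagged.append(True)
            continue
        rho, p = stats.spearmanr(x, y)
        if n <= _EXACT_N_MAX:
            p = _exact_spearman_p(rho, n)
        if n > _EXACT_N_MAX and abs(rho) == 1.0 and np.isnan(p):
            p = 0.0  # t approximation degenerates at |rho| = 1
        rhos.append(float(rho))
        ps.append(float(p))
        flagged.append(False)
    table = pd.DataFrame(
        {"rho": rhos, "p": ps, "constant": flagged}, index=paired.protein.index
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    cls = np.where(
        table["constant"] | (table["fdr"] >= fdr) | table["rho"].isna(),
        "non-significant",
        np.where(table["rho"] > 0, "positive-significant", "negative-significant"),
    )
    table["class"] = cls
    return table


def compare_hazards(
    paired: PairedOmics,
    records: pd.DataFrame,
    endpoints: tuple[str, ...] = ENDPOINTS,
    hr_bounds: tuple[float, float] = (0.5, 2.0),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Dual-layer univariable hazard screen and cross-layer comparison.

    Returns the per-gene x endpoint table (HR and p in both layers, with a
    category: protein-only, mRNA-only, concordant-both, opposing-both or
    neither; "both" categories need p < alpha in both layers and the HRs
    on the same/opposite side of 1) and a summary with per-layer
    all-endpoint significant sets, their overlap, and opposing genes per
    endpoint.
    """
    prot_tab, prot_sig, prot_all = screen_features(
        paired.protein, records, hr_bounds, alpha, endpoints
    )
    mrna_tab, mrna_sig, mrna_all = screen_features(
        paired.mrna, records, hr_bounds, alpha, endpoints
    )
    merged = prot_tab.merge(
        mrna_tab,
        on=["feature", "endpoint"],
        suffixes=("_protein", "_mrna"),
    )

    def categorise(row) -> str:
        p_ok = row["converged_protein"] and row["p_protein"] < alpha
        m_ok = row["converged_mrna"] and row["p_mrna"] < alpha
        if p_ok and m_ok:
            prod = (row["HR_protein"] - 1.0) * (row["HR_mrna"] - 1.0)
            return "opposing-both" if prod < 0 else "concordant-both"
        if p_ok:
            return "protein-only"
        if m_ok:
            return "mRNA-only"
        return "neither"

    merged["category"] = merged.apply(categorise, axis=1)
    opposing = {
        ep: sorted(
            merged.loc[
                (merged["endpoint"] == ep) & (merged["category"] == "opposing-both"),
                "feature",
            ]
        )
        for ep in endpoints
    }
    summary = {
        "protein_all_endpoints": sorted(prot_all),
        "mrna_all_endpoints": sorted(mrna_all),
        "overlap_all_endpoints": sorted(prot_all & mrna_all),
        "protein_significant": {ep: sorted(s) for ep, s in prot_sig.items()},
        "mrna_significant": {ep: sorted(s) for ep, s in mrna_sig.items()},
        "opposing": opposing,
    }
    return merged, summary
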