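"""Signed-hybrid weighted co-expression network modules.

Pipeline: Pearson correlation between protein rows -> signed-hybrid
adjacency a_ij = cor^beta (negative correlations zeroed) -> topological
overlap matrix (TOM) -> average-linkage clustering of 1-TOM -> dynamic
branch cutting with core-scatter dissolution -> eigengene-based module
merging. Module scores for stratification are per-sample medians of member
proteins (the eigengene is used only for merging), split into tertiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNGROUPED = "ungrouped"

# Dynamic-cut deep-split presets: fraction of the dendrogram height range a
# branch's mean internal dissimilarity (core scatter) may reach before the
# branch is dissolved into the ungrouped set. Higher deep split keeps
# looser branches, yielding more, smaller modules.
DEEP_SPLIT_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


@dataclass
class NetworkConfig:
    network_type: str = "signed_hybrid"
    beta: int = 5
    correlation: str = "pearson"
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    cut_height_fraction: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.network_type != "signed_hybrid":
            raise ValueError("only signed_hybrid networks are supported")
        if self.deep_split not in DEEP_SPLIT_MAX_CORE_SCATTER:
            raise ValueError("deep_split must be one of 0..4")


def signed_hybrid_adjacency(cor: np.ndarray, beta: int) -> np.ndarray:
    """a_ij = cor_ij^beta for positive correlations, else 0; unit diagonal."""
    cor = np.asarray(cor, dtype=float)
    if np.nanmax(np.abs(cor)) > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    a = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_threshold(
    matrix: pd.DataFrame,
    beta_grid: range | list[int] = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, int | None]:
    """Scale-free topology fit across candidate soft thresholds.

    For each beta: adjacency, connectivity k_i, and a regression of
    log10 p(k) on log10 k over connectivity bins; the signed R^2 is
    R^2 * -sign(slope) so scale-free (negative-slope) fits score
    positively. Suggested beta = smallest with signed R^2 >= ``r2_target``;
    None (flagged unreliable) when no beta qualifies.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 proteins")
    cor = np.corrcoef(matrix.to_numpy(float))
    if not (cor[np.triu_indices_from(cor, k=1)] > 0).any():
        raise ValueError("no positive correlations: signed-hybrid network empty")
    rows = []
    for beta in beta_grid:
        a = signed_hybrid_adjacency(cor, beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        k_pos = k[k > 0]
        if k_pos.size < 3:
            rows.append({"beta": beta, "r2": np.nan, "mean_k": float(k.mean())})
            continue
        edges = np.linspace(k_pos.min(), k_pos.max() + 1e-12, n_bins + 1)
        which = np.digitize(k_pos, edges[1:-1])
        xs, ys = [], []
        for b in range(n_bins):
            cnt = int((which == b).sum())
            if cnt == 0:
                continue
            xs.append(np.log10(k_pos[which == b].mean()))
            ys.append(np.log10(cnt / k_pos.size))
        if len(xs) < 3:
            rows.append({"beta": beta, "r2": np.nan, "mean_k": float(k.mean())})
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = np.array(ys) - (slope * np.array(xs) + intercept)
        ss_tot = float(np.var(ys) * len(ys))
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        rows.append(
            {"beta": beta, "r2": r2 * -np.sign(slope), "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows).set_index("beta")
    # a fit on a near-empty network is meaningless however good it looks
    ok = table.index[(table["r2"] >= r2_target) & (table["mean_k"] >= 1.0)]
    suggested = int(ok[0]) if len(ok) else None
    if suggested is None:
        logger.warning("no beta reaches scale-free R^2 %.2f; suggestion unreliable",
                       r2_target)
    return table, suggested


def tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    """1 - TOM with TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbour adjacency products; k is connectivity
    excluding the diagonal. TOM_ii = 1 so the self-dissimilarity is 0.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    ao = a.copy()
    np.fill_diagonal(ao, 0.0)
    l = ao @ ao
    k = ao.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - ao
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + ao) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


@dataclass
class ModuleAssignment:
    membership: pd.Series  # protein -> module id or UNGROUPED
    merge_heights: np.ndarray
    config: NetworkConfig

    @property
    def module_sizes(self) -> pd.Series:
        return self.membership[self.membership != UNGROUPED].value_counts()

    def members(self, module_id: str) -> pd.Index:
        return self.membership.index[self.membership == module_id]


def module_eigengene(matrix: pd.DataFrame, members: pd.Index) -> pd.Series:
    """Sign-oriented first principal component of the member proteins."""
    sub = matrix.loc[members].to_numpy(float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sub = sub / np.where(sd > 0, sd, 1.0)
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    pc = vt[0]
    # orient so the eigengene correlates positively with the average member
    if np.corrcoef(pc, sub.mean(axis=0))[0, 1] < 0:
        pc = -pc
    return pd.Series(pc, index=matrix.columns)


def merge_close_modules(
    matrix: pd.DataFrame,
    membership: pd.Series,
    merge_cut_height: float = 0.25,
) -> pd.Series:
    """Merge modules whose eigengene dissimilarity 1-cor is below the cut.

    Iterates (closest pair first) until no pair is closer than the cut, so
    re-running on the result is a no-op.
    """
    membership = membership.copy()
    while True:
        mods = sorted(set(membership) - {UNGROUPED})
        if len(mods) < 2:
            return membership
        eigs = pd.DataFrame(
            {
                m: module_eigengene(matrix, membership.index[membership == m])
                for m in mods
            }
        )
        diss = 1.0 - eigs.corr().to_numpy()
        iu = np.triu_indices(len(mods), k=1)
        pos = np.argmin(diss[iu])
        if diss[iu][pos] >= merge_cut_height:
            return membership
        i, j = iu[0][pos], iu[1][pos]
        membership[membership == mods[j]] = mods[i]


def detect_modules(
    dissimilarity: np.ndarray,
    config: NetworkConfig,
    protein_ids: list[str] | pd.Index | None = None,
    matrix: pd.DataFrame | None = None,
) -> ModuleAssignment:
    """Average-linkage tree, dynamic branch cut, and (optionally) merging.

    The dynamic cut takes the static branches below ``cut_height_fraction``
    of the dendrogram height range, keeps those of at least
    ``min_module_size`` proteins, and dissolves branches whose core
    scatter (mean internal dissimilarity) exceeds the deep-split preset.
    When ``matrix`` is given, modules closer than ``merge_cut_height`` in
    eigengene dissimilarity are merged.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be square and symmetric")
    p = D.shape[0]
    if protein_ids is None:
        protein_ids = (
            list(matrix.index) if matrix is not None else [f"P{i}" for i in range(p)]
        )
    membership = pd.Series(UNGROUPED, index=pd.Index(protein_ids), dtype=object)
    if p < config.min_module_size:
        warnings.warn("fewer proteins than min_module_size: all ungrouped",
                      stacklevel=2)
        return ModuleAssignment(membership, np.array([]), config)

    Z = average(squareform(D, checks=False))
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    cut = hmin + config.cut_height_fraction * (hmax - hmin)
    raw = fcluster(Z, t=cut, criterion="distance")

    scatter_cap = hmin + DEEP_SPLIT_MAX_CORE_SCATTER[config.deep_split] * (
        cut - hmin
    )
    next_id = 1
    for cl in np.unique(raw):
        idx = np.where(raw == cl)[0]
        if idx.size < config.min_module_size:
            continue
        sub = D[np.ix_(idx, idx)]
        core_scatter = float(sub[np.triu_indices(idx.size, k=1)].mean())
        if core_scatter > scatter_cap:
            continue
        membership.iloc[idx] = f"SPM{next_id}"
        next_id += 1

    if matrix is not None and (membership != UNGROUPED).any():
        membership = merge_close_modules(
            matrix, membership, config.merge_cut_height
        )
    return ModuleAssignment(membership, heights, config)


def module_score(
    matrix: pd.DataFrame, assignment: ModuleAssignment | pd.Series, module_id: str
) -> pd.Series:
    """Per-sample median expression over the module's member proteins."""
    membership = (
        assignment.membership if isinstance(assignment, ModuleAssignment) else assignment
    )
    members = membership.index[membership == module_id]
    members = members.intersection(matrix.index)
    if len(members) == 0:
        raise ValueError(f"module {module_id!r} has no members in the matrix")
    return matrix.loc[members].median(axis=0).rename(module_id)


def tertile_stratify(score: pd.Series) -> pd.Series:
    """Split samples at the empirical tertiles of the score.

    Boundaries use the <=-lower rule: a sample exactly at a tertile
    boundary joins the lower stratum. With distinct scores the strata sizes
    differ by at most one.
    """
    q1, q2 = score.quantile([1 / 3, 2 / 3])
    labels = pd.Series("intermediate", index=score.index, name="stratum")
    labels[score <= q1] = "low"
    labels[score > q2] = "high"
    return labels


def export_edge_list(
    similarity: np.ndarray,
    node_ids: list[str] | pd.Index,
    threshold: float = 0.05,
    assignment: ModuleAssignment | pd.Series | None = None,
) -> pd.DataFrame:
    """Undirected edges (i < j) with similarity above the threshold.

    Columns: source, target, weight, plus module annotations when an
    assignment is supplied. Importable by standard graph tools.
    """
    S = np.asarray(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or not np.allclose(S, S.T):
        raise ValueError("similarity must be square and symmetric")
    node_ids = list(node_ids)
    iu, ju = np.triu_indices(S.shape[0], k=1)
    keep = S[iu, ju] > threshold
    edges = pd.DataFrame(
        {
            "source": [node_ids[i] for i in iu[keep]],
            "target": [node_ids[j] for j in ju[keep]],
            "weight": S[iu[keep], ju[keep]],
        }
    )
    if assignment is not None:
        membership = (
            assignment.membership
            if isinstance(assignment, ModuleAssignment)
            else assignment
        )
        edges["source_module"] = membership.reindex(edges["source"]).to_numpy()
        edges["target_module"] = membership.reindex(edges["target"]).to_numpy()
    return edges
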