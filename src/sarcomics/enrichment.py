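"""Gene-set scoring: ssGSEA, pre-ranked GSEA and overrepresentation.

ssGSEA integrates the difference between the weighted in-set and unweighted
out-of-set rank ECDFs down the per-sample expression ordering (weighting
exponent 0.75, rank normalisation). Pre-ranked GSEA is the weighted
Kolmogorov-Smirnov running-sum statistic with gene-label permutations.
Overrepresentation uses the hypergeometric upper tail with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GeneSets = dict[str, tuple[str, list[str]]]


def _set_members(sets: GeneSets, name: str) -> list[str]:
    entry = sets[name]
    return entry[1] if isinstance(entry, tuple) else list(entry)


def filter_sets(
    sets: GeneSets,
    universe: pd.Index | list[str],
    min_size: int = 1,
    max_size: int | None = None,
) -> dict[str, list[str]]:
    """Restrict each set to the measured universe and apply size bounds."""
    uni = set(universe)
    out = {}
    for name in sets:
        members = [g for g in _set_members(sets, name) if g in uni]
        if len(members) < min_size:
            logger.info("set %s skipped (%d members in matrix)", name, len(members))
            continue
        if max_size is not None and len(members) > max_size:
            logger.info("set %s skipped (%d members > %d)", name, len(members), max_size)
            continue
        out[name] = members
    return out


def _ssgsea_sample(
    values: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Running-sum integral for one sample given a descending ordering."""
    w = np.abs(values[order]) ** alpha
    mask = in_set[order]
    n = values.size
    n_out = n - int(mask.sum())
    win = np.where(mask, w, 0.0)
    denom_in = win.sum()
    if denom_in == 0 or n_out == 0:
        return 0.0
    p_in = np.cumsum(win) / denom_in
    p_out = np.cumsum(~mask) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    matrix: pd.DataFrame,
    sets: GeneSets,
    alpha: float = 0.75,
    rank_normalise: bool = True,
    min_size: int = 10,
    zscore_across_sets: bool = True,
    zscore_axis: str = "sets",
) -> pd.DataFrame:
    """Per-sample enrichment scores (samples x sets), z-scored normalised ES.

    Normalised ES = ES / (max ES - min ES over all sets and samples). With
    ``zscore_axis="sets"`` each sample's normalised scores are z-scored
    over the set collection; ``"samples"`` z-scores each set across samples
    instead (the form a clustered heatmap typically uses).
    """
    if matrix.isna().any().any():
        raise ValueError("ssgsea requires a complete (imputed) matrix")
    filtered = filter_sets(sets, matrix.index, min_size=min_size)
    if not filtered:
        raise ValueError("no gene set passes the size filter")
    X = matrix.to_numpy(float)
    if rank_normalise:
        # highest expression receives rank n; ties broken by row order
        X = np.argsort(np.argsort(X, axis=0, kind="stable"), axis=0) + 1.0
    masks = {
        name: matrix.index.isin(members)
        for name, members in filtered.items()
    }
    es = np.empty((matrix.shape[1], len(filtered)))
    for si in range(matrix.shape[1]):
        col = X[:, si]
        order = np.argsort(-col, kind="stable")
        for gi, name in enumerate(filtered):
            es[si, gi] = _ssgsea_sample(col, order, masks[name], alpha)
    scores = pd.DataFrame(es, index=matrix.columns, columns=list(filtered))
    span = float(es.max() - es.min())
    nes = scores / span if span > 0 else scores
    if not zscore_across_sets:
        return nes
    if zscore_axis == "sets":
        mu, sd = nes.mean(axis=1), nes.std(axis=1, ddof=0)
        return nes.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    if zscore_axis == "samples":
        mu, sd = nes.mean(axis=0), nes.std(axis=0, ddof=0)
        return nes.sub(mu, axis=1).div(sd.where(sd > 0, 1.0), axis=1)
    raise ValueError("zscore_axis must be 'sets' or 'samples'")


def _gsea_es(
    metric: np.ndarray, mask_sorted: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and running sum for a sorted ranking."""
    w = np.abs(metric)
    win = np.where(mask_sorted, w, 0.0)
    denom_in = win.sum()
    n_out = (~mask_sorted).sum()
    if denom_in == 0 or n_out == 0:
        return 0.0, np.zeros(metric.size)
    running = np.cumsum(win / denom_in - (~mask_sorted) / n_out)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _null_es_batch(
    metric: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for random same-size sets, vectorised over permutations."""
    n = metric.size
    w = np.abs(metric)
    # each row: a random boolean membership of `size` genes
    masks = np.zeros((n_perm, n), dtype=bool)
    idx = np.argsort(rng.uniform(size=(n_perm, n)), axis=1)[:, :size]
    np.put_along_axis(masks, idx, True, axis=1)
    win = np.where(masks, w[None, :], 0.0)
    denom_in = win.sum(axis=1, keepdims=True)
    denom_in = np.where(denom_in > 0, denom_in, 1.0)
    n_out = n - size
    running = np.cumsum(
        win / denom_in - (~masks) / max(n_out, 1), axis=1
    )
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSets,
    min_size: int = 9,
    max_size: int = 501,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene -> metric (log2 fold change) ranking.

    Genes are sorted by decreasing metric (ties broken by identifier for
    determinism); the null permutes set membership over the ranked list.
    NES divides ES by the mean same-sign null ES; FDR follows the standard
    pooled-NES procedure, sign-separated.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    ranking = ranking.sort_index(kind="stable")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    metric = ranking.to_numpy(float)
    genes = ranking.index
    filtered = filter_sets(sets, genes, min_size=min_size, max_size=max_size)
    if not filtered:
        raise ValueError("no gene set passes the size filters")
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes = {}
    for name, members in filtered.items():
        mask = genes.isin(members)
        es, running = _gsea_es(metric, mask)
        size = int(mask.sum())
        null_es = _null_es_batch(metric, size, n_perm, rng)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size == 0:
            same_sign = np.array([1.0])
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        mean_abs = np.abs(same_sign).mean()
        nes = es / mean_abs if mean_abs > 0 else 0.0
        null_nes = np.where(
            null_es >= 0,
            null_es / max(null_es[null_es >= 0].mean(), 1e-12)
            if (null_es >= 0).any()
            else 0.0,
            -null_es / min(null_es[null_es < 0].mean(), -1e-12)
            if (null_es < 0).any()
            else 0.0,
        )
        null_nes_pool.append(null_nes)
        obs_nes[name] = nes
        peak = int(np.argmax(np.abs(running)))
        leading = (
            list(genes[: peak + 1][mask[: peak + 1]])
            if es >= 0
            else list(genes[peak:][mask[peak:]])
        )
        rows.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "p": float(p),
                "leading_edge": leading,
            }
        )
    table = pd.DataFrame(rows).set_index("set")

    pooled = np.concatenate(null_nes_pool)
    obs = table["nes"].to_numpy()
    fdr = np.empty(obs.size)
    for i, nes in enumerate(obs):
        if nes >= 0:
            num = np.mean(pooled[pooled >= 0] >= nes) if (pooled >= 0).any() else 1.0
            den = np.mean(obs[obs >= 0] >= nes)
        else:
            num = np.mean(pooled[pooled < 0] <= nes) if (pooled < 0).any() else 1.0
            den = np.mean(obs[obs < 0] <= nes)
        fdr[i] = min(num / max(den, 1e-12), 1.0)
    table["fdr"] = fdr
    return table


def ora(
    hits: set[str] | list[str],
    universe: set[str] | list[str],
    sets: GeneSets,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of hits within each set.

    p = P(X >= overlap) with population |universe|, successes
    |set & universe|, draws |hits|; BH adjustment across sets.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name in sets:
        members = set(_set_members(sets, name)) & universe
        overlap = len(hits & members)
        if len(hits) == 0:
            p = 1.0
        else:
            p = float(
                stats.hypergeom.sf(
                    overlap - 1, len(universe), len(members), len(hits)
                )
            )
        rows.append(
            {"set": name, "set_size": len(members), "overlap": overlap, "p": p}
        )
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]
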