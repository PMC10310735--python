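"""Consensus clustering of samples with statistical validation.

Three complementary tools:

* resampling consensus clustering (pairwise co-clustering frequencies over
  item/feature subsamples) with CDF / delta-area / silhouette model
  selection;
* SigClust: a Monte-Carlo test of whether a 2-cluster split beats the best
  split of a single Gaussian with eigenvalue-thresholded covariance;
* Monte-Carlo-null consensus: compares the proportion of ambiguous
  consensus entries (PAC) on the real data against reference datasets that
  preserve the observed principal-component eigen-spectrum.

Matrices are protein-by-sample; clustering is always over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, complete, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

_LINKAGES = {"average": average, "complete": complete}


def _sample_distance(X: np.ndarray, metric: str) -> np.ndarray:
    """Distance between sample columns of a protein-by-sample array.

    Correlation distances are 1 - r with r over proteins; columns must be
    non-constant for spearman/pearson.
    """
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        return squareform(pdist(X.T))
    if metric == "pearson":
        r = np.corrcoef(X.T)
    elif metric == "spearman":
        ranks = stats.rankdata(X, axis=0)
        r = np.corrcoef(ranks.T)
    else:
        raise ValueError(f"unknown distance {metric!r}")
    if np.isnan(r).any():
        raise FloatingPointError("constant column under correlation distance")
    np.fill_diagonal(r, 1.0)
    return 1.0 - r


def _lloyd_kmeans(
    obs: np.ndarray, k: int, rng: np.random.Generator, n_init: int = 3,
    max_iter: int = 50,
) -> np.ndarray:
    """Plain Lloyd k-means on an observations-by-features array.

    Small-problem workhorse for the Monte-Carlo loops, where the per-call
    overhead of a full estimator object would dominate the runtime.
    """
    n = obs.shape[0]
    best_labels, best_inertia = None, np.inf
    for _ in range(n_init):
        centers = obs[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1, dtype=int)
        for _it in range(max_iter):
            d2 = ((obs[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            if (new_labels == labels).all():
                break
            labels = new_labels
            for j in range(k):
                mask = labels == j
                if mask.any():
                    centers[j] = obs[mask].mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    centers[j] = obs[d2.min(axis=1).argmax()]
        inertia = d2.min(axis=1).sum()
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    return best_labels


def _cluster_once(
    X: np.ndarray,
    k: int,
    distance: str,
    link: str,
    base: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if base == "kmeans":
        if X.shape[1] <= 2000:
            return _lloyd_kmeans(X.T, k, rng)
        km = KMeans(
            n_clusters=k, n_init=3, random_state=int(rng.integers(2**31))
        )
        return km.fit_predict(X.T)
    D = _sample_distance(X, distance)
    Z = _LINKAGES[link](squareform(D, checks=False))
    return fcluster(Z, t=k, criterion="maxclust")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices plus the resampling bookkeeping."""

    consensus: dict[int, np.ndarray]
    co_sample_counts: np.ndarray
    sample_ids: list[str]
    params: dict = field(default_factory=dict)


def run_consensus(
    matrix: pd.DataFrame,
    distance: str = "spearman",
    linkage_method: str = "average",
    base: str = "hierarchical",
    k_range: range | list[int] = range(2, 11),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampling consensus clustering over a range of cluster counts.

    Defaults reproduce the conventional configuration: 80% item and feature
    resampling, 1000 repetitions, k from 2 to 10, agglomerative clustering
    with Spearman distance and average linkage.
    """
    k_range = list(k_range)
    X = matrix.to_numpy(float)
    p, n = X.shape
    if n <= max(k_range):
        raise ValueError("need more samples than the largest k")
    rng = np.random.default_rng(seed)
    n_item = max(int(np.floor(p_item * n)), max(k_range) + 1)
    n_feat = max(int(np.floor(p_feature * p)), 1)

    S = np.zeros((n, n))
    C = {k: np.zeros((n, n)) for k in k_range}
    skipped = 0
    for _ in range(reps):
        items = rng.choice(n, size=n_item, replace=False)
        feats = rng.choice(p, size=n_feat, replace=False)
        sub = X[np.ix_(feats, items)]
        S[np.ix_(items, items)] += 1.0
        try:
            for k in k_range:
                lab = _cluster_once(
                    sub, k, distance, linkage_method, base, rng
                )
                same = lab[:, None] == lab[None, :]
                C[k][np.ix_(items, items)] += same
        except FloatingPointError:
            skipped += 1
            S[np.ix_(items, items)] -= 1.0
            continue
    if skipped:
        logger.warning("%d/%d resamples skipped (constant features)", skipped, reps)

    consensus = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            M = np.where(S > 0, C[k] / np.where(S > 0, S, 1), 0.0)
            M = (M + M.T) / 2.0
            np.fill_diagonal(M, 1.0)
            consensus[k] = M
    return ConsensusResult(
        consensus=consensus,
        co_sample_counts=S,
        sample_ids=list(matrix.columns),
        params={
            "distance": distance,
            "linkage": linkage_method,
            "base": base,
            "reps": reps,
            "p_item": p_item,
            "p_feature": p_feature,
            "seed": seed,
        },
    )


def consensus_cdf_area(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of the off-diagonal consensus entries and its area.

    The area is the step integral sum((u_i - u_{i-1}) * F(u_i)) over sorted
    entry values, the convention of the originating consensus procedure; a
    pure 0/1 matrix therefore saturates at area 1.
    """
    iu = np.triu_indices_from(M, k=1)
    vals = np.sort(M[iu])
    m = vals.size
    uniq, counts = np.unique(vals, return_counts=True)
    F = np.cumsum(counts) / m
    prev = np.concatenate(([0.0], uniq[:-1]))
    area = float(np.sum((uniq - prev) * F))
    return uniq, F, area


@dataclass
class ClusterSelection:
    areas: dict[int, float]
    delta_areas: dict[int, float]
    silhouettes: dict[int, float]
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]]
    chosen_k: int
    labels: pd.Series
    labels_per_k: dict[int, pd.Series] = field(default_factory=dict)


def consensus_labels(M: np.ndarray, k: int, sample_ids: list[str]) -> pd.Series:
    """Final labels: average-linkage cut of 1 - consensus at k clusters."""
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    lab = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(lab, index=sample_ids, name="cluster")


def evaluate_k(
    result: ConsensusResult,
    matrix: pd.DataFrame | None = None,
    method: str = "elbow",
    delta_threshold: float = 0.025,
) -> ClusterSelection:
    """Model-selection diagnostics and an automatic choice of k.

    The default ``elbow`` rule chooses the k after which the delta-area
    drops the most: real consensus matrices keep accruing small amounts of
    area indefinitely, so the meaningful signal is the sharp fall-off
    after the true k rather than an absolute level. The ``threshold`` rule
    instead takes the smallest k whose delta-area at k+1 falls below
    ``delta_threshold`` and whose silhouette (on 1 - consensus) is a local
    maximum, falling back to the best silhouette.
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        raise ValueError("need at least two values of k")
    cdfs, areas = {}, {}
    for k in ks:
        u, F, a = consensus_cdf_area(result.consensus[k])
        cdfs[k] = (u, F)
        areas[k] = a
    deltas = {ks[0]: areas[ks[0]]}
    for prev_k, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev_k]) / areas[prev_k] if areas[prev_k] else 0.0

    sils, labels_per_k = {}, {}
    for k in ks:
        lab = consensus_labels(result.consensus[k], k, result.sample_ids)
        labels_per_k[k] = lab
        D = 1.0 - result.consensus[k]
        np.fill_diagonal(D, 0.0)
        if lab.nunique() < 2:
            sils[k] = -1.0
        else:
            sils[k] = float(silhouette_score(D, lab.to_numpy(), metric="precomputed"))

    def flat_after(k: int) -> bool:
        nxt = [kk for kk in ks if kk > k]
        return bool(nxt) and deltas[nxt[0]] < delta_threshold

    def locally_max_sil(k: int) -> bool:
        i = ks.index(k)
        left = sils[ks[i - 1]] if i > 0 else -np.inf
        right = sils[ks[i + 1]] if i + 1 < len(ks) else -np.inf
        return sils[k] >= left and sils[k] >= right

    if method == "elbow":
        saturated = [k for k in ks if areas[k] >= 0.995]
        if saturated:
            # a perfectly bimodal CDF pins down the true k exactly
            chosen = saturated[0]
        else:
            drops = {}
            for i, k in enumerate(ks):
                nxt = deltas[ks[i + 1]] if i + 1 < len(ks) else 0.0
                drops[k] = deltas[k] - nxt
            best = max(drops.values())
            chosen = min(k for k in ks if drops[k] == best)
    elif method == "threshold":
        candidates = [k for k in ks if flat_after(k) and locally_max_sil(k)]
        if candidates:
            chosen = candidates[0]
        else:
            flat = [k for k in ks if flat_after(k)]
            chosen = flat[0] if flat else max(sils, key=sils.get)
    else:
        raise ValueError("method must be 'elbow' or 'threshold'")

    return ClusterSelection(
        areas=areas,
        delta_areas=deltas,
        silhouettes=sils,
        cdfs=cdfs,
        chosen_k=chosen,
        labels=labels_per_k[chosen],
        labels_per_k=labels_per_k,
    )


# ---------------------------------------------------------------------------
# SigClust


@dataclass
class SigClustResult:
    cluster_index: float
    null_indices: np.ndarray
    p_value: float
    n_sim: int
    eigen_mode: str


def _cluster_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster SS / total SS for sample columns of X."""
    total = float(((X - X.mean(axis=1, keepdims=True)) ** 2).sum())
    if total == 0:
        return 0.0
    within = 0.0
    for g in np.unique(labels):
        sub = X[:, labels == g]
        within += float(((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum())
    return within / total


def _two_means_index(X: np.ndarray, rng: np.random.Generator) -> float:
    lab = _lloyd_kmeans(X.T, 2, rng)
    return _cluster_index(X, lab)


def sigclust(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_sim: int = 1000,
    eigen_mode: str = "hard",
    seed: int = 0,
) -> SigClustResult:
    """Significance of a 2-cluster split against a single-Gaussian null.

    The null covariance is diagonal with the data's covariance eigenvalues
    after hard thresholding: eigenvalues below the background noise level
    sigma^2 (robustly estimated as (MAD / 0.6745)^2 over all matrix
    entries) are replaced by sigma^2. Each null dataset is split by
    2-means and scored by the cluster index CI = within-SS / total-SS;
    p = (1 + #{null CI <= observed CI}) / (n_sim + 1).
    """
    X = matrix.to_numpy(float)
    d, n = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    lab = np.asarray(labels)
    if len(np.unique(lab)) != 2:
        raise ValueError("sigclust requires exactly 2 groups")
    for g in np.unique(lab):
        if (lab == g).sum() < 2:
            raise ValueError("each group needs at least 2 samples")

    ci_obs = _cluster_index(X, lab)

    centered = X - X.mean(axis=1, keepdims=True)
    # eigenvalues of the d x d sample covariance via SVD of the n-column data
    sv = np.linalg.svd(centered, compute_uv=False)
    eig = np.zeros(d)
    eig[: sv.size] = sv**2 / max(n - 1, 1)
    mad = float(np.median(np.abs(X - np.median(X))))
    sigma2 = (mad / 0.6745) ** 2
    if eigen_mode == "hard":
        eig = np.where(eig < sigma2, sigma2, eig)
    else:
        raise ValueError(f"unsupported eigen_mode {eigen_mode!r}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(eig)[:, None]
    null = np.empty(n_sim)
    for s in range(n_sim):
        Xn = rng.standard_normal((d, n)) * scale
        null[s] = _two_means_index(Xn, rng)

    p = (1.0 + float(np.sum(null <= ci_obs))) / (n_sim + 1.0)
    return SigClustResult(
        cluster_index=ci_obs,
        null_indices=null,
        p_value=p,
        n_sim=n_sim,
        eigen_mode=eigen_mode,
    )


def sigclust_overall(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[float, dict[tuple, SigClustResult]]:
    """Pairwise SigClust over >2 clusters; overall p = max pairwise p."""
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    results: dict[tuple, SigClustResult] = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            mask = labels.isin([g1, g2])
            res = sigclust(
                matrix.loc[:, mask.to_numpy()],
                labels[mask].to_numpy(),
                n_sim=n_sim,
                seed=seed + 13 * i,
            )
            results[(g1, g2)] = res
    overall = max(r.p_value for r in results.values())
    return overall, results


# ---------------------------------------------------------------------------
# Monte-Carlo-null consensus (PAC against spectrum-matched references)


def pac_score(
    M: np.ndarray, window: tuple[float, float] = (0.1, 0.9)
) -> float:
    """Proportion of ambiguous consensus entries strictly inside the window."""
    iu = np.triu_indices_from(M, k=1)
    vals = M[iu]
    lo, hi = window
    return float(np.mean((vals > lo) & (vals < hi)))


@dataclass
class MonteCarloConsensusResult:
    real_pac: dict[int, float]
    null_pac: dict[int, np.ndarray]
    relative_score: dict[int, float]
    p_values: dict[int, float]
    chosen_k: int | None
    labels: pd.Series | None


def _spectrum_matched_null(
    X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a dataset whose PC eigenvalue spectrum matches X's.

    X is protein-by-sample; samples are the observations. New normal scores
    are drawn in the eigenbasis with the observed singular-value scaling.
    """
    centered = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    n = X.shape[1]
    Z = rng.standard_normal((s.size, n))
    sd = s / np.sqrt(max(n - 1, 1))  # per-PC standard deviation
    return U @ (Z * sd[:, None])


def monte_carlo_consensus(
    matrix: pd.DataFrame,
    base: str = "kmeans",
    k_range: range | list[int] = range(2, 11),
    reps: int = 100,
    n_null: int = 100,
    window: tuple[float, float] = (0.1, 0.9),
    alpha: float = 0.05,
    seed: int = 0,
) -> MonteCarloConsensusResult:
    """Consensus-cluster the data and spectrum-matched Gaussian references.

    Per k: relative score = ln(mean null PAC / real PAC) and empirical
    p = (1 + #{null PAC <= real PAC}) / (n_null + 1). Chosen k maximises
    the relative score among k with p < alpha; None when no k is
    significant (the no-structure verdict).
    """
    if n_null < 20:
        raise ValueError("n_null must be >= 20")
    X = matrix.to_numpy(float)
    centered = X - X.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(centered) < 2:
        raise ValueError("degenerate covariance (rank < 2)")
    k_range = list(k_range)
    rng = np.random.default_rng(seed)

    real = run_consensus(
        matrix, base=base, k_range=k_range, reps=reps,
        p_item=0.8, p_feature=0.8, seed=int(rng.integers(2**31)),
    )
    floor = 1.0 / max(len(real.sample_ids) ** 2, 1)
    real_pac = {k: pac_score(real.consensus[k], window) for k in k_range}

    null_pac = {k: np.empty(n_null) for k in k_range}
    for b in range(n_null):
        Xn = _spectrum_matched_null(X, rng)
        dfn = pd.DataFrame(Xn, index=matrix.index, columns=matrix.columns)
        resn = run_consensus(
            dfn, base=base, k_range=k_range, reps=reps,
            p_item=0.8, p_feature=0.8, seed=int(rng.integers(2**31)),
        )
        for k in k_range:
            null_pac[k][b] = pac_score(resn.consensus[k], window)

    rel, pvals = {}, {}
    for k in k_range:
        r = max(real_pac[k], floor)
        nmean = max(float(null_pac[k].mean()), floor)
        rel[k] = float(np.log(nmean / r))
        pvals[k] = (1.0 + float(np.sum(null_pac[k] <= real_pac[k]))) / (
            n_null + 1.0
        )
    sig = [k for k in k_range if pvals[k] < alpha]
    chosen = max(sig, key=lambda k: rel[k]) if sig else None
    labels = (
        consensus_labels(real.consensus[chosen], chosen, real.sample_ids)
        if chosen
        else None
    )
    return MonteCarloConsensusResult(
        real_pac=real_pac,
        null_pac=null_pac,
        relative_score=rel,
        p_values=pvals,
        chosen_k=chosen,
        labels=labels,
    )
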