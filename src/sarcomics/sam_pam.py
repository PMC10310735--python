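"""Differential abundance (SAM) and nearest-shrunken-centroid panels (PAM).

SAM scores each protein with a (optionally moderated) two-sample statistic
and assigns permutation-based q-values; the nearest-shrunken-centroid
classifier soft-thresholds standardised class-centroid differences,
selects the shrinkage by stratified cross-validation (largest shrinkage at
the minimum misclassification error, for parsimony) and yields a compact
marker panel whose centroids transfer to external cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamResult:
    table: pd.DataFrame  # per protein: means, s, score, fold_change, q
    s0: float
    n_perm: int
    statistic: str
    fdr: float
    min_fc: float

    @property
    def significant(self) -> pd.Index:
        """Upregulated significant set: q <= fdr and fold change >= min_fc."""
        t = self.table
        return t.index[(t["q"] <= self.fdr) & (t["fold_change"] >= self.min_fc)]


def _pooled_scatter(
    X: np.ndarray, mask2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group means and the SAM gene-wise scatter s_i."""
    n2 = int(mask2.sum())
    n1 = X.shape[1] - n2
    x1, x2 = X[:, ~mask2], X[:, mask2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(
        axis=1
    )
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m1, m2, s


def _scores(X: np.ndarray, mask2: np.ndarray, s0: float) -> np.ndarray:
    m1, m2, s = _pooled_scatter(X, mask2)
    denom = s + s0
    bad = denom <= 0
    if bad.any():
        floor = denom[~bad].min() if (~bad).any() else 1e-12
        logger.warning("%d zero-variance proteins; score floored", int(bad.sum()))
        denom = np.where(bad, floor, denom)
    return (m2 - m1) / denom


def _null_label_masks(
    mask2: np.ndarray, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Permuted class assignments forming the null ensemble.

    The observed assignment and its complement are excluded (they carry
    the alternative, not the null). When the number of distinct
    assignments is at most ``n_perm`` all of them are enumerated, making
    the q-values exact and seed-independent; otherwise assignments are
    sampled at random.
    """
    from itertools import combinations
    from math import comb

    n = mask2.size
    n2 = int(mask2.sum())
    obs = frozenset(np.where(mask2)[0])
    comp = frozenset(np.where(~mask2)[0])
    if comb(n, n2) <= n_perm:
        out = []
        for idx in combinations(range(n), n2):
            if frozenset(idx) in (obs, comp):
                continue
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            out.append(m)
        return out
    out = []
    while len(out) < n_perm:
        m = rng.permutation(mask2)
        key = frozenset(np.where(m)[0])
        if key in (obs, comp):
            continue
        out.append(m)
    return out


def sam_two_class(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    fdr: float = 0.01,
    min_fc: float = 1.5,
    n_perm: int = 1000,
    statistic: str = "t_stat",
    seed: int = 0,
) -> SamResult:
    """Two-class unpaired SAM on a log2 protein-by-sample matrix.

    ``statistic="t_stat"`` uses the plain Student denominator (s0 = 0);
    ``"d_stat"`` adds the exchangeability constant s0 = median(s_i).
    q-values come from label permutations: the expected null exceedance
    count over the observed count at each score threshold (the E[V]/R
    plug-in with pi0 = 1), monotonised over the score ranking; fold change
    is on the linear scale, 2^(mean2 - mean1).
    """
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("sam_two_class requires exactly 2 classes")
    mask2 = lab == groups[1]
    if mask2.sum() < 2 or (~mask2).sum() < 2:
        raise ValueError("both classes need at least 2 samples")
    X = matrix.to_numpy(float)

    _, _, s = _pooled_scatter(X, mask2)
    s0 = float(np.median(s)) if statistic == "d_stat" else 0.0
    if statistic not in ("d_stat", "t_stat"):
        raise ValueError(f"unknown statistic {statistic!r}")
    d = _scores(X, mask2, s0)
    m1, m2, _ = _pooled_scatter(X, mask2)

    rng = np.random.default_rng(seed)
    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    thresholds = abs_d[order]
    perms = _null_label_masks(mask2, n_perm, rng)
    null_counts = np.empty((len(perms), X.shape[0]))
    for b, perm in enumerate(perms):
        d_null = np.abs(_scores(X, perm, s0))
        d_null.sort()
        # null exceedances of each observed threshold
        null_counts[b] = X.shape[0] - np.searchsorted(d_null, thresholds, "left")
    mean_null = null_counts.mean(axis=0)
    n_called = np.arange(1, X.shape[0] + 1, dtype=float)
    q_sorted = np.minimum(mean_null / n_called, 1.0)
    # monotone non-decreasing as |d| decreases
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    table = pd.DataFrame(
        {
            "mean_1": m1,
            "mean_2": m2,
            "s": s,
            "score": d,
            "fold_change": np.exp2(m2 - m1),
            "q": q,
        },
        index=matrix.index,
    )
    return SamResult(
        table=table, s0=s0, n_perm=n_perm, statistic=statistic,
        fdr=fdr, min_fc=min_fc,
    )


def unique_subtype_markers(
    matrix: pd.DataFrame,
    subtype_labels: pd.Series,
    min_group: int = 21,
    fdr: float = 0.01,
    min_fc: float = 1.5,
    n_perm: int = 1000,
    statistic: str = "t_stat",
    seed: int = 0,
) -> tuple[dict[str, pd.Index], int]:
    """Per-subtype uniquely upregulated proteins (one-vs-rest SAM).

    Only subtypes with at least ``min_group`` cases qualify (i.e. strictly
    more than 20 at the default). "Unique" means significant for exactly
    one qualifying subtype; returns per-subtype unique sets and the size of
    their union.
    """
    labels = pd.Series(np.asarray(subtype_labels), index=matrix.columns)
    counts = labels.value_counts()
    qualifying = sorted(counts.index[counts >= min_group])
    if len(qualifying) < 2:
        raise ValueError("need at least 2 subtypes meeting the size threshold")
    sig: dict[str, set] = {}
    for i, st in enumerate(qualifying):
        binary = (labels == st).astype(int)
        res = sam_two_class(
            matrix, binary, fdr=fdr, min_fc=min_fc, n_perm=n_perm,
            statistic=statistic, seed=seed + i,
        )
        sig[st] = set(res.significant)
    unique: dict[str, pd.Index] = {}
    for st in qualifying:
        others = set().union(*(sig[o] for o in qualifying if o != st))
        unique[st] = pd.Index(sorted(sig[st] - others))
    union_count = len(set().union(*(set(v) for v in unique.values())))
    return unique, union_count


# ---------------------------------------------------------------------------
# PAM / nearest shrunken centroid


@dataclass
class NscModel:
    classes: list
    priors: np.ndarray
    overall_centroid: pd.Series
    class_centroids: pd.DataFrame  # protein x class
    s: pd.Series
    s0: float
    mk: np.ndarray
    d: pd.DataFrame  # standardised differences, protein x class
    delta_grid: np.ndarray
    cv_errors: np.ndarray
    selected_delta: float
    seed: int
    zscore_first: bool = True

    def shrunken_d(self, delta: float) -> pd.DataFrame:
        d = self.d.to_numpy()
        return pd.DataFrame(
            np.sign(d) * np.maximum(np.abs(d) - delta, 0.0),
            index=self.d.index,
            columns=self.d.columns,
        )

    def retained(self, delta: float | None = None) -> pd.Index:
        delta = self.selected_delta if delta is None else delta
        dp = self.shrunken_d(delta)
        return dp.index[(dp != 0).any(axis=1)]

    def shrunken_centroids(self, delta: float | None = None) -> pd.DataFrame:
        delta = self.selected_delta if delta is None else delta
        dp = self.shrunken_d(delta).to_numpy()
        denom = (self.s + self.s0).to_numpy()[:, None]
        cent = self.overall_centroid.to_numpy()[:, None] + self.mk[None, :] * denom * dp
        return pd.DataFrame(cent, index=self.d.index, columns=self.d.columns)

    def to_json_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "priors": self.priors.tolist(),
            "overall_centroid": self.overall_centroid.to_dict(),
            "class_centroids": self.class_centroids.to_dict(),
            "s": self.s.to_dict(),
            "s0": self.s0,
            "selected_delta": float(self.selected_delta),
            "retained": list(self.retained()),
            "seed": self.seed,
        }


def _fit_centroids(X: np.ndarray, lab: np.ndarray, classes: list):
    n = X.shape[1]
    K = len(classes)
    overall = X.mean(axis=1)
    cent = np.empty((X.shape[0], K))
    mk = np.empty(K)
    ss = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        mask = lab == c
        nk = int(mask.sum())
        cent[:, j] = X[:, mask].mean(axis=1)
        mk[j] = np.sqrt(1.0 / nk - 1.0 / n)
        ss += ((X[:, mask] - cent[:, j][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    d = (cent - overall[:, None]) / (mk[None, :] * (s + s0)[:, None])
    return overall, cent, mk, s, s0, d


def _predict_raw(
    X: np.ndarray,
    cent_shrunk: np.ndarray,
    s_plus_s0: np.ndarray,
    priors: np.ndarray,
    retained_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Discriminant scores delta_k and argmin labels (first index on ties)."""
    if retained_mask.sum() == 0:
        # fully shrunk model: only priors discriminate
        delta = np.tile(-2.0 * np.log(priors), (X.shape[1], 1))
        return delta, np.argmin(delta, axis=1)
    Xr = X[retained_mask]
    cr = cent_shrunk[retained_mask]
    sr = s_plus_s0[retained_mask][:, None]
    delta = np.empty((X.shape[1], cr.shape[1]))
    for j in range(cr.shape[1]):
        delta[:, j] = (((Xr - cr[:, j][:, None]) / sr) ** 2).sum(axis=0)
    delta -= 2.0 * np.log(priors)[None, :]
    return delta, np.argmin(delta, axis=1)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score across samples (applied before SAM/PAM)."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return matrix.sub(mu, axis=0).div(sd, axis=0)


def pam_train(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 10,
    n_delta: int = 30,
    zscore_first: bool = True,
    seed: int = 0,
) -> NscModel:
    """Train a nearest-shrunken-centroid model with cross-validated shrinkage.

    Standardised differences d_ik = (class mean - overall mean) /
    (m_k (s_i + s0)) with m_k = sqrt(1/n_k - 1/n) are soft-thresholded over
    a 30-point grid from 0 to max |d_ik|; stratified k-fold CV records the
    misclassification error per grid point. Class priors are proportional
    to class sizes.
    """
    lab = np.asarray(labels)
    classes = sorted(pd.unique(lab))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if zscore_first:
        matrix = zscore_rows(matrix)
    X = matrix.to_numpy(float)
    n = X.shape[1]
    counts = np.array([(lab == c).sum() for c in classes], dtype=float)
    folds_eff = folds
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    if counts.min() < folds:
        folds_eff = int(counts.min())
        logger.warning("reducing CV folds from %d to %d", folds, folds_eff)
    priors = counts / n

    overall, cent, mk, s, s0, d = _fit_centroids(X, lab, classes)
    delta_grid = np.linspace(0.0, float(np.abs(d).max()), n_delta)

    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    errors = np.zeros(n_delta)
    for train_idx, test_idx in skf.split(X.T, lab):
        ov_t, cent_t, mk_t, s_t, s0_t, d_t = _fit_centroids(
            X[:, train_idx], lab[train_idx], classes
        )
        counts_t = np.array([(lab[train_idx] == c).sum() for c in classes])
        priors_t = counts_t / counts_t.sum()
        for gi, delta in enumerate(delta_grid):
            dp = np.sign(d_t) * np.maximum(np.abs(d_t) - delta, 0.0)
            cent_shrunk = ov_t[:, None] + mk_t[None, :] * (s_t + s0_t)[:, None] * dp
            retained = (dp != 0).any(axis=1)
            _, pred = _predict_raw(
                X[:, test_idx], cent_shrunk, s_t + s0_t, priors_t, retained
            )
            true = np.array([classes.index(c) for c in lab[test_idx]])
            errors[gi] += int((pred != true).sum())
    errors /= n

    model = NscModel(
        classes=classes,
        priors=priors,
        overall_centroid=pd.Series(overall, index=matrix.index),
        class_centroids=pd.DataFrame(cent, index=matrix.index, columns=classes),
        s=pd.Series(s, index=matrix.index),
        s0=s0,
        mk=mk,
        d=pd.DataFrame(d, index=matrix.index, columns=classes),
        delta_grid=delta_grid,
        cv_errors=errors,
        selected_delta=0.0,
        seed=seed,
        zscore_first=zscore_first,
    )
    model.selected_delta = select_min_error(model)[0]
    return model


def select_min_error(model: NscModel) -> tuple[float, pd.Index, float]:
    """Largest shrinkage attaining the minimum CV error (parsimony tie-break)."""
    errs = model.cv_errors
    best = errs.min()
    idx = int(np.max(np.where(np.isclose(errs, best))))
    delta = float(model.delta_grid[idx])
    return delta, model.retained(delta), float(best)


@dataclass
class Prediction:
    labels: pd.Series
    discriminants: pd.DataFrame  # sample x class delta_k
    probabilities: pd.DataFrame  # softmin of discriminants
    ties: pd.Series  # True where argmin was tied (broken by class order)
    dropped_features: list


def pam_predict(
    model: NscModel, new_matrix: pd.DataFrame, delta: float | None = None
) -> Prediction:
    """Apply shrunken centroids to an external protein-by-sample matrix.

    Requires at least 80% of the retained panel to be present; missing
    retained proteins are dropped from the discriminant with a warning.
    When the model was trained on per-protein z-scores, the same transform
    is applied to the new cohort.
    """
    if model.zscore_first:
        new_matrix = zscore_rows(new_matrix)
    retained = model.retained(delta)
    present = retained.intersection(new_matrix.index)
    if len(retained) and len(present) / len(retained) < 0.8:
        raise ValueError(
            f"only {len(present)}/{len(retained)} retained proteins present "
            "(<80% overlap); refusing to predict"
        )
    dropped = list(retained.difference(present))
    if dropped:
        logger.warning("%d retained proteins absent; dropped", len(dropped))

    order = model.d.index
    cent_shrunk = model.shrunken_centroids(delta)
    keep = order.isin(present)
    X = new_matrix.reindex(order).to_numpy(float)
    X = np.where(np.isnan(X), 0.0, X)
    delta_scores, pred_idx = _predict_raw(
        X,
        cent_shrunk.to_numpy(),
        (model.s + model.s0).to_numpy(),
        model.priors,
        keep,
    )
    ties = pd.Series(
        (np.isclose(delta_scores, delta_scores.min(axis=1, keepdims=True)).sum(axis=1)
         > 1),
        index=new_matrix.columns,
        name="tie",
    )
    labels = pd.Series(
        [model.classes[i] for i in pred_idx],
        index=new_matrix.columns,
        name="predicted",
    )
    # softmin on half the discriminant difference (Gaussian posterior form)
    z = -0.5 * (delta_scores - delta_scores.min(axis=1, keepdims=True))
    w = np.exp(z)
    probs = w / w.sum(axis=1, keepdims=True)
    return Prediction(
        labels=labels,
        discriminants=pd.DataFrame(
            delta_scores, index=new_matrix.columns, columns=model.classes
        ),
        probabilities=pd.DataFrame(
            probs, index=new_matrix.columns, columns=model.classes
        ),
        ties=ties,
        dropped_features=dropped,
    )
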