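"""Normalisation, filtering, imputation and TIL-density arithmetic.

The quantification substrate is a set of multiplexed batches (plexes), each
carrying up to ``plex_size`` tumour channels plus one pooled-reference
channel. Normalisation follows a four-step procedure: per-batch
sample/reference ratio, log2 transform, per-protein median centring across
samples, and per-sample standardisation (mean 0, sd 1). Each step is
individually invocable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)


@dataclass
class PlexBatch:
    """One multiplexed batch: protein x channel linear intensities.

    ``intensities`` columns are channel/sample ids; exactly one column,
    named by ``reference_channel``, is the pooled reference.
    """

    intensities: pd.DataFrame
    reference_channel: str
    batch_id: str = ""

    def __post_init__(self) -> None:
        if self.reference_channel not in self.intensities.columns:
            raise ValueError(
                f"reference channel {self.reference_channel!r} not in batch"
            )
        vals = self.intensities.to_numpy(float)
        if np.nanmin(vals) < 0:
            raise ValueError("intensities must be non-negative or missing")

    @property
    def sample_channels(self) -> list[str]:
        return [c for c in self.intensities.columns if c != self.reference_channel]


@dataclass
class RawIntensitySet:
    """Collection of plex batches sharing a protein index."""

    batches: list[PlexBatch]

    @property
    def sample_ids(self) -> list[str]:
        return [s for b in self.batches for s in b.sample_channels]

    @property
    def protein_ids(self) -> pd.Index:
        idx = self.batches[0].intensities.index
        for b in self.batches[1:]:
            idx = idx.union(b.intensities.index)
        return idx


@dataclass
class TilRecord:
    """Replicate-core lymphocyte counts for one sample and marker."""

    core_counts: list[float]
    preservation_fraction: list[float]
    marker: str = "CD3"

    def __post_init__(self) -> None:
        if len(self.core_counts) != len(self.preservation_fraction):
            raise ValueError("counts and preservation fractions must align")
        if len(self.core_counts) == 0:
            raise ValueError("at least one replicate core required")
        if any(c < 0 for c in self.core_counts):
            raise ValueError("negative cell counts are invalid")
        if any(not 0 <= p <= 1 for p in self.preservation_fraction):
            raise ValueError("preservation fractions must lie in [0, 1]")


# Microscope-field conversion: counts at x400 on the TMA core are scaled by
# this factor to yield cells per mm^2.
TIL_AREA_FACTOR = 1.274
# Cores with less than half the section preserved are unreliable and dropped.
TIL_MIN_PRESERVATION = 0.5

EXCLUDED = "excluded"


def filter_completeness(matrix: pd.DataFrame, min_frac: float = 0.75) -> pd.DataFrame:
    """Keep proteins observed in at least ``min_frac`` of samples."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    frac = matrix.notna().mean(axis=1)
    out = matrix.loc[frac >= min_frac]
    if out.empty:
        warnings.warn("completeness filter removed every protein", stacklevel=2)
    return out


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k nearest protein rows.

    Distance between rows is Euclidean over co-observed samples, rescaled by
    sqrt(d / d_obs) to correct for unequal overlap. Each missing cell becomes
    the unweighted mean of the k nearest rows observed at that sample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for pid, row in matrix.iterrows():
        if row.isna().all():
            raise ValueError(f"protein {pid!r} has no observed values")
    if not matrix.isna().any().any():
        return matrix.copy()

    X = matrix.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = nan_euclidean_distances(X)  # sqrt(d/d_obs)-rescaled by construction
    np.fill_diagonal(D, np.inf)

    out = X.copy()
    missing_rows = np.where(np.isnan(X).any(axis=1))[0]
    for i in missing_rows:
        order = np.argsort(D[i], kind="stable")
        for j in np.where(np.isnan(X[i]))[0]:
            donors = order[~np.isnan(X[order, j]) & np.isfinite(D[i, order])]
            if donors.size == 0:
                raise ValueError(
                    f"no donor row observed at sample {matrix.columns[j]!r}"
                )
            if donors.size < k:
                logger.warning(
                    "only %d candidate neighbours (< k=%d) for row %s; using all",
                    donors.size,
                    k,
                    matrix.index[i],
                )
            out[i, j] = X[donors[:k], j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_reference_ratio(raw: RawIntensitySet) -> pd.DataFrame:
    """Step 1+2: per-batch sample/reference ratio, then log2.

    Proteins whose reference intensity is zero or missing in a batch are
    excluded from that batch (values set missing) with a logged reason.
    """
    cols = []
    for b in raw.batches:
        ref = b.intensities[b.reference_channel]
        bad = ~(ref > 0)
        if bad.any():
            logger.warning(
                "batch %s: %d proteins with zero/missing reference excluded",
                b.batch_id,
                int(bad.sum()),
            )
        samples = b.intensities[b.sample_channels]
        ratio = samples.div(ref.where(~bad), axis=0)
        cols.append(np.log2(ratio))
    merged = pd.concat(cols, axis=1)
    return merged


def median_center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Step 3: subtract the per-protein median across samples."""
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def standardize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Step 4: z-score each sample column (mean 0, sd 1, ddof 0)."""
    mu = matrix.mean(axis=0, skipna=True)
    sd = matrix.std(axis=0, ddof=0, skipna=True)
    sd = sd.where(sd > 0, 1.0)
    return matrix.sub(mu, axis=1).div(sd, axis=1)


def reference_ratio_normalize(raw: RawIntensitySet) -> pd.DataFrame:
    """Full normalisation: ratio -> log2 -> row median centre -> column z-score."""
    return standardize_columns(median_center_rows(log2_reference_ratio(raw)))


def til_density(record: TilRecord) -> float | str:
    """Average TIL density in cells/mm^2, or ``"excluded"``.

    Counts from cores with preservation in [0.5, 1] are corrected to 100%
    area (divided by the preserved fraction), replicate-averaged, and scaled
    by the microscope-field factor 1.274.
    """
    corrected = [
        c / p
        for c, p in zip(record.core_counts, record.preservation_fraction)
        if p >= TIL_MIN_PRESERVATION
    ]
    if not corrected:
        return EXCLUDED
    return float(np.mean(corrected)) * TIL_AREA_FACTOR


@dataclass
class MedianStrata:
    labels: pd.Series
    median: float


def stratify_by_median(values: pd.Series) -> MedianStrata:
    """Split samples into high (>= cohort median) and low groups."""
    if len(values) < 2:
        raise ValueError("need at least 2 samples to stratify")
    med = float(values.median())
    if values.nunique() == 1:
        warnings.warn("all values identical; every sample assigned high",
                      stacklevel=2)
    labels = pd.Series(
        np.where(values >= med, "high", "low"), index=values.index, name="stratum"
    )
    return MedianStrata(labels=labels, median=med)
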