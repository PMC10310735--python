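"""Synthetic multi-plex proteomic cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
multi-subtype cohort quantified in 10-sample plexes plus a pooled-reference
channel, planted subtype mean shifts on marker proteins, planted correlated
protein modules driven by latent factors, abundance-dependent (MNAR)
missingness, batch effects, proportional-hazards survival linked to the
planted structure, and a paired transcriptome with controlled per-gene
mRNA-protein Spearman correlation.

The default configuration mirrors a large FFPE sarcoma cohort of the kind
this pipeline targets: 321 tumours in 11-channel plexes, 8148 proteins with
log-normal dynamic range, and missingness calibrated so roughly 40% of
proteins are quantified in every sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PlexBatch, RawIntensitySet


class InvalidConfigError(ValueError):
    """Configuration violates a generator invariant."""


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    ``subtype_effect`` is the log2 mean shift planted on each subtype's
    marker proteins. ``module_within_correlation`` is the target pairwise
    Pearson correlation of member proteins (achieved through a shared latent
    factor with loading lambda = noise_sd * sqrt(r / (1 - r)), so the
    closed form r = lambda^2 / (lambda^2 + noise_sd^2) holds exactly when
    batch_sd = 0). ``mnar_strength`` controls how steeply the probability of
    a missing value rises as abundance falls (0 = purely random
    missingness). ``plex_dropout_rate`` is the mean per-(protein, plex)
    probability that a protein is not identified in an entire run, the
    dominant source of incomplete rows in isobaric experiments.
    """

    n_samples: int = 321
    n_proteins: int = 8148
    n_subtypes: int = 3
    subtype_proportions: tuple[float, ...] | None = None
    subtype_effect: float = 1.0
    n_marker_proteins_per_subtype: int = 50
    module_sizes: tuple[int, ...] = (100, 80, 60, 50, 41)
    module_within_correlation: float = 0.7
    plex_size: int = 10
    batch_sd: float = 0.2
    noise_sd: float = 0.5
    missing_rate: float = 0.0005
    mnar_strength: float = 1.0
    plex_dropout_rate: float = 0.46
    survival_betas: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3
    followup_cap: float = 5.0
    baseline_hazard: float = 0.25
    clinical_risk_link: float = 0.0
    rho_mixture: tuple[tuple[float, float], ...] = ((0.803, 0.0), (0.197, 0.7))
    plex_assignment: str = "randomized"  # or "grouped" (by subtype)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise InvalidConfigError("need at least 2 subtypes")
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple(
                [1.0 / self.n_subtypes] * self.n_subtypes
            )
        if len(self.subtype_proportions) != self.n_subtypes:
            raise InvalidConfigError("one proportion per subtype required")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise InvalidConfigError("subtype proportions must sum to 1")
        n_module = sum(self.module_sizes)
        n_marker = self.n_subtypes * self.n_marker_proteins_per_subtype
        if n_module + n_marker > self.n_proteins:
            raise InvalidConfigError(
                "module and marker proteins exceed n_proteins"
            )
        if self.plex_size < 2:
            raise InvalidConfigError("plex_size must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if not 0 <= self.module_within_correlation < 1:
            raise InvalidConfigError("module correlation must lie in [0, 1)")
        if self.mnar_strength < 0:
            raise InvalidConfigError("mnar_strength must be >= 0")
        if self.followup_cap <= 0:
            raise InvalidConfigError("followup_cap must be positive")
        if self.plex_assignment not in ("randomized", "grouped"):
            raise InvalidConfigError("plex_assignment: randomized or grouped")
        for w, r in self.rho_mixture:
            if abs(r) > 1:
                raise InvalidConfigError("|rho| targets must lie in [-1, 1]")
            if w < 0:
                raise InvalidConfigError("rho mixture weights must be >= 0")


@dataclass
class GroundTruth:
    """Everything planted in the cohort, for downstream recovery checks."""

    subtype_labels: pd.Series  # sample -> subtype label
    marker_proteins: dict[str, list[str]]  # subtype -> planted markers
    module_membership: pd.Series  # protein -> module id ("" = none)
    module_factors: pd.DataFrame  # sample x module latent factors
    batch_assignment: pd.Series  # sample -> batch id
    true_rho: pd.Series  # gene -> Spearman target
    true_hazard_coefs: dict[str, float]
    risk_scores: pd.DataFrame | None  # sample x endpoint linear predictors
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_labels": self.subtype_labels.to_dict(),
            "marker_proteins": self.marker_proteins,
            "module_membership": self.module_membership.to_dict(),
            "batch_assignment": self.batch_assignment.to_dict(),
            "true_rho": self.true_rho.to_dict(),
            "true_hazard_coefs": self.true_hazard_coefs,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# Log2 location and scale of the base (protein-level) abundance
# distribution; sd 1.5 reproduces a proteome-like dynamic range of roughly
# four orders of magnitude, which is what makes abundance-dependent
# missingness behave realistically.
BASE_LOG2_MEAN = 20.0
BASE_LOG2_SD = 1.5

# Whole-plex dropout follows a detection-limit model: the probit steepness 8
# (in units of the standardised base abundance) corresponds to a
# limit-of-detection spread of BASE_LOG2_SD / 8 ~ 0.2 log2 units per run.
# With the default mean dropout rate this reproduces a cohort in which
# roughly 40% of identified proteins are quantified in every sample.
LOD_STEEPNESS = 8.0


def _sample_features(config: CohortConfig, rng: np.random.Generator):
    """Assign subtypes, batches, marker/module proteins and latent factors."""
    n, p = config.n_samples, config.n_proteins
    samples = [f"S{i:04d}" for i in range(n)]
    proteins = [f"P{i:05d}" for i in range(p)]

    counts = np.floor(np.asarray(config.subtype_proportions) * n).astype(int)
    counts[0] += n - counts.sum()
    subtype_names = [f"ST{j + 1}" for j in range(config.n_subtypes)]
    labels = np.repeat(subtype_names, counts)
    rng.shuffle(labels)
    subtype_labels = pd.Series(labels, index=samples, name="subtype")

    order = (
        np.argsort(labels, kind="stable")
        if config.plex_assignment == "grouped"
        else rng.permutation(n)
    )
    batch_of = np.empty(n, dtype=object)
    for pos, samp_idx in enumerate(order):
        batch_of[samp_idx] = f"B{pos // config.plex_size:03d}"
    batch_assignment = pd.Series(batch_of, index=samples, name="batch")

    cursor = 0
    marker_proteins: dict[str, list[str]] = {}
    for name in subtype_names:
        marker_proteins[name] = proteins[
            cursor : cursor + config.n_marker_proteins_per_subtype
        ]
        cursor += config.n_marker_proteins_per_subtype
    membership = pd.Series("", index=proteins, name="module")
    for m, size in enumerate(config.module_sizes, start=1):
        membership.iloc[cursor : cursor + size] = f"M{m}"
        cursor += size

    factors = pd.DataFrame(
        rng.standard_normal((n, len(config.module_sizes))),
        index=samples,
        columns=[f"M{m + 1}" for m in range(len(config.module_sizes))],
    )
    return samples, proteins, subtype_labels, batch_assignment, marker_proteins, membership, factors


def _missing_probability(
    log2_abundance: np.ndarray, rate: float, strength: float
) -> np.ndarray:
    """Probit-link MNAR mixed with MCAR, calibrated to a mean rate.

    p = rate * Phi(-z * strength) / E[Phi(-z * strength)] with z the
    standardised log2 abundance; strength 0 reduces to uniform MCAR.
    """
    if rate == 0:
        return np.zeros_like(log2_abundance)
    z = (log2_abundance - log2_abundance.mean()) / max(log2_abundance.std(), 1e-12)
    raw = stats.norm.sf(z * strength)
    return np.clip(rate * raw / raw.mean(), 0.0, 1.0)


def generate_raw_plexes(
    config: CohortConfig,
) -> tuple[RawIntensitySet, GroundTruth]:
    """Simulate the multiplexed raw intensities and their ground truth.

    Sample intensity is 2^(base + subtype shift + module latent component +
    batch effect + noise). The pooled-reference channel of every plex is the
    per-protein mean of the cohort's linear abundances; since a physical
    reference aliquot runs inside each plex, the batch effect multiplies the
    reference as well, which is exactly why the ratio step cancels it.
    """
    rng = np.random.default_rng(config.seed)
    (
        samples,
        proteins,
        subtype_labels,
        batch_assignment,
        marker_proteins,
        membership,
        factors,
    ) = _sample_features(config, rng)
    n, p = config.n_samples, config.n_proteins

    base = rng.normal(BASE_LOG2_MEAN, BASE_LOG2_SD, size=p)
    L = np.tile(base[:, None], (1, n))

    for name, members in marker_proteins.items():
        mask = subtype_labels.to_numpy() == name
        idx = membership.index.get_indexer(members)
        L[np.ix_(idx, mask)] += config.subtype_effect

    r = config.module_within_correlation
    lam = config.noise_sd * np.sqrt(r / (1 - r)) if r > 0 else 0.0
    for m in factors.columns:
        idx = np.where(membership.to_numpy() == m)[0]
        L[idx, :] += lam * factors[m].to_numpy()[None, :]

    batches = sorted(batch_assignment.unique())
    batch_offsets = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, size=(p, len(batches))),
        index=proteins,
        columns=batches,
    )
    batch_cols = batch_assignment.to_numpy()
    for b in batches:
        L[:, batch_cols == b] += batch_offsets[b].to_numpy()[:, None]

    if config.noise_sd > 0:
        L += rng.normal(0.0, config.noise_sd, size=(p, n))

    intensity = np.exp2(L)
    reference_base = intensity.mean(axis=1)  # exact cohort-mean abundance

    # missingness: per-(protein, plex) dropout (whole run) + per-entry MNAR
    plex_p = _missing_probability(
        base,
        config.plex_dropout_rate,
        LOD_STEEPNESS if config.mnar_strength > 0 else 0.0,
    )
    entry_p = _missing_probability(
        L.ravel(), config.missing_rate, config.mnar_strength
    ).reshape(p, n)
    entry_missing = rng.uniform(size=(p, n)) < entry_p

    plex_list = []
    for b in batches:
        cols = [s for s, sb in batch_assignment.items() if sb == b]
        col_idx = [samples.index(s) for s in cols]
        vals = intensity[:, col_idx].copy()
        vals[entry_missing[:, col_idx]] = np.nan
        dropped = rng.uniform(size=p) < plex_p
        vals[dropped, :] = np.nan
        ref_name = f"{b}_ref"
        ref = reference_base * np.exp2(batch_offsets[b].to_numpy())
        df = pd.DataFrame(vals, index=proteins, columns=cols)
        df[ref_name] = ref
        plex_list.append(PlexBatch(df, reference_channel=ref_name, batch_id=b))

    weights = np.array([w for w, _ in config.rho_mixture], dtype=float)
    weights = weights / weights.sum()
    rho_vals = np.array([r_ for _, r_ in config.rho_mixture])
    true_rho = pd.Series(
        rho_vals[rng.choice(len(rho_vals), size=p, p=weights)],
        index=proteins,
        name="rho",
    )

    truth = GroundTruth(
        subtype_labels=subtype_labels,
        marker_proteins=marker_proteins,
        module_membership=membership,
        module_factors=factors,
        batch_assignment=batch_assignment,
        true_rho=true_rho,
        true_hazard_coefs=dict(config.survival_betas),
        risk_scores=None,
        seed=config.seed,
    )
    return RawIntensitySet(plex_list), truth


def generate_paired_transcriptome(
    protein_matrix: pd.DataFrame, truth: GroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """Emit an mRNA matrix with controlled per-gene Spearman correlation.

    Uses a Gaussian copula on ranks: the protein row is mapped to normal
    scores, mixed with independent noise at the Pearson equivalent
    2*sin(pi*rho_s/6) of the Spearman target, and the result is the mRNA
    value (already normal-scale, suitable for rank statistics).
    """
    missing = protein_matrix.index.difference(truth.true_rho.index)
    if len(missing):
        raise InvalidConfigError(
            f"no correlation target for genes: {list(missing[:3])} ..."
        )
    rho_s = truth.true_rho.loc[protein_matrix.index].to_numpy()
    if np.any(np.abs(rho_s) > 1):
        raise InvalidConfigError("|true_rho| must lie in [-1, 1]")
    rng = np.random.default_rng(truth.seed + 101 if seed is None else seed)
    n = protein_matrix.shape[1]
    ranks = protein_matrix.rank(axis=1, method="average").to_numpy()
    z_prot = stats.norm.ppf((ranks - 0.5) / n)
    r_pearson = 2.0 * np.sin(np.pi * rho_s / 6.0)
    noise = rng.standard_normal(protein_matrix.shape)
    z_mrna = (
        r_pearson[:, None] * z_prot
        + np.sqrt(1.0 - r_pearson**2)[:, None] * noise
    )
    return pd.DataFrame(
        z_mrna, index=protein_matrix.index, columns=protein_matrix.columns
    )


def _feature_value(key: str, truth: GroundTruth) -> np.ndarray:
    """Resolve a planted-feature key to a per-sample vector.

    Keys: ``subtype:<label>`` (0/1 indicator) or ``module:<id>`` (latent
    factor driving that module).
    """
    if key.startswith("subtype:"):
        label = key.split(":", 1)[1]
        if label not in set(truth.subtype_labels):
            raise InvalidConfigError(f"unknown subtype {label!r} in survival_betas")
        return (truth.subtype_labels == label).astype(float).to_numpy()
    if key.startswith("module:"):
        mod = key.split(":", 1)[1]
        if mod not in truth.module_factors.columns:
            raise InvalidConfigError(f"unknown module {mod!r} in survival_betas")
        return truth.module_factors[mod].to_numpy()
    raise InvalidConfigError(f"unrecognised planted feature key {key!r}")


ENDPOINTS = ("LRFS", "MFS", "OS")


def simulate_survival(
    truth: GroundTruth, config: CohortConfig
) -> pd.DataFrame:
    """Simulate clinical covariates and exponential proportional-hazards
    event times for the three endpoints.

    Latent death, local-recurrence and metastasis times are drawn
    independently from exponential hazards scaled by exp(linear predictor);
    composite endpoints take the earlier of the component event and death.
    Censoring is independent exponential plus an administrative cap at
    ``followup_cap`` years. Clinical covariates are independent of planted
    risk unless ``clinical_risk_link`` > 0 links tumour grade to it.
    """
    rng = np.random.default_rng(config.seed + 7919)
    samples = truth.subtype_labels.index
    n = len(samples)

    lp = np.zeros(n)
    for key, beta in config.survival_betas.items():
        lp += beta * _feature_value(key, truth)

    lam = config.baseline_hazard * np.exp(lp)
    t_death = rng.exponential(1.0 / lam)
    t_local = rng.exponential(1.0 / lam)
    t_meta = rng.exponential(1.0 / lam)

    if config.censoring_rate > 0:
        c_rate = config.baseline_hazard * config.censoring_rate / (
            1.0 - config.censoring_rate
        )
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    followup = np.minimum(t_cens, config.followup_cap)

    clin = pd.DataFrame(index=samples)
    clin["subtype"] = truth.subtype_labels
    risk_pct = stats.rankdata(lp) / n
    grade_shift = config.clinical_risk_link * (risk_pct - 0.5)
    clin["grade"] = np.clip(
        rng.integers(1, 4, size=n) + np.round(2 * grade_shift).astype(int), 1, 3
    )
    clin["size_cm"] = np.round(rng.lognormal(1.8, 0.6, size=n), 1)
    clin["depth"] = rng.choice(["superficial", "deep"], size=n, p=[0.3, 0.7])
    clin["margin"] = rng.choice(["R0", "R1", "R2"], size=n, p=[0.7, 0.25, 0.05])
    clin["age"] = rng.integers(18, 90, size=n)
    clin["sex"] = rng.choice(["F", "M"], size=n)
    clin["performance_status"] = rng.choice([0, 1, 2], size=n, p=[0.5, 0.4, 0.1])

    clin["time_to_death"] = np.where(t_death <= followup, t_death, np.nan)
    clin["time_to_local_recurrence"] = np.where(
        t_local <= followup, t_local, np.nan
    )
    clin["time_to_metastasis"] = np.where(t_meta <= followup, t_meta, np.nan)
    clin["last_followup"] = followup

    first = {
        "LRFS": np.minimum(t_local, t_death),
        "MFS": np.minimum(t_meta, t_death),
        "OS": t_death,
    }
    for ep in ENDPOINTS:
        event = first[ep] <= followup
        time = np.where(event, first[ep], followup)
        time = np.minimum(time, config.followup_cap)
        event = event & (first[ep] <= config.followup_cap)
        clin[f"{ep}_time"] = time
        clin[f"{ep}_event"] = event.astype(int)

    truth.risk_scores = pd.DataFrame(
        {ep: lp for ep in ENDPOINTS}, index=samples
    )
    return clin
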