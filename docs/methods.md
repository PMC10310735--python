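# Methods

This note documents the statistical models behind `sarcomics`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical decisions a user relying on the results should
know about.

## Quantification model and normalisation

The pipeline assumes isobaric multiplexed quantification: plexes of up to
`plex_size` tumour channels (default 10) plus one pooled-reference channel
mixed from representative cases and measured in every plex. Because the
reference aliquot physically runs inside each plex, the sample/reference
ratio removes multiplicative between-plex effects; the package applies the
four normalisation steps in order — (1) per-plex sample/reference ratio,
(2) log2, (3) per-protein median centring across samples, (4) per-sample
z-scoring — each individually invocable. Step 4 is idempotent to 1e-10.
Standardisation uses the standard deviation (ddof 0); a median-absolute-
deviation variant was considered and rejected as the less conventional
reading of "standardised".

In the orchestrated pipeline the completeness filter (default: proteins in
< 75% of samples removed) and kNN imputation run on the log2 ratio matrix,
i.e. after steps 1–2 and before steps 3–4. Imputing on the log-ratio scale
rather than raw intensities keeps the neighbour distances meaningful across
the proteome's dynamic range; the ratio step is entrywise, so it commutes
with filtering.

kNN imputation (default k = 10, the originating algorithm's conventional
default) fills each missing cell with the unweighted
mean of the k nearest protein rows that are observed at that sample.
Distances are Euclidean over co-observed coordinates rescaled by
√(d/d_obs) — the standard correction for unequal overlap — and rows with
fewer than k eligible donors fall back to all available donors with a
logged warning.

## Synthetic cohorts

The generator's default configuration mirrors a large archival sarcoma
cohort of the kind the pipeline targets: 321 tumours in 10+1-channel plexes, 8148 proteins, three
subtypes, and missingness calibrated so that roughly 40% of proteins are
quantified in every sample (the observed regime for FFPE TMT cohorts of
this size). The signal model in log2 space is

    x_is = b_i + effect·1[i marker of subtype(s)] + λ·f_{m(i),s}
           + batch_{b(s),i} + ε_is

with base abundances b_i ~ N(20, 1.5²) (a proteome-like dynamic range of
about four orders of magnitude), marker shifts of `subtype_effect` log2
units (default 1.0), module latent factors f ~ N(0,1) with loading
λ = σ_ε·√(r/(1−r)) so the within-module Pearson correlation is exactly
r = λ²/(λ²+σ_ε²) when batch effects are off, per-(protein, plex) batch
offsets ~ N(0, batch_sd²), and residual noise σ_ε = 0.5 log2 units. The
reference channel is the exact per-protein mean of the realised cohort
abundances, multiplied by the plex's batch factor (the reference is treated
as a noiseless aliquot; its measurement noise is folded into the sample
term).

Missingness has two components, both probit-linked to abundance when
`mnar_strength` > 0 and uniform when it is 0:

* whole-plex dropout (a protein not identified in a run), the dominant
  mechanism in isobaric data, with a steep detection-limit probit
  (steepness 8 in standardised-abundance units, i.e. a limit-of-detection
  spread of ~0.2 log2 units) and mean rate 0.46;
* scattered entry-level missingness at a low default rate (5·10⁻⁴),
  since reporter ions are almost always present once a protein is
  identified in a plex.

With these defaults a 321 × 8148 cohort yields ≈ 3000 fully observed
proteins and ≈ 4400 identified per run. Plex assignment is randomised by
default; grouped-by-subtype is available for studying confounded designs.

The paired transcriptome uses a Gaussian copula on ranks: protein rows are
mapped to normal scores and mixed with independent noise at the Pearson
equivalent 2·sin(πρ_s/6) of the per-gene Spearman target, giving exact
control of the target in expectation; targets of ±1 are emitted as
deterministic monotone copies. The default target mixture places ρ = 0.7 on
19.7% of genes and 0 elsewhere, the positive-correlation regime typical of
matched tumour proteome/transcriptome panels.

Survival is exponential proportional hazards: latent death, local
recurrence and metastasis times with hazard `baseline_hazard`·exp(Σβ·x),
composite endpoints (LRFS = first of recurrence/death, MFS = first of
metastasis/death), independent exponential censoring tuned to the requested
censoring fraction, and administrative capping at `followup_cap` (default
5 years). Clinical covariates are generated independently of the planted
risk unless `clinical_risk_link` ties tumour grade to it — this lets
multivariable-adjustment tests distinguish confounded from independent
signals.

What the generator does **not** emulate: peptide-level quantification and
isotope-impurity interference, ratio compression, non-Gaussian heavy-tailed
abundance noise, correlated missingness between related proteins, informative
censoring, and cohort heterogeneity in follow-up practice. Tests passing on
these cohorts therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artefact of real
acquisitions.

## Consensus clustering and model selection

`run_consensus` subsamples 80% of samples and 80% of proteins per
repetition (1000 repetitions, k = 2..10 by default), clusters each
subsample (agglomerative with Spearman/Pearson/Euclidean distance and
average or complete linkage, or k-means), and tallies co-clustering over
co-sampling counts (0/0 defined as 0). Final labels at any k come from an
average-linkage cut of 1 − consensus, the convention of the consensus-clustering literature.

The CDF area of a consensus matrix is the step integral
Σ(u_i − u_{i−1})·F(u_i) over sorted entry values, so a perfectly 0/1 matrix
saturates at 1. The automatic choice of k defaults to an elbow rule: if any
k saturates the area (≥ 0.995) the smallest such k wins; otherwise k is the
point after which the relative delta-area drops the most. An absolute
threshold rule (smallest k with Δ(k+1) < 0.025 and a locally maximal
silhouette) is available via `method="threshold"`, but in practice consensus
matrices keep accruing small amounts of area at every k — post-elbow deltas
plateau around 0.05–0.08 on realistic cohorts regardless of repetition
count — so an absolute cutoff either never fires or fires everywhere; the
drop rule is scale-free and recovers planted k reliably. Automatic selection
approximates what is ultimately a judgement call made by inspecting the CDF,
delta-area and tracking plots.

SigClust tests a 2-cluster split against a single zero-mean Gaussian whose
covariance is diagonal with the data's covariance eigenvalues after hard
thresholding: eigenvalues below the background noise σ̂² are replaced by
σ̂², with σ̂² = (MAD of all matrix entries / 0.6745)², the robust estimate
the hard-thresholding variant calls for. Each of the n_sim (default 1000)
null datasets is split by 2-means and scored by CI = within-SS/total-SS;
p = (1 + #{null CI ≤ observed CI})/(n_sim + 1). For more than two observed
clusters the test runs on every cluster pair and reports the maximum
pairwise p as the overall significance (the 2-vs-rest alternative was
rejected as it conflates separation with imbalance). Because the null draws
from *sample* eigenvalues, whose spread overstates the population spectrum,
the test is somewhat conservative: null p-values are super-uniform rather
than exactly uniform, and empirical type-I error at nominal 0.05 is well
below 0.05.

The Monte-Carlo consensus variant consensus-clusters the real data and
`n_null` Gaussian reference datasets matched to the observed
principal-component eigenvalue spectrum, scores each with PAC (the fraction
of off-diagonal consensus entries strictly inside (0.1, 0.9)), and reports
per k the relative score ln(mean null PAC / real PAC) and the empirical
p = (1 + #{null PAC ≤ real PAC})/(n_null + 1). The chosen k maximises the
relative score among k with p < 0.05; when no k is significant the verdict
is "no structure" (chosen_k = None). PAC values are floored at one over the
squared sample count before taking logs. Internal defaults (100 repetitions,
100 null datasets) are this package's own.

## SAM and nearest shrunken centroids

Two-class SAM uses the gene-wise scatter
s_i = √((1/n₁+1/n₂)·pooled SS/(n₁+n₂−2)) and either the plain Student
denominator (`t_stat`, the default for two-class marker calling) or the moderated `d_stat` with exchangeability
constant s₀ = median(s_i) (the standard SAM choice; used for the multiclass
SAM→PAM feature pool). q-values are the E[V]/R permutation plug-in with
π₀ = 1: for each |score| threshold, the expected number of null exceedances
across label permutations over the observed count, monotonised along the
score ranking. All distinct label assignments are enumerated exactly
whenever their number is at most n_perm — making q-values deterministic on
small cohorts — and the observed assignment and its complement are excluded
from the null ensemble (they carry the alternative). Significance requires
q ≤ FDR (default 1%) and linear fold change ≥ 1.5.

Subtype-unique markers run one-vs-rest SAM for every subtype with more than
20 cases; "unique" means upregulated-significant for exactly one qualifying
subtype.

The nearest-shrunken-centroid classifier standardises centroid differences
d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)), m_k = √(1/n_k − 1/n), soft-thresholds
them over a 30-point grid from 0 to max|d_ik|, and scores sample x by
δ_k(x) = Σ(x_i − x̄′_ik)²/(s_i+s₀)² − 2·ln π_k over retained proteins, with
priors proportional to class size. Shrinkage is selected by stratified
10-fold cross-validation as the **largest** Δ attaining the minimum error
(parsimony tie-break). Per-protein z-scoring is applied before training by
default and recorded in the model so external cohorts are transformed
identically at prediction; prediction refuses matrices carrying less than
80% of the retained panel and flags argmin ties (broken by class order).

## Co-expression modules

Signed-hybrid adjacency (negative correlations zeroed, β = 5 by default;
`pick_soft_threshold` reports the scale-free fit R² and mean connectivity
over a β grid and suggests the smallest β with signed R² ≥ 0.8 and mean
connectivity ≥ 1). TOM and 1−TOM follow the standard formula with unit
diagonal. Module detection is a reimplementation of dynamic hybrid branch
cutting in simplified form: a static cut at 0.99 of the dendrogram height
range, minimum module size 30, and dissolution of branches whose core
scatter (mean internal dissimilarity) exceeds the deep-split preset — the
published deepSplit 0–4 semantics mapped to maximum-core-scatter fractions
(0.64, 0.73, 0.82, 0.91, 0.95) of the cut range, deep split 2 by default.
It is not a line-for-line port of the reference algorithm (no iterative
branch decomposition or PAM-stage reassignment), but recovers planted
blocks of 40–60 proteins at within-correlation 0.7 with Jaccard ≥ 0.8
while leaving noise proteins ungrouped.

Modules whose sign-oriented first-principal-component summaries (eigengenes)
have Pearson dissimilarity 1 − cor below 0.25 are merged, closest pair
first, until stable — so merging is idempotent. The eigengene exists only
for merging; the module score used for stratification is the per-sample
median over member proteins, split at the empirical tertiles with boundary
values assigned to the lower stratum (strata sizes then differ by at most
one for distinct scores). Network edge export defaults to TOM similarity
above 0.05; the choice of TOM as the exported similarity is this package's own
convention, so edge counts are comparable only between runs of this
pipeline.

## Enrichment

ssGSEA ranks each sample's genes (rank normalisation on by default; ties
broken by row order), weights in-set ranks by |rank|^0.75, and integrates
the difference between the weighted in-set and unweighted out-of-set ECDFs
down the ordering. Sets with fewer than 10 members in the matrix are
skipped. Normalised ES divides by the global max−min span; scores are then
z-scored within each sample across the set collection (the literal reading
of "z-scored across gene sets"), with the per-set-across-samples axis —
what a clustered heatmap typically wants — available by flag.

Pre-ranked GSEA sorts by decreasing metric (ties broken by identifier for
determinism), uses the weighted Kolmogorov–Smirnov running sum with weight
|metric|, permutes set membership for the null (vectorised), normalises ES
by the mean same-sign null ES, and computes FDR by the standard pooled-NES
procedure, sign-separated. Size filters default to 9–501 members.
Overrepresentation is the exact hypergeometric upper tail with
Benjamini–Hochberg adjustment.

## Survival

Endpoints are built from raw event columns: LRFS events are local
recurrence or death, MFS metastasis or death, OS death; event-free samples
are censored at last follow-up and everything is administratively capped at
5 years. Cox models use lifelines with Efron tie handling; monotone
likelihood (complete separation) is flagged rather than silently reported.
The per-feature hazard screen standardises each feature first so the
HR > 2 / HR < 0.5 rule operates per standard deviation (the rule is
scale-dependent otherwise; the per-unit alternative can be had by disabling
standardisation). Features whose univariable fit does not converge, or
whose |log HR| exceeds 15, are excluded from significant sets.

Martingale cutpoints: residuals of the null model (event indicator minus
Nelson–Aalen cumulative hazard at the observed time) are smoothed against
the log-transformed covariate with a running-line smoother (span 0.5); the
cutpoint is the zero crossing nearest the steepest smoothed slope. Two
fallbacks return the median with a warning: no zero crossing, and no
detectable association between covariate and residuals (Spearman p ≥ 0.05)
— without the association gate, noise crossings would masquerade as
cutpoints on unrelated covariates.

The likelihood-ratio gain of nested Cox models is
gain% = 100·(LRχ²_ext − LRχ²_base)/LRχ²_base with a χ² p-value on the added
degrees of freedom; nesting and identical records are enforced.

## Concordance

Layers are intersected on gene identifiers and samples. Per-gene Spearman
p-values are exact (full permutation enumeration) for ≤ 8 shared samples
and use the t approximation above that — the exact path's cost grows
factorially and is pointless once the approximation is accurate — with BH
classes at FDR 0.05 for both the positive and negative direction. The
dual-layer hazard comparison reuses the survival screen per layer and
endpoint; "opposing" requires p < 0.05 in both layers with hazard ratios on
opposite sides of 1.

## Problem sizes in the test suite and acceptance script

The statistical checks run on deliberately compact instances: null
calibration on 50×20 matrices (100 seeds), SigClust calibration on 10×40
single Gaussians (200 simulations of 100 nulls), subtype recovery on
300-sample/400-protein cohorts with 100-repetition consensus, module
recovery on 755-protein cohorts, and Cox coverage on 200 seeds of n = 500.
These sizes give stable Monte-Carlo estimates of every rate being asserted
while keeping the full suite in the low minutes; all of them are the
package's own choices and are configurable upward.

## Known limitations

* The dynamic tree cut is a behavioural reimplementation, not a port;
  branch-level agreement with the reference implementation on borderline
  topologies is not guaranteed.
* SigClust is conservative (see above); borderline cluster significance
  should be read with that bias in mind.
* The GSEA FDR uses the pooled-NES estimator, which is itself an
  approximation with known granularity at small permutation counts.
* No competing risks, time-varying covariates, or module-preservation
  statistics across cohorts.
* Gene identifiers must already match across layers and gene sets; no
  orthology or identifier mapping is provided.
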