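# sarcomics

A tested, reusable implementation of a pan-sarcoma proteomic analysis
pipeline for multiplexed (TMT-style) tumour cohorts: pooled-reference
normalisation, consensus subtype discovery with significance testing,
nearest-shrunken-centroid marker panels, weighted co-expression modules,
gene-set enrichment, survival modelling, and proteome–transcriptome
concordance — together with a synthetic-cohort generator with known ground
truth so that every stage can be exercised and validated without access to
patient data.

It is written for computational biologists analysing isobaric-labelled
protein quantification matrices (proteins × samples, organised in plexes
with a pooled-reference channel) alongside clinical annotation and,
optionally, a paired transcriptome.

## The methods at the core

* **Normalisation.** Per plex, each sample channel is divided by the
  pooled-reference channel, log2-transformed, median-centred per protein and
  z-scored per sample. Because the reference aliquot runs inside every plex,
  the ratio step cancels between-plex batch effects. Proteins observed in
  fewer than 75% of samples are removed; the remainder are imputed by
  k-nearest-neighbour rows (Euclidean over co-observed samples, rescaled by
  √(d/d_obs)).
* **Consensus clustering.** Pairwise co-clustering frequencies over
  1000 resamples of 80% of samples and 80% of proteins give a consensus
  matrix M_k per cluster count k; k is chosen from the CDF area of M_k
  (Δ(k) = (A(k) − A(k−1))/A(k−1)) and silhouettes. Cluster significance uses
  SigClust (cluster index CI = within-SS/total-SS against a single-Gaussian
  null with hard-thresholded covariance eigenvalues) and a Monte-Carlo
  consensus variant that compares the proportion of ambiguous consensus
  entries (PAC) against eigen-spectrum-matched Gaussian references.
* **SAM–PAM panels.** Two-class SAM scores d_i = (x̄₂ − x̄₁)/(s_i + s₀) with
  permutation q-values (significant at FDR < 1% and fold change ≥ 1.5);
  nearest-shrunken-centroid classification soft-thresholds the standardised
  centroid differences d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)), selecting the
  shrinkage Δ* by 10-fold cross-validation (largest Δ at minimum error).
* **Co-expression modules.** Signed-hybrid adjacency a_ij = cor_ij^β
  (β = 5), topological overlap TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 −
  a_ij), average-linkage clustering of 1 − TOM with dynamic branch cutting
  (deep split 2, minimum module size 30) and eigengene merging at cut height
  0.25. Module scores are per-sample medians of member proteins, stratified
  into tertiles.
* **Survival.** LRFS/MFS/OS from primary surgery with administrative
  censoring at 5 years; Kaplan–Meier and Cox models (Efron ties) via
  lifelines; per-feature hazard screening (significant when p < 0.05 and
  HR > 2 or < 0.5 per SD); martingale-residual cutpoints for non-linear
  covariates; and the likelihood-ratio gain
  gain% = 100·(LRχ²_ext − LRχ²_base)/LRχ²_base for nested model comparisons.
* **Concordance.** Per-gene Spearman ρ between protein and mRNA layers with
  BH-FDR classes, dual-layer hazard screening, the all-endpoint overlap
  between layers, and opposing-direction detection.

## Worked example

Simulate a 300-sample cohort with three planted subtypes (1.0 log2 marker
shift), normalise it, rediscover the subtypes, reduce them to a marker
panel, and test the planted survival effect:

```python
from sarcomics.pipeline import run_pipeline

config = {
    "stages": ["simulate", "preprocess", "cluster", "classify", "survival"],
    "cohort": {
        "n_samples": 300, "n_proteins": 400, "n_subtypes": 3,
        "subtype_effect": 1.0, "n_marker_proteins_per_subtype": 50,
        "module_sizes": [60, 50],
        "survival_betas": {"subtype:ST1": 0.69},  # log 2: HR = 2 for ST1
    },
    "cluster": {"reps": 200, "k_max": 6, "sigclust": True},
}
manifest = run_pipeline(config, "demo_out", seed=0)
```

The manifest records, per stage (values printed by the run above):

```text
simulate    n_complete_proteins 149 of 400  (missingness emulates plex dropout)
preprocess  n_proteins_kept 198 after the 75% completeness filter
cluster     chosen_k 3, ari_vs_truth 1.0, sigclust_overall_p 0.002
classify    panel_size 46 at cv_error 0.0, panel_precision 1.0
survival    logrank_p < 1e-4, cox_llr_chi2 24.7, HR(cluster 3 vs 1) = 1.91
```

Reading it: consensus clustering recovers the three planted subtypes
exactly (adjusted Rand index 1.0) and every pairwise split is significant
(SigClust p = 0.002, the smallest value 500 null simulations can resolve);
the shrunken-centroid panel keeps 46 proteins — all planted markers — at
zero cross-validated error; and the Cox hazard ratio for the cluster
carrying the planted log-hazard of 0.69 is estimated at 1.91 against a true
value of 2.

The same stages are available as shell subcommands
(`sarcomics simulate|preprocess|cluster|sam|pam|modules|ssgsea|gsea|ora|survival|concord|run`,
each with `--config`, `--seed`, `--out`).

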