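"""Configuration-driven orchestration of the analysis stages.

``run_pipeline`` executes the requested stages in dependency order
(simulate -> preprocess -> cluster / classify / modules / enrich ->
survival / concordance), writes every artefact in the documented text
formats, and records a manifest (parameters, seeds, SHA-256 hashes of the
outputs and the summary metrics each stage computed) sufficient to
reproduce any output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import concordance, consensus, enrichment, io, modules, sam_pam, survival
from .preprocess import (
    filter_completeness,
    knn_impute,
    log2_reference_ratio,
    median_center_rows,
    standardize_columns,
)
from .synthetic import (
    CohortConfig,
    generate_paired_transcriptome,
    generate_raw_plexes,
    simulate_survival,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate",
    "preprocess",
    "cluster",
    "classify",
    "modules",
    "enrich",
    "survival",
    "concord",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineState:
    """In-memory artefacts passed between stages."""

    def __init__(self) -> None:
        self.raw = None
        self.truth = None
        self.clinical: pd.DataFrame | None = None
        self.normalized: pd.DataFrame | None = None
        self.labels: pd.Series | None = None
        self.records: pd.DataFrame | None = None
        self.assignment = None
        self.mrna: pd.DataFrame | None = None

    def require(self, attr: str, needed_by: str):
        val = getattr(self, attr)
        if val is None:
            raise RuntimeError(
                f"stage {needed_by!r}: missing upstream artefact {attr!r}"
            )
        return val


def run_pipeline(
    config: dict, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Execute the stages listed in ``config['stages']`` and write a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate"])
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    seed = int(config.get("seed", 0) if seed is None else seed)

    state = PipelineState()
    manifest: dict = {"seed": seed, "stages": {}, "outputs": {}}
    for stage in stages:
        runner = globals()[f"_stage_{stage}"]
        info = runner(config, state, out, seed)
        manifest["stages"][stage] = info
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _stage_simulate(config, state, out, seed) -> dict:
    cc = dict(config.get("cohort", {}))
    cc.setdefault("seed", seed)
    cohort = CohortConfig(**cc)
    raw, truth = generate_raw_plexes(cohort)
    clinical = simulate_survival(truth, cohort)
    state.raw, state.truth, state.clinical = raw, truth, clinical
    state.cohort = cohort

    manifest_rows = []
    for b in raw.batches:
        for ch in b.intensities.columns:
            manifest_rows.append(
                {
                    "channel": ch,
                    "batch": b.batch_id,
                    "role": "reference" if ch == b.reference_channel else "sample",
                }
            )
    pd.DataFrame(manifest_rows).to_csv(out / "batch_manifest.csv", index=False)
    io.write_clinical(clinical, out / "clinical.csv")
    truth.to_json(out / "ground_truth.json")
    io.write_config(
        {k: v for k, v in dataclasses.asdict(cohort).items()},
        out / "cohort_config.yaml",
    )
    n_complete = int(
        pd.concat(
            [b.intensities[b.sample_channels] for b in raw.batches], axis=1
        ).notna().all(axis=1).sum()
    )
    return {
        "seed": cohort.seed,
        "n_samples": cohort.n_samples,
        "n_proteins": cohort.n_proteins,
        "n_complete_proteins": n_complete,
    }


def _stage_preprocess(config, state, out, seed) -> dict:
    raw = state.require("raw", "preprocess")
    p = config.get("preprocess", {})
    ratio = log2_reference_ratio(raw)
    filtered = filter_completeness(ratio, p.get("min_frac", 0.75))
    imputed = knn_impute(filtered, p.get("knn_k", 10))
    normalized = standardize_columns(median_center_rows(imputed))
    state.normalized = normalized
    io.write_matrix(normalized, out / "normalized_matrix.tsv")
    return {
        "n_proteins_kept": int(normalized.shape[0]),
        "min_frac": p.get("min_frac", 0.75),
        "knn_k": p.get("knn_k", 10),
    }


def _stage_cluster(config, state, out, seed) -> dict:
    mat = state.require("normalized", "cluster")
    c = config.get("cluster", {})
    res = consensus.run_consensus(
        mat,
        distance=c.get("distance", "spearman"),
        linkage_method=c.get("linkage", "average"),
        base=c.get("base", "hierarchical"),
        k_range=range(2, c.get("k_max", 10) + 1),
        reps=c.get("reps", 1000),
        p_item=c.get("p_item", 0.8),
        p_feature=c.get("p_feature", 0.8),
        seed=seed,
    )
    sel = consensus.evaluate_k(res)
    state.labels = sel.labels
    sel.labels.to_frame().to_csv(out / "cluster_labels.csv")
    info = {
        "chosen_k": sel.chosen_k,
        "areas": sel.areas,
        "delta_areas": sel.delta_areas,
        "silhouettes": sel.silhouettes,
    }
    if state.truth is not None:
        info["ari_vs_truth"] = float(
            adjusted_rand_score(
                state.truth.subtype_labels.reindex(sel.labels.index), sel.labels
            )
        )
    if c.get("sigclust", False):
        overall_p, _ = consensus.sigclust_overall(
            mat, sel.labels, n_sim=c.get("sigclust_sims", 1000), seed=seed
        )
        info["sigclust_overall_p"] = overall_p
    return info


def _stage_classify(config, state, out, seed) -> dict:
    mat = state.require("normalized", "classify")
    labels = state.labels
    if labels is None and state.truth is not None:
        labels = state.truth.subtype_labels.reindex(mat.columns)
    if labels is None:
        raise RuntimeError("stage 'classify': no labels available")
    c = config.get("classify", {})
    model = sam_pam.pam_train(
        mat, labels, folds=c.get("folds", 10), seed=seed
    )
    delta, retained, err = sam_pam.select_min_error(model)
    (out / "nsc_model.json").write_text(json.dumps(model.to_json_dict(), indent=1))
    info = {
        "selected_delta": delta,
        "panel_size": len(retained),
        "cv_error": err,
    }
    if state.truth is not None:
        planted = set().union(*state.truth.marker_proteins.values())
        if planted and len(retained):
            info["panel_precision"] = len(set(retained) & planted) / len(retained)
    return info


def _stage_modules(config, state, out, seed) -> dict:
    mat = state.require("normalized", "modules")
    m = config.get("modules", {})
    cfg = modules.NetworkConfig(
        beta=m.get("beta", 5),
        min_module_size=m.get("min_module_size", 30),
        deep_split=m.get("deep_split", 2),
        merge_cut_height=m.get("merge_cut_height", 0.25),
    )
    cor = np.corrcoef(mat.to_numpy(float))
    adj = modules.signed_hybrid_adjacency(cor, cfg.beta)
    diss = modules.tom_dissimilarity(adj)
    assignment = modules.detect_modules(diss, cfg, mat.index, matrix=mat)
    state.assignment = assignment
    assignment.membership.to_frame().to_csv(
        out / "module_assignment.tsv", sep="\t"
    )
    mods = sorted(set(assignment.membership) - {modules.UNGROUPED})
    scores = pd.DataFrame(
        {mid: modules.module_score(mat, assignment, mid) for mid in mods}
    )
    io.write_matrix(scores.T, out / "module_scores.tsv")
    edges = modules.export_edge_list(
        1.0 - diss, mat.index, m.get("edge_threshold", 0.05), assignment
    )
    edges.to_csv(out / "edge_list.tsv", sep="\t", index=False)
    return {
        "n_modules": len(mods),
        "module_sizes": assignment.module_sizes.to_dict(),
        "n_edges": int(len(edges)),
        "beta": cfg.beta,
    }


def _stage_enrich(config, state, out, seed) -> dict:
    mat = state.require("normalized", "enrich")
    e = config.get("enrich", {})
    gmt_path = e.get("gmt")
    if gmt_path:
        sets = io.read_gmt(gmt_path)
    elif state.truth is not None:
        # gene sets from the planted structure: one set per module + markers
        sets = {
            f"MODULE_{m}": ("planted module", list(ids))
            for m, ids in state.truth.module_membership.groupby(
                state.truth.module_membership
            ).groups.items()
            if m != ""
        }
        sets.update(
            {
                f"MARKERS_{st}": ("planted markers", list(v))
                for st, v in state.truth.marker_proteins.items()
            }
        )
        io.write_gmt(sets, out / "planted_sets.gmt")
    else:
        raise RuntimeError("stage 'enrich': no gene sets (provide enrich.gmt)")
    scores = enrichment.ssgsea(
        mat, sets, alpha=e.get("alpha", 0.75), min_size=e.get("min_size", 10)
    )
    io.write_matrix(scores.T, out / "ssgsea_scores.tsv")
    return {"n_sets_scored": int(scores.shape[1])}


def _stage_survival(config, state, out, seed) -> dict:
    clinical = state.require("clinical", "survival")
    records = survival.build_endpoints(clinical)
    state.records = records
    records.to_csv(out / "survival_records.csv", index=False)
    s = config.get("survival", {})
    info: dict = {"n_records": int(len(records))}
    groups = None
    if state.labels is not None:
        groups = state.labels
    elif "subtype" in clinical.columns:
        groups = clinical["subtype"]
    if groups is not None and groups.nunique() > 1:
        ep = s.get("endpoint", "MFS")
        km = survival.km_fit(records, groups, endpoint=ep)
        info["logrank_p"] = km.logrank_p
        covs = pd.get_dummies(
            groups.rename("group"), drop_first=True, dtype=float
        )
        fit = survival.cox_fit(records, covs, endpoint=ep)
        info["cox_llr_chi2"] = fit.llr_chi2
        info["hazard_ratios"] = fit.hazard_ratios.to_dict()
    return info


def _stage_concord(config, state, out, seed) -> dict:
    mat = state.require("normalized", "concord")
    truth = state.require("truth", "concord")
    records = state.records
    mrna = generate_paired_transcriptome(mat, truth, seed=seed + 101)
    io.write_matrix(mrna, out / "mrna_matrix.tsv")
    paired = concordance.pair_layers(mat, mrna)
    table = concordance.correlate_layers(paired)
    table.to_csv(out / "concordance_table.tsv", sep="\t")
    info = {
        "n_shared_genes": paired.n_shared_genes,
        "n_positive_significant": int((table["class"] == "positive-significant").sum()),
        "n_negative_significant": int((table["class"] == "negative-significant").sum()),
    }
    if records is not None and config.get("concord", {}).get("hazards", False):
        merged, summary = concordance.compare_hazards(paired, records)
        merged.to_csv(out / "hazard_comparison.tsv", sep="\t", index=False)
        (out / "venn_counts.json").write_text(
            json.dumps(
                {
                    "protein_all_endpoints": len(summary["protein_all_endpoints"]),
                    "mrna_all_endpoints": len(summary["mrna_all_endpoints"]),
                    "overlap": len(summary["overlap_all_endpoints"]),
                },
                indent=1,
            )
        )
        info["overlap_all_endpoints"] = len(summary["overlap_all_endpoints"])
    return info
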