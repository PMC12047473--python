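"""End-to-end orchestration: QC -> normalize -> DE/GSEA -> TCR -> model -> RI.

The pipeline consumes a cohort (simulated or loaded from disk), selects
responder pathways per cancer type and IRAT subset, builds per-sample GSEA
and clonal fold-change indices, evaluates the bootstrapped penalized
classifier, and computes the per-sample Response Index. Every stage logs
one line with its input/output sizes and persists its table under the run
directory.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as iio
from .de_gsea import (
    gsea_index_per_sample,
    gsea_null_es,
    gsea_permutation_p,
    rank_by_log2fc,
    select_responder_pathways,
    wilcoxon_de,
)
from .preprocess import QCThresholds, normalize_log1p_cp10k, qc_filter_cells
from .response_index import TP_CELL_TYPES, TS_CELL_TYPES, ri_table
from .response_model import (
    assemble_features,
    bootstrap_evaluate,
    confusion_stats,
    feature_weightage,
    fit_penalized_logistic,
    majority_vote,
)
from .synthetic_data import SimConfig, simulate_cohort
from .tcr_repertoire import (
    build_clonotypes,
    clonal_fc_index,
    extract_response_specific,
    repertoires_by_group,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds, modes and seeds for one run."""

    input_dir: str | None = None          # fixture directory; None -> simulate
    sim: SimConfig | None = None
    ts_cell_types: list[str] = field(default_factory=lambda: list(TS_CELL_TYPES))
    tp_cell_types: list[str] = field(default_factory=lambda: list(TP_CELL_TYPES))
    qc: QCThresholds = field(default_factory=QCThresholds)
    mito_prefix: str = "MT-"
    de_alpha: float = 0.05
    de_correction: str = "bonferroni"
    n_perm: int = 10_000
    pathway_p_thresh: float = 0.05
    min_cells: int = 10
    n_rounds: int = 100
    train_frac: float = 0.70
    mixing: float = 0.3
    n_folds: int = 10
    n_lambda: int = 100
    ri_mode: str = "formula"
    fc_term_mode: str = "ratio"
    permute_labels: bool = False
    seed: int = 0

    @property
    def irat_cell_types(self) -> list[str]:
        return self.ts_cell_types + self.tp_cell_types


def _load_cohort(config: PipelineConfig):
    if config.input_dir is not None:
        matrix = iio.read_mtx_triplet(config.input_dir)
        meta = iio.read_cell_metadata(os.path.join(config.input_dir, "cell_metadata.tsv"))
        contigs = iio.read_contigs(os.path.join(config.input_dir, "contigs.csv"))
        gene_sets = iio.read_gmt(os.path.join(config.input_dir, "gene_sets.gmt"))
        return matrix, meta, contigs, gene_sets
    sim = config.sim or SimConfig(seed=config.seed)
    matrix, meta, contigs, gene_sets, _truth = simulate_cohort(sim)
    return matrix, meta, contigs, gene_sets


def permute_response_labels(meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Shuffle R/NR labels among labeled post-treatment samples (sample level)."""
    meta = meta.copy()
    sample_resp = (
        meta[(meta["treatment"] == "post") & meta["response"].isin(["R", "NR"])]
        .drop_duplicates("sample_id")
        .sort_values("sample_id")
    )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(sample_resp["response"].to_numpy())
    mapping = dict(zip(sample_resp["sample_id"], shuffled))
    mask = meta["sample_id"].isin(mapping)
    meta.loc[mask, "response"] = meta.loc[mask, "sample_id"].map(mapping)
    return meta


def select_pathways_for_cohort(matrix, meta, gene_sets, config: PipelineConfig,
                               seed: int) -> dict:
    """Responder-pathway selection per (cancer type, IRAT subset).

    For each cancer and IRAT, DE compares the subset's cells in one
    response group against all other post-treatment cells of that cancer;
    Bonferroni-significant genes ranked by log2FC feed the preranked GSEA,
    whose permutation null (random same-size gene sets) is cached per
    (ranking, set size). Selected are pathways positively and significantly
    enriched in responders and above the non-responder ES.
    """
    rng = np.random.default_rng(seed)
    selected: dict = {}
    post = meta[(meta["treatment"] == "post") & meta["response"].isin(["R", "NR"])]
    for cancer in sorted(post["cancer_type"].unique()):
        sub = post[post["cancer_type"] == cancer]
        for ct in config.irat_cell_types:
            results = {}
            for resp in ("R", "NR"):
                in_bc = sub.loc[(sub["cell_type"] == ct) & (sub["response"] == resp),
                                "barcode"].to_numpy()
                out_bc = sub.loc[~((sub["cell_type"] == ct) & (sub["response"] == resp)),
                                 "barcode"].to_numpy()
                if len(in_bc) < config.min_cells or len(out_bc) == 0:
                    results[resp] = {}
                    continue
                de = wilcoxon_de(matrix, in_bc, out_bc)
                ranked = rank_by_log2fc(de, alpha=config.de_alpha,
                                        correction=config.de_correction)
                enriched = {}
                if len(ranked) >= 2:
                    null_cache: dict[int, np.ndarray] = {}
                    for name, members in gene_sets.items():
                        overlap = len(set(members) & set(ranked.genes))
                        if overlap == 0 or overlap == len(ranked):
                            continue
                        if overlap not in null_cache:
                            null_cache[overlap] = gsea_null_es(ranked, overlap,
                                                               config.n_perm, rng)
                        enriched[name] = gsea_permutation_p(
                            ranked, members, n_perm=config.n_perm, seed=rng,
                            pathway=name, null_es=null_cache[overlap])
                results[resp] = enriched
            selected[(cancer, ct)] = select_responder_pathways(
                results["R"], results["NR"], p_thresh=config.pathway_p_thresh)
            logger.info("pathway selection %s/%s: %d R results, %d NR results, %d selected",
                        cancer, ct, len(results["R"]), len(results["NR"]),
                        len(selected[(cancer, ct)]))
    return selected


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute the full pipeline; returns and persists the summary."""
    os.makedirs(out_dir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_perm, seed_gsea, seed_model = (int(s.generate_state(1)[0] % (2**31))
                                        for s in ss.spawn(3))

    matrix, meta, contigs, gene_sets = _load_cohort(config)
    logger.info("cohort: %d genes x %d cells, %d samples",
                matrix.n_genes, matrix.n_cells, meta["sample_id"].nunique())

    retained, qc_report = qc_filter_cells(matrix, config.qc, config.mito_prefix)
    matrix = matrix.subset_cells(retained)
    meta = meta[meta["barcode"].isin(set(retained))].reset_index(drop=True)
    matrix = normalize_log1p_cp10k(matrix)
    logger.info("qc: retained %d/%d cells", qc_report["n_retained"], qc_report["n_input"])
    iio.write_json(qc_report, os.path.join(out_dir, "qc_report.json"))

    # --- TCR stage -------------------------------------------------------
    clonotypes, tcr_report = build_clonotypes(contigs, meta)
    logger.info("tcr: %d clonotyped cells, %d unique clonotypes",
                tcr_report["n_clonotyped_cells"], tcr_report["n_unique_clonotypes"])
    clonotypes = clonotypes.merge(meta[["barcode", "cancer_type"]], on="barcode")
    clonal_frames, n_r_spec, n_nr_spec = [], 0, 0
    specific_by_cancer = {}
    for cancer in sorted(meta["cancer_type"].unique()):
        c_meta = meta[meta["cancer_type"] == cancer]
        c_clono = clonotypes[clonotypes["cancer_type"] == cancer]
        specific = extract_response_specific(repertoires_by_group(c_clono, c_meta))
        specific_by_cancer[cancer] = specific
        n_r_spec += len(specific.r_specific)
        n_nr_spec += len(specific.nr_specific)
        for ct in config.irat_cell_types:
            frame = clonal_fc_index(c_clono, c_meta, specific, ct, per_sample=True)
            frame["cancer_type"] = cancer
            clonal_frames.append(frame)
    clonal_rows = pd.concat(clonal_frames, ignore_index=True)
    clonal_rows.to_csv(os.path.join(out_dir, "clonal_fc_indices.tsv"), sep="\t", index=False)

    # --- DE / GSEA stage -------------------------------------------------
    selected = select_pathways_for_cohort(matrix, meta, gene_sets, config, seed_gsea)
    iio.write_json({f"{c}|{ct}": v for (c, ct), v in selected.items()},
                   os.path.join(out_dir, "selected_pathways.json"))
    gsea_frames = []
    post = meta[(meta["treatment"] == "post") & meta["response"].isin(["R", "NR"])]
    for cancer in sorted(post["cancer_type"].unique()):
        c_meta = meta[meta["cancer_type"] == cancer]
        samples = sorted(post.loc[post["cancer_type"] == cancer, "sample_id"].unique())
        for ct in config.irat_cell_types:
            frame = gsea_index_per_sample(matrix, c_meta, selected[(cancer, ct)],
                                          gene_sets, ct, samples=samples,
                                          min_cells=config.min_cells)
            frame["cancer_type"] = cancer
            gsea_frames.append(frame)
    gsea_rows = pd.concat(gsea_frames, ignore_index=True)
    gsea_rows.to_csv(os.path.join(out_dir, "gsea_indices.tsv"), sep="\t", index=False)

    # --- model stage -----------------------------------------------------
    # The permuted-label null applies from here on: the per-sample indices
    # are deterministic constructions over the repertoires and rankings, and
    # the group-specific repertoire step is label-circular by definition
    # (whatever labeling defines the groups, its exclusive clonotypes track
    # it), so the calibration null permutes the labels the classifier and
    # the RI comparison see, with features held fixed.
    meta_model = permute_response_labels(meta, seed_perm) if config.permute_labels else meta
    if config.permute_labels:
        logger.info("response labels permuted for model/RI stages (seed %d)", seed_perm)
    table = assemble_features(gsea_rows, clonal_rows, meta_model,
                              cell_types=config.irat_cell_types)
    boot = bootstrap_evaluate(table, n_rounds=config.n_rounds,
                              train_frac=config.train_frac, seed=seed_model,
                              mixing=config.mixing, n_folds=config.n_folds,
                              n_lambda=config.n_lambda)
    full_fit = fit_penalized_logistic(table.X_standardized, table.y,
                                      mixing=config.mixing, n_folds=config.n_folds,
                                      seed=seed_model, n_lambda=config.n_lambda)
    classes, vote_flags = majority_vote(boot.votes, fallback=full_fit, table=table)
    pred = np.array([classes[s] for s in table.samples])
    confusion = confusion_stats(pred, table.y)
    weights = feature_weightage(boot.coefs)
    weightages = dict(zip(table.feature_names, weights.round(10)))
    iio.write_json(
        {
            "mean_auc": boot.mean_auc,
            "aucs": boot.aucs,
            "lambdas": boot.lambdas,
            "votes": {s: v for s, v in sorted(boot.votes.items())},
            "fallback_samples": sorted(s for s, f in vote_flags.items() if f),
            "weightages": weightages,
        },
        os.path.join(out_dir, "model_results.json"),
    )

    # --- response index --------------------------------------------------
    ri = ri_table(gsea_rows, clonal_rows, meta_model,
                  ts_cell_types=config.ts_cell_types,
                  tp_cell_types=config.tp_cell_types,
                  mode=config.ri_mode, fc_term_mode=config.fc_term_mode)
    ri.to_csv(os.path.join(out_dir, "response_index.tsv"), sep="\t", index=False)
    ri_r = ri.loc[ri["response"] == "R", "ri"].to_numpy()
    ri_nr = ri.loc[ri["response"] == "NR", "ri"].to_numpy()
    if len(ri_r) and len(ri_nr):
        _, ri_p = stats.mannwhitneyu(ri_r, ri_nr, alternative="greater")
    else:
        ri_p = float("nan")

    summary = {
        "n_samples": int(len(table.samples)),
        "n_cells": int(matrix.n_cells),
        "mean_auc": boot.mean_auc,
        "confusion": confusion,
        "weightages": weightages,
        "n_responder_specific_clonotypes": int(n_r_spec),
        "n_nonresponder_specific_clonotypes": int(n_nr_spec),
        "median_ri_responder": float(np.median(ri_r)) if len(ri_r) else float("nan"),
        "median_ri_nonresponder": float(np.median(ri_nr)) if len(ri_nr) else float("nan"),
        "ri_mannwhitney_p": float(ri_p),
        "seed": config.seed,
    }
    iio.write_json(summary, os.path.join(out_dir, "summary.json"))
    logger.info("pipeline done: mean AUC %.3f, accuracy %.3f",
                boot.mean_auc, confusion["accuracy"])
    return summary


def config_from_dict(payload: dict) -> PipelineConfig:
    """Build a PipelineConfig (and nested SimConfig/QCThresholds) from JSON."""
    payload = dict(payload)
    sim = payload.pop("sim", None)
    qc = payload.pop("qc", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    config = PipelineConfig(**payload)
    if sim is not None:
        sim = dict(sim)
        if "clonal_expansion" in sim:
            sim["clonal_expansion"] = {
                tuple(k.split("|")): v for k, v in sim["clonal_expansion"].items()
            }
        config.sim = SimConfig(**sim)
    if qc is not None:
        config.qc = QCThresholds(**qc)
    return config
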