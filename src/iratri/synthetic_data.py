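"""Synthetic multi-cancer single-cell cohorts with planted response effects.

The generator emulates the structure of a pan-cancer immunotherapy cohort:
per cancer type, post-treatment responder (R) and non-responder (NR)
samples plus treatment-naive (pre) and normal-tissue samples; per sample,
a negative-binomial count matrix over a shared gene universe; per T cell,
a paired-chain TCR clonotype. Two response effects are planted with known
ground truth:

* pathway activity — a log2 fold change of ``pathway_effect`` multiplies
  the mean of responder-pathway genes in tumor-suppressive (TS) subsets of
  R samples, and of non-responder-pathway genes in tumor-promoting (TP)
  subsets of NR samples;
* clonal expansion — TCR-bearing cells draw, with a per-(cell type, group)
  probability, an expanded clonotype from a pool that exists only in that
  response group's samples, so group-specific clonotypes are exclusive by
  construction.

The negative-binomial count model is chosen for over-dispersion with
closed-form moments; gene means are log-normal, each cell type carries a
small block of up-shifted marker genes, and a block of ``MT-`` genes
provides a mitochondrial fraction for QC. Three independent random streams
(expression, TCR, cell assignment) are derived from the seed so changing
one configuration block does not perturb the others.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from . import io as iio
from .preprocess import CountMatrix
from .response_index import TP_CELL_TYPES, TS_CELL_TYPES
from .tcr_repertoire import clonotype_key

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BACKGROUND_CELL_TYPES = ["CD4_other", "CD8_other"]
IRAT_CELL_TYPES = TS_CELL_TYPES + TP_CELL_TYPES


def _default_proportions() -> dict[str, float]:
    props = {ct: 0.12 for ct in IRAT_CELL_TYPES}
    props.update({ct: 0.26 for ct in BACKGROUND_CELL_TYPES})
    return props


def _default_expansion() -> dict[tuple[str, str], float]:
    """Expected fraction of TCR+ cells carrying group-specific expanded clones."""
    exp: dict[tuple[str, str], float] = {}
    for ct in TS_CELL_TYPES:
        exp[(ct, "R")] = 0.5
        exp[(ct, "NR")] = 0.1
    for ct in TP_CELL_TYPES:
        exp[(ct, "R")] = 0.1
        exp[(ct, "NR")] = 0.5
    for ct in BACKGROUND_CELL_TYPES:
        exp[(ct, "R")] = 0.05
        exp[(ct, "NR")] = 0.05
    return exp


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    ``samples_per_group`` counts samples cohort-wide; they are distributed
    round-robin across cancer types. ``pathway_effect`` is the planted
    log2 fold change; ``clonal_expansion`` maps (cell type, response group)
    to the expected fraction of that type's TCR-bearing cells carrying
    group-specific expanded clonotypes.
    """

    n_cancer_types: int = 2
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"R": 20, "NR": 20, "pre": 6, "normal": 4}
    )
    cells_per_sample: int = 500
    n_genes: int = 1000
    cell_type_proportions: Mapping[str, float] = field(default_factory=_default_proportions)
    pathway_effect: float = 1.0
    n_pathways: int = 20
    genes_per_pathway: int = 25
    n_responder_pathways: int = 4
    n_nonresponder_pathways: int = 4
    clonal_expansion: Mapping[tuple[str, str], float] = field(default_factory=_default_expansion)
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    n_mito_genes: int = 10
    mito_mean_factor: float = 8.0
    marker_genes_per_type: int = 10
    marker_fold: float = 4.0
    tcr_rate: float = 0.92
    single_chain_rate: float = 0.04
    shared_clonotype_rate: float = 0.25
    pool_size_specific: int = 150
    pool_size_shared: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.array(list(self.cell_type_proportions.values()), dtype=float)
        if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("cell_type_proportions must be a simplex summing to 1")
        missing = [ct for ct in IRAT_CELL_TYPES if ct not in self.cell_type_proportions]
        if missing:
            raise ValueError(f"cell_type_proportions must include the IRATs; missing {missing}")
        if len(self.cell_type_proportions) < len(IRAT_CELL_TYPES) + 2:
            raise ValueError("need at least 2 background cell types besides the IRATs")
        if self.cells_per_sample < len(self.cell_type_proportions):
            raise ValueError("cells_per_sample must be >= number of cell types")
        n_pathway_genes = self.n_pathways * self.genes_per_pathway
        n_reserved = self.n_mito_genes + self.marker_genes_per_type * len(self.cell_type_proportions)
        if n_pathway_genes + n_reserved > self.n_genes:
            raise ValueError("gene universe too small for disjoint pathway/marker/mito blocks")
        if self.n_responder_pathways + self.n_nonresponder_pathways > self.n_pathways:
            raise ValueError("more planted than total pathways")

    @property
    def cell_types(self) -> list[str]:
        return list(self.cell_type_proportions)

    @property
    def cancer_types(self) -> list[str]:
        return [f"cancer{chr(ord('A') + i)}" for i in range(self.n_cancer_types)]


@dataclass
class TruthRecord:
    """Planted ground truth for recovery tests."""

    planted_de_genes: dict          # (cell_type, group) -> {gene: log2fc}
    planted_responder_pathways: dict  # pathway -> direction ("up_in_R" / "up_in_NR")
    planted_clonotype_specificity: dict  # cancer -> {key: "R-specific"|"NR-specific"|"shared"}
    true_sample_labels: dict        # sample_id -> "R"/"NR"


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(12, 19))
    middle = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length - 2))
    return "C" + middle + "F"


def _unique_clonotype(rng: np.random.Generator, used: set[str]) -> tuple[str, str, str]:
    while True:
        alpha, beta = _random_cdr3(rng), _random_cdr3(rng)
        key = clonotype_key(alpha, beta)
        if key not in used:
            used.add(key)
            return alpha, beta, key


def _sample_plan(config: SimConfig) -> pd.DataFrame:
    """One row per sample: sample_id, cancer_type, treatment, response."""
    rows = []
    cancers = config.cancer_types
    for group, n in config.samples_per_group.items():
        for i in range(n):
            cancer = cancers[i % len(cancers)]
            if group in ("R", "NR"):
                treatment, response = "post", group
            elif group == "pre":
                treatment, response = "pre", "NA"
            elif group == "normal":
                treatment, response = "normal", "NA"
            else:
                raise ValueError(f"unknown sample group {group!r}")
            sample_id = f"{cancer}_{group}{i:02d}"
            rows.append((sample_id, cancer, treatment, response))
    return pd.DataFrame(rows, columns=["sample_id", "cancer_type", "treatment", "response"])


def simulate_cohort(config: SimConfig):
    """Generate (CountMatrix, cell table, contig table, gene sets, TruthRecord).

    Deterministic under ``config.seed``: the same configuration regenerates
    bit-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_tcr, rng_assign = (np.random.default_rng(s) for s in ss.spawn(3))

    genes, gene_sets, mito_idx, marker_idx, base_means = _gene_universe(config, rng_expr)
    plan = _sample_plan(config)

    # responder pathways planted up in TS subsets of R samples; the
    # complementary block up in TP subsets of NR samples
    pathway_names = list(gene_sets)
    r_pathways = pathway_names[: config.n_responder_pathways]
    nr_pathways = pathway_names[config.n_responder_pathways:
                                config.n_responder_pathways + config.n_nonresponder_pathways]
    planted_direction = {p: "up_in_R" for p in r_pathways}
    planted_direction.update({p: "up_in_NR" for p in nr_pathways})

    gene_pos = {g: i for i, g in enumerate(genes)}
    r_gene_idx = np.array(sorted({gene_pos[g] for p in r_pathways for g in gene_sets[p]}), dtype=int)
    nr_gene_idx = np.array(sorted({gene_pos[g] for p in nr_pathways for g in gene_sets[p]}), dtype=int)

    planted_de: dict = {}
    for ct in TS_CELL_TYPES:
        planted_de[(ct, "R")] = {genes[i]: config.pathway_effect for i in r_gene_idx}
    for ct in TP_CELL_TYPES:
        planted_de[(ct, "NR")] = {genes[i]: config.pathway_effect for i in nr_gene_idx}

    cell_types = config.cell_types
    props = np.array([config.cell_type_proportions[ct] for ct in cell_types])

    meta_rows = []
    count_blocks = []
    contig_rows = []
    pools = _clonotype_pools(config, rng_tcr)
    occurrence: dict[str, dict[str, set[str]]] = {c: {} for c in config.cancer_types}

    for rec in plan.itertuples(index=False):
        n_cells = config.cells_per_sample
        type_idx = rng_assign.choice(len(cell_types), size=n_cells, p=props)
        barcodes = [f"{rec.sample_id}-{i:04d}" for i in range(n_cells)]
        for bc, ti in zip(barcodes, type_idx):
            meta_rows.append((bc, rec.sample_id, rec.sample_id, rec.cancer_type,
                              rec.treatment, rec.response, cell_types[ti]))

        counts = _sample_counts(config, rng_expr, type_idx, cell_types, base_means,
                                marker_idx, mito_idx, r_gene_idx, nr_gene_idx,
                                rec.response)
        count_blocks.append(sparse.csc_matrix(counts.T))

        contig_rows.extend(
            _sample_tcrs(config, rng_tcr, rec, barcodes, type_idx, cell_types,
                         pools[rec.cancer_type], occurrence[rec.cancer_type])
        )

    meta = pd.DataFrame(meta_rows, columns=iio.CELL_META_COLUMNS)
    matrix = CountMatrix(
        genes=np.asarray(genes),
        cells=meta["barcode"].to_numpy(),
        counts=sparse.hstack(count_blocks).tocsr(),
    )
    contigs = pd.DataFrame(contig_rows, columns=["barcode", "chain", "cdr3"])

    specificity = {
        cancer: {
            key: ("R-specific" if groups == {"R"}
                  else "NR-specific" if groups == {"NR"} else "shared")
            for key, groups in occ.items()
        }
        for cancer, occ in occurrence.items()
    }
    truth = TruthRecord(
        planted_de_genes=planted_de,
        planted_responder_pathways=planted_direction,
        planted_clonotype_specificity=specificity,
        true_sample_labels={r.sample_id: r.response for r in plan.itertuples(index=False)
                            if r.response in ("R", "NR")},
    )
    return matrix, meta, contigs, gene_sets, truth


def _gene_universe(config: SimConfig, rng: np.random.Generator):
    """Gene names, disjoint pathway sets, mito/marker index blocks, base means."""
    n = config.n_genes
    width = len(str(n))
    mito_idx = np.arange(config.n_mito_genes)
    names = [f"MT-G{i + 1}" for i in mito_idx]
    names += [f"G{i + 1:0{width}d}" for i in range(config.n_mito_genes, n)]

    n_types = len(config.cell_type_proportions)
    marker_block = np.arange(config.n_mito_genes,
                             config.n_mito_genes + config.marker_genes_per_type * n_types)
    marker_idx = {
        ct: marker_block[i * config.marker_genes_per_type:(i + 1) * config.marker_genes_per_type]
        for i, ct in enumerate(config.cell_type_proportions)
    }

    free = np.arange(marker_block[-1] + 1 if len(marker_block) else config.n_mito_genes, n)
    chosen = rng.choice(free, size=config.n_pathways * config.genes_per_pathway, replace=False)
    gene_sets = {
        f"PW{p + 1:03d}": sorted(names[i] for i in
                                 chosen[p * config.genes_per_pathway:(p + 1) * config.genes_per_pathway])
        for p in range(config.n_pathways)
    }

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    base[mito_idx] *= config.mito_mean_factor
    return names, gene_sets, mito_idx, marker_idx, base


def _sample_counts(config, rng, type_idx, cell_types, base_means, marker_idx,
                   mito_idx, r_gene_idx, nr_gene_idx, response):
    """Negative-binomial counts (cells x genes) for one sample."""
    n_cells = len(type_idx)
    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    effect = 2.0 ** config.pathway_effect
    for ti, ct in enumerate(cell_types):
        rows = np.flatnonzero(type_idx == ti)
        if not len(rows):
            continue
        mu = base_means.copy()
        mu[marker_idx[ct]] *= config.marker_fold
        if response == "R" and ct in TS_CELL_TYPES:
            mu[r_gene_idx] *= effect
        elif response == "NR" and ct in TP_CELL_TYPES:
            mu[nr_gene_idx] *= effect
        r = config.nb_dispersion
        p = r / (r + mu)
        counts[rows] = rng.negative_binomial(r, p, size=(len(rows), config.n_genes))
    return counts


def _clonotype_pools(config: SimConfig, rng: np.random.Generator) -> dict:
    """Per-cancer pools of unique clonotypes; keys globally unique."""
    used: set[str] = set()
    pools = {}
    for cancer in config.cancer_types:
        pools[cancer] = {
            "R": [_unique_clonotype(rng, used) for _ in range(config.pool_size_specific)],
            "NR": [_unique_clonotype(rng, used) for _ in range(config.pool_size_specific)],
            "shared": [_unique_clonotype(rng, used) for _ in range(config.pool_size_shared)],
            "_used": used,
        }
    return pools


def _sample_tcrs(config, rng, sample, barcodes, type_idx, cell_types, pool, occurrence):
    """Contig rows for one sample; records realized clonotype occurrence by group."""
    rows = []
    group = sample.response if sample.response in ("R", "NR") else None
    for bc, ti in zip(barcodes, type_idx):
        if rng.random() >= config.tcr_rate:
            continue  # non-T contaminant without TCR
        ct = cell_types[ti]
        expansion = config.clonal_expansion.get((ct, group), 0.0) if group else 0.0
        u = rng.random()
        if group and u < expansion:
            alpha, beta, key = pool[group][int(rng.integers(len(pool[group])))]
        elif u < expansion + config.shared_clonotype_rate:
            alpha, beta, key = pool["shared"][int(rng.integers(len(pool["shared"])))]
        else:
            alpha, beta, key = _unique_clonotype(rng, pool["_used"])
        if rng.random() < config.single_chain_rate:
            # cell yields only one recovered chain; it will fail pairing
            chain = "TRA" if rng.random() < 0.5 else "TRB"
            rows.append((bc, chain, alpha if chain == "TRA" else beta))
            continue
        rows.append((bc, "TRA", alpha))
        rows.append((bc, "TRB", beta))
        occurrence.setdefault(key, set()).add(group or sample.treatment)
    return rows


def write_fixture(artifacts, out_dir: str) -> dict:
    """Persist a simulated cohort; returns a manifest.

    The manifest's ``files`` entry lists the six cohort input files (MTX
    triplet, cell metadata TSV, contig CSV, GMT); the ground-truth JSON is
    written alongside under the separate ``truth`` entry since it is not a
    pipeline input.
    """
    matrix, meta, contigs, gene_sets, truth = artifacts
    os.makedirs(out_dir, exist_ok=True)
    try:
        files = iio.write_mtx_triplet(matrix, out_dir)
        files.append(iio.write_cell_metadata(meta, os.path.join(out_dir, "cell_metadata.tsv")))
        files.append(iio.write_contigs(contigs, os.path.join(out_dir, "contigs.csv")))
        files.append(iio.write_gmt(gene_sets, os.path.join(out_dir, "gene_sets.gmt")))
        truth_path = iio.write_json(
            {
                "planted_de_genes": {f"{ct}|{grp}": v for (ct, grp), v in truth.planted_de_genes.items()},
                "planted_responder_pathways": truth.planted_responder_pathways,
                "planted_clonotype_specificity": truth.planted_clonotype_specificity,
                "true_sample_labels": truth.true_sample_labels,
            },
            os.path.join(out_dir, "truth.json"),
        )
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out_dir}: {exc}") from exc
    return {"files": files, "truth": truth_path, "out_dir": out_dir}
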