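"""Paired-chain clonotype construction and response-specific repertoire analysis.

A clonotype is the pair of CDR3 amino-acid sequences of a cell's TCR alpha
and beta chains, keyed as ``"alpha|beta"``. Cells with only one of the two
chains are discarded. Response-specific repertoires follow a four-way set
difference: clonotypes seen in responders but never in non-responder,
treatment-naive, or normal samples are responder-specific (and symmetrically
for non-responders). The clonal fold-change index summarizes, within a cell
type, the balance of cells bearing responder- vs non-responder-specific
clonotypes as a log2 ratio of Haldane-corrected proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_gsea import bh_adjust

logger = logging.getLogger(__name__)

VALID_CHAINS = ("TRA", "TRB")
HALDANE_EPS = 0.5


def clonotype_key(cdr3_alpha: str, cdr3_beta: str) -> str:
    return f"{cdr3_alpha}|{cdr3_beta}"


@dataclass
class SpecificRepertoires:
    """Disjoint responder- and non-responder-specific clonotype key sets."""

    r_specific: set[str]
    nr_specific: set[str]

    def __post_init__(self) -> None:
        if self.r_specific & self.nr_specific:
            raise ValueError("r_specific and nr_specific overlap")


def build_clonotypes(
    contigs: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Pair TRA/TRB contigs into per-cell clonotypes.

    Barcodes with at least one TRA and one TRB CDR3 get a clonotype; when a
    cell carries several contigs of a chain, the lexicographically smallest
    CDR3 is kept (deterministic stand-in for UMI-based picking). Rows with a
    chain outside TRA/TRB are skipped with a warning; barcodes absent from
    the cell metadata are dropped and counted.

    Returns (table, report) where table has columns
    ``barcode, sample_id, cdr3_alpha, cdr3_beta, key``.
    """
    known = meta.set_index("barcode")["sample_id"]
    bad_chain = ~contigs["chain"].isin(VALID_CHAINS)
    if bad_chain.any():
        logger.warning("skipping %d contig rows with chain outside %s",
                       int(bad_chain.sum()), VALID_CHAINS)
    rows = contigs[~bad_chain]
    unknown_mask = ~rows["barcode"].isin(known.index)
    n_unknown_barcodes = rows.loc[unknown_mask, "barcode"].nunique()
    if n_unknown_barcodes:
        logger.info("dropping %d barcodes absent from cell metadata", n_unknown_barcodes)
    rows = rows[~unknown_mask]

    # lexicographically smallest CDR3 per (barcode, chain)
    best = rows.groupby(["barcode", "chain"], sort=True)["cdr3"].min().unstack("chain")
    for chain in VALID_CHAINS:
        if chain not in best.columns:
            best[chain] = np.nan
    paired = best.dropna(subset=list(VALID_CHAINS))
    n_unpaired = len(best) - len(paired)

    table = pd.DataFrame(
        {
            "barcode": paired.index,
            "sample_id": known.loc[paired.index].to_numpy(),
            "cdr3_alpha": paired["TRA"].to_numpy(),
            "cdr3_beta": paired["TRB"].to_numpy(),
        }
    ).reset_index(drop=True)
    table["key"] = [clonotype_key(a, b) for a, b in zip(table["cdr3_alpha"], table["cdr3_beta"])]
    report = {
        "n_contig_rows": int(len(contigs)),
        "n_rows_bad_chain": int(bad_chain.sum()),
        "n_barcodes_unknown": int(n_unknown_barcodes),
        "n_barcodes_single_chain": int(n_unpaired),
        "n_clonotyped_cells": int(len(table)),
        "n_unique_clonotypes": int(table["key"].nunique()),
    }
    return table, report


def repertoires_by_group(
    clonotypes: pd.DataFrame, meta: pd.DataFrame
) -> dict[str, set[str]]:
    """Clonotype key sets for the R, NR, naive (pre) and normal groups."""
    merged = clonotypes.merge(
        meta[["barcode", "treatment", "response"]], on="barcode", how="left"
    )
    post = merged["treatment"] == "post"
    return {
        "R": set(merged.loc[post & (merged["response"] == "R"), "key"]),
        "NR": set(merged.loc[post & (merged["response"] == "NR"), "key"]),
        "naive": set(merged.loc[merged["treatment"] == "pre", "key"]),
        "normal": set(merged.loc[merged["treatment"] == "normal", "key"]),
    }


def extract_response_specific(
    repertoires: Mapping[str, set[str]]
) -> SpecificRepertoires:
    """Four-way set difference yielding group-exclusive clonotypes.

    ``r_specific = R \\ (NR | naive | normal)`` and symmetrically for
    ``nr_specific``.
    """
    r = set(repertoires.get("R", set()))
    nr = set(repertoires.get("NR", set()))
    naive = set(repertoires.get("naive", set()))
    normal = set(repertoires.get("normal", set()))
    return SpecificRepertoires(
        r_specific=r - nr - naive - normal,
        nr_specific=nr - r - naive - normal,
    )


def clonal_fc_index(
    clonotypes: pd.DataFrame,
    meta: pd.DataFrame,
    specific: SpecificRepertoires,
    cell_type: str,
    per_sample: bool = True,
    unique_clonotypes: bool = False,
) -> pd.DataFrame:
    """Clonal fold-change index for one cell type.

    Among cells of *cell_type* bearing any response-specific clonotype,
    F_R counts cells with responder-specific and F_NR cells with
    non-responder-specific clonotypes (unique clonotypes instead when
    *unique_clonotypes*). With n = F_R + F_NR and the Haldane pseudocount
    eps = 0.5, fc_index = log2(((F_R + eps)/(n + 2 eps)) /
    ((F_NR + eps)/(n + 2 eps))) = log2((F_R + eps)/(F_NR + eps)).

    Computed per sample (``per_sample=True``; classifier features) or pooled
    per response group. Units with zero specific-bearing cells get a missing
    index.
    """
    merged = clonotypes.merge(
        meta[["barcode", "cell_type", "response", "treatment"]], on="barcode", how="left"
    )
    sub = merged[merged["cell_type"] == cell_type]
    unit_col = "sample_id" if per_sample else "response"
    units = sorted(sub[unit_col].dropna().unique())
    rows = []
    for unit in units:
        cells = sub[sub[unit_col] == unit]
        in_r = cells["key"].isin(specific.r_specific)
        in_nr = cells["key"].isin(specific.nr_specific)
        if unique_clonotypes:
            f_r = cells.loc[in_r, "key"].nunique()
            f_nr = cells.loc[in_nr, "key"].nunique()
        else:
            f_r = int(in_r.sum())
            f_nr = int(in_nr.sum())
        n = f_r + f_nr
        if n == 0:
            logger.info("%s %s: no specific-bearing cells; fc_index missing",
                        cell_type, unit)
            fc = np.nan
        else:
            fc = float(np.log2((f_r + HALDANE_EPS) / (f_nr + HALDANE_EPS)))
        rows.append((cell_type, unit, f_r, f_nr, n, fc))
    return pd.DataFrame(
        rows,
        columns=["cell_type", unit_col, "F_R", "F_NR", "n_specific_cells", "fc_index"],
    )


def clonal_frequencies(clonotypes: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cell clonal frequency: fraction of the cell's sample sharing its clonotype."""
    merged = clonotypes.merge(meta[["barcode", "cell_type", "response"]], on="barcode")
    sizes = merged.groupby(["sample_id", "key"])["barcode"].transform("size")
    totals = merged.groupby("sample_id")["barcode"].transform("size")
    out = merged[["barcode", "sample_id", "cell_type", "response", "key"]].copy()
    out["clonal_frequency"] = sizes / totals
    return out


def expansion_tests(
    counts_2x2: Mapping[str, np.ndarray],
    freq_vectors: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> pd.DataFrame:
    """Per-cell-type expansion tests with BH correction across cell types.

    *counts_2x2* maps cell type -> 2x2 table
    [[specific-bearing R, other R], [specific-bearing NR, other NR]] tested
    with the two-sided Fisher exact test (hypergeometric enumeration);
    *freq_vectors* maps cell type -> (R frequencies, NR frequencies) compared
    with a two-sided Welch t-test on the means. Cell types with an empty
    group are skipped with a reason.
    """
    rows, skipped = [], []
    for cell_type in sorted(counts_2x2):
        table = np.asarray(counts_2x2[cell_type])
        freq_r, freq_nr = (np.asarray(v, dtype=float) for v in freq_vectors[cell_type])
        if table[0].sum() == 0 or table[1].sum() == 0 or not len(freq_r) or not len(freq_nr):
            skipped.append((cell_type, "empty group"))
            continue
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        if np.array_equal(freq_r, freq_nr) or (np.ptp(freq_r) == 0 and np.ptp(freq_nr) == 0
                                               and freq_r[0] == freq_nr[0]):
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(freq_r, freq_nr, equal_var=False)
        prop_r = table[0, 0] / table[0].sum()
        prop_nr = table[1, 0] / table[1].sum()
        fold = float(np.log2((prop_r + 1e-9) / (prop_nr + 1e-9)))
        rows.append((cell_type, fisher_p, float(t_stat), float(t_p),
                     float(np.mean(freq_r)), float(np.mean(freq_nr)), fold))
    out = pd.DataFrame(
        rows,
        columns=["cell_type", "fisher_p", "t_stat", "t_p",
                 "mean_freq_R", "mean_freq_NR", "log2_fold_change"],
    )
    if len(out):
        out["fisher_fdr"] = bh_adjust(out["fisher_p"].to_numpy())
        out["t_fdr"] = bh_adjust(out["t_p"].to_numpy())
    for cell_type, reason in skipped:
        logger.info("expansion test skipped for %s: %s", cell_type, reason)
    out.attrs["skipped"] = skipped
    return out
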