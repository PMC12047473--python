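"""Closed-form Response Index (RI) per sample.

The four response-associated T cell subsets split into a tumor-suppressive
(TS) group — CD4+ CXCL13+ Tfh and CD8+ CXCL13+ T — and a tumor-promoting
(TP) group — CD4+ TGF-beta1+ T and CD8+ Temra. Per sample,

    composite_gsea = sum over TS and TP cell types of their GSEA index
                     (each itself a sum of ES over selected pathways)
    composite_fc   = |sum_TS fc_term / sum_TP fc_term|      ("formula" mode)
                   = |sum_TS fc_term| / sum_TP fc_term      ("text" mode)
    RI             = composite_fc * composite_gsea

where the per-cell-type fc_term is either the Haldane-corrected clonal
ratio (F_R + 0.5)/(F_NR + 0.5) ("ratio" mode) or the log2 clonal FC index
("index" mode). Both readings of the composite are implemented because the
ratio-of-sums and the sum-then-absolute forms are not equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tcr_repertoire import HALDANE_EPS

logger = logging.getLogger(__name__)

DENOM_EPS = 1e-9

TS_CELL_TYPES = ["CD4_CXCL13_Tfh", "CD8_CXCL13"]
TP_CELL_TYPES = ["CD4_TGFB1", "CD8_Temra"]


@dataclass
class RIComponents:
    """Per-sample inputs to the RI: ES sums and clonal fc terms per cell type."""

    ts_cell_types: Sequence[str]
    tp_cell_types: Sequence[str]
    es_sums: Mapping[str, float]
    fc_terms: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.ts_cell_types or not self.tp_cell_types:
            raise ValueError("both TS and TP groups must be non-empty")
        if set(self.ts_cell_types) & set(self.tp_cell_types):
            raise ValueError("TS and TP groups overlap")


@dataclass
class RIRecord:
    sample_id: str
    composite_gsea: float
    composite_fc: float
    ri: float
    guarded: bool = False


def composite_indices(components: RIComponents, mode: str = "formula") -> tuple[float, float, bool]:
    """Return (composite_gsea, composite_fc, guarded).

    ``formula`` mode takes the absolute value of the ratio of TS and TP
    fc-term sums; ``text`` mode divides the absolute TS sum by the TP sum.
    A TP sum of zero is guarded with a small epsilon and flagged.
    """
    gsea = sum(components.es_sums.get(ct, 0.0)
               for ct in [*components.ts_cell_types, *components.tp_cell_types])
    ts_sum = sum(components.fc_terms.get(ct, 0.0) for ct in components.ts_cell_types)
    tp_sum = sum(components.fc_terms.get(ct, 0.0) for ct in components.tp_cell_types)
    guarded = tp_sum == 0
    denom = tp_sum if tp_sum != 0 else DENOM_EPS
    if mode == "formula":
        fc = abs(ts_sum / denom)
    elif mode == "text":
        fc = abs(ts_sum) / denom
    else:
        raise ValueError(f"unknown composite mode {mode!r}")
    return float(gsea), float(fc), guarded


def response_index(components: RIComponents, sample_id: str = "",
                   mode: str = "formula") -> RIRecord:
    """RI = composite clonal FC index times composite GSEA index."""
    gsea, fc, guarded = composite_indices(components, mode=mode)
    if not (np.isfinite(gsea) and np.isfinite(fc)):
        raise ValueError(f"non-finite composites for sample {sample_id!r}")
    return RIRecord(sample_id=sample_id, composite_gsea=gsea, composite_fc=fc,
                    ri=fc * gsea, guarded=guarded)


def ri_table(
    gsea_rows: pd.DataFrame,
    clonal_rows: pd.DataFrame,
    meta: pd.DataFrame,
    ts_cell_types: Sequence[str] | None = None,
    tp_cell_types: Sequence[str] | None = None,
    mode: str = "formula",
    fc_term_mode: str = "ratio",
) -> pd.DataFrame:
    """Per-sample RI table from per-(sample, cell type) index rows.

    *gsea_rows* carries ``sample_id, cell_type, gsea_index`` (the ES sums);
    *clonal_rows* carries ``sample_id, cell_type, F_R, F_NR, fc_index``.
    ``fc_term_mode='ratio'`` uses (F_R + 0.5)/(F_NR + 0.5); ``'index'`` uses
    the log2 fc index. Missing per-sample terms are neutral (ratio 1, index
    0, ES 0) and flag the sample.
    """
    ts = list(ts_cell_types or TS_CELL_TYPES)
    tp = list(tp_cell_types or TP_CELL_TYPES)
    labeled_post = (meta["treatment"] == "post") & meta["response"].notna()
    sample_info = (meta[labeled_post]
                   .drop_duplicates("sample_id")
                   .set_index("sample_id")[["cancer_type", "response"]])
    g = gsea_rows.pivot_table(index="sample_id", columns="cell_type",
                              values="gsea_index", aggfunc="first")
    c = clonal_rows.pivot_table(index="sample_id", columns="cell_type",
                                values=["F_R", "F_NR", "fc_index"], aggfunc="first")
    rows = []
    for sample in sample_info.index:
        es_sums, fc_terms, missing = {}, {}, False
        for ct in [*ts, *tp]:
            es = g.at[sample, ct] if (sample in g.index and ct in g.columns) else np.nan
            if np.isnan(es):
                es, missing = 0.0, True
            es_sums[ct] = float(es)
            if fc_term_mode == "ratio":
                fr = c["F_R"].at[sample, ct] if (sample in c.index and ct in c["F_R"].columns) else np.nan
                fnr = c["F_NR"].at[sample, ct] if (sample in c.index and ct in c["F_NR"].columns) else np.nan
                if np.isnan(fr) or np.isnan(fnr):
                    fc_terms[ct], missing = 1.0, True
                else:
                    fc_terms[ct] = (fr + HALDANE_EPS) / (fnr + HALDANE_EPS)
            elif fc_term_mode == "index":
                fc = c["fc_index"].at[sample, ct] if (sample in c.index and ct in c["fc_index"].columns) else np.nan
                if np.isnan(fc):
                    fc_terms[ct], missing = 0.0, True
                else:
                    fc_terms[ct] = float(fc)
            else:
                raise ValueError(f"unknown fc_term_mode {fc_term_mode!r}")
        comp = RIComponents(ts_cell_types=ts, tp_cell_types=tp,
                            es_sums=es_sums, fc_terms=fc_terms)
        rec = response_index(comp, sample_id=sample, mode=mode)
        rows.append((sample, sample_info.at[sample, "cancer_type"],
                     sample_info.at[sample, "response"], rec.composite_gsea,
                     rec.composite_fc, rec.ri, rec.guarded, missing))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "cancer_type", "response", "composite_gsea",
                 "composite_fc", "ri", "guarded", "missing_terms"],
    ).sort_values("ri", ascending=False).reset_index(drop=True)
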