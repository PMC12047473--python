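"""Group-comparison statistics on cell-type composition and pseudotime.

Cell-type proportions between two groups are compared with the pooled
two-proportion z-test, Benjamini-Hochberg corrected across cell types.
Pseudotime distributions are min-max scaled over the pooled lineage to
[0, 1] and compared with Welch's unequal-variance t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .de_gsea import bh_adjust

LOGFC_EPS = 1e-9


def proportion_ztest_bh(counts: pd.DataFrame) -> pd.DataFrame:
    """Pooled two-proportion z-test per cell type with BH correction.

    *counts* needs columns ``cell_type, k1, n1, k2, n2`` (successes and
    totals in the two groups). Rows with a zero total are skipped with a
    reason; equal pooled proportions of 0 or 1 give z = 0, p = 1.
    Adds ``z, p, fdr, log_fc`` where
    log_fc = log2((k1/n1 + eps)/(k2/n2 + eps)).
    """
    rows, skipped = [], []
    for rec in counts.itertuples(index=False):
        if rec.n1 <= 0 or rec.n2 <= 0:
            skipped.append((rec.cell_type, "zero group total"))
            continue
        if not (0 <= rec.k1 <= rec.n1 and 0 <= rec.k2 <= rec.n2):
            raise ValueError(f"{rec.cell_type}: counts outside [0, n]")
        pooled = (rec.k1 + rec.k2) / (rec.n1 + rec.n2)
        if pooled in (0.0, 1.0):
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest([rec.k1, rec.k2], [rec.n1, rec.n2])
        log_fc = float(np.log2((rec.k1 / rec.n1 + LOGFC_EPS) / (rec.k2 / rec.n2 + LOGFC_EPS)))
        rows.append((rec.cell_type, rec.k1, rec.n1, rec.k2, rec.n2,
                     float(z), float(p), log_fc))
    out = pd.DataFrame(rows, columns=["cell_type", "k1", "n1", "k2", "n2",
                                      "z", "p", "log_fc"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    out.attrs["skipped"] = skipped
    return out


def scaled_pseudotime_welch(group_a, group_b) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Min-max scale pooled pseudotimes to [0, 1], then Welch's t-test.

    Returns (scaled_a, scaled_b, t, p) with Satterthwaite degrees of
    freedom inside the test. Each group needs >= 2 values; constant pooled
    values make the scaling undefined and raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 pseudotime values")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        raise ValueError("pooled pseudotimes are constant; min-max scaling undefined")
    scaled_a = (a - lo) / (hi - lo)
    scaled_b = (b - lo) / (hi - lo)
    if np.array_equal(scaled_a, scaled_b):
        return scaled_a, scaled_b, 0.0, 1.0
    t, p = stats.ttest_ind(scaled_a, scaled_b, equal_var=False)
    return scaled_a, scaled_b, float(t), float(p)
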