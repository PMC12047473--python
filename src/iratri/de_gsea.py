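"""Differential expression, log2FC ranking, and a preranked GSEA engine.

Differential expression is the one-group-vs-rest two-sided Wilcoxon
rank-sum test on log-normalized expression, with both Bonferroni and
Benjamini-Hochberg adjusted p-values. For small groups (both sizes <= 10)
the p-value is computed by exhaustive enumeration of rank assignments,
which is exact even under ties; otherwise the normal approximation with
tie correction and continuity correction is used.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum over a ranked gene list (weight exponent 1): hits advance the sum by
|score| normalized to the in-set total, misses retreat by 1/(N - n_hits),
and ES is the signed maximum deviation from zero. Permutation p-values
come from resampling random gene sets of equal size from the ranked genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9
EXACT_MAX_GROUP = 10


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression


def wilcoxon_de(
    matrix,
    cells_in_group: Sequence,
    cells_out_group: Sequence,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of in-group vs out-group cells.

    *matrix* must carry a ``normalized`` layer. Returns a frame with
    columns ``gene, avg_log2fc, p_value, p_bonferroni, p_bh`` (and
    ``group`` when given). ``avg_log2fc`` is
    log2((mean expm1 in + eps) / (mean expm1 out + eps)).
    """
    if matrix.normalized is None:
        raise ValueError("matrix has no normalized layer; run normalize_log1p_cp10k")
    in_set, out_set = set(cells_in_group), set(cells_out_group)
    if in_set & out_set:
        raise ValueError("in-group and out-group cells overlap")
    if not in_set or not out_set:
        raise ValueError("both groups must be non-empty")

    idx_in = matrix.cell_index(list(cells_in_group))
    idx_out = matrix.cell_index(list(cells_out_group))
    X_in = matrix.normalized[:, idx_in]
    X_out = matrix.normalized[:, idx_out]
    n1, n2 = len(idx_in), len(idx_out)

    mean_in = np.maximum(_mean_expm1(X_in), 0.0)
    mean_out = np.maximum(_mean_expm1(X_out), 0.0)
    log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))

    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        pvals = _ranksum_exact(np.asarray(X_in.todense()), np.asarray(X_out.todense()))
    else:
        pvals = _ranksum_normal(X_in, X_out)

    constant = _is_constant(X_in, X_out)
    pvals = np.where(constant, 1.0, pvals)
    log2fc = np.where(constant, 0.0, log2fc)

    m = matrix.n_genes
    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "avg_log2fc": log2fc,
            "p_value": pvals,
            "p_bonferroni": np.minimum(pvals * m, 1.0),
            "p_bh": bh_adjust(pvals),
        }
    )
    if group is not None:
        out["group"] = group
    return out


def _mean_expm1(X: sparse.spmatrix) -> np.ndarray:
    X = X.copy()
    X.data = np.expm1(X.data)
    return np.asarray(X.mean(axis=1)).ravel()


def _is_constant(X_in, X_out) -> np.ndarray:
    """Genes whose value is identical across both groups combined."""
    both = sparse.hstack([X_in, X_out]).tocsr()
    n = both.shape[1]
    nnz = np.diff(both.indptr)
    mins = both.min(axis=1).toarray().ravel()
    maxs = both.max(axis=1).toarray().ravel()
    # all-zero rows (nnz == 0) are constant; dense-constant rows have min == max
    return ((nnz == 0) | ((mins == maxs) & (nnz == n))).astype(bool)


def _ranksum_normal(X_in, X_out) -> np.ndarray:
    """Vectorized normal-approximation rank-sum p with tie and continuity correction."""
    A = np.asarray(X_in.todense(), dtype=np.float64)
    B = np.asarray(X_out.todense(), dtype=np.float64)
    n1, n2 = A.shape[1], B.shape[1]
    n = n1 + n2
    pooled = np.concatenate([A, B], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_term = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.where(sd > 0, sd, 1.0), 0.0)
    p = np.where(sd > 0, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def _tie_term(pooled: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row."""
    srt = np.sort(pooled, axis=1)
    out = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        out[i] = np.sum(counts.astype(np.float64) ** 3 - counts)
    return out


def _ranksum_exact(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Valid under ties. Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w)))
    over the permutation distribution of the in-group rank sum W.
    """
    n1, n2 = A.shape[1], B.shape[1]
    combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    pvals = np.empty(A.shape[0])
    for i in range(A.shape[0]):
        pooled = np.concatenate([A[i], B[i]])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        w_null = ranks[combos].sum(axis=1)
        p_lo = np.mean(w_null <= w_obs + 1e-9)
        p_hi = np.mean(w_null >= w_obs - 1e-9)
        pvals[i] = min(1.0, 2.0 * min(p_lo, p_hi))
    return pvals


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankedList:
    """Genes with non-increasing scores; ties broken lexicographically by gene id."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_log2fc(
    records: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> RankedList:
    """Keep genes passing the corrected threshold, sorted by avg_log2fc descending.

    *correction* is ``bonferroni`` or ``bh``; ties in log2FC are broken by
    lexicographic gene id so the ranking is deterministic.
    """
    col = {"bonferroni": "p_bonferroni", "bh": "p_bh"}.get(correction)
    if col is None:
        raise ValueError(f"unknown correction {correction!r}")
    kept = records.loc[records[col] < alpha, ["gene", "avg_log2fc"]]
    order = np.lexsort((kept["gene"].to_numpy(), -kept["avg_log2fc"].to_numpy()))
    kept = kept.iloc[order]
    return RankedList(genes=kept["gene"].to_numpy(), scores=kept["avg_log2fc"].to_numpy())


# ---------------------------------------------------------------------------
# enrichment score


@dataclass
class EnrichmentResult:
    pathway: str
    es: float
    p_value: float
    n_perm: int
    leading_edge_size: int


def gsea_preranked_es(ranked: RankedList, gene_set: Sequence[str]) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Hit steps are weighted by |score| normalized to the in-set total (uniform
    when all in-set scores are zero); miss steps are uniform over non-hits.
    Raises if the gene set is disjoint from, or covers, the ranked genes.
    """
    pos, weights, n = _hit_positions(ranked, gene_set)
    es, _ = _es_from_hits(pos, weights, n)
    return float(es)


def _hit_positions(ranked: RankedList, gene_set) -> tuple[np.ndarray, np.ndarray, int]:
    n = len(ranked)
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if m == n:
        raise ValueError("gene set covers the entire ranked list")
    pos = np.flatnonzero(mask)
    w = np.abs(ranked.scores[pos])
    total = w.sum()
    weights = w / total if total > 0 else np.full(m, 1.0 / m)
    return pos, weights, n


def _es_from_hits(pos: np.ndarray, weights: np.ndarray, n: int) -> tuple[float, int]:
    """ES and leading-edge size from sorted hit positions and normalized weights.

    The running sum is piecewise linear with extremes attained immediately
    after a hit (candidates ``after``) or immediately before one
    (candidates ``before``); ties between the positive and negative extreme
    resolve to the positive one.
    """
    m = len(pos)
    miss = 1.0 / (n - m)
    j = np.arange(m)
    cum = np.cumsum(weights)
    after = cum - (pos - j) * miss
    before = after - weights
    hi = max(float(after.max()), 0.0)
    lo = min(float(before.min()), 0.0)
    if hi >= -lo:
        es = hi
        leading = int(np.argmax(after)) + 1 if hi > 0 else 0
    else:
        es = lo
        leading = m - int(np.argmin(before))
    return es, leading


def gsea_permutation_p(
    ranked: RankedList,
    gene_set: Sequence[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    pathway: str = "",
    null_es: np.ndarray | None = None,
) -> EnrichmentResult:
    """Two-sided permutation p for the ES of *gene_set* on *ranked*.

    The null is built by drawing ``n_perm`` random gene sets of equal size
    from the ranked genes; p = (1 + #{|ES_null| >= |ES_obs|}) / (1 + n_perm).
    A precomputed *null_es* array (e.g. shared across same-size pathways)
    may be supplied to skip resampling.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pos, weights, n = _hit_positions(ranked, gene_set)
    es, leading = _es_from_hits(pos, weights, n)
    if null_es is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null_es = gsea_null_es(ranked, len(pos), n_perm, rng)
    p = (1.0 + np.sum(np.abs(null_es) >= abs(es))) / (1.0 + len(null_es))
    return EnrichmentResult(
        pathway=pathway, es=float(es), p_value=float(p),
        n_perm=int(len(null_es)), leading_edge_size=leading,
    )


def gsea_null_es(ranked: RankedList, set_size: int, n_perm: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution for random gene sets of *set_size* on *ranked*.

    Vectorized across permutations via the hit-position form of the
    running-sum extreme.
    """
    n = len(ranked)
    m = set_size
    if not 0 < m < n:
        raise ValueError("set_size must be in (0, len(ranked))")
    u = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(u, m - 1, axis=1)[:, :m], axis=1)
    w = np.abs(ranked.scores)[pos]
    totals = w.sum(axis=1, keepdims=True)
    weights = np.where(totals > 0, w / np.where(totals > 0, totals, 1.0), 1.0 / m)
    miss = 1.0 / (n - m)
    j = np.arange(m)
    cum = np.cumsum(weights, axis=1)
    after = cum - (pos - j) * miss
    before = after - weights
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


# ---------------------------------------------------------------------------
# pathway selection and per-sample indices


def select_responder_pathways(
    es_r: Mapping[str, EnrichmentResult],
    es_nr: Mapping[str, EnrichmentResult],
    p_thresh: float = 0.05,
) -> list[str]:
    """Pathways significantly and positively enriched in responders and
    exceeding the non-responder enrichment.

    A pathway absent from the non-responder results contributes an ES of 0
    on that side. The returned list is sorted for determinism; it may be
    empty.
    """
    selected = []
    for name, res in es_r.items():
        es_other = es_nr[name].es if name in es_nr else 0.0
        if res.p_value < p_thresh and res.es > 0 and res.es > es_other:
            selected.append(name)
    return sorted(selected)


def sample_ranked_list(matrix, barcodes_in, barcodes_out) -> RankedList:
    """All-gene ranking by log2FC of mean expm1(normalized), in vs out cells."""
    idx_in = matrix.cell_index(list(barcodes_in))
    idx_out = matrix.cell_index(list(barcodes_out))
    mean_in = _mean_expm1(matrix.normalized[:, idx_in])
    mean_out = _mean_expm1(matrix.normalized[:, idx_out])
    scores = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))
    order = np.lexsort((matrix.genes, -scores))
    return RankedList(genes=matrix.genes[order], scores=scores[order])


def gsea_index_per_sample(
    matrix,
    meta: pd.DataFrame,
    selected_pathways: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    cell_type: str,
    samples: Sequence[str] | None = None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-sample GSEA index for one cell type: sum of ES over selected pathways.

    For each sample the genes are ranked by log2FC of that sample's
    *cell_type* cells against all its other cells; the ES of every selected
    pathway on that ranking is summed. Samples with fewer than *min_cells*
    cells of the type (or no other cells) get a missing index.
    """
    if samples is None:
        samples = sorted(meta["sample_id"].unique())
    rows = []
    for sample in samples:
        sub = meta[meta["sample_id"] == sample]
        in_bc = sub.loc[sub["cell_type"] == cell_type, "barcode"].to_numpy()
        out_bc = sub.loc[sub["cell_type"] != cell_type, "barcode"].to_numpy()
        if len(in_bc) < min_cells or len(out_bc) == 0:
            logger.info("sample %s: %d %s cells (< %d); index missing",
                        sample, len(in_bc), cell_type, min_cells)
            rows.append((sample, cell_type, np.nan))
            continue
        if not selected_pathways:
            rows.append((sample, cell_type, 0.0))
            continue
        ranked = sample_ranked_list(matrix, in_bc, out_bc)
        index = 0.0
        for name in selected_pathways:
            index += gsea_preranked_es(ranked, gene_sets[name])
        rows.append((sample, cell_type, index))
    return pd.DataFrame(rows, columns=["sample_id", "cell_type", "gsea_index"])
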