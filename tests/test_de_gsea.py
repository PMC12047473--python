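import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iratri.de_gsea import (
    RankedList,
    bh_adjust,
    gsea_permutation_p,
    gsea_preranked_es,
    rank_by_log2fc,
    select_responder_pathways,
    wilcoxon_de,
    EnrichmentResult,
)

from conftest import continuous_matrix, dense_matrix


# ---------------------------------------------------------------------------
# oracles


def brute_force_es(scores, hit_mask):
    """Direct running-sum enrichment score: walk the full ranked list."""
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n, m = len(scores), hit_mask.sum()
    total = np.abs(scores[hit_mask]).sum()
    running, best = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            running += (np.abs(scores[i]) / total) if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def enumerate_ranksum_p(x, y):
    """Two-sided rank-sum p by tallying every assignment of pooled values."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    lo = np.mean(sums <= observed + 1e-9)
    hi = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def de_for_values(in_values, out_values):
    """Run wilcoxon_de on a single synthetic gene with given group values."""
    values = np.concatenate([in_values, out_values])[None, :]
    counts = np.ones_like(values, dtype=int)
    matrix = dense_matrix(counts, genes=["g"])
    from scipy import sparse
    matrix.normalized = sparse.csr_matrix(values.astype(float))
    cells = matrix.cells
    return wilcoxon_de(matrix, cells[: len(in_values)], cells[len(in_values):])


# ---------------------------------------------------------------------------
# Wilcoxon DE


def test_wilcoxon_identical_groups_gives_p1_fc0():
    rec = de_for_values([2.0, 3.0, 4.0], [2.0, 3.0, 4.0]).iloc[0]
    # values are not constant, but symmetric groups: p must not be small
    assert rec.p_value == pytest.approx(1.0)
    assert rec.avg_log2fc == pytest.approx(0.0, abs=1e-9)


def test_wilcoxon_constant_gene_p1():
    rec = de_for_values([1.0, 1.0, 1.0], [1.0, 1.0]).iloc[0]
    assert rec.p_value == 1.0
    assert rec.avg_log2fc == 0.0


def test_wilcoxon_exact_small_example():
    """{3,4,5} vs {0,1,2}: all 20 assignments enumerable -> p = 0.1."""
    rec = de_for_values([3.0, 4.0, 5.0], [0.0, 1.0, 2.0]).iloc[0]
    assert rec.p_value == pytest.approx(0.1, abs=1e-12)


@pytest.mark.parametrize("n1,n2,with_ties", [(3, 5, False), (6, 6, False),
                                             (4, 4, True), (7, 5, True)])
def test_wilcoxon_exact_matches_enumeration_oracle(n1, n2, with_ties):
    rng = np.random.default_rng(n1 * 100 + n2)
    for _ in range(5):
        if with_ties:
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
        else:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
        got = de_for_values(x, y).iloc[0].p_value
        assert got == pytest.approx(enumerate_ranksum_p(x, y), abs=1e-12)


def test_wilcoxon_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(42)
    x, y = rng.normal(size=6), rng.normal(size=7)
    got = de_for_values(x, y).iloc[0].p_value
    expected = stats.mannwhitneyu(x, y, method="exact").pvalue
    assert got == pytest.approx(expected, abs=1e-12)


def test_wilcoxon_asymptotic_close_to_exact_for_moderate_groups():
    """Normal approximation tracks the exact distribution at n ~ 12 per group."""
    rng = np.random.default_rng(7)
    for shift in (0.0, 0.5, 1.0):
        x = rng.normal(size=12) + shift
        y = rng.normal(size=12)
        values = np.concatenate([x, y])[None, :].repeat(2, axis=0)
        matrix = continuous_matrix(rng, 2, 24)
        from scipy import sparse
        matrix.normalized = sparse.csr_matrix(values)
        asym = wilcoxon_de(matrix, matrix.cells[:12], matrix.cells[12:]).iloc[0].p_value
        exact = stats.mannwhitneyu(x, y, method="exact").pvalue
        assert asym == pytest.approx(exact, abs=0.01)


def test_wilcoxon_group_overlap_raises(tiny_cohort):
    matrix = continuous_matrix(np.random.default_rng(0), 3, 10)
    with pytest.raises(ValueError, match="overlap"):
        wilcoxon_de(matrix, matrix.cells[:5], matrix.cells[4:])


def test_bonferroni_and_bh_dominate_raw_p():
    rng = np.random.default_rng(1)
    matrix = continuous_matrix(rng, 50, 40)
    de = wilcoxon_de(matrix, matrix.cells[:20], matrix.cells[20:])
    assert (de.p_bonferroni >= de.p_value - 1e-15).all()
    assert (de.p_bh >= de.p_value - 1e-15).all()
    assert np.isfinite(de.avg_log2fc).all()


# ---------------------------------------------------------------------------
# ranking


def test_rank_by_log2fc_threshold_sort_and_ties():
    records = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d", "e"],
            "avg_log2fc": [1.2, -0.3, 0.7, 0.7, 2.0],
            "p_value": [1e-4] * 5,
            "p_bonferroni": [0.01, 0.02, 0.03, 0.04, 0.06],
            "p_bh": [0.01] * 5,
        }
    )
    ranked = rank_by_log2fc(records, alpha=0.05, correction="bonferroni")
    # e excluded (p_bonferroni 0.06 >= 0.05); ties c/d lexicographic
    assert list(ranked.genes) == ["a", "c", "d", "b"]
    assert list(ranked.scores) == [1.2, 0.7, 0.7, -0.3]
    empty = rank_by_log2fc(records.assign(p_bonferroni=1.0))
    assert len(empty) == 0


# ---------------------------------------------------------------------------
# enrichment score


def make_ranked(scores, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return RankedList(genes=np.asarray(genes), scores=scores)


def test_es_single_hit_at_head_is_one():
    ranked = make_ranked([5.0, 4.0, 3.0, 2.0, 1.0])
    assert gsea_preranked_es(ranked, ["g0"]) == pytest.approx(1.0)


def test_es_single_hit_at_tail_matches_running_sum_oracle():
    ranked = make_ranked([5.0, 4.0, 3.0, 2.0, 1.0])
    got = gsea_preranked_es(ranked, ["g4"])
    expected = brute_force_es(ranked.scores, np.array([0, 0, 0, 0, 1], bool))
    assert got == pytest.approx(expected)
    assert got == pytest.approx(-1.0)  # four misses of 1/4 precede the hit


def test_es_two_hit_hand_enumerated_case():
    """N=6, scores 6..1, hits at ranks 1 and 4: peak after the first hit."""
    ranked = make_ranked([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    got = gsea_preranked_es(ranked, ["g0", "g3"])
    # running sum: +6/9, -1/4 steps at misses, +3/9 at rank 4
    steps = [6 / 9, 6 / 9 - 1 / 4, 6 / 9 - 2 / 4, 6 / 9 - 2 / 4 + 3 / 9,
             6 / 9 - 3 / 4 + 3 / 9, 0.0]
    assert got == pytest.approx(max(steps))
    assert got == pytest.approx(brute_force_es(ranked.scores, np.array([1, 0, 0, 1, 0, 0], bool)))


def test_es_matches_oracle_on_random_instances():
    rng = np.random.default_rng(33)
    for _ in range(200):
        n = int(rng.integers(5, 50))
        scores = np.sort(rng.normal(size=n))[::-1]
        m = int(rng.integers(1, n))
        hits = np.zeros(n, bool)
        hits[rng.choice(n, size=m, replace=False)] = True
        ranked = make_ranked(scores)
        got = gsea_preranked_es(ranked, list(ranked.genes[hits]))
        expected = brute_force_es(scores, hits)
        # the positive and negative extremes can tie in magnitude to within
        # rounding; then the chosen sign depends on summation order
        assert abs(got) == pytest.approx(abs(expected), abs=1e-12)
        if abs(got + expected) > 1e-9:  # not an opposite-sign magnitude tie
            assert got == pytest.approx(expected, abs=1e-12)


def test_es_antisymmetric_under_score_negation_and_reversal():
    rng = np.random.default_rng(12)
    for _ in range(50):
        n = int(rng.integers(5, 30))
        scores = np.sort(rng.normal(size=n))[::-1]
        m = int(rng.integers(1, n))
        hit_idx = rng.choice(n, size=m, replace=False)
        ranked = make_ranked(scores)
        flipped = RankedList(genes=ranked.genes[::-1].copy(),
                             scores=(-scores[::-1]).copy())
        genes = list(ranked.genes[hit_idx])
        es_fwd = gsea_preranked_es(ranked, genes)
        es_rev = gsea_preranked_es(flipped, genes)
        assert abs(es_rev) == pytest.approx(abs(es_fwd), abs=1e-12)
        if abs(es_rev - es_fwd) > 1e-9:  # not a magnitude tie
            assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


def test_es_degenerate_sets_raise():
    ranked = make_ranked([3.0, 2.0, 1.0])
    with pytest.raises(ValueError, match="disjoint"):
        gsea_preranked_es(ranked, ["absent"])
    with pytest.raises(ValueError, match="entire"):
        gsea_preranked_es(ranked, ["g0", "g1", "g2"])


# ---------------------------------------------------------------------------
# permutation p


def test_permutation_p_floor_and_determinism():
    ranked = make_ranked(np.linspace(3, -3, 30))
    res = gsea_permutation_p(ranked, ["g0", "g1"], n_perm=200, seed=1)
    again = gsea_permutation_p(ranked, ["g0", "g1"], n_perm=200, seed=1)
    assert res.p_value == again.p_value and res.es == again.es
    assert res.p_value >= 1.0 / 201.0
    # the two top-ranked genes are maximally enriched: p at or near the floor
    assert res.p_value < 0.05
    with pytest.raises(ValueError, match="n_perm"):
        gsea_permutation_p(ranked, ["g0"], n_perm=50, seed=1)


def test_permutation_p_uniform_under_null():
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(500):
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = make_ranked(scores)
        genes = list(rng.choice(ranked.genes, size=3, replace=False))
        pvals.append(gsea_permutation_p(ranked, genes, n_perm=200, seed=rng).p_value)
    stat, p = stats.kstest(pvals, "uniform")
    assert p > 0.01


# ---------------------------------------------------------------------------
# selection


def res(name, es, p):
    return EnrichmentResult(pathway=name, es=es, p_value=p, n_perm=100, leading_edge_size=1)


def test_select_responder_pathways_rules():
    es_r = {"a": res("a", 0.6, 0.01), "b": res("b", -0.4, 0.001),
            "c": res("c", 0.3, 0.01), "d": res("d", 0.5, 0.2), "e": res("e", 0.4, 0.01)}
    es_nr = {"a": res("a", 0.1, 0.5), "b": res("b", -0.6, 0.5),
             "c": res("c", 0.5, 0.5), "d": res("d", 0.0, 0.5)}
    selected = select_responder_pathways(es_r, es_nr)
    # a: all conditions; b: negative ES out; c: not above NR; d: not significant;
    # e: missing from NR side counts as ES 0 -> selected
    assert selected == ["a", "e"]


def test_bh_adjust_stepup_example():
    np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust(np.array([0.03, 0.01, 0.02])),
                               [0.03, 0.03, 0.03])
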