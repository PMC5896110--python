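"""Differential intron retention: result merging, the three NB test styles,
BH adjustment and the permutation Jonckheere-Terpstra trend test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from intrest.diffir import (
    MergedIntExResult,
    bh_adjust,
    deseq_style_test,
    dexseq_style_test,
    edger_style_test,
    jonckheere_statistic,
    jonckheere_trend_test,
    median_of_ratios,
    merge_int_ex,
)
from intrest.refprep import GenomicInterval, JunctionRef, ReferenceRow
from intrest.simdata import (
    intron_count_result,
    simulate_counts,
    simulate_usage_counts,
)
from intrest.summarize import InterestResult


def _intret(rows, counts, samples):
    return InterestResult(mode="IntRet", features=rows, samples=samples,
                          raw_counts=np.asarray(counts))


def _row(gene, ordinal, start):
    return ReferenceRow(GenomicInterval("chr1", start, start + 100, "+"),
                        "intron", gene, frozenset({"t"}), ordinal)


class TestMergeIntEx:
    def test_junction_counts_summed_over_spanning_junctions(self):
        rows = [_row("g1", 1, 100)]
        juncs = [JunctionRef("g1", "chr1", 100, 200, 1),
                 JunctionRef("g1", "chr1", 99, 200, 1)]
        intret = _intret(rows, [[5, 6]], ["a", "b"])
        exex = InterestResult(mode="ExEx", features=juncs, samples=["a", "b"],
                              raw_counts=np.array([[3, 1], [4, 2]]))
        merged = merge_int_ex(intret, exex)
        assert merged.junction_counts.tolist() == [[7, 3]]

    def test_intron_without_junction_excluded_with_reason(self):
        rows = [_row("g1", 1, 100), _row("g1", 2, 400)]
        juncs = [JunctionRef("g1", "chr1", 100, 200, 1)]
        intret = _intret(rows, [[5], [9]], ["a"])
        exex = InterestResult(mode="ExEx", features=juncs, samples=["a"],
                              raw_counts=np.array([[3]]))
        merged = merge_int_ex(intret, exex)
        assert merged.intron_keys == [("g1", 1)]
        assert merged.excluded == [(("g1", 2), "no_junction")]

    def test_identical_count_matrices_give_unit_size_factors(self):
        counts = np.array([[10, 10], [20, 20], [7, 7]])
        assert median_of_ratios(counts) == pytest.approx([1.0, 1.0])

    def test_size_factor_fallback_on_sparse_matrix(self):
        counts = np.array([[0, 4], [8, 0]])
        sf = median_of_ratios(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_disjoint_sample_sets_rejected(self):
        rows = [_row("g1", 1, 100)]
        intret = _intret(rows, [[5]], ["a"])
        exex = InterestResult(mode="ExEx",
                              features=[JunctionRef("g1", "chr1", 100, 200, 1)],
                              samples=["b"], raw_counts=np.array([[3]]))
        with pytest.raises(ValueError):
            merge_int_ex(intret, exex)


class TestStackedTests:
    def test_single_sample_condition_rejected_naming_level(self):
        cs = simulate_counts(n_introns=5, n_per_group=2, seed=0)
        merged = cs.merged
        condition = dict(cs.condition)
        condition[merged.samples[0]] = "lonely"
        with pytest.raises(ValueError, match="lonely"):
            deseq_style_test(merged, condition)

    def test_planted_outlier_filtered_by_cooks_rule(self):
        cs = simulate_counts(n_introns=60, n_per_group=4, seed=1)
        merged = cs.merged
        merged.intron_counts[7, 2] *= 100  # one sample, one intron
        res = deseq_style_test(merged, cs.condition)
        assert res[7].filtered_reason == "cooks_outlier"
        assert np.isnan(res[7].p_value)

    def test_cooks_filter_can_be_disabled(self):
        cs = simulate_counts(n_introns=60, n_per_group=4, seed=1)
        merged = cs.merged
        merged.intron_counts[7, 2] *= 100
        res = deseq_style_test(merged, cs.condition, cooks_filter=False)
        assert res[7].filtered_reason is None

    def test_low_total_counts_prefiltered(self):
        cs = simulate_counts(n_introns=20, n_per_group=3, seed=2)
        merged = cs.merged
        merged.intron_counts[4] = 0
        merged.junction_counts[4] = np.array([1, 0, 0, 0, 0, 1])
        res = deseq_style_test(merged, cs.condition)
        assert res[4].filtered_reason == "low_count"
        assert np.isnan(res[4].p_value)

    def test_sample_order_invariance(self):
        """Permuting the sample order never changes any test's output."""
        cs = simulate_counts(n_introns=40, n_per_group=3, seed=3,
                             differential_fraction=0.2)
        merged = cs.merged
        perm = [4, 1, 5, 0, 3, 2]
        merged_p = MergedIntExResult(
            intron_keys=merged.intron_keys,
            samples=[merged.samples[i] for i in perm],
            intron_counts=merged.intron_counts[:, perm],
            junction_counts=merged.junction_counts[:, perm],
            size_factors={k: v[perm] for k, v in merged.size_factors.items()},
            excluded=[])
        for fn in (deseq_style_test, edger_style_test):
            a = fn(merged, cs.condition)
            b = fn(merged_p, cs.condition)
            pa = [r.p_value for r in a]
            pb = [r.p_value for r in b]
            np.testing.assert_allclose(pa, pb, rtol=1e-3, equal_nan=True)
            assert [r.direction for r in a] == [r.direction for r in b]

    def test_deseq_and_edger_pvalues_rank_correlated(self):
        """Wald and LRT on the same stacked fits produce strongly
        rank-correlated p-values (Spearman >= 0.9)."""
        cs = simulate_counts(n_introns=150, n_per_group=4, seed=4,
                             differential_fraction=0.2)
        a = deseq_style_test(cs.merged, cs.condition, cooks_filter=False)
        b = edger_style_test(cs.merged, cs.condition)
        pa = np.array([r.p_value for r in a])
        pb = np.array([r.p_value for r in b])
        ok = np.isfinite(pa) & np.isfinite(pb)
        rho = stats.spearmanr(pa[ok], pb[ok]).statistic
        assert rho >= 0.9

    def test_direction_consistent_with_fold_change(self):
        cs = simulate_counts(n_introns=120, n_per_group=4, seed=5,
                             differential_fraction=0.25, effect_fold=6.0,
                             min_intron_mean=30.0)
        res = deseq_style_test(cs.merged, cs.condition, alpha=0.01)
        for r in res:
            if r.direction == "up":
                assert r.log2_fold_change > 0 and r.p_adjusted < 0.01
            elif r.direction == "down":
                assert r.log2_fold_change < 0 and r.p_adjusted < 0.01

    def test_unpaired_design_variant_runs(self):
        cs = simulate_counts(n_introns=30, n_per_group=3, seed=6)
        res = deseq_style_test(cs.merged, cs.condition, paired_design=False)
        p = np.array([r.p_value for r in res])
        assert np.isfinite(p).sum() > 20

    def test_covariate_column_accepted(self):
        cs = simulate_counts(n_introns=30, n_per_group=3, seed=7)
        covar = {"age": [0.1, -0.2, 0.3, 0.0, 0.2, -0.1]}
        res = deseq_style_test(cs.merged, cs.condition, covariates=covar)
        assert np.isfinite([r.p_value for r in res]).sum() > 20


class TestDexseqStyle:
    def test_single_intron_gene_excluded_with_reason(self):
        rows = [_row("g1", 1, 100)]
        intret = _intret(rows, [[30, 30, 30, 30]], ["a", "b", "c", "d"])
        res = dexseq_style_test(intret, {"a": "x", "b": "x", "c": "y", "d": "y"})
        assert res[0].filtered_reason == "single_intron_gene"

    def test_gene_wide_uniform_shift_is_null_for_usage_test(self):
        """When all introns of a gene shift retention by the same factor,
        the relative (usage) effect is null."""
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(8)]
        cond = {s: ("test" if i >= 4 else "ctrl") for i, s in enumerate(samples)}
        rows, counts = [], []
        for g in range(30):
            base = rng.uniform(30, 80, size=3)
            for o in range(3):
                rows.append(_row(f"g{g}", o + 1, 1000 * g + 200 * o))
                mu = np.where(np.arange(8) >= 4, base[o] * 3.0, base[o])
                counts.append(rng.poisson(mu))
        res = dexseq_style_test(_intret(rows, counts, samples), cond)
        p = np.array([r.p_value for r in res])
        assert np.isfinite(p).all()
        assert (p < 0.01).mean() <= 0.05

    def test_targeted_intron_change_detected_others_not(self):
        """One intron doubling while the gene's others stay flat is detected;
        the flat introns in unaffected genes are not."""
        us = simulate_usage_counts(n_genes=40, introns_per_gene=4, seed=9,
                                   differential_fraction=0.05, effect_fold=4.0,
                                   base_mean=800.0)
        res = dexseq_style_test(us.result, us.condition)
        padj = np.array([r.p_adjusted for r in res])
        d = us.differential
        assert ((padj < 0.01) & d).sum() / d.sum() >= 0.7
        # genes with no planted intron stay quiet
        genes_with_effect = {us.result.features[i].gene_id
                             for i in np.flatnonzero(d)}
        clean = np.array([us.result.features[i].gene_id not in genes_with_effect
                          for i in range(len(d))])
        assert (padj[clean] < 0.01).mean() <= 0.02

    def test_zero_others_excluded(self):
        rows = [_row("g1", 1, 100), _row("g1", 2, 400)]
        counts = [[30, 31, 29, 30], [0, 0, 0, 0]]
        intret = _intret(rows, counts, ["a", "b", "c", "d"])
        res = dexseq_style_test(intret, {"a": "x", "b": "x", "c": "y", "d": "y"})
        assert res[0].filtered_reason == "zero_others"


def bh_oracle(pvals):
    """Textbook step-up BH on a dense p-vector."""
    m = len(pvals)
    order = np.argsort(pvals)
    out = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvals[i] * m / rank_from_top)
        out[i] = q
        prev = q
    return out


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_capped_at_one(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_nan_passthrough_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 100))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, size=60)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


def jonckheere_exact_p(groups, alternative="increasing"):
    """Exhaustive enumeration over all distinct label assignments."""
    pooled = list(itertools.chain.from_iterable(groups))
    sizes = [len(g) for g in groups]
    obs = jonckheere_statistic([np.asarray(g, float) for g in groups])
    n_extreme = 0
    n_total = 0
    for perm in set(itertools.permutations(pooled)):
        split, start = [], 0
        for s in sizes:
            split.append(np.asarray(perm[start:start + s], float))
            start += s
        stat = jonckheere_statistic(split)
        n_total += 1
        if alternative == "increasing":
            n_extreme += stat >= obs
        else:
            n_extreme += stat <= obs
    return obs, n_extreme / n_total


class TestJonckheere:
    def test_maximal_trend_statistic_and_exact_p(self):
        stat, p = jonckheere_trend_test([[1, 2], [3, 4]], n_permutations=6000,
                                        seed=0)
        assert stat == 4.0
        _, p_exact = jonckheere_exact_p([[1, 2], [3, 4]])
        assert p_exact == pytest.approx(1 / 6)
        assert abs(p - p_exact) <= 2 * math.sqrt(p_exact * (1 - p_exact) / 6000) + 1 / 6000

    def test_all_ties_saturate_statistic(self):
        groups = [[2.0, 2.0], [2.0, 2.0, 2.0]]
        stat, p = jonckheere_trend_test(groups, n_permutations=500, seed=1)
        assert stat == 0.5 * 2 * 3
        assert p > 0.9

    def test_reversed_trend_has_zero_statistic_and_large_p(self):
        stat, p = jonckheere_trend_test([[3, 4], [1, 2]], n_permutations=500,
                                        seed=2, alternative="increasing")
        assert stat == 0.0
        assert p > 0.9

    def test_decreasing_alternative_mirrors(self):
        stat, p = jonckheere_trend_test([[3, 4], [1, 2]], n_permutations=2000,
                                        seed=3, alternative="decreasing")
        assert p < 0.2

    @pytest.mark.parametrize("groups", [
        [[0.3, 1.2, 0.7], [1.9, 0.4], [2.5, 2.2, 0.9]],
        [[5.0, 1.0], [2.0, 2.0], [3.0, 9.0]],
    ])
    def test_permutation_p_matches_exhaustive_enumeration(self, groups):
        """Total n <= 8: permutation p within twice the binomial Monte-Carlo
        error of the exact enumeration p."""
        n_perm = 4000
        stat, p = jonckheere_trend_test(groups, n_permutations=n_perm, seed=4)
        obs, p_exact = jonckheere_exact_p(groups)
        assert stat == obs
        tol = 2 * math.sqrt(p_exact * (1 - p_exact) / n_perm) + 1 / n_perm
        assert abs(p - p_exact) <= tol

    def test_p_floor_is_one_over_permutations_plus_one(self):
        vals = [[float(i)] * 3 for i in range(4)]
        stat, p = jonckheere_trend_test(vals, n_permutations=10_000, seed=5)
        assert p >= 1 / 10_001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_trend_test([[1, 2, 3]])


class TestEngineCrossCheck:
    def test_two_group_wald_concordant_with_pydeseq2(self):
        """Independent route: a plain two-group comparison run through both
        our NB engine and pydeseq2 recovers the same effects — fold-change
        estimates rank-correlate near 1 and the top-ranked gene sets agree.
        (Exact p-value agreement is not expected: the two packages moderate
        dispersions differently.)"""
        pytest.importorskip("pydeseq2")
        import warnings

        import pandas as pd
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        from intrest.nbglm import fit_nb_glm, wald_test

        rng = np.random.default_rng(12)
        n_genes, n = 80, 6
        mu = rng.lognormal(np.log(100), 0.5, size=n_genes)
        fold = np.ones(n_genes)
        fold[:20] = rng.uniform(2.5, 4.0, 20)
        mu_mat = np.outer(mu, np.ones(2 * n))
        mu_mat[:, n:] *= fold[:, None]
        counts = rng.poisson(rng.gamma(20, mu_mat / 20)).astype(int)

        X = np.column_stack([np.ones(2 * n),
                             np.concatenate([np.zeros(n), np.ones(n)])])
        fits = fit_nb_glm(counts.astype(float), X, np.zeros(2 * n))
        p_ours = np.array([wald_test(f, 1)[1] for f in fits])
        lfc_ours = np.array([f.beta[1] for f in fits]) / np.log(2)

        meta = pd.DataFrame({"condition": ["A"] * n + ["B"] * n},
                            index=[f"s{i}" for i in range(2 * n)])
        names = [f"g{i}" for i in range(n_genes)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=pd.DataFrame(counts.T, index=meta.index, columns=names),
                metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            ds.summary()
        ref = ds.results_df.loc[names]
        assert stats.spearmanr(lfc_ours,
                               ref["log2FoldChange"]).statistic >= 0.95
        top_ours = set(np.argsort(p_ours)[:20])
        top_ref = set(np.argsort(ref["pvalue"].to_numpy())[:20])
        assert len(top_ours & top_ref) / 20 >= 0.8
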