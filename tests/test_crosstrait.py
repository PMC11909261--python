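import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pleiocfdr import errors
from pleiocfdr.crosstrait import (
    bootstrap_stratified_se,
    conditional_qq,
    enrichment_reciprocity_check,
    fold_enrichment,
    genomic_spearman,
    irls_trend,
    stratified_enrichment,
    tf_outlier_test,
)
from pleiocfdr.io import AnnotationSet

from conftest import make_joined


def annotation_around(joined, rows, name="ann", half=100):
    sub = joined.iloc[rows]
    return AnnotationSet(
        name,
        pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": sub["pos"].to_numpy() - 1 - half,
                "end": sub["pos"].to_numpy() + half,
            }
        ),
    )


class TestFoldEnrichment:
    def test_toy_counts(self, toy_enrichment_table):
        res = fold_enrichment(toy_enrichment_table)
        assert (res.n_subset, res.n_subset_hits, res.n_all, res.n_all_hits) == (
            10, 4, 20, 5,
        )
        assert res.fold == pytest.approx(1.6, abs=1e-12)

    def test_perfect_dependence(self):
        p = np.concatenate([[0.01], np.linspace(0.06, 0.99, 19)])
        joined = make_joined(p, p)
        assert fold_enrichment(joined).fold == pytest.approx(20.0, abs=1e-12)

    def test_undefined_subset_raises(self):
        joined = make_joined([0.01, 0.02], [0.5, 0.6])
        with pytest.raises(errors.UndefinedEnrichmentError):
            fold_enrichment(joined)

    def test_near_one_under_independence(self):
        rng = np.random.default_rng(0)
        joined = make_joined(rng.random(100_000), rng.random(100_000))
        assert fold_enrichment(joined).fold == pytest.approx(1.0, abs=0.25)


class TestReciprocity:
    def test_toy_reciprocal(self, toy_enrichment_table):
        fxy, fyx = enrichment_reciprocity_check(toy_enrichment_table)
        assert fxy == pytest.approx(1.6, abs=1e-12)
        assert fxy == pytest.approx(fyx, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reciprocity_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        joined = make_joined(rng.random(n), rng.random(n))
        try:
            fxy, fyx = enrichment_reciprocity_check(joined)
        except errors.UndefinedEnrichmentError:
            return
        assert abs(fxy - fyx) <= 1e-12 * max(abs(fxy), abs(fyx), 1.0)

    def test_degenerate_direction_errors(self):
        joined = make_joined([0.5, 0.6], [0.01, 0.6])
        with pytest.raises(errors.UndefinedEnrichmentError):
            enrichment_reciprocity_check(joined)


class TestStratified:
    def test_full_stratum_equals_global(self, toy_enrichment_table):
        ann = annotation_around(toy_enrichment_table, range(20))
        strat = stratified_enrichment(toy_enrichment_table, ann)
        glob = fold_enrichment(toy_enrichment_table)
        assert strat.fold == glob.fold

    def test_conditioning_only_stratum(self, toy_enrichment_table):
        # the 10 aux-significant variants: conditional and marginal proportions
        # coincide inside the stratum -> fold exactly 1
        ann = annotation_around(toy_enrichment_table, range(10))
        assert stratified_enrichment(toy_enrichment_table, ann).fold == pytest.approx(
            1.0, abs=1e-12
        )

    def test_empty_stratum_errors(self, toy_enrichment_table):
        ann = AnnotationSet(
            "off", pd.DataFrame({"chrom": ["9"], "start": [0], "end": [10]})
        )
        with pytest.raises(errors.UndefinedEnrichmentError):
            stratified_enrichment(toy_enrichment_table, ann)


class TestBootstrap:
    def test_duplicated_intervals_zero_se(self, toy_enrichment_table):
        # five copies of one interval: every resampled union is identical
        pos = toy_enrichment_table["pos"]
        one = pd.DataFrame(
            {"chrom": ["1"], "start": [int(pos.min()) - 1], "end": [int(pos.max())]}
        )
        dup = AnnotationSet("dup", pd.concat([one] * 5, ignore_index=True))
        res = bootstrap_stratified_se(toy_enrichment_table, dup, n_boot=50, seed=1)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_warns_zero_se(self, toy_enrichment_table):
        ann = annotation_around(toy_enrichment_table, range(20))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = bootstrap_stratified_se(toy_enrichment_table, ann, n_boot=1, seed=1)
        assert res.se == 0.0
        assert any("1 replicate" in str(w.message) for w in rec)

    def test_matches_independent_loop(self, toy_enrichment_table):
        """Double implementation: replay the identical resampling with an
        independently written loop and compare the SE to 1e-12."""
        from pleiocfdr._rng import substream
        from pleiocfdr.crosstrait import _interval_members

        joined = toy_enrichment_table
        ann = annotation_around(joined, [0, 3, 7, 12, 18])
        res = bootstrap_stratified_se(joined, ann, n_boot=200, seed=7)

        rng = substream(7, "bootstrap")
        members = _interval_members(joined, ann)
        pt = joined["p_target"].to_numpy()
        pa = joined["p_aux"].to_numpy()
        folds = []
        for _ in range(200):
            draw = rng.integers(0, len(members), size=len(members))
            member = np.zeros(len(joined), dtype=bool)
            for j in draw:
                member[members[j]] = True
            ht = pt[member] < 0.05
            ha = pa[member] < 0.05
            if ha.sum() == 0 or ht.sum() == 0 or member.sum() == 0:
                continue
            folds.append(((ht & ha).sum() / ha.sum()) / (ht.sum() / member.sum()))
        assert res.se == pytest.approx(float(np.std(folds, ddof=1)), abs=1e-12)

    def test_too_few_intervals(self, toy_enrichment_table):
        ann = annotation_around(toy_enrichment_table, [0])
        with pytest.raises(errors.InsufficientDataError):
            bootstrap_stratified_se(toy_enrichment_table, ann)


def blocks_for(joined, n_blocks, per_block):
    rows = []
    pos = joined["pos"].to_numpy()
    for b in range(n_blocks):
        lo = b * per_block
        hi = lo + per_block - 1
        rows.append(("1", pos[lo] - 1, pos[hi]))
    return AnnotationSet("blocks", pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestGenomicSpearman:
    def _table_with_block_means(self, means_t, means_a):
        # one variant per block: block mean of -log10 p is just that variant's
        pt = 10.0 ** -np.asarray(means_t, dtype=float)
        pa = 10.0 ** -np.asarray(means_a, dtype=float)
        joined = make_joined(pt, pa)
        return joined, blocks_for(joined, len(means_t), 1)

    def test_identical_ranks(self):
        joined, blocks = self._table_with_block_means([1.0, 2.0, 3.0], [0.5, 0.9, 2.1])
        assert genomic_spearman(joined, blocks) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        joined, blocks = self._table_with_block_means([1.0, 2.0, 3.0], [2.1, 0.9, 0.5])
        assert genomic_spearman(joined, blocks) == pytest.approx(-1.0)

    def test_textbook_five_block_example(self):
        # rank pairs (1,2),(2,1),(3,3),(4,5),(5,4): 1 - 6*4/(5*24) = 0.8
        joined, blocks = self._table_with_block_means(
            [1, 2, 3, 4, 5], [2, 1, 3, 5, 4]
        )
        assert genomic_spearman(joined, blocks) == pytest.approx(0.8, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        pt = rng.random(40)
        pa = rng.random(40)
        joined = make_joined(pt, pa)
        blocks = blocks_for(joined, 8, 5)
        r1 = genomic_spearman(joined, blocks)
        joined2 = make_joined(pt**3, pa)  # strictly monotone in p
        r2 = genomic_spearman(joined2, blocks)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_insufficient_blocks(self):
        joined, blocks = self._table_with_block_means([1, 2], [1, 2])
        with pytest.raises(errors.InsufficientDataError):
            genomic_spearman(joined, blocks)

    def test_literal_unsquared_formula_degenerates_to_one(self):
        joined, blocks = self._table_with_block_means(
            [1, 2, 3, 4, 5], [2, 1, 3, 5, 4]
        )
        assert genomic_spearman(joined, blocks, literal_formula=True) == pytest.approx(1.0)


class TestIrlsTrend:
    def test_exact_line_recovery(self):
        x = np.arange(6, dtype=float)
        fit = irls_trend(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_resists_gross_outlier(self):
        x = np.arange(8, dtype=float)
        y = 2 * x + 1
        y[3] = 300.0
        fit = irls_trend(x, y)
        # oracle: OLS on the clean points recovers the true line exactly
        assert fit.slope == pytest.approx(2.0, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(errors.InsufficientDataError):
            irls_trend([0, 1, 2], [0, 1, 2])

    def test_band_contains_fit(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 30)
        y = 2 * x + 1 + 0.1 * rng.standard_normal(30)
        fit = irls_trend(x, y)
        yhat, lo, hi = fit.band(x)
        assert (lo <= yhat).all() and (yhat <= hi).all()
        assert fit.p_value < 0.001


class TestTfOutlier:
    BG = [1.0 + 0.1 * z for z in (-1.5, -1, -0.5, -0.25, 0, 0, 0.25, 0.5, 1, 1.5)]

    def test_half_at_background_mean(self):
        assert tf_outlier_test(float(np.mean(self.BG)), self.BG) == pytest.approx(0.5)

    def test_matches_t_cdf_oracle_at_three_sd(self):
        m = float(np.mean(self.BG))
        sd = float(np.std(self.BG, ddof=1))
        p = tf_outlier_test(m + 3 * sd, self.BG)
        assert p == pytest.approx(float(stats.t.sf(3, df=9)), rel=1e-12)

    def test_monotone_in_target(self):
        ps = [tf_outlier_test(x, self.BG) for x in (1.0, 1.5, 2.0, 5.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_spread_errors(self):
        with pytest.raises(errors.DegenerateDistributionError):
            tf_outlier_test(1.3, [1.0] * 10)

    def test_small_background_errors(self):
        with pytest.raises(errors.InsufficientDataError):
            tf_outlier_test(1.3, [1.0, 1.1])


class TestConditionalQQ:
    def test_full_threshold_equals_unconditional(self):
        rng = np.random.default_rng(2)
        joined = make_joined(rng.random(500), rng.random(500))
        curves = conditional_qq(joined, strata_thresholds=(1.0, 0.1))
        uncond = curves[0]
        assert uncond.n == 500
        np.testing.assert_array_equal(
            uncond.observed_quantiles, np.sort(-np.log10(joined["p_target"]))
        )
        np.testing.assert_allclose(
            uncond.expected_quantiles, -np.log10(np.arange(500, 0, -1) / 501.0)
        )
        assert curves[1].n < 500

    def test_uniform_within_ks_band(self):
        """Independent uniform target P: each curve stays inside the 99% KS
        band around the diagonal."""
        rng = np.random.default_rng(5)
        joined = make_joined(rng.random(5000), rng.random(5000))
        for c in conditional_qq(joined):
            band = stats.ksone.ppf(1 - 0.005, c.n)
            obs_cdf_gap = np.abs(
                10.0 ** -c.observed_quantiles - 10.0 ** -c.expected_quantiles
            )
            assert obs_cdf_gap.max() <= band + 1.0 / (c.n + 1)

    def test_empty_stratum_skipped_with_warning(self):
        joined = make_joined([0.5, 0.6], [0.5, 0.6])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            curves = conditional_qq(joined, strata_thresholds=(1.0, 1e-6))
        assert len(curves) == 1
        assert any("empty" in str(w.message) for w in rec)

    def test_expected_quantiles_increasing(self):
        rng = np.random.default_rng(8)
        joined = make_joined(rng.random(1000), rng.random(1000))
        for c in conditional_qq(joined):
            assert (np.diff(c.expected_quantiles) > 0).all()
            assert len(c.expected_quantiles) == len(c.observed_quantiles)
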