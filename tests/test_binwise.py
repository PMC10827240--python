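"""GC reweighting, bin short/long ratios, and chromosome-arm z-scores."""

import numpy as np
import pandas as pd
import pytest

from cffrag.binwise import (ArmZScorer, assign_bins, bin_ratios,
                            binwise_feature_matrix, filter_bins, gc_density,
                            gc_strata_weights, loess_residuals, make_bins,
                            normalize_profile, target_gc_distribution)


class TestGCReweighting:
    def test_weight_is_density_ratio(self):
        # all fragments in stratum 41; sample density 1.0 there
        gc = np.full(100, 0.415)
        target = np.zeros(100)
        target[41] = 0.02
        target[50] = 0.98
        w = gc_strata_weights(gc, target)
        assert np.allclose(w, 0.02)

    def test_identity_when_sample_equals_target(self, rng):
        gc = rng.uniform(0.2, 0.8, size=5000)
        target = gc_density(gc)
        assert np.allclose(gc_strata_weights(gc, target), 1.0)

    def test_reweighted_histogram_matches_target(self, rng):
        """Importance reweighting identity: the weighted GC histogram equals
        the target (restricted to the sample's support) within TV 1e-6 when
        no weight is capped."""
        gc = rng.beta(5, 5, size=20_000)
        strata = np.clip((gc * 100).astype(int), 0, 99)
        support = np.bincount(strata, minlength=100) > 0
        target = np.where(support, rng.uniform(0.5, 1.5, 100), 0.0)
        target /= target.sum()
        w = gc_strata_weights(gc, target, cap=np.inf)
        weighted = np.bincount(strata, weights=w, minlength=100)
        weighted /= weighted.sum()
        assert 0.5 * np.abs(weighted - target).sum() < 1e-6

    def test_target_median_and_normalization(self):
        d1, d2, d3 = np.zeros(100), np.zeros(100), np.zeros(100)
        d1[[10, 20]] = [0.01, 0.99]
        d2[[10, 20]] = [0.02, 0.98]
        d3[[10, 20]] = [0.05, 0.95]
        gs = [np.repeat(np.array([0.105, 0.205]), [int(d[10] * 1000), int(d[20] * 1000)])
              for d in (d1, d2, d3)]
        target = target_gc_distribution(gs)
        assert target.sum() == pytest.approx(1.0, abs=1e-12)
        # stratum-10 densities (0.01, 0.02, 0.05) -> median 0.02 before renorm
        assert target[10] == pytest.approx(0.02, abs=1e-12)
        single = target_gc_distribution(gs[:1])
        np.testing.assert_allclose(single, gc_density(gs[0]), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            target_gc_distribution([])


def _bins_one_chrom():
    return make_bins({"chr1": 10_000_000}, bin_size=5_000_000).assign(
        gc=0.45, mappability=0.95)


def _frags(lengths, starts, chrom="chr1"):
    lengths = np.asarray(lengths)
    starts = np.asarray(starts)
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + lengths, "gc": 0.4,
                         "length": lengths})


class TestBinRatios:
    def test_raw_ratio(self):
        frags = _frags([120] * 30 + [200] * 60, np.arange(90) * 100 + 1000)
        r = bin_ratios(frags, np.ones(90), _bins_one_chrom())
        assert r.iloc[0] == pytest.approx(0.5)

    def test_window_edges_excluded(self):
        frags = _frags([99, 100, 150, 151, 220, 221], np.arange(6) * 50 + 100)
        from cffrag.binwise import bin_weights
        bw = bin_weights(frags, np.ones(6), _bins_one_chrom())
        assert bw.loc[0, "short_weight"] == 2   # 100 and 150
        assert bw.loc[0, "long_weight"] == 2    # 151 and 220

    def test_ratio_invariant_to_weight_scale(self, rng):
        frags = _frags(rng.integers(90, 230, 200), rng.integers(0, 9_000_000, 200))
        w = rng.uniform(0.5, 2.0, size=200)
        r1 = bin_ratios(frags, w, _bins_one_chrom())
        r2 = bin_ratios(frags, 2 * w, _bins_one_chrom())
        pd.testing.assert_series_equal(r1, r2)

    def test_midpoint_assignment(self):
        bins = _bins_one_chrom()
        # fragment straddles the bin boundary; midpoint decides
        frags = _frags([200], [4_999_950])  # midpoint 5_000_050 -> bin 1
        assert assign_bins(frags, bins)[0] == 1

    def test_empty_long_is_missing(self):
        frags = _frags([120], [100])
        r = bin_ratios(frags, np.ones(1), _bins_one_chrom())
        assert np.isnan(r.iloc[0]) and np.isnan(r.iloc[1])

    def test_profile_standardization(self):
        r = pd.Series([1.0, 2.0, 3.0])
        z = normalize_profile(r)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_subsampling_halves_counts_not_ratios(self, rng):
        lengths = rng.integers(90, 230, 20_000)
        frags = _frags(lengths, rng.integers(0, 9_000_000, 20_000))
        bins = _bins_one_chrom()
        full = bin_ratios(frags, np.ones(len(frags)), bins)
        half_idx = rng.choice(len(frags), size=len(frags) // 2, replace=False)
        half = bin_ratios(frags.iloc[half_idx].reset_index(drop=True),
                          np.ones(len(half_idx)), bins)
        p = (lengths <= 150).mean()
        se = np.sqrt(p * (1 - p) / len(half_idx))  # binomial noise scale
        assert abs(full.mean() - half.mean()) < 2 * 4 * se / (1 - p)


class TestBinFilters:
    def test_gc_and_mappability_exclusions(self):
        bins = make_bins({"chr1": 15_000_000})
        bins["gc"] = [0.45, 0.25, 0.45]
        bins["mappability"] = [0.95, 0.95, 0.85]
        kept = filter_bins(bins)
        assert list(kept["start"]) == [0]

    def test_terminal_partial_bin_kept(self):
        bins = make_bins({"chr1": 12_000_000})
        assert list(bins["end"] - bins["start"]) == [5_000_000, 5_000_000, 2_000_000]


class TestArmZScores:
    def test_center_scaling(self):
        healthy_s = pd.DataFrame({"chr1p": [90.0, 100, 110], "chr1q": [10.0, 20, 30]})
        healthy_l = healthy_s + 1
        scorer = ArmZScorer().fit(healthy_s, healthy_l)
        z = scorer.transform(pd.DataFrame({"chr1p": [120.0], "chr1q": [20.0]}),
                             pd.DataFrame({"chr1p": [101.0], "chr1q": [21.0]}))
        assert z.loc[0, "z_short_chr1p"] == pytest.approx(2.0)
        assert z.loc[0, "z_short_chr1q"] == pytest.approx(0.0)

    def test_zero_sd_arm_dropped(self):
        healthy_s = pd.DataFrame({"chr1p": [100.0, 100], "chr1q": [1.0, 2]})
        healthy_l = pd.DataFrame({"chr1p": [3.0, 4], "chr1q": [5.0, 6]})
        with pytest.warns(UserWarning, match="zero healthy sd"):
            scorer = ArmZScorer().fit(healthy_s, healthy_l)
        assert scorer.arms_ == ["chr1q"]

    def test_null_z_standard_normal(self, rng):
        """Samples drawn from the healthy law score ~N(0,1) against an
        independent healthy reference."""
        arms = [f"a{i}" for i in range(10)]
        ref_s = pd.DataFrame(rng.normal(100, 10, (20, 10)), columns=arms)
        ref_l = pd.DataFrame(rng.normal(200, 15, (20, 10)), columns=arms)
        scorer = ArmZScorer().fit(ref_s, ref_l)
        test_s = pd.DataFrame(rng.normal(100, 10, (50, 10)), columns=arms)
        test_l = pd.DataFrame(rng.normal(200, 15, (50, 10)), columns=arms)
        z = scorer.transform(test_s, test_l)
        assert abs(z.to_numpy().mean()) < 0.15
        assert 0.7 < z.to_numpy().std() < 1.4

    def test_loess_equals_linear_fit_on_linear_data(self, rng):
        gc = rng.uniform(0.35, 0.55, size=60)
        y = 3.0 + 12.0 * gc  # exactly linear: any local-linear fit is exact
        res = loess_residuals(y, gc, frac=1.0)
        coeffs = np.polyfit(gc, y, 1)
        ols_res = y - np.polyval(coeffs, gc)
        assert np.abs(res - ols_res).max() < 1e-6


class TestFeatureMatrix:
    def test_planted_bins_dominate_group_difference(self, small_cohort):
        cfg = small_cohort.config
        frags = small_cohort.fragments_by_sample()
        sheet = small_cohort.sample_sheet
        healthy = sheet.loc[sheet["label"] == "healthy", "sample_id"].tolist()
        feats, n_ratio = binwise_feature_matrix(
            frags, cfg.genome.bins(), cfg.genome.arms(), healthy)
        labels = sheet.set_index("sample_id")["label"]
        ratio = feats.iloc[:, :n_ratio]
        diff = (ratio.loc[labels[labels == "MPNST"].index].mean()
                - ratio.loc[healthy].mean()).abs()
        top = {ratio.columns.get_loc(c)
               for c in diff.sort_values(ascending=False).index[:len(cfg.planted_bins)]}
        assert top == set(cfg.planted_bins)

    def test_shapes_and_row_permutation(self, small_cohort):
        cfg = small_cohort.config
        frags = small_cohort.fragments_by_sample()
        sheet = small_cohort.sample_sheet
        healthy = sheet.loc[sheet["label"] == "healthy", "sample_id"].tolist()
        feats, n_ratio = binwise_feature_matrix(
            frags, cfg.genome.bins(), cfg.genome.arms(), healthy)
        n_bins = len(cfg.genome.bins())
        n_arms = 2 * cfg.genome.n_chrom
        assert n_ratio == n_bins
        assert feats.shape == (len(sheet), n_bins + 2 * n_arms)
        assert feats.notna().all().all()
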