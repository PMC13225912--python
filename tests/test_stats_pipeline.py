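"""Bin-size rule, mixed model, quintiles, fold flagging, slopes, distribution tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from synaptodyn.stats_pipeline import (
    DEFAULT_BIN_CANDIDATES,
    binned_mean,
    compare_slopes,
    distribution_tests,
    fit_treatment_time_lme,
    flag_fold_increase,
    make_binned_table,
    quintile_subsets,
    select_bin_size,
    _lag1_acf,
)


def _ar1(rho, n, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0, sigma / np.sqrt(1 - rho**2))
    eps = rng.normal(0, sigma, n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


class TestSelectBinSize:
    def test_white_noise_selects_smallest(self):
        rng = np.random.default_rng(0)
        assert select_bin_size(rng.normal(size=2000)) == 1

    def test_ar1_matches_brute_force_scan(self):
        series = _ar1(0.9, 10_000, seed=5)
        got = select_bin_size(series)
        # brute force: first candidate whose binned lag-1 ACF < 0.3
        oracle = next(
            w for w in DEFAULT_BIN_CANDIDATES if _lag1_acf(binned_mean(series, w)) < 0.3
        )
        assert got == oracle
        assert got > 1  # rho = 0.9 per frame is far above threshold unbinned

    def test_constant_series_falls_back_to_largest(self):
        with pytest.warns(UserWarning, match="largest"):
            w = select_bin_size(np.full(2000, 3.0))
        assert w == DEFAULT_BIN_CANDIDATES[-1]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_bin_size(np.random.default_rng(0).normal(size=50))

    def test_threshold_monotonicity(self):
        """A stricter (lower) threshold never selects a smaller bin."""
        series = _ar1(0.9, 10_000, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # strictest thresholds hit the fallback
            widths = [
                select_bin_size(series, threshold=th)
                for th in (0.6, 0.45, 0.3, 0.15, 0.05)
            ]
        assert widths == sorted(widths)


def _lme_table(seed, beta_interact=0.0, n_images=3, n_tracks=12, n_bins=6,
               sd_image=0.3, sd_track=0.5, sd_eps=0.4):
    """Data generated from the mixed model itself (known slopes/variances)."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm_idx, arm in enumerate(("control", "sema4d")):
        for i in range(n_images):
            img = f"{arm}_{i}"
            b_img = rng.normal(0, sd_image)
            for t in range(n_tracks):
                b_track = rng.normal(0, sd_track)
                for b in range(n_bins):
                    time_min = (b + 0.5) * 5.0
                    mu = 1.0 + 0.01 * time_min + b_img + b_track
                    if arm == "sema4d":
                        mu += beta_interact * time_min
                    rows.append(
                        dict(image_id=img, track_id=f"{img}_t{t}", treatment=arm,
                             bin_index=b, time_min=time_min,
                             displacement=mu + rng.normal(0, sd_eps))
                    )
    return pd.DataFrame(rows)


class TestLME:
    def test_recovers_planted_interaction_slope(self):
        fit = fit_treatment_time_lme(_lme_table(3, beta_interact=0.05), "displacement")
        assert fit.interaction_p < 0.01
        assert abs(fit.interaction_coef - 0.05) < 2.5 * fit.interaction_se
        assert fit.random_variances["image"] > 0

    def test_degenerate_constant_response(self):
        df = _lme_table(1)
        df["displacement"] = 2.0
        fit = fit_treatment_time_lme(df, "displacement")
        assert fit.interaction_coef == 0.0 and fit.interaction_p == 1.0
        assert fit.random_variances == {"image": 0.0, "track": 0.0}

    def test_interaction_coverage(self):
        """95% Wald CI covers the planted slope in most model-generated replicates."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            fit = fit_treatment_time_lme(_lme_table(100 + seed, beta_interact=0.03),
                                         "displacement")
            lo = fit.interaction_coef - 1.96 * fit.interaction_se
            hi = fit.interaction_coef + 1.96 * fit.interaction_se
            hits += lo <= 0.03 <= hi
        assert hits / n_rep >= 0.85

    def test_requires_two_images_per_arm(self):
        df = _lme_table(2)
        df = df[df.image_id.isin(["control_0", "sema4d_0", "sema4d_1"])]
        with pytest.raises(ValueError):
            fit_treatment_time_lme(df, "displacement")

    def test_three_way_interactions_with_covariate(self):
        df = _lme_table(4, beta_interact=0.05)
        rng = np.random.default_rng(0)
        df["area"] = rng.uniform(0.2, 0.6, len(df))
        fit = fit_treatment_time_lme(df, "displacement", covariates=["area"])
        terms = set(fit.fixed_effects.index)
        assert any(t.count(":") == 2 for t in terms)  # a 3-way term is present
        assert fit.interaction_term in terms


class TestBinnedTable:
    def test_within_track_means_and_midpoints(self):
        df = pd.DataFrame(
            dict(image_id="i", track_id=1, treatment="control",
                 frame=np.arange(8), displacement=np.arange(8.0))
        )
        out = make_binned_table(df, 4, 15.0, "displacement")
        assert len(out) == 2
        np.testing.assert_allclose(out["displacement"], [1.5, 5.5])
        np.testing.assert_allclose(out["time_min"], [0.5, 1.5])  # bin midpoints


class TestQuintiles:
    def test_ten_distinct_tracks_groups_of_two(self):
        df = pd.DataFrame(dict(track_id=np.arange(10), base=np.arange(10.0)))
        groups = quintile_subsets(df, "base")
        assert [len(g) for g in groups] == [2] * 5
        assert groups[0].tolist() == [0, 1] and groups[-1].tolist() == [8, 9]

    def test_all_tied_split_by_track_id(self):
        df = pd.DataFrame(dict(track_id=np.arange(10)[::-1], base=np.ones(10)))
        groups = quintile_subsets(df, "base")
        assert [len(g) for g in groups] == [2] * 5
        assert groups[0].tolist() == [0, 1]


class TestFoldIncrease:
    @pytest.mark.parametrize("peak,included", [(1.49, False), (1.5, True), (2.0, True)])
    def test_threshold_boundary(self, peak, included):
        series = {0: np.concatenate([np.ones(10), [peak], np.ones(10)])}
        flagged = flag_fold_increase(series, 1.5)
        assert (0 in flagged) is included


class TestCompareSlopes:
    def test_identical_slopes(self):
        x = np.tile(np.arange(10.0), 2)
        y = 0.3 * x
        g = np.repeat(["a", "b"], 10)
        out = compare_slopes(x, y, g)
        assert out.slopes["a"] == pytest.approx(0.3)
        assert out.slopes["b"] == pytest.approx(0.3)
        assert out.interaction_p > 0.99

    def test_distinct_noiseless_slopes(self):
        x = np.tile(np.arange(10.0), 2)
        y = np.concatenate([0.3 * np.arange(10.0), 0.5 * np.arange(10.0)])
        y = y + np.tile(np.random.default_rng(0).normal(0, 1e-9, 10), 2)
        out = compare_slopes(x, y, np.repeat(["a", "b"], 10))
        assert out.slopes["a"] == pytest.approx(0.3, abs=1e-6)
        assert out.slopes["b"] == pytest.approx(0.5, abs=1e-6)
        assert out.interaction_p < 1e-6

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(1)
        hits = {"a": 0, "b": 0}
        n_rep = 50
        for _ in range(n_rep):
            x = np.tile(np.linspace(0, 10, 30), 2)
            y = np.concatenate([0.3 * x[:30], 0.5 * x[30:]]) + rng.normal(0, 0.5, 60)
            out = compare_slopes(x, y, np.repeat(["a", "b"], 30))
            for g, true in (("a", 0.3), ("b", 0.5)):
                lo, hi = out.conf_ints[g]
                hits[g] += lo <= true <= hi
        assert hits["a"] / n_rep >= 0.85 and hits["b"] / n_rep >= 0.85

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes(np.ones(20), np.arange(20.0), np.repeat(["a", "b"], 10))


class TestDistributionTests:
    def test_identical_samples_ks(self):
        x = np.arange(50.0)
        out = distribution_tests(x, x, "ks")
        assert out.statistic == 0.0 and out.pvalue == 1.0

    def test_extreme_fisher_table(self):
        out = distribution_tests([10, 0], [0, 10], "fisher")
        assert out.pvalue < 1e-3

    def test_mannwhitney_and_chi2_run(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 100), rng.normal(1, 1, 100)
        assert distribution_tests(a, b, "mannwhitney").pvalue < 0.01
        assert distribution_tests(a, b, "chi2_binned").pvalue < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            distribution_tests([], [1.0], "ks")

    def test_ks_power_matches_permutation_oracle(self):
        """KS decisions agree with a permutation test on shifted samples."""

        def perm_p(a, b, n_perm, rng):
            from scipy.stats import ks_2samp

            obs = ks_2samp(a, b).statistic
            pooled = np.concatenate([a, b])
            count = 0
            for _ in range(n_perm):
                rng.shuffle(pooled)
                count += ks_2samp(pooled[: len(a)], pooled[len(a):]).statistic >= obs
            return (count + 1) / (n_perm + 1)

        rng = np.random.default_rng(3)
        agreements = 0
        n_data = 12
        for _ in range(n_data):
            a = rng.normal(0, 1, 200)
            b = rng.normal(0.35, 1, 200)
            p_ks = distribution_tests(a, b, "ks").pvalue
            p_perm = perm_p(a, b, 200, rng)
            agreements += (p_ks < 0.05) == (p_perm < 0.05)
        assert agreements >= n_data - 1
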