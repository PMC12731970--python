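"""Nonparametric battery: Friedman, KS screen, pairwise Bonferroni, Cohen's d."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from mirrorsim.stats import (
    StatsResult,
    cohens_d,
    friedman,
    ks_normality,
    pairwise_bonferroni,
    run_study_analysis,
)


class TestFriedman:
    def test_perfectly_ordered_blocks(self):
        # 4 blocks, 3 conditions, identical ordering: chi2_F = 8.0
        m = np.tile([1.0, 2.0, 3.0], (4, 1))
        res = friedman(m)
        assert res.statistic == pytest.approx(8.0)
        # exact permutation: 6 of the 6^4 arrangements reach 8.0
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(6 / 1296)

    def test_all_equal_cells(self):
        res = friedman(np.ones((4, 3)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_asymptotic_close_to_exact_small_n(self, rng):
        m = rng.normal(size=(3, 3))
        exact = friedman(m)
        asym = friedman(m, exact_limit=1)
        assert asym.extra["method"] == "asymptotic"
        assert abs(exact.p_value - asym.p_value) < 0.15

    def test_matches_scipy_without_ties(self, rng):
        m = rng.normal(size=(30, 4))
        mine = friedman(m, exact_limit=1)
        ref = sps.friedmanchisquare(*m.T)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_invariance_within_blocks(self, rng):
        m = rng.normal(size=(8, 4))
        a = friedman(np.exp(m), exact_limit=1)
        b = friedman(m, exact_limit=1)
        assert a.statistic == pytest.approx(b.statistic)

    def test_missing_cells_rejected(self):
        m = np.ones((3, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman(m)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman(np.ones((1, 3)))


class TestKSNormality:
    def test_uniform_sample_rejected(self, rng):
        res = ks_normality(rng.uniform(size=1000), reps=2000, seed=0)
        assert res.p_value < 0.05

    def test_normal_sample_calibrated(self):
        rejections = 0
        for i in range(10):
            x = np.random.default_rng(100 + i).standard_normal(300)
            if ks_normality(x, reps=1000, seed=1).p_value < 0.05:
                rejections += 1
        assert rejections <= 2

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(20))


class TestCohensD:
    def test_known_value(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=30)
        assert cohens_d(x, x.copy()) == pytest.approx(0.0)

    def test_paired_form(self):
        x = np.array([2.0, 4.0, 6.0, 8.0])
        y = x - np.array([1.0, 2.0, 1.0, 2.0])
        d = cohens_d(x, y, paired=True)
        diff = np.array([1.0, 2.0, 1.0, 2.0])
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([0.0, 0.0], [0.0, 0.0])


def _ranksum_perm_p(x, y):
    """Brute-force permutation distribution of the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(idx)].sum()
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestPairwise:
    def test_bonferroni_adjustment_definition(self, rng):
        groups = {g: rng.normal(size=15) for g in "abcd"}
        for res in pairwise_bonferroni(groups):
            assert res.p_adjusted == pytest.approx(min(1.0, 6 * res.p_value))
            assert res.extra["m"] == 6

    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        res = pairwise_bonferroni({"a": x, "b": x.copy()})
        assert res[0].p_adjusted == 1.0

    def test_ranksum_matches_exact_permutation_small_n(self, rng):
        for i in range(5):
            r = np.random.default_rng(i)
            x, y = r.normal(size=6), r.normal(size=6)
            res = pairwise_bonferroni({"x": x, "y": y}, m=1)[0]
            assert res.p_value == pytest.approx(_ranksum_perm_p(x, y), abs=1e-9)

    def test_signed_rank_matches_exact_permutation(self):
        r = np.random.default_rng(5)
        x, y = r.normal(size=8), r.normal(size=8)
        res = pairwise_bonferroni({"x": x, "y": y}, kind="paired", m=1)[0]
        # oracle: enumerate all 2^8 sign flips of the differences
        d = x - y
        ranks = sps.rankdata(np.abs(d))
        obs = ranks[d > 0].sum()
        n = len(d)
        mu = n * (n + 1) / 4
        stats = []
        for signs in itertools.product([0, 1], repeat=n):
            s = ranks[np.array(signs, dtype=bool)].sum()
            stats.append(abs(s - mu) >= abs(obs - mu) - 1e-12)
        assert res.p_value == pytest.approx(np.mean(stats), abs=1e-9)

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            pairwise_bonferroni({"a": [1, 2, 3], "b": [1, 2]}, kind="paired")

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            StatsResult("t", 0.0, p_value=0.5, p_adjusted=0.4)


def _synthetic_records(rng, offset_means, n_per_group=20):
    """Record-level draws (no rendering) for statistical calibration tests."""
    rows = []
    for g, mu in offset_means.items():
        for pi in range(n_per_group):
            for trial in (1, 2):
                for k, tooth in enumerate((12, 21, 31, 42)):
                    rows.append({
                        "group": g,
                        "participant_id": f"{g}{pi:03d}",
                        "trial": trial,
                        "task_index": k + 1 + 4 * (trial - 1),
                        "tooth": tooth,
                        "distance_mm": rng.gamma(4.0, mu / 4.0),
                        "ratio_pct": rng.normal(2.8, 0.35),
                        "ellipticity": np.clip(rng.normal(0.88, 0.05), 0.2, 1.0),
                        "theta_deg": 5.0,
                        "time_s": rng.lognormal(2.0, 0.35),
                        "valid": True,
                    })
    return pd.DataFrame(rows)


class TestRunStudyAnalysis:
    def test_single_group_rejected(self, rng):
        df = _synthetic_records(rng, {"ID": 1.2}, n_per_group=4)
        with pytest.raises(ValueError, match="2 groups"):
            run_study_analysis(df, ks_reps=200)

    def test_report_structure(self, rng):
        df = _synthetic_records(rng, {"ID": 1.1, "ST": 1.7}, n_per_group=8)
        rep = run_study_analysis(df, ks_reps=200, seed=0)
        assert rep["groups"] == ["ID", "ST"]
        dist = rep["metrics"]["distance_mm"]
        assert "tooth 21 trial 1" in dist["between_groups"]
        assert dist["between_groups"]["tooth 21 trial 1"][0]["test"] == "rank-sum"
        assert "ID trial 1" in dist["friedman_by_tooth"]
        assert "ID" in dist["trial_comparison"]
        assert "friedman_by_task" in rep["metrics"]["time_s"]

    def test_null_rarely_significant(self):
        """Identical profiles: each per-cell Bonferroni family rejects at
        most ~5% of the time (pooled over cells and replicates)."""
        sig_families = 0
        total_families = 0
        for i in range(8):
            rng = np.random.default_rng(200 + i)
            df = _synthetic_records(rng, {"ID": 1.4, "ST": 1.4}, n_per_group=20)
            rep = run_study_analysis(df, ks_reps=100, seed=i)
            for fam in rep["metrics"]["distance_mm"]["between_groups"].values():
                total_families += 1
                if any(r["p_adjusted"] < 0.05 for r in fam):
                    sig_families += 1
        # expected rate <= 0.05; allow binomial noise at 64 families
        assert sig_families / total_families <= 0.125

    def test_separated_groups_detected(self):
        """ID 1.1 vs ST 1.7 mm at study-like sizes: detected consistently."""
        detections = 0
        for i in range(5):
            rng = np.random.default_rng(300 + i)
            df = _synthetic_records(rng, {"ID": 1.1, "ST": 1.7}, n_per_group=21)
            rep = run_study_analysis(df, ks_reps=100, seed=i)
            fams = rep["metrics"]["distance_mm"]["between_groups"]
            if any(r["p_adjusted"] < 0.05 for fam in fams.values() for r in fam):
                detections += 1
        assert detections >= 5 * 0.9

    def test_pipeline_records_accepted(self, small_cohort_df):
        rep = run_study_analysis(small_cohort_df, ks_reps=100, seed=0)
        assert rep["n_records"] <= len(small_cohort_df)
        assert set(rep["metrics"]) == {"distance_mm", "ratio_pct",
                                       "ellipticity", "time_s"}
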