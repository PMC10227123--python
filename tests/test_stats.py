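import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import wmtraj as wt
from conftest import make_matrix


def series(vals):
    return pd.Series({i: v for i, v in enumerate(vals)})


class TestOnewayAnova:
    def test_textbook_sum_of_squares(self):
        """Groups (1,2,3) and (4,5,6): SSB = 13.5, SSW = 4, F = 13.5."""
        values = series([1, 2, 3, 4, 5, 6])
        groups = series([1, 1, 1, 2, 2, 2])
        res = wt.oneway_anova(values, groups)
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.eta2 == pytest.approx(13.5 / 17.5)

    def test_identical_group_means_give_zero_F(self):
        values = series([1, 2, 3, 1, 2, 3])
        groups = series([1, 1, 1, 2, 2, 2])
        res = wt.oneway_anova(values, groups)
        assert res.F == pytest.approx(0.0)
        assert res.eta2 == pytest.approx(0.0)

    def test_group_with_single_observation_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            wt.oneway_anova(series([1, 2, 3]), series([1, 1, 2]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            wt.oneway_anova(series([2, 2, 2, 2]), series([1, 1, 2, 2]))

    def test_missing_values_dropped_pairwise(self):
        values = series([1, 2, np.nan, 4, 5, 6])
        groups = series([1, 1, 1, 2, 2, 2])
        res = wt.oneway_anova(values, groups)
        assert res.group_summaries.loc[1, "n"] == 2
        assert res.df_within == 3


class TestReferenceAgreement:
    """Randomized fixtures against scipy/statsmodels implementations."""

    @pytest.fixture(scope="class")
    def fixtures(self):
        rng = np.random.default_rng(123)
        out = []
        for _ in range(50):
            k = int(rng.integers(2, 5))
            ns = rng.integers(5, 20, size=k)
            vals, grps = [], []
            for g, n in enumerate(ns, start=1):
                vals.extend(rng.normal(rng.normal(0, 1), 1.0, size=n))
                grps.extend([g] * n)
            out.append((np.array(vals), np.array(grps)))
        return out

    def test_anova_matches_scipy(self, fixtures):
        for vals, grps in fixtures:
            res = wt.oneway_anova(series(vals), series(grps))
            ref = sps.f_oneway(*[vals[grps == g] for g in np.unique(grps)])
            assert res.F == pytest.approx(ref.statistic, abs=1e-8, rel=1e-8)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_eta2_F_identity(self, fixtures):
        for vals, grps in fixtures:
            res = wt.oneway_anova(series(vals), series(grps))
            implied = (res.eta2 / (1 - res.eta2)) * (res.df_within / res.df_between)
            assert res.F == pytest.approx(implied, rel=1e-10)

    def test_tukey_matches_statsmodels(self, fixtures):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for vals, grps in fixtures[:25]:
            res = wt.tukey_hsd(series(vals), series(grps), bonferroni_families=1)
            ref = pairwise_tukeyhsd(vals, grps)
            ref_p = np.asarray(ref.pvalues)
            got_p = res.pairs["adjusted_p"].to_numpy()
            np.testing.assert_allclose(got_p, ref_p, atol=1e-6)

    def test_paired_t_matches_scipy(self, fixtures):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            pre = rng.normal(size=n)
            post = pre - rng.normal(0.2, 0.5, size=n)
            res = wt.paired_t(series(pre), series(post))
            ref = sps.ttest_rel(pre, post)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)
            assert res.df == n - 1


class TestTukey:
    def test_equal_means_flag_nothing(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 20) for _ in range(3)])
        vals -= np.repeat([vals[:20].mean(), vals[20:40].mean(), vals[40:].mean()], 20)
        grps = np.repeat([1, 2, 3], 20)
        res = wt.tukey_hsd(series(vals), series(grps))
        assert not res.pairs["significant"].any()

    def test_bonferroni_family_shrinks_alpha(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.0, 1, 15)])
        grps = np.repeat([1, 2], 15)
        loose = wt.tukey_hsd(series(vals), series(grps), bonferroni_families=1)
        tight = wt.tukey_hsd(series(vals), series(grps), bonferroni_families=3)
        assert loose.alpha == pytest.approx(0.05)
        assert tight.alpha == pytest.approx(0.05 / 3)
        # adjusted p values themselves are identical; only the flag moves
        np.testing.assert_allclose(
            loose.pairs["adjusted_p"], tight.pairs["adjusted_p"]
        )

    def test_mean_diff_antisymmetry(self):
        vals = series([1, 2, 3, 4, 5, 6])
        grps = series([1, 1, 1, 2, 2, 2])
        res = wt.tukey_hsd(vals, grps)
        row = res.pairs.iloc[0]
        assert row["mean_diff"] == pytest.approx(-3.0)


class TestPairedT:
    def test_no_change_gives_zero(self):
        pre = series([1.0, 2.0, 3.0])
        res = wt.paired_t(pre, pre)
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_hand_arithmetic_diffs_1_2_3(self):
        pre = series([1.0, 2.0, 3.0])
        post = series([0.0, 0.0, 0.0])
        res = wt.paired_t(pre, post)
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.cohens_d == pytest.approx(2.0)
        assert res.df == 2


class TestTrajectoryDescriptives:
    def test_per_participant_first_last_improvement(self):
        vals = np.array(
            [
                [1.0, 2.0, 2.5],
                [2.0, 2.0, 2.0],
                [3.0, np.nan, 3.5],  # missing middle: last observed is 3.5
                [1.5, 2.5, np.nan],  # missing tail: last observed is 2.5
            ]
        )
        m = make_matrix(vals)
        part = wt.Partition(
            k=2,
            participants=m.participants,
            labels=np.array([1, 1, 2, 2]),
            seeds=np.full((2, 3), np.nan),
            n=4,
        )
        desc = wt.trajectory_descriptives(part, m)
        assert desc.loc[1, "improvement_mean"] == pytest.approx((1.5 + 0.0) / 2)
        assert desc.loc[2, "improvement_mean"] == pytest.approx((0.5 + 1.0) / 2)
        assert desc.loc[2, "first_day_mean"] == pytest.approx(2.25)

    def test_learner_clusters_outgain_nonlearners(self, default_cohort,
                                                  default_partition):
        desc = wt.trajectory_descriptives(default_partition, default_cohort.matrix)
        assert desc.loc[2, "improvement_mean"] > desc.loc[1, "improvement_mean"]
        assert desc.loc[3, "improvement_mean"] > desc.loc[1, "improvement_mean"]


class TestPredictorScreen:
    def test_report_has_one_row_per_predictor(self, default_cohort,
                                              default_partition):
        baseline = default_cohort.baseline.set_index("participant_id")
        screen = wt.predictor_screen(
            default_partition, baseline, predictors=["age", "gender", "cdt_pre"]
        )
        assert list(screen.table().index) == ["age", "gender", "cdt_pre"]

    def test_constant_predictor_rejected(self, default_partition):
        baseline = pd.DataFrame(
            {"flat": 1.0},
            index=default_partition.participants,
        )
        with pytest.raises(ValueError, match="zero variance"):
            wt.predictor_screen(default_partition, baseline, predictors=["flat"])

    def test_planted_cognition_gaps_detected(self, default_cohort,
                                             default_partition):
        baseline = default_cohort.baseline.set_index("participant_id")
        screen = wt.predictor_screen(
            default_partition, baseline,
            predictors=["age", "gender", "cdt_pre", "flanker_pre"],
        )
        assert screen.anovas["flanker_pre"].p < 0.05
        assert "flanker_pre" in screen.tukeys


class TestTypeIError:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 500
        for _ in range(reps):
            grps = rng.integers(1, 4, size=60)
            vals = rng.normal(size=60)
            res = wt.oneway_anova(series(vals), series(grps))
            rejections += res.p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)
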