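"""Summary-statistics layer: pooled/paired t, ANOVA, LSD, correlation,
pooling — cross-checked against scipy/pingouin and raw-data computation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from talusmorph import (
    GroupSummary,
    ValidationError,
    cohort_report,
    lsd_pairwise,
    oneway_anova_from_summaries,
    paired_t,
    pearson_r,
    pooled_t_from_summaries,
    summarize,
    weighted_pool,
)
from talusmorph.stats import format_p

# published reference summaries used repeatedly below
MALE = GroupSummary(37, 21.90, 1.97, "male")
FEMALE = GroupSummary(54, 19.57, 1.26, "female")
RIGHT = GroupSummary(41, 20.69, 2.00, "right")
LEFT = GroupSummary(50, 20.37, 1.92, "left")
REGIONS = [
    GroupSummary(91, 15.97, 3.08, "AM"),
    GroupSummary(91, 22.06, 3.94, "AL"),
    GroupSummary(91, 27.95, 12.08, "PL"),
    GroupSummary(91, 34.17, 16.22, "PM"),
    GroupSummary(91, 22.44, 5.05, "MP"),
    GroupSummary(91, 16.97, 3.09, "MA"),
]


class TestPooledT:
    def test_reference_sex_contrast(self):
        res = pooled_t_from_summaries(MALE, FEMALE)
        assert res.value == pytest.approx(6.894, rel=0.01)
        assert res.df == 89
        assert res.p_two_sided < 1e-8

    def test_reference_side_contrast(self):
        res = pooled_t_from_summaries(RIGHT, LEFT)
        assert res.value == pytest.approx(0.783, rel=0.01)
        assert res.p_two_sided == pytest.approx(0.436, abs=0.01)

    def test_identical_summaries_give_t_zero_p_one(self):
        res = pooled_t_from_summaries(MALE, MALE)
        assert res.value == 0.0 and res.p_two_sided == 1.0

    def test_zero_variance_unequal_means_flags_infinite(self):
        res = pooled_t_from_summaries(
            GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0)
        )
        assert res.infinite and np.isinf(res.value)

    def test_matches_scipy_from_stats(self):
        obs = pooled_t_from_summaries(MALE, FEMALE)
        t, p = sps.ttest_ind_from_stats(
            MALE.mean, MALE.sd, MALE.n, FEMALE.mean, FEMALE.sd, FEMALE.n
        )
        assert obs.value == pytest.approx(t, abs=1e-12)
        assert obs.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_summary_and_raw_paths_agree(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(20, 2, 37), rng.normal(19, 1.5, 54)
        obs = pooled_t_from_summaries(summarize(x), summarize(y))
        t, p = sps.ttest_ind(x, y, equal_var=True)
        assert obs.value == pytest.approx(t, abs=1e-9)


class TestPairedT:
    def test_identical_samples_give_zero(self):
        x = np.arange(10.0)
        assert paired_t(x, x).value == 0.0

    def test_hand_computed_example(self):
        # d = (1, 2, 3): t = mean/SE = 2 / (1/sqrt(3))
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.value == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == 2

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)
        res = paired_t(x, y)
        t, p = sps.ttest_rel(x, y)
        assert res.value == pytest.approx(t, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)


class TestAnovaLSD:
    def test_reference_six_region_anova(self):
        res = oneway_anova_from_summaries(REGIONS)
        assert res.value == pytest.approx(54.905, rel=0.01)
        assert res.df == (5, 540)

    def test_identical_groups_give_f_zero(self):
        res = oneway_anova_from_summaries([MALE, MALE, MALE])
        assert res.value == pytest.approx(0.0, abs=1e-20)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        f = oneway_anova_from_summaries([MALE, FEMALE]).value
        t = pooled_t_from_summaries(MALE, FEMALE).value
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_agrees_with_raw_data_anova(self):
        rng = np.random.default_rng(2)
        samples = [rng.normal(m, 2.0, 40) for m in (10, 11, 13)]
        obs = oneway_anova_from_summaries([summarize(s) for s in samples])
        f, p = sps.f_oneway(*samples)
        assert obs.value == pytest.approx(f, rel=1e-9)
        assert obs.p_two_sided == pytest.approx(p, rel=1e-6)

    def test_reference_claimed_lsd_pairs_are_significant(self):
        results = {r.label: r for r in lsd_pairwise(REGIONS)}
        for label in ("PL vs PM", "PL vs MP", "AL vs PL", "AL vs MA", "AM vs AL"):
            assert results[label].p_two_sided < 0.001

    def test_lsd_identical_pair_p_one(self):
        results = lsd_pairwise([MALE, MALE])
        assert results[0].p_two_sided == 1.0

    def test_lsd_equals_pooled_t_only_for_two_groups(self):
        two = lsd_pairwise([MALE, FEMALE])[0]
        pooled = pooled_t_from_summaries(MALE, FEMALE)
        assert two.p_two_sided == pytest.approx(pooled.p_two_sided, abs=1e-12)
        three = {r.label: r for r in lsd_pairwise([MALE, FEMALE, RIGHT])}
        # with k = 3 the MSW and df change, so the statistic must differ
        assert abs(three["male vs female"].value - pooled.value) > 0.1

    def test_lsd_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "y": np.concatenate([rng.normal(m, 2, 25) for m in (10, 11.5, 13)]),
            "g": np.repeat(["a", "b", "c"], 25),
        })
        ours = {r.label: r for r in lsd_pairwise(
            [summarize(df.loc[df.g == g, "y"].to_numpy(), label=g) for g in "abc"]
        )}
        pg = pingouin.pairwise_tests(dv="y", between="g", data=df, padjust="none")
        for _, row in pg.iterrows():
            label = f"{row['A']} vs {row['B']}"
            # pingouin uses per-pair variance, LSD the pooled MSW: same
            # direction and similar magnitude on homoscedastic data
            assert np.sign(ours[label].value) == np.sign(row["T"])
            assert ours[label].value == pytest.approx(row["T"], rel=0.2)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x).value == pytest.approx(1.0)
        assert pearson_r(x, -x).value == pytest.approx(-1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=91), rng.normal(size=91)
        res = pearson_r(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.value == pytest.approx(r, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, abs=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValidationError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestWeightedPool:
    def test_reference_pooled_fitted_mean(self):
        pooled = weighted_pool([MALE, FEMALE])
        assert pooled.mean == pytest.approx(20.52, abs=0.01)
        assert pooled.sd == pytest.approx(1.95, abs=0.02)
        assert pooled.n == 91

    def test_side_pooling_cross_check(self):
        pooled = weighted_pool([RIGHT, LEFT])
        assert pooled.mean == pytest.approx(20.51, abs=0.01)

    def test_single_group_returned_unchanged(self):
        assert weighted_pool([MALE]) == MALE

    def test_pooled_sd_equals_raw_sd(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(10, 2, 30), rng.normal(14, 3, 50)
        pooled = weighted_pool([summarize(x), summarize(y)])
        assert pooled.sd == pytest.approx(np.concatenate([x, y]).std(ddof=1), rel=1e-12)
        assert pooled.mean == pytest.approx(np.concatenate([x, y]).mean(), rel=1e-12)


class TestTypeIError:
    """Null-simulation calibration: rejection rates at alpha = 0.05 must sit
    near 0.05 (seeded, 1000 replicates each)."""

    def test_pooled_t_calibration(self):
        rng = np.random.default_rng(10)
        rejections = sum(
            pooled_t_from_summaries(
                summarize(rng.normal(20, 2, 37)), summarize(rng.normal(20, 2, 54))
            ).p_two_sided < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_paired_t_calibration(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(1000):
            base = rng.normal(20, 2, 30)
            x = base + rng.normal(0, 0.5, 30)
            y = base + rng.normal(0, 0.5, 30)
            rejections += paired_t(x, y).p_two_sided < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_pearson_calibration(self):
        rng = np.random.default_rng(12)
        rejections = sum(
            pearson_r(rng.normal(size=91), rng.normal(size=91)).p_two_sided < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestCohortReport:
    def _records(self, n_subjects=30, sex_scale=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            sex = "male" if i % 2 == 0 else "female"
            scale = sex_scale if sex == "male" else 1.0
            base = {
                "r_am": rng.normal(16, 2), "r_al": rng.normal(22, 2),
                "r_pm": rng.normal(34, 3), "r_pl": rng.normal(28, 3),
                "r_ma": rng.normal(17, 2), "r_mp": rng.normal(22, 2),
                "r_cyl": rng.normal(20.5, 1.5),
            }
            for side in ("right", "left"):
                rows.append({
                    "specimen_id": f"s{i}", "sex": sex, "age": rng.uniform(15, 68),
                    "side": side,
                    **{k: scale * v + rng.normal(0, 0.2) for k, v in base.items()},
                    "cyl_rms": 0.5,
                })
        return pd.DataFrame(rows)

    def test_constructed_sex_effect_is_positive_everywhere(self):
        df = self._records(sex_scale=1.12, seed=7)
        report = cohort_report(df)
        for col in ("r_am", "r_al", "r_pm", "r_pl", "r_ma", "r_mp", "r_cyl"):
            assert report["tests"][f"t_sex_{col}"]["value"] > 0

    def test_age_correlation_near_zero_without_age_effect(self):
        df = self._records(seed=8)
        report = cohort_report(df)
        assert abs(report["tests"]["corr_age_r_cyl"]["value"]) < 0.3

    def test_paired_t_present_for_bilateral_cohort(self):
        report = cohort_report(self._records(seed=9))
        assert "paired_t_r_cyl" in report["tests"]
        assert report["tests"]["paired_t_r_cyl"]["df"] == 29

    def test_single_specimen_cohort_yields_valid_empty_report(self):
        df = self._records(n_subjects=1).iloc[:1]
        report = cohort_report(df)
        assert report["n_records"] == 1
        assert report["tests"] == {} or "anova_regions" not in report["tests"]
        assert len(report["skipped"]) > 0

    def test_age_cut_defaults_to_median(self):
        df = self._records(seed=10)
        report = cohort_report(df)
        assert report["age_cut"] == pytest.approx(df["age"].median())


def test_p_value_formatting():
    assert format_p(0.0004) == "< 0.001"
    assert format_p(0.0361) == "0.036"
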