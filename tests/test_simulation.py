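"""Monte Carlo evaluation and the agreement-metric battery."""

import numpy as np
import pandas as pd
import pytest

from procat import (
    CatConfig,
    SimulationConfig,
    ThetaDistribution,
    agreement_report,
    category_probabilities,
    generate_thetas,
    make_fixture_bank,
    records_frame,
    run_monte_carlo,
    simulate_full_responses,
    usage_table,
)


class TestGenerateThetas:
    def test_standard_normal_moments(self):
        cfg = SimulationConfig(
            n_respondents=100_000,
            theta_distribution=ThetaDistribution(kind="standard_normal"),
            seed=1,
        )
        th = generate_thetas(cfg)
        assert abs(th.mean()) < 0.02
        assert abs(th.std() - 1.0) < 0.02

    def test_empirical_single_score_is_constant(self):
        cfg = SimulationConfig(
            n_respondents=50,
            theta_distribution=ThetaDistribution(kind="empirical", scores=(60.0,)),
            seed=1,
        )
        th = generate_thetas(cfg)
        assert np.all(th == th[0])
        assert th[0] == pytest.approx((60.0 - 50.0) / 12.5)

    def test_score_scale_back_transform(self):
        cfg = SimulationConfig(
            n_respondents=100_000,
            theta_distribution=ThetaDistribution(kind="normal_score_scale", mean=43.9, sd=18.7),
            seed=2,
        )
        th = generate_thetas(cfg)
        # affine inverse: logit mean = (43.9 - 50) / 12.5 = -0.488
        assert th.mean() == pytest.approx(-0.488, abs=0.02)
        assert th.std() == pytest.approx(18.7 / 12.5, abs=0.02)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ThetaDistribution(kind="cauchy")

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_respondents=100, seed=9)
        assert np.array_equal(generate_thetas(cfg), generate_thetas(cfg))


class TestSimulateResponses:
    def test_extreme_theta_gives_top_categories(self, fixture_bank):
        for item in fixture_bank:
            assert category_probabilities(item, 8.0)[-1] > 0.99
        rng = np.random.default_rng(0)
        rv = simulate_full_responses(8.0, fixture_bank, rng)
        tops = [rv.entries[it.item_id] == it.n_categories for it in fixture_bank]
        assert np.mean(tops) > 0.9

    def test_same_seed_identical_responses(self, fixture_bank):
        rv1 = simulate_full_responses(0.4, fixture_bank, np.random.default_rng(5))
        rv2 = simulate_full_responses(0.4, fixture_bank, np.random.default_rng(5))
        assert rv1 == rv2

    def test_category_frequencies_match_model(self, fixture_bank):
        theta = 0.25
        rng = np.random.default_rng(3)
        item = fixture_bank[0]
        n = 4000
        draws = np.array(
            [simulate_full_responses(theta, fixture_bank, rng).entries[item.item_id]
             for _ in range(n)]
        )
        freq = np.bincount(draws, minlength=item.n_categories + 1)[1:] / n
        assert np.max(np.abs(freq - category_probabilities(item, theta))) < 0.03


class TestRunMonteCarlo:
    def test_seeded_determinism(self, fixture_bank):
        cfg = SimulationConfig(n_respondents=3, seed=17)
        r1 = run_monte_carlo(fixture_bank, cfg)
        r2 = run_monte_carlo(fixture_bank, cfg)
        assert records_frame(r1).equals(records_frame(r2))

    def test_unreachable_threshold_equates_arms(self, fixture_bank):
        cfg = SimulationConfig(
            n_respondents=20, seed=4, cat_config=CatConfig(se_threshold=0.0)
        )
        for rec in run_monte_carlo(fixture_bank, cfg):
            assert rec.cat_result.final.score_0_100 == rec.full_estimate.score_0_100

    def test_item_reduction_on_fixture_bank(self, fixture_bank):
        cfg = SimulationConfig(n_respondents=150, seed=12)
        records = run_monte_carlo(fixture_bank, cfg)
        report = agreement_report(records)
        assert report.items_median < 10  # adaptive stopping actually bites
        assert report.median_sem < 0.3


class TestAgreementReport:
    def _frame(self, cat, full, n_items=None, sem=0.2):
        n = len(cat)
        return pd.DataFrame(
            {
                "cat_score": cat,
                "full_score": full,
                "n_items": n_items if n_items is not None else [2] * n,
                "cat_se_logit": [sem] * n,
            }
        )

    def test_identity_scores(self):
        full = [30.0, 45.0, 50.0, 62.0, 71.0]
        rep = agreement_report(self._frame(full, full))
        assert rep.mean_error == 0
        assert rep.mean_absolute_error == 0
        assert rep.rmse == 0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.bland_altman["loa_lower"] == 0
        assert rep.bland_altman["loa_upper"] == 0

    def test_constant_shift(self):
        full = np.array([30.0, 45.0, 50.0, 62.0, 71.0])
        rep = agreement_report(self._frame(full + 2.0, full))
        assert rep.mean_error == pytest.approx(2.0)
        assert rep.mean_absolute_error == pytest.approx(2.0)
        assert rep.rmse == pytest.approx(2.0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.bland_altman["loa_lower"] == pytest.approx(2.0)
        assert rep.bland_altman["loa_upper"] == pytest.approx(2.0)
        assert rep.regression_slope == pytest.approx(1.0)
        assert rep.regression_intercept == pytest.approx(2.0)

    def test_hand_sized_spreadsheet_oracle(self):
        cat = np.array([41.0, 47.5, 52.0, 58.5, 69.0])
        full = np.array([40.0, 49.0, 50.0, 60.0, 66.0])
        rep = agreement_report(self._frame(cat, full))
        diff = cat - full
        assert rep.mean_error == pytest.approx(diff.mean())
        assert rep.mean_absolute_error == pytest.approx(np.abs(diff).mean())
        assert rep.rmse == pytest.approx(np.sqrt((diff**2).mean()))
        # Pearson by raw formula
        r = np.sum((cat - cat.mean()) * (full - full.mean())) / np.sqrt(
            np.sum((cat - cat.mean()) ** 2) * np.sum((full - full.mean()) ** 2)
        )
        assert rep.pearson_r == pytest.approx(r)
        # regression of CAT on full-length by normal equations
        slope = np.sum((full - full.mean()) * (cat - cat.mean())) / np.sum(
            (full - full.mean()) ** 2
        )
        intercept = cat.mean() - slope * full.mean()
        assert rep.regression_slope == pytest.approx(slope)
        assert rep.regression_intercept == pytest.approx(intercept)
        assert rep.r_squared == pytest.approx(r**2)
        # Bland-Altman limits
        sd = diff.std(ddof=1)
        assert rep.bland_altman["loa_lower"] == pytest.approx(diff.mean() - 1.96 * sd)
        assert rep.bland_altman["loa_upper"] == pytest.approx(diff.mean() + 1.96 * sd)
        # MAE >= |ME| always; LoA bracket contains the mean difference
        assert rep.mean_absolute_error >= abs(rep.mean_error)
        assert (
            rep.bland_altman["loa_lower"]
            <= rep.bland_altman["mean_difference"]
            <= rep.bland_altman["loa_upper"]
        )

    def test_icc_cross_checked_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        full = rng.normal(50, 15, 40)
        cat = full + rng.normal(0.5, 3.0, 40)
        rep = agreement_report(self._frame(cat, full))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["cat", "full"], 40),
                "score": np.column_stack([cat, full]).ravel(),
            }
        )
        icc_table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        want = icc_table.loc[icc_table["Type"] == "ICC(A,1)", "ICC"].item()
        assert rep.icc == pytest.approx(want, abs=1e-10)

    def test_zero_variance_marked_undefined(self):
        rep = agreement_report(self._frame([50.0] * 4, [50.0] * 4))
        assert rep.pearson_r is None
        assert rep.icc is None
        assert rep.r_squared is None

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            agreement_report(self._frame([1.0, 2.0], [1.0, 2.0]))

    def test_metrics_collapse_when_threshold_vanishes(self, fixture_bank):
        cfg = SimulationConfig(
            n_respondents=60, seed=10, cat_config=CatConfig(se_threshold=1e-6)
        )
        rep = agreement_report(run_monte_carlo(fixture_bank, cfg))
        assert rep.mean_error == 0
        assert rep.mean_absolute_error == 0
        assert rep.rmse == 0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)


class TestUsageTable:
    def test_first_item_administered_to_everyone(self, fixture_bank):
        cfg = SimulationConfig(n_respondents=40, seed=21)
        records = run_monte_carlo(fixture_bank, cfg)
        table = usage_table(records, fixture_bank)
        assert (table["count"] == 40).sum() >= 1
        first = records[0].cat_result.state.administered[0]
        assert table.set_index("item_id").loc[first, "count"] == 40

    def test_unreachable_threshold_everything_100_percent(self, fixture_bank):
        cfg = SimulationConfig(
            n_respondents=10, seed=2, cat_config=CatConfig(se_threshold=0.0)
        )
        table = usage_table(run_monte_carlo(fixture_bank, cfg), fixture_bank)
        assert np.all(table["percentage"] == 100.0)

    def test_counts_conserved(self, fixture_bank):
        cfg = SimulationConfig(n_respondents=40, seed=21)
        records = run_monte_carlo(fixture_bank, cfg)
        table = usage_table(records, fixture_bank)
        total = sum(len(r.cat_result.state.administered) for r in records)
        assert table["count"].sum() == total


class TestEndToEnd:
    def test_recalibrated_bank_gives_similar_item_burden(self, recovery):
        true_bank, _, model = recovery
        cfg = SimulationConfig(n_respondents=150, seed=31)
        med_true = agreement_report(run_monte_carlo(true_bank, cfg)).items_median
        refit_bank = model.item_bank_
        med_refit = agreement_report(run_monte_carlo(refit_bank, cfg)).items_median
        assert abs(med_true - med_refit) <= 1
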