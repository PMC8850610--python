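import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcnef import PipelineConfig
from fcnef.errors import InputError, ParameterError
from fcnef.group_analysis import (
    change_scores,
    correlate_changes,
    exclude_outliers,
    fit_change_model,
    likelihood_ratio_test,
    loo_predict,
    repeated_measures_task_model,
    resting_fc,
)
from fcnef.preprocess import bandpass, build_nuisance, regress_out
from fcnef.synthetic_data import (
    CohortSpec,
    SignalSpec,
    simulate_cohort,
    simulate_roi_pair,
)
from oracles import resting_fc_bruteforce


class TestRestingFC:
    def test_identical_series_give_unity(self, rng, config):
        pair = simulate_roi_pair(590, SignalSpec(target_r=0.0), seed=0)
        r = resting_fc(pair.roi1, pair.roi1.copy(), pair.motion,
                       pair.tissue_means, config)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_pipeline(self, config):
        for seed in range(3):
            pair = simulate_roi_pair(300, SignalSpec(target_r=-0.3,
                                                     spike_volumes=(50, 120)),
                                     seed=seed)
            mine = resting_fc(pair.roi1, pair.roi2, pair.motion,
                              pair.tissue_means, config)
            ref = resting_fc_bruteforce(
                pair.roi1, pair.roi2, pair.motion.values,
                pair.nuisance.design, config.sphere_head_radius_mm,
                config.fd_threshold_mm, config.tr_seconds,
                config.resting_band)
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_scrubbing_removes_spike_driven_correlation(self, config):
        # a multi-frame motion excursion carries a large shared signal
        # artifact not spanned by the motion/derivative regressors;
        # removing the high-FD frames must bring the estimate closer to
        # the planted clean value than leaving them in
        target = -0.5
        hump = np.array([1.0, 2.0, 3.0, 2.0, 1.0])        # mm positions
        artifact = np.array([5.0, 15.0, 25.0, 15.0, 5.0])  # shared signal
        diffs = []
        for seed in range(20):
            pair = simulate_roi_pair(590, SignalSpec(target_r=target),
                                     seed=seed)
            motion = pair.motion.values.copy()
            motion[200:205, 0] += hump
            roi1 = pair.roi1.copy()
            roi2 = pair.roi2.copy()
            roi1[200:205] += artifact
            roi2[200:205] += artifact
            scrubbed = resting_fc(roi1, roi2, motion, pair.tissue_means,
                                  config)
            # same pipeline without the scrubbing step
            stacked = np.column_stack([roi1, roi2])
            resid = regress_out(stacked, build_nuisance(
                motion, pair.tissue_means))
            filt = bandpass(resid, config.tr_seconds, *config.resting_band)
            unscrubbed = np.corrcoef(filt[:, 0], filt[:, 1])[0, 1]
            diffs.append(abs(unscrubbed - target) - abs(scrubbed - target))
        assert np.mean(diffs) > 0

    def test_overscrubbed_series_rejected(self, config):
        pair = simulate_roi_pair(20, SignalSpec(), seed=0)
        motion = pair.motion.values.copy()
        motion[1:, 0] = np.arange(1, 20) * 2.0   # every frame FD > 0.5
        with pytest.raises(InputError):
            resting_fc(pair.roi1, pair.roi2, motion, pair.tissue_means,
                       config)


class TestChangeScores:
    @pytest.fixture
    def cohort(self):
        table, _ = simulate_cohort(CohortSpec(n_participants=8, seed=2))
        return table

    def test_delta_is_later_minus_day0(self):
        rows = []
        for day, bdi in (("Day0", 20.0), ("FCNefDay4", 15.0)):
            rows.append({"participant_id": "P01", "experiment_id": 1,
                         "day": day, "BDI": bdi, "RRS_depression": 30,
                         "RRS_brooding": 10, "RRS_reflection": 10,
                         "STAI2": 40, "rs_fc": 0.0})
        cs = change_scores(pd.DataFrame(rows).assign(), "FCNefDay4")
        assert cs.loc[0, "delta_BDI"] == -5.0

    def test_missing_horizon_drops_participant_only_there(self, cohort):
        # experiment-1 participants have no Post2m rows
        cs_day4 = change_scores(cohort, "FCNefDay4")
        cs_post = change_scores(cohort, "Post2m")
        assert len(cs_day4) == 8
        assert set(cs_post.participant_id) == set(
            cohort[cohort.experiment_id == 2].participant_id)

    def test_antisymmetry_under_day_swap(self, cohort):
        swapped = cohort.copy()
        swapped["day"] = swapped["day"].map(
            {"Day0": "FCNefDay4", "FCNefDay4": "Day0"}).fillna(swapped["day"])
        a = change_scores(cohort, "FCNefDay4").set_index("participant_id")
        b = change_scores(swapped, "FCNefDay4").set_index("participant_id")
        np.testing.assert_allclose(a["delta_BDI"], -b.loc[a.index, "delta_BDI"])

    def test_empty_result_rejected(self, cohort):
        only_day0 = cohort[cohort.day == "Day0"]
        with pytest.raises(InputError):
            change_scores(only_day0, "FCNefDay4")


class TestOutlierExclusion:
    def test_hand_computed_mask_for_skewed_set(self):
        # {0,0,0,0,100}: mean 20, sample SD ~44.7 -> 100 is ~1.79 SD, kept
        mask = exclude_outliers([0, 0, 0, 0, 100], k=2.0)
        assert mask.all()

    def test_true_outlier_excluded(self):
        values = [0.0] * 10 + [100.0]
        mask = exclude_outliers(values, k=2.0)
        assert not mask[-1] and mask[:-1].all()

    def test_zero_variance_keeps_all(self):
        assert exclude_outliers([5.0, 5.0, 5.0], k=2.0).all()

    def test_symmetric_pair_kept(self):
        assert exclude_outliers([-1.0, 0.0, 1.0], k=2.0).all()

    def test_shift_and_scale_invariance(self, rng):
        x = rng.standard_normal(50)
        base = exclude_outliers(x)
        np.testing.assert_array_equal(base, exclude_outliers(3.0 * x + 7.0))


class TestChangeModel:
    def test_noiseless_slope_exact(self):
        table, _ = simulate_cohort(CohortSpec(n_participants=12, beta=20.0,
                                              residual_sd=0.0, seed=0,
                                              follow_up=False))
        fit = fit_change_model(change_scores(table), "BDI")
        assert fit.params["delta_rs_fc"] == pytest.approx(20.0, abs=1e-8)
        assert fit.anova.loc["delta_rs_fc", "F"] > 1e10

    def test_slope_covered_by_ci(self):
        # 95% CI covers the planted slope in >= 90 of 100 seeds
        cover = 0
        for seed in range(100):
            table, _ = simulate_cohort(
                CohortSpec(n_participants=200, beta=20.0, residual_sd=2.0,
                           follow_up=False, seed=seed))
            fit = fit_change_model(change_scores(table), "BDI")
            b = fit.params["delta_rs_fc"]
            se = fit.bse["delta_rs_fc"]
            cover += (b - 1.96 * se) <= 20.0 <= (b + 1.96 * se)
        assert cover >= 90

    def test_interaction_model_has_four_coefficients(self):
        table, _ = simulate_cohort(CohortSpec(seed=1, follow_up=False))
        fit = fit_change_model(change_scores(table), "BDI",
                               include_experiment_interaction=True)
        assert list(fit.params.index) == [
            "const", "delta_rs_fc", "experiment2", "delta_rs_fc:experiment2"]

    def test_outlier_screen_reduces_n(self):
        table, _ = simulate_cohort(CohortSpec(n_participants=12, seed=4,
                                              follow_up=False))
        cs = change_scores(table)
        cs.loc[0, "delta_BDI"] = 500.0
        fit = fit_change_model(cs, "BDI", outlier_k=2.0)
        assert fit.n_used == len(cs) - 1

    def test_row_order_invariance(self):
        table, _ = simulate_cohort(CohortSpec(seed=5, follow_up=False))
        cs = change_scores(table)
        shuffled = cs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f1 = fit_change_model(cs, "BDI")
        f2 = fit_change_model(shuffled, "BDI")
        assert f1.params["delta_rs_fc"] == pytest.approx(
            f2.params["delta_rs_fc"])
        assert f1.llf == pytest.approx(f2.llf)

    def test_aic_identity(self):
        table, _ = simulate_cohort(CohortSpec(seed=6, follow_up=False))
        fit = fit_change_model(change_scores(table), "BDI")
        assert fit.aic == pytest.approx(2 * (fit.n_params + 1) - 2 * fit.llf)


class TestLikelihoodRatio:
    def _fits(self, seed=7, **spec_kwargs):
        table, _ = simulate_cohort(CohortSpec(seed=seed, follow_up=False,
                                              **spec_kwargs))
        cs = change_scores(table)
        return (fit_change_model(cs, "BDI", True),
                fit_change_model(cs, "BDI", False))

    def test_identical_models_give_chi2_zero(self):
        full, _ = self._fits()
        lrt = likelihood_ratio_test(full, full)
        assert lrt.chi2 == 0.0 and lrt.p == 1.0

    def test_experiment_block_has_two_degrees_of_freedom(self):
        full, reduced = self._fits()
        assert likelihood_ratio_test(full, reduced).df == 2

    def test_non_nested_models_rejected(self):
        full, reduced = self._fits()
        with pytest.raises(InputError):
            likelihood_ratio_test(reduced, full)

    def test_strong_experiment_effect_detected(self):
        full, reduced = self._fits(seed=8, n_participants=40,
                                   experiment_effect=10.0, residual_sd=2.0)
        assert likelihood_ratio_test(full, reduced).p < 0.001


class TestLeaveOneOut:
    def test_noiseless_cohort_predicted_exactly(self):
        table, _ = simulate_cohort(CohortSpec(n_participants=10, beta=20.0,
                                              residual_sd=0.0, seed=0,
                                              follow_up=False))
        loo = loo_predict(change_scores(table), "BDI")
        np.testing.assert_allclose(loo.table["predicted"],
                                   loo.table["actual"], atol=1e-8)
        assert loo.r == pytest.approx(1.0, abs=1e-9)

    def test_study_sized_cohort_predicts_well(self):
        # n = 19, strong planted slope, small noise: LOO r > 0.6 in
        # >= 90 of 100 seeds
        good = 0
        for seed in range(100):
            table, _ = simulate_cohort(
                CohortSpec(n_participants=19, beta=20.0, residual_sd=1.0,
                           follow_up=False, seed=seed))
            loo = loo_predict(change_scores(table), "BDI")
            good += loo.r > 0.6
        assert good >= 90

    def test_null_cohort_centered_at_or_below_zero(self):
        rs = []
        for seed in range(40):
            table, _ = simulate_cohort(
                CohortSpec(n_participants=19, beta=0.0, residual_sd=2.0,
                           follow_up=False, seed=seed))
            rs.append(loo_predict(change_scores(table), "BDI").r)
        assert np.mean(rs) < 0.15

    def test_too_few_records_rejected(self):
        table, _ = simulate_cohort(CohortSpec(n_participants=4, seed=0,
                                              follow_up=False))
        with pytest.raises(InputError):
            loo_predict(change_scores(table), "BDI")


class TestCorrelation:
    def test_perfectly_linear_pairs(self):
        cs = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(5)],
            "experiment_id": 1,
            "delta_rs_fc": [-0.2, -0.1, 0.0, 0.1, 0.2],
            "delta_BDI": [-4.0, -2.0, 0.0, 2.0, 4.0],
        })
        r, p = correlate_changes(cs, "BDI")
        assert r == pytest.approx(1.0)

    def test_hand_listed_pairs_match_direct_formula(self):
        x = np.array([-0.15, -0.05, 0.02, 0.08, 0.11])
        y = np.array([-3.0, -1.0, 0.5, 1.0, 2.5])
        cs = pd.DataFrame({"participant_id": list("abcde"),
                           "experiment_id": 1,
                           "delta_rs_fc": x, "delta_BDI": y})
        r, p = correlate_changes(cs, "BDI")
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(stats.pearsonr(x, y).pvalue)

    def test_independent_pairs_near_zero(self, rng):
        cs = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(1000)],
            "experiment_id": 1,
            "delta_rs_fc": rng.standard_normal(1000),
            "delta_BDI": rng.standard_normal(1000),
        })
        r, _ = correlate_changes(cs, "BDI")
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        cs = pd.DataFrame({"participant_id": list("abc"),
                           "experiment_id": 1,
                           "delta_rs_fc": [0.0, 0.0, 0.0],
                           "delta_BDI": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError):
            correlate_changes(cs, "BDI")


class TestRepeatedMeasuresModel:
    def _scores(self, slope, intercept_sd, residual_sd, seed, n=19):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n):
            intercept = 50.0 + rng.normal(0.0, intercept_sd)
            for day in range(1, 5):
                rows.append({
                    "participant_id": f"P{p:02d}", "day": day,
                    "score": intercept + slope * day
                    + rng.normal(0.0, residual_sd),
                })
        return pd.DataFrame(rows)

    def test_noiseless_day_slope_recovered(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = repeated_measures_task_model(self._scores(3.0, 5.0, 0.0, 0))
        assert fit.params["day"] == pytest.approx(3.0, abs=1e-6)

    def test_variance_components_recovered_within_factor_two(self):
        ratios_g, ratios_r = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(100):
                fit = repeated_measures_task_model(
                    self._scores(3.0, 5.0, 1.0, seed))
                res = fit.results
                ratios_g.append(float(np.asarray(res.cov_re)[0, 0]) / 25.0)
                ratios_r.append(float(res.scale) / 1.0)
        assert 0.5 < np.mean(ratios_g) < 2.0
        assert 0.5 < np.mean(ratios_r) < 2.0

    def test_single_day_rejected(self):
        df = self._scores(3.0, 5.0, 1.0, 0)
        with pytest.raises(InputError):
            repeated_measures_task_model(df[df.day == 1])

    def test_day_effect_detected_when_planted(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = repeated_measures_task_model(self._scores(3.0, 5.0, 1.0, 1))
        assert fit.anova.loc["day", "p"] < 1e-6
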