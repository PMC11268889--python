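"""Estimators: log-ratio, logistic success model, penalized trend, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import owlstrike as o
from owlstrike.stats import (
    ForceTrendModel,
    HuntingSuccessModel,
    SeparationError,
    descriptive_tables,
    ratio_of_means_log,
)


class TestRatioOfMeansLog:
    def test_identical_groups_ratio_one(self):
        a = np.array([2.0, 3.0, 4.0])
        est = ratio_of_means_log(a, a.copy(), n_boot=100, seed=0)
        assert est.ratio == pytest.approx(1.0)

    def test_elementwise_halving_gives_two(self):
        a = np.array([2.0, 3.0, 4.0, 8.0])
        est = ratio_of_means_log(a, a / 2.0, n_boot=100, seed=0)
        assert est.ratio == pytest.approx(2.0)

    def test_symmetry_product_is_one(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(2, 0.3, 50), rng.lognormal(1.8, 0.3, 60)
        fwd = ratio_of_means_log(a, b, n_boot=50, seed=0).ratio
        rev = ratio_of_means_log(b, a, n_boot=50, seed=0).ratio
        assert fwd * rev == pytest.approx(1.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_means_log(np.array([1.0, -2.0]), np.array([1.0]))

    def test_recovers_generated_sex_ratio(self):
        """Forces generated at a true F/M perch ratio of 1.26 are recovered."""
        rng = np.random.default_rng(7)
        f = rng.lognormal(np.log(9.94), 0.25, 400)
        m = rng.lognormal(np.log(7.91), 0.25, 400)
        est = ratio_of_means_log(f, m, n_boot=500, seed=7)
        assert est.ci_low <= 1.26 <= est.ci_high
        assert est.ratio == pytest.approx(1.26, rel=0.05)

    def test_bootstrap_ci_coverage(self):
        """Nominal 95% percentile CI covers the truth 90-98% of the time."""
        rng = np.random.default_rng(11)
        true = 1.26
        covered = 0
        reps = 200
        for i in range(reps):
            a = rng.lognormal(np.log(9.94), 0.3, 60)
            b = rng.lognormal(np.log(7.91), 0.3, 60)
            est = ratio_of_means_log(a, b, n_boot=200, seed=i)
            covered += est.ci_low <= true <= est.ci_high
        assert 0.90 <= covered / reps <= 0.98


def _attempts_frame(force, strategy, success, sex=None):
    df = pd.DataFrame(
        {
            "prehunt_perch_force_N": force,
            "strategy": strategy,
            "success": success,
        }
    )
    if sex is not None:
        df["sex"] = sex
    return df


class TestSuccessModel:
    def test_single_class_raises_separation_error(self):
        df = _attempts_frame(
            np.linspace(5, 12, 40), ["sit_and_wait"] * 40, [True] * 40
        )
        with pytest.raises(SeparationError):
            o.fit_success_glm(df)

    def test_perfectly_separated_predictor_raises(self):
        force = np.concatenate([np.full(20, 5.0), np.full(20, 12.0)])
        success = [False] * 20 + [True] * 20
        df = _attempts_frame(force, ["sit_and_wait"] * 40, success)
        with pytest.raises(SeparationError):
            o.fit_success_glm(df)

    def test_two_by_two_table_odds_ratio_recovered(self):
        """Balanced 2x2 design with true strategy OR = 2.0."""
        rng = np.random.default_rng(5)
        n = 400
        strategy = np.array(["on_the_wing", "sit_and_wait"] * (n // 2))
        p = np.where(strategy == "sit_and_wait", 0.5, 1.0 / 3.0)  # odds 1.0 vs 0.5
        success = rng.random(n) < p
        force = rng.normal(9.0, 1.0, n)  # irrelevant covariate
        res = o.fit_success_glm(_attempts_frame(force, strategy, success))
        ors = res.odds_ratios()
        assert ors.loc["sit_and_wait", "ci_low"] <= 2.0 <= ors.loc["sit_and_wait", "ci_high"]

    def test_matches_direct_likelihood_optimiser(self):
        """IRLS equals brute-force likelihood maximisation on 30 rows."""
        rng = np.random.default_rng(3)
        n = 30
        strategy = rng.choice(["sit_and_wait", "on_the_wing"], n)
        force = rng.normal(9, 1.5, n)
        logits = -0.5 - 0.4 * (force - 9) * (strategy == "sit_and_wait")
        success = rng.random(n) < 1 / (1 + np.exp(-logits))
        if success.all() or not success.any():  # ensure two classes
            success[0] = not success[0]
        model = HuntingSuccessModel(_attempts_frame(force, strategy, success))
        res = model.fit()

        def nll(beta):
            eta = model.X @ beta
            return np.sum(np.log1p(np.exp(eta)) - model.y * eta)

        opt = minimize(nll, np.zeros(model.X.shape[1]), method="BFGS", tol=1e-12)
        assert np.allclose(res.params.values, opt.x, atol=1e-3)

    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 200
        strategy = rng.choice(["sit_and_wait", "on_the_wing"], n)
        force = rng.normal(9, 1.5, n)
        success = rng.random(n) < 0.3
        if success.all() or not success.any():
            success[0] = not success[0]
        model = HuntingSuccessModel(_attempts_frame(force, strategy, success))
        res = model.fit()
        ref = sm.Logit(model.y, model.X).fit(disp=0)
        assert np.allclose(res.params.values, ref.params, atol=1e-6)
        assert np.allclose(res.bse.values, ref.bse, atol=1e-5)

    def test_recovers_generating_or_per_newton(self):
        """Attempts generated at OR 0.85 per newton recover it across seeds."""
        cfg = o.SyntheticNightConfig(seed=0)
        covered = 0
        for seed in range(5):
            meta = o.OwlMetadata(f"m{seed}", "M", 0.281)
            att = o.simulate_attempts(8000, cfg, meta, np.random.default_rng(seed))
            att = att[att["prehunt_gap"] < 90.0]
            res = o.fit_success_glm(att)
            orn, lo, hi = res.or_per_newton("sit_and_wait")
            covered += lo <= 0.85 <= hi
        assert covered >= 4

    def test_summary_mentions_per_newton_or(self):
        cfg = o.SyntheticNightConfig(seed=0)
        att = o.simulate_attempts(
            5000, cfg, o.OwlMetadata("f", "F", 0.322), np.random.default_rng(1)
        )
        text = o.fit_success_glm(att).summary()
        assert "per +1 N" in text and "force_z:sit_and_wait" in text


class TestForceTrend:
    def test_flat_input_has_no_significant_decline(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 3600, 400)
        y = np.exp(np.log(9.0) + rng.normal(0, 0.2, 400))
        res = ForceTrendModel(x, y, "pole").fit(n_boot=100, seed=2)
        assert not res.significant_decline_mask.any()

    def test_decline_before_hunt_flagged_in_final_segment(self):
        """Force declining over the last 30 min pre-hunt: the mask is true
        near the hunt and false far from it."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3600, 600)
        mu = np.log(9.0) + 0.3 * np.minimum(x, 1800.0) / 1800.0
        y = np.exp(mu + rng.normal(0, 0.15, 600))
        res = ForceTrendModel(x, y, "pole").fit(n_boot=150, seed=2)
        near = res.grid < 1500.0
        far = res.grid > 2400.0
        assert res.significant_decline_mask[near].mean() > 0.8
        assert res.significant_decline_mask[far].mean() < 0.2

    def test_monotone_input_positive_derivative_on_interior(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 100, 300))
        y = 5.0 + 0.05 * x + rng.normal(0, 0.1, 300)
        res = ForceTrendModel(x, y).fit(n_boot=50, seed=0)
        assert np.all(res.derivative[5:-5] > 0)

    def test_band_brackets_fit(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, 200)
        y = np.exp(np.log(8) + rng.normal(0, 0.2, 200))
        res = ForceTrendModel(x, y).fit(n_boot=80, seed=1)
        assert np.all(res.band_low <= res.fitted)
        assert np.all(res.fitted <= res.band_high)

    def test_too_few_events_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            res = ForceTrendModel(np.arange(10.0), np.full(10, 9.0), "tree").fit()
        assert res is None

    def test_grouped_interface(self, processed_f):
        perches = processed_f.landings[
            (processed_f.landings["subtype"] == "perch")
            & np.isfinite(processed_f.landings["time_to_next_hunt"])
        ]
        out = o.trend_with_derivative(perches, n_boot=30, seed=0)
        assert isinstance(out, dict)


class TestDescriptiveTables:
    def _single_row_landings(self):
        return pd.DataFrame(
            {
                "owl_id": ["f", "m"],
                "sex": ["F", "M"],
                "subtype": ["perch", "perch"],
                "force_N": [9.94, 7.91],
                "force_per_kg": [9.94 / 0.322, 7.91 / 0.281],
                "bw_multiple": [9.94 / (0.322 * 9.81), 7.91 / (0.281 * 9.81)],
                "loaded_with_prey": [False, False],
            }
        )

    def test_printed_perch_means_give_ratio_126(self):
        table = descriptive_tables(landings=self._single_row_landings(), n_boot=10, seed=0)
        row = table[(table["metric"] == "perch_force_N") & (table["group"] == "F/M")]
        assert row["value"].iloc[0] == pytest.approx(1.26, abs=0.005)

    def test_printed_speed_means_give_gap_023(self):
        attempts = pd.DataFrame(
            {
                "sex": ["F", "M"],
                "strategy": ["on_the_wing", "on_the_wing"],
                "success": [True, False],
                "flight_speed": [5.47, 5.24],
            }
        )
        table = descriptive_tables(attempts=attempts, n_boot=10, seed=0)
        gap = table[(table["metric"] == "flight_speed") & (table["group"] == "F-M")]
        assert gap["value"].iloc[0] == pytest.approx(0.23, abs=1e-9)

    def test_single_owl_rows_report_n(self):
        table = descriptive_tables(landings=self._single_row_landings(), n_boot=10, seed=0)
        f_row = table[(table["metric"] == "perch_force_N") & (table["group"] == "F")]
        assert int(f_row["n"].iloc[0]) == 1

    def test_pipeline_output_table_is_tidy(self, processed_f):
        table = descriptive_tables(
            processed_f.landings, processed_f.attempts, processed_f.trips,
            n_boot=50, seed=0,
        )
        assert set(table.columns) == {"metric", "group", "value", "ci_low", "ci_high", "n"}
        assert len(table) > 4
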