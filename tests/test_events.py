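"""Analysis units: forces, strategies, outcomes, context, trips."""

import numpy as np
import pandas as pd
import pytest

import owlstrike as o
from owlstrike.config import EventConfig
from owlstrike.containers import GpsTrack
from owlstrike.events import (
    bodyweight_multiple,
    categorize_strategy,
    compute_landing_force,
    flag_loaded_with_prey,
    flight_speed_before_strike,
    infer_outcomes,
    prehunt_context,
    segment_trips,
    time_to_next_hunt,
)


class TestLandingForce:
    def test_unit_case(self):
        assert compute_landing_force(1.0, 1.0) == pytest.approx(9.81)

    def test_female_strike_worked_example(self):
        # peak that reproduces the mean female strike force at 322 g body mass
        assert compute_landing_force(12.92, 0.322) == pytest.approx(40.8, abs=0.05)

    def test_zero_peak_zero_force(self):
        assert compute_landing_force(0.0, 0.5) == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_landing_force(1.0, 0.0)

    @pytest.mark.parametrize("peak,mass", [(2.0, 0.3), (13.0, 0.28), (0.5, 1.2)])
    def test_linear_in_both_arguments(self, peak, mass):
        f = compute_landing_force(peak, mass)
        assert compute_landing_force(2 * peak, mass) == pytest.approx(2 * f)
        assert compute_landing_force(peak, 2 * mass) == pytest.approx(2 * f)


class TestBodyweightMultiple:
    def test_female_strike_near_thirteen(self):
        assert bodyweight_multiple(40.8, 0.322) == pytest.approx(12.9, abs=0.05)

    def test_unit_force(self):
        assert bodyweight_multiple(9.81, 1.0) == pytest.approx(1.0)

    def test_male_perch_near_three(self):
        assert bodyweight_multiple(7.91, 0.281) == pytest.approx(2.87, abs=0.01)

    def test_inverse_of_force(self):
        assert bodyweight_multiple(compute_landing_force(5.5, 0.3), 0.3) == pytest.approx(5.5)


class TestStrategy:
    @pytest.mark.parametrize(
        "dur,expected",
        [
            (0.0, "sit_and_wait"),
            (1.0, "sit_and_wait"),  # "a maximum of 1 s" is inclusive
            (3.0, "excluded"),
            (4.9, "excluded"),
            (5.0, "on_the_wing"),  # "at least 5 s" is inclusive
            (30.0, "on_the_wing"),
        ],
    )
    def test_boundaries(self, dur, expected):
        assert categorize_strategy(dur) == expected

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            categorize_strategy(-1.0)

    def test_categories_partition_attempts(self, processed_f):
        assert set(processed_f.attempts["strategy"]) <= {
            "sit_and_wait", "on_the_wing", "excluded"
        }


def _stream(rows):
    return pd.DataFrame(rows, columns=["t", "kind", "x", "y"])


class TestOutcomeInference:
    def test_feeding_soon_after_is_success(self):
        ev = _stream([(10, "strike", 100, 0), (50, "feeding", np.nan, np.nan)])
        out = infer_outcomes(ev, (0, 0))
        assert out["success"].iloc[0]

    def test_back_to_back_strikes_is_failure(self):
        ev = _stream([(10, "strike", 100, 0), (60, "strike", 120, 0)])
        out = infer_outcomes(ev, (0, 0))
        assert not out["success"].iloc[0]

    def test_perch_away_from_nest_breaks_the_chain(self):
        ev = _stream(
            [(10, "strike", 100, 0), (40, "perch", 150, 0), (90, "feeding", np.nan, np.nan)]
        )
        out = infer_outcomes(ev, (0, 0))
        assert not out["success"].iloc[0]

    def test_nest_arrival_perch_does_not_break_direct_return(self):
        ev = _stream(
            [(10, "strike", 100, 0), (40, "perch", 1.0, 1.0), (45, "nest_enter", np.nan, np.nan)]
        )
        out = infer_outcomes(ev, (0, 0))
        assert out["success"].iloc[0]

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Independent re-scan oracle over small random event streams."""

        def oracle(ev, nest, radius=30.0):
            ev = ev.sort_values("t").reset_index(drop=True)
            res = {}
            for i in range(len(ev)):
                if ev.loc[i, "kind"] != "strike":
                    continue
                verdict = False
                for j in range(i + 1, len(ev)):
                    k = ev.loc[j, "kind"]
                    if k in ("feeding", "nest_enter"):
                        verdict = True
                        break
                    if k == "strike":
                        break
                    d = np.hypot(ev.loc[j, "x"] - nest[0], ev.loc[j, "y"] - nest[1])
                    if k == "perch" and not (np.isfinite(d) and d <= radius):
                        break
                res[float(ev.loc[i, "t"])] = verdict
            return res

        rng = np.random.default_rng(42)
        kinds = np.array(["strike", "perch", "feeding", "nest_enter"])
        for _ in range(25):
            n = int(rng.integers(3, 30))
            ev = _stream(
                [
                    (
                        float(t),
                        rng.choice(kinds, p=[0.4, 0.4, 0.1, 0.1]),
                        float(rng.choice([0.0, 200.0])),
                        0.0,
                    )
                    for t in np.sort(rng.uniform(0, 1000, n))
                ]
            )
            got = infer_outcomes(ev, (0, 0))
            want = oracle(ev, (0, 0))
            assert {r.t: r.success for r in got.itertuples()} == want

    def test_synthetic_outcomes_recovered(self, night_f, night_m, processed_f, processed_m):
        agree = tot = 0
        for night, res in ((night_f, processed_f), (night_m, processed_m)):
            truth = night.landings[night.landings["label"] == "landing_strike"].set_index("t")
            det = res.attempts.set_index("t")
            common = truth.index.intersection(det.index)
            agree += ((truth.loc[common, "outcome"] == "success")
                      == det.loc[common, "success"]).sum()
            tot += len(common)
        assert tot > 10
        assert agree / tot >= 0.9


class TestPrehuntContext:
    def _perches(self):
        return pd.DataFrame({"t": [100.0, 400.0], "force_N": [9.0, 8.0]})

    def test_recent_perch_attached(self):
        force, gap = prehunt_context(150.0, self._perches())
        assert force == 9.0 and gap == 50.0

    def test_gap_beyond_ninety_seconds_nulls_force(self):
        force, gap = prehunt_context(520.0, self._perches())
        assert force is None and gap == 120.0

    def test_no_prior_perch(self):
        force, gap = prehunt_context(50.0, self._perches())
        assert force is None and gap is None


class TestFlightSpeed:
    def _track(self, speeds):
        x = np.concatenate([[0.0], np.cumsum(speeds)])
        return GpsTrack(t=np.arange(len(x), dtype=float), x=x, y=np.zeros(len(x)))

    def test_uniform_speed(self):
        track = self._track([5.0] * 30)
        assert flight_speed_before_strike(track, 30.0) == pytest.approx(5.0)

    def test_median_robust_to_single_outlier_fix(self):
        speeds = [5.0] * 30
        speeds[20] = 80.0  # one bad fix
        track = self._track(speeds)
        assert flight_speed_before_strike(track, 30.0) == pytest.approx(5.0, abs=0.01)

    def test_too_few_fixes_is_null(self):
        track = GpsTrack(t=np.array([0.0]), x=np.array([0.0]), y=np.array([0.0]))
        assert flight_speed_before_strike(track, 0.5) is None


class TestTimeToNextHunt:
    def test_simple_gap(self):
        out = time_to_next_hunt(np.array([0.0]), np.array([600.0]))
        assert out[0] == 600.0

    def test_perch_after_last_strike_is_null(self):
        out = time_to_next_hunt(np.array([700.0]), np.array([600.0]))
        assert np.isnan(out[0])

    def test_successive_perches_decrease(self):
        out = time_to_next_hunt(np.array([0.0, 100.0, 200.0]), np.array([300.0]))
        assert np.all(np.diff(out) < 0)


class TestLoadedFlag:
    def test_perch_between_success_and_return_flagged(self):
        landings = pd.DataFrame(
            {"t": [10.0, 50.0], "subtype": ["strike", "perch"]}
        )
        outcomes = pd.DataFrame({"t": [10.0], "success": [True], "confirm_t": [80.0]})
        flags = flag_loaded_with_prey(landings, outcomes)
        assert list(flags) == [False, True]

    def test_perch_after_failed_strike_not_flagged(self):
        landings = pd.DataFrame({"t": [10.0, 50.0], "subtype": ["strike", "perch"]})
        outcomes = pd.DataFrame({"t": [10.0], "success": [False], "confirm_t": [np.nan]})
        assert not flag_loaded_with_prey(landings, outcomes).any()

    def test_loaded_events_excluded_from_summary_forces(self, processed_f):
        table = o.descriptive_tables(processed_f.landings, n_boot=50, seed=0)
        loaded = processed_f.landings[processed_f.landings["loaded_with_prey"]]
        if len(loaded):
            perch_n = table[(table["metric"] == "perch_force_N") & (table["group"] == "F")]
            n_all = (processed_f.landings["subtype"] == "perch").sum()
            assert int(perch_n["n"].iloc[0]) == n_all - len(loaded)


class TestTrips:
    def test_scheduled_trips_recovered(self, night_f, processed_f):
        assert len(processed_f.trips) == night_f.config.n_trips

    def test_stationary_night_has_no_trips(self):
        track = GpsTrack(
            t=np.arange(100, dtype=float),
            x=np.random.default_rng(0).normal(0, 1, 100),
            y=np.random.default_rng(1).normal(0, 1, 100),
        )
        assert len(segment_trips(track, (0.0, 0.0))) == 0

    def test_durations_sum_below_night_duration(self, night_f, processed_f):
        total_min = processed_f.trips["duration_min"].sum()
        assert total_min * 60 <= night_f.trace.duration

    def test_sw_frequency_matches_truth_when_detection_perfect(self, night_f, processed_f):
        truth = night_f.landings[night_f.landings["label"] == "landing_strike"]
        truth_counted = truth[truth["strategy"] != "excluded"]
        want = (truth_counted["strategy"] == "sit_and_wait").mean()
        att = processed_f.attempts[processed_f.attempts["strategy"] != "excluded"]
        got = (att["strategy"] == "sit_and_wait").mean()
        assert got == pytest.approx(want, abs=0.02)
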