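"""Kaplan-Meier and Aalen-Johansen estimators against hand-computed oracles."""

import numpy as np
import pytest

import lifetimerisk as lr
from lifetimerisk.estimators import StepSurvival


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        s = lr.km_fit([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(s.values, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # S(1) = 2/3; censor at 2; S(3) = 2/3 * (1 - 1/1) = 0
        s = lr.km_fit([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(s.times, [1.0, 3.0])
        np.testing.assert_allclose(s.values, [2 / 3, 0.0])

    def test_all_censored_is_flat_one(self, caplog):
        s = lr.km_fit([1, 2, 3], [0, 0, 0])
        assert len(s.times) == 0
        assert s.eval_at(10.0)["value"].iloc[0] == 1.0

    def test_ties_grouped(self):
        s = lr.km_fit([2, 2, 2, 5], [1, 1, 0, 1])
        # at t=2: 2 deaths among 4 at risk -> 1/2; at 5: 1 death of 1 -> 0
        np.testing.assert_allclose(s.values, [0.5, 0.0])
        assert list(s.n_event) == [2, 1]
        assert list(s.n_risk) == [4, 1]

    def test_no_censoring_matches_empirical_randomised(self, rng):
        t = rng.exponential(5.0, 200)
        s = lr.km_fit(t, np.ones(200, dtype=int))
        grid = np.array([1.0, 3.0, 8.0])
        emp = [(t > g).mean() for g in grid]
        np.testing.assert_allclose(s.eval_at(grid)["value"], emp, atol=1e-12)

    def test_ci_bounds_bracket_estimate(self, rng):
        t = rng.exponential(5.0, 300)
        e = rng.integers(0, 2, 300)
        s = lr.km_fit(t, e)
        assert np.all(s.lo <= s.values + 1e-12)
        assert np.all(s.values <= s.hi + 1e-12)
        assert np.all((s.lo >= 0) & (s.hi <= 1))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lr.km_fit([], [])
        with pytest.raises(ValueError):
            lr.km_fit([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError):
            lr.km_fit([1.0], [2])


class TestCodeEvents:
    @pytest.mark.parametrize("status,metric,expect", [
        ("dead_other", "MFS", 0),   # other-cause deaths censored under MFS
        ("dead_other", "OS", 1),
        ("dead_cancer", "MFS", 1),
        ("dead_cancer", "OS", 1),
        ("alive", "MFS", 0),
        ("alive", "OS", 0),
    ])
    def test_event_coding(self, status, metric, expect):
        co = lr.Cohort.from_records([dict(
            id="a", sex="male", age_dx=60.0, year_dx=2000.0, futime=5.0,
            status=status, morph=8720, site="C69.3")])
        durations, events = lr.code_events(co, metric)
        assert durations[0] == 5.0
        assert events[0] == expect


class TestAalenJohansen:
    def test_two_case_hand_oracle(self):
        c1, c2 = lr.cif_fit([1, 2], [1, 2])
        np.testing.assert_allclose(c1.values, [0.5, 0.5])
        np.testing.assert_allclose(c2.values, [0.0, 0.5])

    def test_four_case_hand_oracle(self):
        # times {1,2,3,4}, causes {1, censored, 2, 1}
        c1, c2 = lr.cif_fit([1, 2, 3, 4], [1, 0, 2, 1])
        np.testing.assert_allclose(c1.times, [1.0, 3.0, 4.0])
        np.testing.assert_allclose(c1.values, [1 / 4, 1 / 4, 5 / 8])
        np.testing.assert_allclose(c2.values, [0.0, 3 / 8, 3 / 8])

    def test_single_cause_collapses_to_km_complement(self, rng):
        t = rng.exponential(3.0, 100)
        c1, c2 = lr.cif_fit(t, np.ones(100, dtype=int))
        np.testing.assert_allclose(c1.values[-1], 1.0, atol=1e-12)
        km = lr.km_fit(t, np.ones(100, dtype=int))
        np.testing.assert_allclose(c1.values, 1.0 - km.values, atol=1e-12)

    def test_conservation_identity_machine_precision(self, rng):
        t = np.round(rng.exponential(5.0, 400), 1) + 0.1  # heavy ties
        c = rng.integers(0, 3, 400)
        c1, c2 = lr.cif_fit(t, c)
        km = lr.km_fit(t, (c > 0).astype(int))
        np.testing.assert_allclose(c1.values + c2.values + km.values, 1.0, atol=1e-12)

    def test_matches_lifelines_on_tie_free_input(self, rng):
        from lifelines import AalenJohansenFitter
        t = rng.exponential(5.0, 60)  # continuous: no ties, no jitter applied
        c = rng.integers(0, 3, 60)
        if not ((c == 1).any() and (c == 2).any()):  # pragma: no cover
            pytest.skip("degenerate draw")
        ours, _ = lr.cif_fit(t, c)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, c, event_of_interest=1)
        theirs = ajf.cumulative_density_.iloc[:, 0]
        for tt, v in zip(ours.times, ours.values):
            np.testing.assert_allclose(theirs.loc[:tt].iloc[-1], v, atol=1e-10)

    def test_missing_cause_curve_is_zero(self, caplog):
        c1, c2 = lr.cif_fit([1, 2], [2, 2])
        assert np.all(c1.values == 0.0)
        assert c2.values[-1] == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lr.cif_fit([1, 2], [0, 0])
        with pytest.raises(ValueError):
            lr.cif_fit([1], [3])


class TestEvalAt:
    def _curve(self):
        return StepSurvival([2.0], [0.5], [0.4], [0.6], [10], [5], kind="survival")

    def test_right_continuity_at_step(self):
        assert self._curve().eval_at(2.0)["value"].iloc[0] == 0.5

    def test_before_first_event_is_baseline(self):
        out = self._curve().eval_at([0.0, 1.99])
        assert list(out["value"]) == [1.0, 1.0]

    def test_extrapolation_flagged(self):
        out = self._curve().eval_at([1.0, 2.0, 50.0])
        assert list(out["extrapolated"]) == [False, False, True]
        assert out["value"].iloc[2] == 0.5

    def test_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            self._curve().eval_at(-1.0)


class TestOnSyntheticCohort:
    def test_mfs_at_least_os_pointwise(self, study_cohort):
        os_c = lr.km_fit(*lr.code_events(study_cohort, "OS"))
        mfs_c = lr.km_fit(*lr.code_events(study_cohort, "MFS"))
        grid = np.arange(1.0, 36.0)
        assert np.all(mfs_c.eval_at(grid)["value"].to_numpy()
                      >= os_c.eval_at(grid)["value"].to_numpy() - 1e-12)

    def test_one_minus_mfs_converges_to_net_risk(self, study_cohort, study_trigam):
        """KM with other-cause deaths censored estimates exp(-cumulative excess
        hazard): the net survival implied by the injected trigam wave."""
        mfs_c = lr.km_fit(*lr.code_events(study_cohort, "MFS"))
        at35 = mfs_c.eval_at(35.0).iloc[0]
        theory = np.exp(-study_trigam.cum_hazard(35.0))
        se = (at35["hi"] - at35["lo"]) / (2 * 1.96)
        assert abs(at35["value"] - theory) < 3 * se
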