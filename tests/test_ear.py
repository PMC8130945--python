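"""Person-year tabulation, excess absolute risk, and the trigam fit."""

import numpy as np
import pandas as pd
import pytest

import lifetimerisk as lr
from lifetimerisk.ear import EarTable, _garwood, default_breaks


def _flat_table(rate, years=(1990, 2020)):
    n_age, n_year = 111, years[1] - years[0] + 1
    return lr.LifeTable(0, 110, years[0], years[1], np.full((2, n_age, n_year), rate))


def _cohort(rows):
    recs = []
    for i, r in enumerate(rows):
        d = dict(id=f"c{i}", sex="male", age_dx=60.0, year_dx=2000.0,
                 futime=1.0, status="alive", morph=8720, site="C69.3")
        d.update(r)
        recs.append(d)
    return lr.Cohort.from_records(recs)


class TestDefaultBreaks:
    def test_widths_nondecreasing_first_bin_half_year(self):
        b = default_breaks()
        widths = np.diff(b)
        assert b[0] == 0.0 and b[1] == 0.5
        assert np.all(np.diff(widths) >= -1e-12)
        assert b[-1] == 42.0

    def test_custom_breaks_echoed(self):
        co = _cohort([{"futime": 1.5}])
        ear = lr.tabulate_ear(co, _flat_table(0.01), breaks=[0.0, 1.0, 2.0])
        np.testing.assert_allclose(ear.breaks, [0.0, 1.0, 2.0])
        assert len(ear.df) == 2


class TestTabulate:
    def test_single_cell_integration(self):
        # one person, m = 0.02 constant, followed one year alive
        co = _cohort([{"age_dx": 60.0, "year_dx": 2000.0, "futime": 1.0}])
        ear = lr.tabulate_ear(co, _flat_table(0.02), breaks=[0.0, 1.0])
        row = ear.df.iloc[0]
        assert row["PY"] == pytest.approx(1.0)
        assert row["E"] == pytest.approx(0.02)
        assert row["O"] == 0
        assert row["EAR"] == pytest.approx(-0.02)

    def test_birthday_lexis_split(self):
        # rate 0.02 below age 61, 0.04 from 61 on; half a year in each
        table = _flat_table(0.02)
        table.rates[:, 61:, :] = 0.04
        co = _cohort([{"age_dx": 60.5, "year_dx": 2000.0, "futime": 1.0}])
        ear = lr.tabulate_ear(co, table, breaks=[0.0, 1.0])
        assert ear.df.iloc[0]["E"] == pytest.approx(0.03)

    def test_death_counted_in_containing_interval(self):
        co = _cohort([{"futime": 2.5, "status": "dead_other"}])
        ear = lr.tabulate_ear(co, _flat_table(0.01), breaks=[0.0, 2.0, 4.0])
        np.testing.assert_array_equal(ear.df["O"], [0, 1])

    def test_followup_beyond_last_break_names_case(self):
        co = _cohort([{"id": "offender", "futime": 3.0}])
        with pytest.raises(ValueError, match="offender"):
            lr.tabulate_ear(co, _flat_table(0.01), breaks=[0.0, 1.0, 2.0])

    def test_py_and_deaths_conserved(self, study_cohort, gm_table):
        ear = lr.tabulate_ear(study_cohort, gm_table)
        assert ear.total_py == pytest.approx(study_cohort.df["futime"].sum(), rel=1e-12)
        assert ear.total_deaths == int((study_cohort.df["status"] != "alive").sum())

    def test_expected_deaths_match_daily_grid_oracle(self, small_cohort, gm_table):
        """E from exact Lexis splitting vs midpoint integration on a daily grid
        (each day sampled at eighth-day resolution to resolve cell boundaries)."""
        breaks = default_breaks()
        ear = lr.tabulate_ear(small_cohort, gm_table, breaks)
        e_oracle = np.zeros(len(breaks) - 1)
        step = 1.0 / 365.0 / 8.0
        for _, case in small_cohort.df.iterrows():
            grid = np.arange(0.0, case["futime"], step)
            mids = grid + np.minimum(step, case["futime"] - grid) / 2.0
            durs = np.minimum(step, case["futime"] - grid)
            m = gm_table.get_rate(case["sex"], case["age_dx"] + mids, case["year_dx"] + mids)
            bins = np.clip(np.searchsorted(breaks, grid, side="right") - 1, 0, len(breaks) - 2)
            np.add.at(e_oracle, bins, m * durs)
        mask = e_oracle > 0
        np.testing.assert_allclose(ear.df["E"].to_numpy()[mask], e_oracle[mask], rtol=1e-4)

    def test_garwood_zero_count_lower_bound(self):
        lo, hi = _garwood(np.array([0, 3]))
        assert lo[0] == 0.0
        assert lo[1] < 3 < hi[1]

    def test_all_cause_counting_ignores_cod_labels(self, misreported_cohorts, gm_table):
        a = lr.tabulate_ear(misreported_cohorts[0.0], gm_table)
        b = lr.tabulate_ear(misreported_cohorts[0.3], gm_table)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestTrigamFit:
    def _dense_table(self, params, py=5000.0, e_per_bin=5.0, width=0.5, tmax=40.0):
        edges = np.arange(0.0, tmax + 1e-9, width)
        mid = edges[:-1] + width / 2
        lam = e_per_bin + params.hazard(mid) * py
        df = pd.DataFrame({
            "t_lo": edges[:-1], "t_hi": edges[1:], "t_mid": mid,
            "PY": py, "O": np.round(lam).astype(int), "E": e_per_bin,
        })
        return EarTable(df, edges)

    def test_self_consistency_recovers_auc(self, study_trigam):
        ear = self._dense_table(study_trigam)
        fit = lr.fit_trigam(ear, seed=0)
        assert fit.converged
        assert fit.auc == pytest.approx(study_trigam.auc, rel=0.02)

    def test_null_counts_give_near_zero_auc(self):
        null = lr.TrigamParams(A=0.0, H=0.0)
        ear = self._dense_table(null, e_per_bin=7.0)
        fit = lr.fit_trigam(ear, seed=0)
        assert fit.auc <= 0.01

    def test_fix_triangle_drops_triangle(self, study_trigam):
        ear = self._dense_table(study_trigam)
        fit = lr.fit_trigam(ear, fix_triangle=True, seed=0)
        assert fit.params.H == 0.0
        # gamma wave alone still captures most of the excess mass
        assert fit.auc == pytest.approx(study_trigam.auc, rel=0.1)

    def test_too_few_intervals_rejected(self, study_trigam):
        ear = self._dense_table(study_trigam, width=10.0)
        with pytest.raises(ValueError, match="6 intervals"):
            lr.fit_trigam(ear)

    def test_report_is_flat_key_value_text(self, study_trigam):
        fit = lr.fit_trigam(self._dense_table(study_trigam), seed=0)
        lines = fit.report().splitlines()
        assert all(len(line.split()) == 2 for line in lines)
        keys = {line.split()[0] for line in lines}
        assert {"A", "k", "theta", "H", "p_c", "w", "AUC", "loglik"} <= keys


class TestAucConversion:
    def test_headline_conversion(self):
        assert lr.survival_from_auc(0.555) == pytest.approx(0.57, abs=5e-3)
        assert lr.lifetime_risk_from_auc(0.555) == pytest.approx(0.43, abs=5e-3)

    @pytest.mark.parametrize("auc,risk", [(0.0, 0.0), (np.log(2.0), 0.5)])
    def test_analytic_points(self, auc, risk):
        assert lr.lifetime_risk_from_auc(auc) == pytest.approx(risk, abs=1e-12)

    def test_negative_auc_rejected(self):
        with pytest.raises(ValueError):
            lr.lifetime_risk_from_auc(-0.1)
        with pytest.raises(ValueError):
            lr.survival_from_auc(-0.1)
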