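import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from grazerates.errors import ConfigurationError, UndefinedRateError
from grazerates.rates import (
    FLAG_NEGATIVE_CLEARANCE,
    FLAG_OUTSIDE_WINDOW,
    clearance_rate,
    detect_decline_window,
    exponential_growth_rate,
    grazing_table,
    ingestion_rate,
    linear_growth_rate,
    log_mean_concentration,
    summarize_rates,
)
from grazerates.synthetic_data import SimParams, simulate_grazing
from grazerates.timeseries_io import Experiment
from oracles import brute_force_decline_window

conc = st.floats(min_value=1e-3, max_value=1e9, allow_nan=False)


class TestExponentialGrowthRate:
    def test_closed_form_ln_e(self):
        s = make_series([0, 5], [100, 271.828], flask_id="c")
        assert exponential_growth_rate(s).value == pytest.approx(0.2, rel=1e-4)

    def test_constant_series_rate_zero(self):
        s = make_series([0, 2, 4], [500, 500, 500])
        assert exponential_growth_rate(s).value == 0.0

    def test_hundredfold_rise_over_20_days(self):
        s = make_series([0, 20], [1000, 1000], [200, 20000], flask_id="g")
        est = exponential_growth_rate(s, which="predator")
        assert est.value == pytest.approx(math.log(100) / 20, rel=1e-12)

    def test_zero_endpoint_is_undefined(self):
        s = make_series([0, 2], [1000, 0])
        with pytest.raises(UndefinedRateError):
            exponential_growth_rate(s)

    def test_window_selects_endpoints(self):
        s = make_series([0, 2, 4, 6], [1000, 2000, 4000, 8000])
        est = exponential_growth_rate(s, window=(2, 6))
        assert est.value == pytest.approx(math.log(2) / 2)
        assert est.window == (2.0, 6.0)


class TestLinearGrowthRate:
    def test_exact_geometric_series(self):
        s = make_series([0, 1, 2, 3], [1000, 1100, 1210, 1331])
        est = linear_growth_rate(s)
        assert est.value == pytest.approx(0.1, rel=1e-9)
        assert est.fit_r2 == pytest.approx(1.0)

    def test_constant_series(self):
        s = make_series([0, 2, 4], [500, 500, 500])
        assert linear_growth_rate(s).value == pytest.approx(0.0, abs=1e-12)

    def test_two_points_match_endpoint_estimator_transform(self):
        s = make_series([0, 4], [1000, 3000])
        mu_lin = linear_growth_rate(s).value
        mu_exp = exponential_growth_rate(s).value
        assert mu_lin == pytest.approx(math.exp(mu_exp) - 1, rel=1e-12)

    def test_zero_counts_excluded_from_fit(self):
        # zero at day 2 must be dropped, leaving the exact geometric fit
        s = make_series([0, 2, 4, 6], [1000, 0, 1210, 1331])
        kept = make_series([0, 4, 6], [1000, 1210, 1331])
        assert linear_growth_rate(s).value == pytest.approx(
            linear_growth_rate(kept).value, rel=1e-12
        )

    def test_insufficient_positive_points(self):
        s = make_series([0, 2, 4], [1000, 0, 0])
        with pytest.raises(UndefinedRateError):
            linear_growth_rate(s)


class TestLogMean:
    def test_equal_endpoints(self):
        assert log_mean_concentration(500.0, 500.0) == 500.0

    def test_hand_value(self):
        assert log_mean_concentration(1000.0, 100.0) == pytest.approx(
            900 / math.log(10), rel=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(UndefinedRateError):
            log_mean_concentration(0.0, 100.0)

    @settings(deadline=None)
    @given(b0=conc, b1=conc)
    def test_bounded_by_endpoints(self, b0, b1):
        m = log_mean_concentration(b0, b1)
        assert min(b0, b1) * (1 - 1e-9) <= m <= max(b0, b1) * (1 + 1e-9)

    @settings(deadline=None)
    @given(b0=conc, eps=st.floats(-1e-10, 1e-10))
    def test_continuity_at_equal_endpoints(self, b0, eps):
        assert log_mean_concentration(b0, b0 * (1 + eps)) == pytest.approx(
            b0, rel=1e-9
        )


class TestClearanceIngestion:
    def test_k_equals_g_gives_zero(self):
        assert clearance_rate(0.074, 0.074, 2000.0) == 0.0

    def test_hand_value(self):
        assert clearance_rate(0.074, -0.126, 2000.0) == pytest.approx(1.0e-4)

    def test_negative_unclamped(self):
        assert clearance_rate(0.05, 0.10, 100.0) < 0

    def test_nonpositive_predator_rejected(self):
        with pytest.raises(UndefinedRateError):
            clearance_rate(0.1, 0.0, 0.0)

    def test_ingestion_is_product(self):
        assert ingestion_rate(390.865, 1.0e-4) == pytest.approx(0.0390865)
        assert ingestion_rate(1234.5, 0.0) == 0.0


class TestDeclineWindow:
    def test_clean_monotone_decline(self):
        s = make_series([0, 2, 4, 6, 8], [1000, 800, 400, 150, 40])
        assert detect_decline_window(s) == (0.0, 8.0)

    def test_monotone_increase_gives_none(self):
        s = make_series([0, 2, 4, 6], [100, 200, 400, 800])
        assert detect_decline_window(s) is None

    def test_rise_then_decline(self):
        days = list(range(0, 21, 2))
        prey = [1000, 1500, 2100, 1700, 1200, 800, 500, 300, 170, 90, 40]
        s = make_series(days, prey)
        win = detect_decline_window(s)
        assert win == (4.0, 20.0)
        assert win == brute_force_decline_window(days, prey)

    def test_matches_brute_force_on_noisy_series(self):
        rng = np.random.default_rng(7)
        days = list(range(0, 21, 2))
        for _ in range(20):
            prey = np.abs(rng.lognormal(6, 1.0, size=len(days))) + 1
            s = make_series(days, prey)
            assert detect_decline_window(s) == brute_force_decline_window(
                days, list(prey)
            )

    def test_r2_threshold_configurable(self):
        # strictly decreasing but strongly curved on log scale (R^2 ~ 0.75)
        s = make_series([0, 2, 4], [1000, 999, 10])
        assert detect_decline_window(s, r2_min=0.9) is None
        assert detect_decline_window(s, r2_min=0.5) == (0.0, 4.0)


class TestGrazingTable:
    def test_no_grazing_signal(self):
        ctrl = make_series([0, 2, 4], [1000, 1100, 1210], flask_id="c1")
        gz = make_series([0, 2, 4], [1000, 1100, 1210], [200, 200, 200],
                         flask_id="g1")
        rows = grazing_table(Experiment(series=(ctrl, gz)), "F8")
        assert len(rows) == 2
        for r in rows:
            assert r.F == pytest.approx(0.0, abs=1e-15)
            assert r.I == pytest.approx(0.0, abs=1e-12)

    def test_single_interval_hand_chain(self, toy_pair_experiment):
        (row,) = grazing_table(toy_pair_experiment, "F8")
        F = (math.log(1.16) - math.log(0.7)) / (2 * 200)
        B_avg = -300 / (math.log(700) - math.log(1000))
        assert row.k == pytest.approx(math.log(1.16) / 2, rel=1e-12)
        assert row.g == pytest.approx(math.log(0.7) / 2, rel=1e-12)
        assert row.F == pytest.approx(F, rel=1e-12)
        assert row.B_avg == pytest.approx(B_avg, rel=1e-12)
        assert row.P == pytest.approx(200.0)
        assert row.I == pytest.approx(B_avg * F, rel=1e-12)

    def test_noiseless_constant_predator_recovers_F_exactly(self):
        params = SimParams(k=0.074, F_true=1.0e-4, C0=200.0, mu_c=0.0)
        gz = simulate_grazing(params, flask_id="g1", prey_strain="HL3E12",
                              predator_strain="F8")
        ctrl = simulate_grazing(
            SimParams(k=0.074, C0=0.0), flask_id="c1", prey_strain="HL3E12"
        )
        rows = grazing_table(Experiment(series=(ctrl, gz)), "F8")
        assert len(rows) == 10
        for r in rows:
            assert r.F == pytest.approx(1.0e-4, rel=1e-9)
            assert r.I == pytest.approx(r.B_avg * r.F, rel=1e-12)

    def test_growing_predator_log_mean_P_keeps_F_exact(self):
        params = SimParams(k=0.074, F_true=1.0e-4, C0=200.0, mu_c=0.23)
        gz = simulate_grazing(params, flask_id="g1", prey_strain="HL3E12",
                              predator_strain="F8")
        ctrl = simulate_grazing(
            SimParams(k=0.074, C0=0.0), flask_id="c1", prey_strain="HL3E12"
        )
        rows = grazing_table(Experiment(series=(ctrl, gz)), "F8")
        for r in rows:
            assert r.F == pytest.approx(1.0e-4, rel=1e-9)

    def test_missing_control_is_configuration_error(self):
        ctrl = make_series([0, 2], [1000, 1100], flask_id="c1",
                           prey_strain="SH2A6")
        gz = make_series([0, 2], [1000, 700], [200, 200], flask_id="g1",
                         prey_strain="SH2A6")
        exp = Experiment(series=(ctrl, gz))
        with pytest.raises(ConfigurationError):
            grazing_table(exp, "E8")  # no flasks grazed by E8

    def test_decline_window_mode_flags_growth_phase(self):
        days = list(range(0, 21, 2))
        params = SimParams(k=0.074, F_true=1.0e-4, C0=200.0,
                           mu_c=math.log(100) / 20)
        gz = simulate_grazing(params, days, flask_id="g1",
                              prey_strain="HL3E12", predator_strain="F8")
        ctrl = simulate_grazing(SimParams(k=0.074, C0=0.0), days,
                                flask_id="c1", prey_strain="HL3E12")
        rows = grazing_table(
            Experiment(series=(ctrl, gz)), "F8", mode="decline_window"
        )
        window = detect_decline_window(gz)
        assert window is not None
        flagged = {r.interval for r in rows if FLAG_OUTSIDE_WINDOW in r.flags}
        kept = {r.interval for r in rows if FLAG_OUTSIDE_WINDOW not in r.flags}
        assert kept  # some usable decline intervals exist
        for t0, t1 in kept:
            assert window[0] <= t0 and t1 <= window[1]
        # the early growth phase is excluded
        assert any(t1 <= window[0] for t0, t1 in flagged)
        summary = summarize_rates(rows)
        assert summary["n_intervals"] == len(kept)

    def test_negative_clearance_flagged_and_kept(self):
        ctrl = make_series([0, 2], [1000, 1100], flask_id="c1")
        gz = make_series([0, 2], [1000, 1500], [200, 200], flask_id="g1")
        (row,) = grazing_table(Experiment(series=(ctrl, gz)), "F8")
        assert row.F < 0
        assert FLAG_NEGATIVE_CLEARANCE in row.flags
        # kept in summary by default, excluded on request
        assert summarize_rates([row])["n_intervals"] == 1
        assert summarize_rates([row], include_negative_clearance=False)[
            "n_intervals"
        ] == 0
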