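"""Nitrogen balance integration and biomass partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mesbalance import (
    InputError,
    MESBalanceModel,
    ReactorConfig,
    SimulationParams,
    accumulate_biomass,
    nitrogen_increment,
    simulate,
)
from mesbalance.balance import nitrogen_ledger
from mesbalance.calibration import REFERENCE_CALIBRATION, OdNitrogenCalibration
from mesbalance.config import DEFAULT_FEED_N

IDENTITY_CAL = OdNitrogenCalibration(slope=1.0, intercept=0.0)


def _series(t, c_aq, od):
    return pd.DataFrame({"t_days": t, "c_n_aq_out": c_aq, "od600": od})


class TestNitrogenIncrement:
    def test_balanced_in_and_out_retains_nothing(self, config):
        c_in = config.feed_nitrogen(1.0)
        assert nitrogen_increment(config, c_in, 0.0, dt=2.0, t=2.0) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        cfg = ReactorConfig(c_n_in=0.00748)
        dn = nitrogen_increment(cfg, 0.005, 0.001, dt=3.5, t=3.5)
        assert dn == pytest.approx(7.77e-5, rel=1e-6)

    def test_lysis_regime_gives_negative_increment(self, config):
        c_in = config.feed_nitrogen(100.0)
        assert nitrogen_increment(config, 2 * c_in, 0.0, dt=1.0, t=100.0) < 0

    def test_nonpositive_dt_rejected(self, config):
        with pytest.raises(InputError):
            nitrogen_increment(config, 0.005, 0.0, dt=0.0, t=1.0)

    def test_feed_step_averaged_exactly_inside_interval(self):
        cfg = ReactorConfig(c_n_in=((0.0, 0.004), (10.0, 0.008)))
        # interval [8, 12]: half at 0.004, half at 0.008 -> mean 0.006
        dn = nitrogen_increment(cfg, 0.0, 0.0, dt=4.0, t=12.0)
        assert dn == pytest.approx(cfg.f_in * 0.006 * 4.0, rel=1e-12)


class TestAccumulateBiomass:
    def test_flat_trajectory_without_exchange(self, config):
        c_in = config.feed_nitrogen(0.0)
        series = _series([0.0, 3.5, 7.0, 10.5], [c_in] * 4, [0.0] * 4)
        traj = accumulate_biomass(config, series, REFERENCE_CALIBRATION)
        assert np.allclose(traj["n_x_total"], config.n_x0)
        assert config.n_x0 == pytest.approx(2.19e-3, rel=0.01)
        assert np.allclose(traj["biofilm_fraction"], 1.0)

    def test_stoichiometric_division(self, config):
        # one interval retaining exactly 2 mmol N -> +10 mmol biomass at nu=0.2
        c_in = config.feed_nitrogen(0.0)
        dt = 0.002 / (config.f_in * c_in)
        series = _series([0.0, dt], [c_in, 0.0], [0.0, 0.0])
        traj = accumulate_biomass(config, series, REFERENCE_CALIBRATION)
        gain = traj["n_x_total"].iloc[1] - traj["n_x_total"].iloc[0]
        assert gain == pytest.approx(0.010, rel=1e-12)

    def test_recovers_simulator_truth_within_2pct(self, config, plateau, plateau_05):
        truth, _ = plateau
        traj = accumulate_biomass(
            config, plateau_05, REFERENCE_CALIBRATION, dissolved_holdup=True
        )
        nx_true = np.interp(traj["t_days"], truth["t_days"], truth["n_x_total"])
        late = traj["t_days"] > 5.0
        rel = np.abs(traj["n_x_total"][late] - nx_true[late]) / nx_true[late]
        assert rel.max() < 0.02

    def test_doubling_nu_halves_biomass_gain(self, config, plateau_05):
        lo = accumulate_biomass(config, plateau_05, REFERENCE_CALIBRATION)
        hi = accumulate_biomass(
            config.with_(nu_nx=0.4), plateau_05, REFERENCE_CALIBRATION, n_x0=config.n_x0
        )
        gain_lo = lo["n_x_total"] - config.n_x0
        gain_hi = hi["n_x_total"] - config.n_x0
        assert np.allclose(gain_hi, 0.5 * gain_lo)

    def test_zero_od_means_all_biofilm(self, config):
        c_in = config.feed_nitrogen(0.0)
        series = _series([0.0, 2.0, 4.0], [c_in, 0.5 * c_in, 0.2 * c_in], [0.0] * 3)
        traj = accumulate_biomass(config, series, REFERENCE_CALIBRATION)
        assert np.allclose(traj["n_px"], 0.0)
        assert np.allclose(traj["n_bx"], traj["n_x_total"])

    def test_planktonic_only_growth_attributed_to_planktonic(self, config):
        params = SimulationParams(
            inoculum_biofilm_frac=0.0,
            k_det=0.0,
            horizon=30.0,
            dt_solver=0.02,
            seed=4,
        )
        _, samples = simulate(config, params)
        traj = accumulate_biomass(
            config, samples, REFERENCE_CALIBRATION, dissolved_holdup=True
        )
        ok = traj["t_days"] > 0
        frac = traj.loc[ok, "biofilm_fraction"].dropna()
        assert (frac <= 0.05).all()

    def test_negative_biofilm_flagged_not_clipped(self, config):
        # planktonic nitrogen larger than total biomass -> negative biofilm
        c_in = config.feed_nitrogen(0.0)
        series = _series([0.0, 1.0], [c_in, c_in], [0.0, 2.0])
        traj = accumulate_biomass(config, series, REFERENCE_CALIBRATION)
        row = traj.iloc[1]
        assert row["flag_negative_biofilm"]
        assert row["n_bx"] < 0
        assert np.isnan(row["biofilm_fraction"])

    def test_input_errors(self, config):
        with pytest.raises(InputError):
            accumulate_biomass(config, _series([], [], []), REFERENCE_CALIBRATION)
        with pytest.raises(InputError):
            accumulate_biomass(
                config, _series([2.0, 1.0], [0.0, 0.0], [0.0, 0.0]), REFERENCE_CALIBRATION
            )

    def test_trapezoidal_option_differs_but_converges(self, config, plateau_05):
        rect = accumulate_biomass(config, plateau_05, REFERENCE_CALIBRATION)
        trap = accumulate_biomass(
            config, plateau_05, REFERENCE_CALIBRATION, integration="trapz"
        )
        diff = np.abs(rect["n_x_total"] - trap["n_x_total"])
        assert diff.iloc[-1] < 0.02 * rect["n_x_total"].iloc[-1]
        assert (diff > 0).any()


class TestConservation:
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 15),
    )
    @settings(max_examples=40, deadline=None)
    def test_import_equals_export_plus_retention(self, seed, n):
        """The increment construction conserves nitrogen to machine precision."""
        rng = np.random.default_rng(seed)
        cfg = ReactorConfig(c_n_in=((0.0, DEFAULT_FEED_N), (5.0, 2 * DEFAULT_FEED_N)))
        t = np.cumsum(rng.uniform(0.2, 3.0, size=n))
        series = _series(
            t, rng.uniform(0, 0.01, size=n), rng.uniform(0, 1.0, size=n)
        )
        ledger = nitrogen_ledger(cfg, series, REFERENCE_CALIBRATION)
        assert ledger["imported"] == pytest.approx(
            ledger["exported"] + ledger["retained"], rel=1e-13, abs=1e-18
        )
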