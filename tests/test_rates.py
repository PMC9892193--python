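"""Volumetric rates, q-values, and specific growth rate."""

import numpy as np
import pandas as pd
import pytest

from mesbalance import (
    InputError,
    ReactorConfig,
    accumulate_biomass,
    specific_growth_rate,
    specific_rates,
    volumetric_rate,
    volumetric_rates,
)
from mesbalance.calibration import REFERENCE_CALIBRATION
from mesbalance.stoichiometry import DEFAULT_STOICHIOMETRY


def _biomass_frame(t, n_x, c_px=None):
    c_px = np.zeros_like(np.asarray(t, dtype=float)) if c_px is None else c_px
    return pd.DataFrame({"t_days": t, "n_x_total": n_x, "c_px": c_px})


class TestVolumetricRate:
    def test_steady_state_equals_dilution_rate(self, config):
        c = 5.71 / 60.05  # mol/L acetate
        r = volumetric_rate(config, c, c, c_in=0.0, dt=3.5)
        r_g = r * 60.05
        assert r_g == pytest.approx(0.714, rel=1e-3)
        # inside the reported pseudo-steady-state band 0.74 +/- 0.13
        assert 0.74 - 0.13 < r_g < 0.74 + 0.13

    def test_pass_through_no_reaction(self, config):
        assert volumetric_rate(config, 0.01, 0.01, c_in=0.01, dt=1.0) == pytest.approx(0.0)

    def test_batch_limit_is_accumulation_only(self):
        cfg = ReactorConfig(f_in=1e-12)
        r = volumetric_rate(cfg, 0.01, 0.02, c_in=0.0, dt=2.0)
        assert r == pytest.approx(0.005, rel=1e-6)

    def test_nonpositive_dt_rejected(self, config):
        with pytest.raises(InputError):
            volumetric_rate(config, 0.0, 0.01, 0.0, dt=-1.0)

    def test_dilution_identity_at_simulator_steady_state(self, config, steady):
        """r_i * V = F * c_out once product washout has equilibrated."""
        _, samples = steady
        sub = samples[samples["t_days"] > 110].reset_index(drop=True)
        rv = volumetric_rates(config, sub)
        for p in ("acetate", "butyrate"):
            lhs = rv[f"r_{p}"].mean() * config.v_tc
            rhs = config.f_in * sub[p].iloc[1:].mean()
            assert lhs == pytest.approx(rhs, rel=0.01)


class TestSpecificRates:
    def test_direct_substitution(self, config):
        rates = pd.DataFrame({"t_mid_days": [1.0], "r_acetate": [0.05]})
        biomass = _biomass_frame([0.0, 2.0], [0.012, 0.012])
        out = specific_rates(config, rates, biomass)
        assert out["q_acetate"].iloc[0] == pytest.approx(1.0)

    def test_zero_rates_give_zero_total(self, config):
        rates = pd.DataFrame(
            {"t_mid_days": [1.0], "r_acetate": [0.0], "r_butyrate": [0.0]}
        )
        biomass = _biomass_frame([0.0, 2.0], [0.01, 0.01])
        out = specific_rates(config, rates, biomass)
        assert out["q_p_total"].iloc[0] == pytest.approx(0.0)

    def test_round_trip_identity(self, config):
        """q_i * n_X == r_i * V * C_i on every interval, machine precision."""
        rng = np.random.default_rng(7)
        t_mid = np.arange(0.5, 10.0, 1.0)
        rates = pd.DataFrame(
            {
                "t_mid_days": t_mid,
                "r_acetate": rng.uniform(0, 0.1, t_mid.size),
                "r_hexanoate": rng.uniform(0, 0.01, t_mid.size),
            }
        )
        tb = np.arange(0.0, 11.0, 1.0)
        biomass = _biomass_frame(tb, rng.uniform(0.005, 0.05, tb.size))
        out = specific_rates(config, rates, biomass)
        for p, c_i in (("acetate", 2), ("hexanoate", 6)):
            lhs = out[f"q_{p}"] * out["n_x_mid"]
            rhs = out[f"r_{p}"] * config.v_tc * c_i
            assert np.allclose(lhs, rhs, rtol=1e-14)

    def test_zero_biomass_flagged_missing(self, config):
        rates = pd.DataFrame({"t_mid_days": [1.0], "r_acetate": [0.05]})
        biomass = _biomass_frame([0.0, 2.0], [0.0, 0.0])
        out = specific_rates(config, rates, biomass)
        assert out["flag_zero_biomass"].iloc[0]
        assert np.isnan(out["q_acetate"].iloc[0])

    def test_recovers_true_qp_on_simulator(self, config, plateau, plateau_05):
        truth, _ = plateau
        biomass = accumulate_biomass(
            config, plateau_05, REFERENCE_CALIBRATION, dissolved_holdup=True
        )
        rv = volumetric_rates(config, plateau_05)
        out = specific_rates(config, rv, biomass)
        late = out[out["t_mid_days"] > 50.0]
        q_true = 0.2  # sum of the scenario's q_p profile
        assert late["q_p_total"].mean() == pytest.approx(q_true, rel=0.05)


class TestSpecificGrowthRate:
    def test_constant_biomass_zero_mu(self, config):
        biomass = _biomass_frame([0.0, 1.0, 2.0], [0.01, 0.01, 0.01])
        out = specific_growth_rate(config, biomass)
        assert np.allclose(out["mu"], 0.0)

    @pytest.mark.parametrize("dt", [1.0, 0.5, 0.1])
    def test_exponential_growth_recovery(self, config, dt):
        mu = 0.12
        t = np.arange(0.0, 10.0 + dt / 2, dt)
        biomass = _biomass_frame(t, 0.002 * np.exp(mu * t))
        out = specific_growth_rate(config, biomass)
        # log-linear regression on the same points is the oracle
        slope = np.polyfit(t, np.log(0.002 * np.exp(mu * t)), 1)[0]
        assert out["mu"].mean() == pytest.approx(slope, rel=0.01 * dt / 0.1 + 0.005)

    def test_discretization_error_decreases_with_dt(self, config):
        mu = 0.12
        errs = []
        for dt in (1.0, 0.5, 0.1):
            t = np.arange(0.0, 10.0 + dt / 2, dt)
            biomass = _biomass_frame(t, 0.002 * np.exp(mu * t))
            out = specific_growth_rate(config, biomass)
            errs.append(abs(out["mu"].mean() - mu))
        assert errs[0] > errs[1] > errs[2]

    def test_declining_biomass_negative_mu(self, config):
        biomass = _biomass_frame([0.0, 1.0, 2.0], [0.02, 0.015, 0.012])
        out = specific_growth_rate(config, biomass)
        assert (out["mu"] < 0).all()

    def test_washout_term_adds_export(self, config):
        t = [0.0, 1.0]
        biomass = _biomass_frame(t, [0.01, 0.01], c_px=[0.02, 0.02])
        with_w = specific_growth_rate(config, biomass, include_washout=True)
        without = specific_growth_rate(config, biomass, include_washout=False)
        expected = config.f_in * 0.02 / 0.01
        assert with_w["mu"].iloc[0] - without["mu"].iloc[0] == pytest.approx(expected)

    def test_peak_mu_matches_simulator_truth(self, config, plateau, plateau_05):
        truth, _ = plateau
        biomass = accumulate_biomass(
            config, plateau_05, REFERENCE_CALIBRATION, dissolved_holdup=True
        )
        out = specific_growth_rate(config, biomass)
        k = out["mu"].idxmax()
        t_pk = out.loc[k, "t_mid_days"]
        mu_true = np.interp(t_pk, truth["t_days"], truth["mu_true"])
        assert out.loc[k, "mu"] == pytest.approx(mu_true, rel=0.10)

    def test_smoothing_preserves_length(self, config):
        t = np.arange(0.0, 10.5, 0.5)
        biomass = _biomass_frame(t, 0.002 * np.exp(0.1 * t))
        out = specific_growth_rate(config, biomass, smooth_window=3)
        assert len(out) == len(t) - 1
        assert out["mu"].notna().all()

    def test_too_few_samples_rejected(self, config):
        with pytest.raises(InputError):
            specific_growth_rate(config, _biomass_frame([0.0], [0.01]))
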