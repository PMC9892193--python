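"""Model/results interface tying the pipeline stages together.

:class:`MESBalanceModel` holds a measurement series, a reactor configuration,
and an OD calibration; its :meth:`~MESBalanceModel.fit` integrates the
nitrogen balance into a biomass trajectory, derives volumetric and
biomass-specific rates, and returns a :class:`MESBalanceResults` carrying the
estimates plus methods for Faradaic efficiency, KPI normalization, and a
text summary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .balance import accumulate_biomass, validate_series
from .calibration import CalibrationSet, OdNitrogenCalibration, as_calibration_set
from .config import ReactorConfig
from .electro_kpi import (
    faradaic_efficiency,
    integrate_charge,
    kpi_report,
    net_production,
    occupancy,
)
from .errors import InputError
from .rates import specific_growth_rate, specific_rates, volumetric_rates
from .stoichiometry import DEFAULT_STOICHIOMETRY, StoichiometryTable


class MESBalanceModel:
    """Nitrogen-balance biomass estimation for a continuous biofilm reactor.

    Parameters
    ----------
    data
        Measurement table: ``t_days``, ``c_n_aq_out`` (mol/L), ``od600``,
        optional product columns (mol/L) and ``current_a``.
    config
        Reactor configuration.
    calibration
        OD600 -> planktonic-nitrogen calibration (single model or dated set).

    Examples
    --------
    >>> from mesbalance import MESBalanceModel, ReactorConfig, simulate, SimulationParams
    >>> cfg = ReactorConfig()
    >>> truth, samples = simulate(cfg, SimulationParams(seed=1))
    >>> res = MESBalanceModel(samples, cfg).fit()
    >>> res.biomass["biofilm_fraction"].iloc[-1] > 0.9
    True
    """

    def __init__(
        self,
        data: pd.DataFrame,
        config: ReactorConfig,
        calibration: OdNitrogenCalibration | CalibrationSet | None = None,
        stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
    ):
        from .calibration import REFERENCE_CALIBRATION

        self.data = validate_series(data.reset_index(drop=True))
        self.config = config
        self.calibration = as_calibration_set(calibration or REFERENCE_CALIBRATION)
        self.stoich = stoich

    @classmethod
    def from_csv(
        cls,
        measurements: str | Path,
        config: ReactorConfig | str | Path | None = None,
        calibration: OdNitrogenCalibration | CalibrationSet | str | Path | None = None,
        units: str = "mol",
    ) -> "MESBalanceModel":
        """Build a model from files on disk (measurement CSV, YAML config,
        calibration-table CSV)."""
        from . import io as _io

        if isinstance(config, (str, Path)):
            config, _ = _io.read_config(config)
        data = _io.read_measurements(measurements, units=units)
        if isinstance(calibration, (str, Path)):
            calibration = _io.read_calibration(calibration)
        return cls(data, config or ReactorConfig(), calibration)

    def fit(
        self,
        *,
        integration: str = "rect",
        include_washout: bool = True,
        smooth_window: int = 1,
        dissolved_holdup: bool = False,
        n_x0: float | None = None,
    ) -> "MESBalanceResults":
        """Run the balance -> rates pipeline and return the results object.

        Parameters mirror the underlying stages: ``integration`` selects the
        rectangular (default) or trapezoidal increment rule, ``include_washout``
        adds the planktonic washout term to mu, ``smooth_window`` applies a
        centered rolling mean to mu, ``dissolved_holdup`` corrects increments
        for the dissolved-N inventory change, and ``n_x0`` overrides the
        inoculum biomass.
        """
        biomass = accumulate_biomass(
            self.config,
            self.data,
            self.calibration,
            n_x0=n_x0,
            integration=integration,
            dissolved_holdup=dissolved_holdup,
        )
        products = [p for p in self.stoich.products if p in self.data.columns]
        rates = None
        if len(self.data) >= 2:
            mu = specific_growth_rate(
                self.config,
                biomass,
                include_washout=include_washout,
                smooth_window=smooth_window,
            )
            if products:
                rv = volumetric_rates(self.config, self.data, tuple(products))
                rates = specific_rates(self.config, rv, biomass, self.stoich)
                rates = rates.merge(mu, on="t_mid_days", suffixes=("", "_mu"))
            else:
                rates = mu
        return MESBalanceResults(self, biomass, rates)


class MESBalanceResults:
    """Estimates produced by :meth:`MESBalanceModel.fit`.

    Attributes
    ----------
    biomass : pandas.DataFrame
        Per-sample biomass partition (total / planktonic / biofilm, C-mol).
    rates : pandas.DataFrame or None
        Per-interval volumetric rates, q-values, and mu.
    """

    def __init__(self, model: MESBalanceModel, biomass: pd.DataFrame, rates):
        self.model = model
        self.config = model.config
        self.biomass = biomass
        self.rates = rates

    # -- electro-KPIs -------------------------------------------------------

    def _window(self, window: tuple[float, float] | None) -> tuple[float, float]:
        t = self.model.data["t_days"]
        return window if window is not None else (float(t.iloc[0]), float(t.iloc[-1]))

    def faradaic_efficiency(self, window: tuple[float, float] | None = None) -> float:
        """Electron recovery in products + biomass over a time window, %."""
        if "current_a" not in self.model.data.columns:
            raise InputError("no current_a column in the measurement series")
        t0, t1 = self._window(window)
        data = self.model.data
        mask = (data["t_days"] >= t0) & (data["t_days"] <= t1)
        sub = data.loc[mask]
        if len(sub) < 2:
            raise InputError("window contains fewer than 2 samples")
        t = sub["t_days"].to_numpy()
        q_t = integrate_charge(t, sub["current_a"].to_numpy())
        produced = {
            p: net_production(self.config, t, sub[p].to_numpy())
            for p in self.model.stoich.products
            if p in sub.columns
        }
        bm = self.biomass.loc[mask.to_numpy()]
        d_nx = float(bm["n_x_total"].iloc[-1] - bm["n_x_total"].iloc[0])
        exported_x = float(
            np.trapezoid(self.config.f_in * bm["c_px"].to_numpy(), t)
        )
        return faradaic_efficiency(
            produced, d_nx + exported_x, q_t, self.model.stoich
        )

    def kpi_report(self, window: tuple[float, float] | None = None) -> pd.DataFrame:
        """Standard KPI table over a (pseudo-steady-state) window.

        Titers are window-mean concentrations (g/L); production rates are
        window-mean volumetric rates re-expressed per catholyte volume,
        electrode volume, and projected surface area; current density is the
        window-mean (signed) current per PSA and per cathode volume.
        """
        if self.rates is None:
            raise InputError("rates unavailable (need >= 2 samples)")
        t0, t1 = self._window(window)
        stoich = self.model.stoich
        data = self.model.data
        mask = (data["t_days"] >= t0) & (data["t_days"] <= t1)
        sub = data.loc[mask]
        rmask = (self.rates["t_mid_days"] >= t0) & (self.rates["t_mid_days"] <= t1)
        rsub = self.rates.loc[rmask]
        titers, rates_cv = {}, {}
        for p in stoich.products:
            if p not in sub.columns or f"r_{p}" not in rsub.columns:
                continue
            titers[p] = float(sub[p].mean()) * stoich.molar_mass(p)
            rates_cv[p] = float(rsub[f"r_{p}"].mean()) * stoich.molar_mass(p)
        cd_psa = np.nan
        if "current_a" in sub.columns:
            cd_psa = float(sub["current_a"].mean()) / self.config.electrode_psa_m2
        fe = None
        if "current_a" in sub.columns:
            fe = self.faradaic_efficiency((t0, t1))
        occ = occupancy(self.config, self.biofilm_packing((t0, t1)))
        return kpi_report(self.config, titers, rates_cv, cd_psa, fe, occ)

    def biofilm_packing(self, window: tuple[float, float] | None = None) -> float:
        """Biofilm biomass per electrode volume at the window end, mmol/cm^3."""
        _, t1 = self._window(window)
        bm = self.biomass[self.biomass["t_days"] <= t1]
        n_bx = float(bm["n_bx"].iloc[-1])
        return max(0.0, n_bx) * 1000.0 / self.config.electrode_volume

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary (plain text)."""
        cfg = self.config
        bm = self.biomass
        lines = [
            "Nitrogen-balance biomass estimation",
            "=" * 51,
            f"Samples: {len(bm):>5d}    span: {bm['t_days'].iloc[0]:.1f}-"
            f"{bm['t_days'].iloc[-1]:.1f} d",
            f"Catholyte volume: {cfg.v_tc:.3g} L   flow: {cfg.f_in:.4g} L/d   "
            f"HRT: {cfg.hrt_days:.3g} d",
            f"nu_N,X: {cfg.nu_nx} mol-N/C-mol   MW_X: {cfg.mw_x} g/C-mol",
            "-" * 51,
            f"Final total biomass:    {bm['n_x_total'].iloc[-1] * 1e3:9.3f} mmol",
            f"Final planktonic:       {bm['n_px'].iloc[-1] * 1e3:9.4f} mmol",
            f"Final biofilm:          {bm['n_bx'].iloc[-1] * 1e3:9.3f} mmol",
        ]
        frac = bm["biofilm_fraction"].iloc[-1]
        if np.isfinite(frac):
            lines.append(f"Final biofilm fraction: {100 * frac:9.2f} %")
        lines.append(
            f"Biofilm packing:        {self.biofilm_packing():9.3f} mmol/cm^3 "
            f"({occupancy(cfg, self.biofilm_packing()):.1f}% of theoretical)"
        )
        if self.rates is not None and "mu" in self.rates.columns:
            mu = self.rates["mu"].dropna()
            if len(mu):
                lines.append(
                    f"mu (peak / final):      {mu.max():9.4f} / {mu.iloc[-1]:.4f} 1/d"
                )
        if self.rates is not None and "q_p_total" in self.rates.columns:
            qp = self.rates["q_p_total"].dropna()
            if len(qp):
                lines.append(
                    f"q_p total (final):      {qp.iloc[-1]:9.4f} mol-C/C-mol/d"
                )
        if "current_a" in self.model.data.columns:
            try:
                lines.append(
                    f"Faradaic efficiency:    {self.faradaic_efficiency():9.2f} %"
                )
            except InputError:
                pass
        nflag = int(bm["flag_negative_biofilm"].sum())
        if nflag:
            lines.append(f"Flagged samples (negative biofilm): {nflag}")
        lines.append("=" * 51)
        return "\n".join(lines)

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        """Write biomass and rate tables under ``outdir``."""
        from . import io as _io

        outdir = Path(outdir)
        paths = {"biomass": _io.write_table(self.biomass, outdir / "biomass.csv")}
        if self.rates is not None:
            paths["rates"] = _io.write_table(self.rates, outdir / "rates.csv")
        return paths
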