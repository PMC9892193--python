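"""Volumetric and biomass-specific rates from the component mass balance.

For any compound i in a well-mixed, continuously fed compartment,

    dn_i/dt = F*c_i,in - F*c_i,out + r_i*V_TC

with n_i = c_i*V_TC and outflow concentration equal to the current catholyte
concentration. Discretised forward over a sampling interval this gives the
volumetric production rate

    r_i = (c_next - c_prev)/dt + (F/V_TC)*(c_next - c_in)

Biomass-specific rates put r_i on a per-biomass basis (q-values),

    q_i = r_i * V_TC * C_i / n_X,T        [mol-C per C-mol-X per day]

with C_i the carbon number of product i, and the biomass amount evaluated at
the interval midpoint (linear interpolation). The specific growth rate mu is
the same balance applied to biomass itself: the accumulation term plus the
planktonic washout F*c_pX (no biomass enters with the feed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ReactorConfig
from .errors import InputError
from .stoichiometry import DEFAULT_STOICHIOMETRY, StoichiometryTable


def volumetric_rate(
    config: ReactorConfig,
    c_prev: float,
    c_next: float,
    c_in: float,
    dt: float,
) -> float:
    """Volumetric production rate over one interval, mol L^-1 d^-1.

    ``c_in`` is zero for products formed in the reactor; the batch limit
    (F = 0) reduces to the accumulation term dc/dt, and at steady state
    (c constant) the rate equals the dilution term F*(c - c_in)/V_TC.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    return (c_next - c_prev) / dt + (config.f_in / config.v_tc) * (c_next - c_in)


def volumetric_rates(
    config: ReactorConfig,
    series: pd.DataFrame,
    products: tuple[str, ...] = ("acetate", "butyrate", "hexanoate"),
    c_in: float = 0.0,
) -> pd.DataFrame:
    """Per-interval volumetric rates for each product column present.

    Returns a frame indexed by interval midpoint ``t_mid_days`` with one
    ``r_<product>`` column (mol L^-1 d^-1) per available product.
    """
    t = series["t_days"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InputError("need at least 2 samples to form intervals")
    dt = np.diff(t)
    out = {"t_mid_days": 0.5 * (t[:-1] + t[1:])}
    for p in products:
        if p not in series.columns:
            continue
        c = series[p].to_numpy(dtype=float)
        out[f"r_{p}"] = np.diff(c) / dt + (config.f_in / config.v_tc) * (c[1:] - c_in)
    return pd.DataFrame(out)


def _midpoint_biomass(biomass: pd.DataFrame, t_mid: np.ndarray) -> np.ndarray:
    tb = biomass["t_days"].to_numpy(dtype=float)
    nx = biomass["n_x_total"].to_numpy(dtype=float)
    return np.interp(t_mid, tb, nx)


def specific_rates(
    config: ReactorConfig,
    rates: pd.DataFrame,
    biomass: pd.DataFrame,
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
) -> pd.DataFrame:
    """Convert volumetric rates to biomass-specific q-values on a C-mol basis.

    ``q_p_total`` sums the carbon in all products jointly. Intervals with
    non-positive midpoint biomass yield missing q-values and are flagged.
    """
    t_mid = rates["t_mid_days"].to_numpy(dtype=float)
    n_x = _midpoint_biomass(biomass, t_mid)
    bad = n_x <= 0
    out = {"t_mid_days": t_mid, "n_x_mid": n_x}
    total = np.zeros_like(t_mid)
    for col in rates.columns:
        if not col.startswith("r_"):
            continue
        product = col[2:]
        c_i = stoich.carbon_number(product)
        r = rates[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = r * config.v_tc * c_i / n_x
        q = np.where(bad, np.nan, q)
        out[col] = r
        out[f"q_{product}"] = q
        total = total + np.where(bad, np.nan, q)
    out["q_p_total"] = total
    out["flag_zero_biomass"] = bad
    return pd.DataFrame(out)


def specific_growth_rate(
    config: ReactorConfig,
    biomass: pd.DataFrame,
    *,
    include_washout: bool = True,
    smooth_window: int = 1,
) -> pd.DataFrame:
    """Specific growth rate mu per sampling interval, d^-1.

    mu = [dn_X,T/dt + F*c_pX] / n_X(midpoint); the washout term uses the
    planktonic concentration measured at the interval end and can be
    disabled (``include_washout=False``) for a pure accumulation estimate.
    ``smooth_window`` applies a centered rolling mean over that many
    intervals (1 = no smoothing). Negative mu indicates net biomass loss
    (decay and/or detachment exceeding growth).
    """
    if len(biomass) < 2:
        raise InputError("need at least 2 biomass samples")
    if smooth_window < 1:
        raise InputError("smooth_window must be >= 1")
    t = biomass["t_days"].to_numpy(dtype=float)
    nx = biomass["n_x_total"].to_numpy(dtype=float)
    cpx = biomass["c_px"].to_numpy(dtype=float)
    dt = np.diff(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    nx_mid = 0.5 * (nx[:-1] + nx[1:])
    r_x_v = np.diff(nx) / dt
    if include_washout:
        r_x_v = r_x_v + config.f_in * cpx[1:]
    bad = nx_mid <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = r_x_v / nx_mid
    mu = np.where(bad, np.nan, mu)
    if smooth_window > 1:
        mu = (
            pd.Series(mu)
            .rolling(smooth_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return pd.DataFrame(
        {"t_mid_days": t_mid, "mu": mu, "flag_zero_biomass": bad}
    )
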