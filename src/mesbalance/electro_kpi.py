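"""Charge integration, Faradaic efficiency, and reactor KPI normalizations.

Faradaic efficiency (electron recovery) is the fraction of the electric
charge passed at the cathode that ends up in reduced products and biomass:

    FE% = 100 * F_const * (sum_i n_i*e_i + n_X*gamma_X) / Q_T

with e_i the electrons per mole of product i (8 / 20 / 32 for acetate /
butyrate / hexanoate), gamma_X the degree of reduction of biomass (4.2 e- per
C-mol for standard biomass grown on ammonium), and Q_T the trapezoidal
integral of |current| over the period. Net product amounts count both export
through the outflow and accumulation in the catholyte.

Production-rate and current-density normalizations convert between the bases
commonly reported for electrochemical bioreactors: catholyte volume,
electrode (cathode) volume, and projected surface area (PSA).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import ReactorConfig
from .errors import InputError
from .stoichiometry import DEFAULT_STOICHIOMETRY, FARADAY, StoichiometryTable


def integrate_charge(
    t_days: np.ndarray,
    current_a: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Total charge passed, coulombs: trapezoidal integral of |i| over time.

    Cathodic currents are conventionally negative; the magnitude is
    integrated. ``window=(t0, t1)`` restricts the integral, interpolating
    the current linearly at the window edges.
    """
    t = np.asarray(t_days, dtype=float)
    i = np.abs(np.asarray(current_a, dtype=float))
    if t.ndim != 1 or t.size != i.size:
        raise InputError("time and current arrays must be 1-D and equal length")
    if np.any(np.diff(t) <= 0):
        raise InputError("time points must be strictly increasing")
    if window is not None:
        t0, t1 = window
        if t1 <= t0:
            raise InputError("empty integration window")
        if t0 < t[0] or t1 > t[-1]:
            raise InputError("window extends beyond the current series")
        inside = (t > t0) & (t < t1)
        tt = np.concatenate([[t0], t[inside], [t1]])
        ii = np.interp(tt, t, i)
        t, i = tt, ii
    if t.size < 2:
        raise InputError("need at least 2 points to integrate")
    return float(np.trapezoid(i, t) * 86400.0)


def net_production(
    config: ReactorConfig,
    t_days: np.ndarray,
    conc: np.ndarray,
    c_in: float = 0.0,
) -> float:
    """Net amount of a compound produced over a period, mol.

    Export through the outflow (trapezoidal integral of F*(c - c_in)) plus
    the change in catholyte inventory V_TC*(c_end - c_start).
    """
    t = np.asarray(t_days, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise InputError("need at least 2 samples")
    export = float(np.trapezoid(config.f_in * (c - c_in), t))
    inventory = config.v_tc * float(c[-1] - c[0])
    return export + inventory


def faradaic_efficiency(
    produced: Mapping[str, float],
    biomass_produced: float,
    q_t: float,
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
) -> float:
    """Faradaic efficiency, percent.

    Parameters
    ----------
    produced
        Net moles of each product formed over the period.
    biomass_produced
        Net C-mol of biomass formed (counted with gamma_X electrons each).
    q_t
        Total charge passed over the same period, coulombs (> 0).
    """
    if q_t <= 0:
        raise InputError("total charge must be positive")
    electrons = sum(
        produced[p] * stoich.electrons(p) for p in produced
    ) + biomass_produced * stoich.gamma_x
    return 100.0 * FARADAY * electrons / q_t


def normalize_rates(config: ReactorConfig, rate_catholyte: float) -> dict[str, float]:
    """Re-express a catholyte-volume rate on the electrode bases.

    Parameters
    ----------
    rate_catholyte
        Production rate per catholyte volume, g L^-1 d^-1.

    Returns
    -------
    dict
        ``rate_catholyte_volume`` (g L^-1 d^-1), ``rate_electrode_volume``
        (g per L of cathode per day), ``rate_psa`` (g m^-2 d^-1).
    """
    if config.electrode_volume <= 0 or config.electrode_psa <= 0:
        raise InputError("electrode geometry must be positive")
    total = rate_catholyte * config.v_tc  # g/d
    return {
        "rate_catholyte_volume": rate_catholyte,
        "rate_electrode_volume": total / config.electrode_volume_l,
        "rate_psa": total / config.electrode_psa_m2,
    }


def normalize_current(config: ReactorConfig, current_density_psa: float) -> float:
    """Convert a PSA current density (A m^-2) to cathode-volume basis (kA m^-3)."""
    if config.electrode_thickness <= 0:
        raise InputError("electrode thickness must be positive")
    return current_density_psa / config.electrode_thickness_m / 1000.0


def theoretical_packing(
    config: ReactorConfig,
    cell_density: float = 1.09,
    dry_fraction: float = 0.30,
) -> float:
    """Maximum possible biomass packing of the electrode, mmol C-mol cm^-3.

    A fully biomass-filled volume at wet cell density ``cell_density``
    (g cm^-3) and dry-weight fraction ``dry_fraction`` holds
    cell_density * dry_fraction / MW_X moles of biomass per cm^3.
    """
    if cell_density <= 0 or not (0 < dry_fraction <= 1):
        raise InputError("cell density and dry fraction must be positive")
    return cell_density * dry_fraction / config.mw_x * 1000.0


def occupancy(
    config: ReactorConfig,
    biomass_conc_electrode: float,
    cell_density: float = 1.09,
    dry_fraction: float = 0.30,
) -> float:
    """Percent of the electrode's physical space occupied by biomass.

    ``biomass_conc_electrode`` is the biofilm biomass per electrode volume,
    mmol cm^-3, compared against the theoretical maximum packing.
    """
    if biomass_conc_electrode < 0:
        raise InputError("biomass concentration must be non-negative")
    return 100.0 * biomass_conc_electrode / theoretical_packing(
        config, cell_density, dry_fraction
    )


def kpi_report(
    config: ReactorConfig,
    titers_g_per_l: Mapping[str, float],
    rates_catholyte: Mapping[str, float],
    current_density_psa: float,
    fe_percent: float | None = None,
    occupancy_percent: float | None = None,
) -> pd.DataFrame:
    """Assemble the standard KPI table: one row per product.

    Columns mirror the usual reporting layout: titer, production rate per
    catholyte volume / electrode volume / PSA, and the two current-density
    bases (identical on every row as they are per-reactor quantities), plus
    optional Faradaic efficiency and space occupancy.
    """
    rows = []
    cd_vol = normalize_current(config, current_density_psa)
    for product, titer in titers_g_per_l.items():
        norm = normalize_rates(config, rates_catholyte[product])
        row = {
            "product": product,
            "titer_g_per_l": titer,
            **norm,
            "current_density_psa": current_density_psa,
            "current_density_volume": cd_vol,
        }
        if fe_percent is not None:
            row["fe_percent"] = fe_percent
        if occupancy_percent is not None:
            row["occupancy_percent"] = occupancy_percent
        rows.append(row)
    return pd.DataFrame(rows)
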