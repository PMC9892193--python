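"""Reactor configuration: geometry, flows, feed nitrogen schedule, stoichiometry.

Defaults describe a bench-scale microbial electrosynthesis cell: 0.12 L of
catholyte continuously fed at 0.625 mL/h (hydraulic retention time 8 days)
through a 7.35 cm^3 carbon-felt cathode of 7.35 cm^2 projected surface area
and 1 cm thickness, with ammonium (0.4 g/L NH4Cl, 7.478e-3 mol-N/L) as the
sole nitrogen source. The feed nitrogen concentration may be a step function
of time to represent medium-composition changes during the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

#: mol-N per litre contributed by 0.4 g/L NH4Cl (MW 53.49 g/mol).
DEFAULT_FEED_N = 0.4 / 53.49


@dataclass(frozen=True)
class ReactorConfig:
    """Fixed operating parameters of a continuously fed cathode compartment.

    Parameters
    ----------
    v_tc
        Total catholyte volume, L.
    f_in
        Feed flow rate, L/day.
    f_out
        Outflow rate, L/day. Defaults to ``f_in`` (constant liquid volume,
        pH-titrant flow neglected).
    c_n_in
        Feed total dissolved nitrogen, mol/L. Either a single number or a
        piecewise-constant schedule as a sequence of ``(t_start_days, value)``
        pairs sorted by start time; the first pair must start at or before 0.
    nu_nx
        Nitrogen content of dry biomass, mol-N per C-mol biomass.
    mw_x
        Biomass molar mass, g per C-mol.
    electrode_volume
        Cathode (felt) volume, cm^3.
    electrode_psa
        Projected surface area of the cathode, cm^2.
    electrode_thickness
        Cathode thickness, cm.
    n_n0
        Initial amount of dissolved nitrogen in the compartment, mol.
    inoculum_g_per_l
        Inoculated biomass concentration, g/L (dry weight), used for the
        default initial biomass amount ``n_x0``.
    """

    v_tc: float = 0.12
    f_in: float = 0.625e-3 * 24.0  # 0.625 mL/h in L/day
    f_out: float | None = None
    c_n_in: float | tuple[tuple[float, float], ...] = DEFAULT_FEED_N
    nu_nx: float = 0.2
    mw_x: float = 25.25
    electrode_volume: float = 7.35
    electrode_psa: float = 7.35
    electrode_thickness: float = 1.0
    n_n0: float = DEFAULT_FEED_N * 0.12
    inoculum_g_per_l: float = 0.46

    def __post_init__(self) -> None:
        if self.v_tc <= 0 or self.f_in <= 0:
            raise InputError("v_tc and f_in must be positive")
        if self.nu_nx <= 0 or self.mw_x <= 0:
            raise InputError("nu_nx and mw_x must be positive")
        if min(self.electrode_volume, self.electrode_psa, self.electrode_thickness) <= 0:
            raise InputError("electrode dimensions must be positive")
        geom = self.electrode_psa * self.electrode_thickness
        if not math.isclose(self.electrode_volume, geom, rel_tol=0.01):
            raise InputError(
                f"electrode_volume {self.electrode_volume} cm^3 inconsistent with "
                f"psa*thickness = {geom} cm^3 (>1% off)"
            )
        if isinstance(self.c_n_in, (tuple, list)):
            sched = tuple((float(t), float(c)) for t, c in self.c_n_in)
            if not sched:
                raise InputError("empty feed-nitrogen schedule")
            if sched[0][0] > 0:
                raise InputError("feed-nitrogen schedule must start at or before t=0")
            if any(b[0] <= a[0] for a, b in zip(sched, sched[1:])):
                raise InputError("feed-nitrogen schedule start times must increase")
            if any(c < 0 for _, c in sched):
                raise InputError("feed nitrogen concentrations must be non-negative")
            object.__setattr__(self, "c_n_in", sched)
        elif self.c_n_in < 0:
            raise InputError("c_n_in must be non-negative")

    # -- derived quantities -------------------------------------------------

    @property
    def flow_out(self) -> float:
        """Outflow rate, L/day (equals inflow unless overridden)."""
        return self.f_in if self.f_out is None else self.f_out

    @property
    def hrt_days(self) -> float:
        """Hydraulic retention time V_TC / F, days."""
        return self.v_tc / self.f_in

    @property
    def n_x0(self) -> float:
        """Inoculum biomass amount, C-mol: (g/L inoculated) * V_TC / MW_X."""
        return self.inoculum_g_per_l * self.v_tc / self.mw_x

    def feed_nitrogen(self, t: float) -> float:
        """Feed total-N concentration at time ``t`` (days), mol/L."""
        if not isinstance(self.c_n_in, tuple):
            return float(self.c_n_in)
        value = self.c_n_in[0][1]
        for t_start, c in self.c_n_in:
            if t >= t_start:
                value = c
            else:
                break
        return value

    def mean_feed_nitrogen(self, t0: float, t1: float) -> float:
        """Time-averaged feed N over ``[t0, t1]``, exact for the step schedule."""
        if t1 <= t0:
            raise InputError("interval must have positive length")
        if not isinstance(self.c_n_in, tuple):
            return float(self.c_n_in)
        edges = [t0] + [t for t, _ in self.c_n_in if t0 < t < t1] + [t1]
        total = sum(
            self.feed_nitrogen(a) * (b - a) for a, b in zip(edges, edges[1:])
        )
        return total / (t1 - t0)

    def with_(self, **kwargs) -> "ReactorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # electrode geometry in SI-ish units used by the KPI normalizations
    @property
    def electrode_volume_l(self) -> float:
        return self.electrode_volume / 1000.0

    @property
    def electrode_psa_m2(self) -> float:
        return self.electrode_psa / 1e4

    @property
    def electrode_thickness_m(self) -> float:
        return self.electrode_thickness / 100.0
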