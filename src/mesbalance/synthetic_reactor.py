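"""Synthetic continuously fed biofilm electrosynthesis reactor.

Generates measurement tables with known ground truth so every stage of the
nitrogen-balance pipeline can be tested without laboratory data. The model
is a deliberately simple CSTR with an attached biofilm compartment:

* biofilm grows with Monod kinetics on dissolved nitrogen, limited
  logistically by the space available on the electrode (``n_bx_max``), and
  loses cells by detachment (to the planktonic pool) and first-order decay;
* planktonic cells grow at the same nitrogen- and space-limited rate, gain
  detached biofilm cells, and wash out with the hydraulic retention time;
* dissolved nitrogen is fed and washed out by the flow, consumed by growth,
  and returned by decay (lysis), which can push the reactor nitrogen above
  the feed concentration late in a run;
* products accumulate at prescribed biomass-specific rates (q_p, C-mol
  basis) and wash out;
* the cathodic current is exactly the stoichiometric electron demand of
  product formation plus biomass growth, so Faradaic efficiency closes at
  100% by construction and is a testable invariant.

The observation process samples the state at a fixed interval and applies
multiplicative Gaussian noise (truncated at zero); OD600 is obtained by
inverting the OD-to-nitrogen calibration line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

import yaml

from .calibration import REFERENCE_CALIBRATION, OdNitrogenCalibration
from .config import ReactorConfig
from .errors import ComputationError, InputError
from .stoichiometry import DEFAULT_STOICHIOMETRY, FARADAY, StoichiometryTable

_PRODUCT_ORDER = ("acetate", "butyrate", "hexanoate")


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic, observation, and numerical parameters of the simulator.

    Rates are first-order constants in 1/day; ``q_p`` entries are biomass-
    specific production rates in mol-C per C-mol biomass per day. ``noise``
    is the relative standard deviation applied to each observable (a single
    number, or a map with keys ``tn``, ``od``, ``products``, ``current``).
    ``thresholds`` optionally gates a product on another product's titer
    (g/L), emulating chain elongation starting only above a precursor
    concentration; ``lag_days`` delays all production.
    """

    mu_max: float = 0.15
    k_n: float = 5e-4
    n_bx_max: float = 0.02
    k_det: float = 0.001
    k_dec: float = 0.0
    q_p: dict[str, float] = field(
        default_factory=lambda: {"acetate": 0.15, "butyrate": 0.04, "hexanoate": 0.01}
    )
    lag_days: float = 0.0
    thresholds: dict[str, tuple[str, float]] = field(default_factory=dict)
    inoculum_biofilm_frac: float = 0.5
    noise: float | dict[str, float] = 0.0
    seed: int = 0
    dt_solver: float = 0.01
    sample_interval: float = 0.5
    horizon: float = 60.0

    def __post_init__(self) -> None:
        if min(self.mu_max, self.k_n, self.k_det, self.k_dec, self.lag_days) < 0:
            raise InputError("rate constants and lag must be non-negative")
        if self.n_bx_max <= 0:
            raise InputError("n_bx_max must be positive")
        if not 0.0 <= self.inoculum_biofilm_frac <= 1.0:
            raise InputError("inoculum_biofilm_frac must lie in [0, 1]")
        if self.sample_interval < self.dt_solver:
            raise InputError("sample_interval must be >= dt_solver")
        if any(q < 0 for q in self.q_p.values()):
            raise InputError("q_p values must be non-negative")

    def noise_for(self, observable: str) -> float:
        if isinstance(self.noise, dict):
            return float(self.noise.get(observable, 0.0))
        return float(self.noise)

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def _active_q(
    params: SimulationParams,
    t: float,
    conc: dict[str, float],
    stoich: StoichiometryTable,
) -> dict[str, float]:
    """Instantaneous q_p per product, applying lag and titer thresholds."""
    if t < params.lag_days:
        return {p: 0.0 for p in params.q_p}
    q = {}
    for p, value in params.q_p.items():
        gate, thr = params.thresholds.get(p, (None, 0.0))
        if gate is not None:
            titer_g = conc.get(gate, 0.0) * stoich.molar_mass(gate)
            if titer_g < thr:
                value = 0.0
        q[p] = value
    return q


def simulate(
    config: ReactorConfig,
    params: SimulationParams,
    calibration: OdNitrogenCalibration = REFERENCE_CALIBRATION,
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate the reactor ODEs and sample noisy observations.

    Returns
    -------
    (ground_truth, samples)
        ``ground_truth``: dense frame (step ``dt_solver``) with true
        ``n_bx``, ``n_px``, ``n_x_total`` (C-mol), ``c_n`` (mol/L),
        ``c_<product>`` (mol/L), instantaneous ``mu_true`` and ``q_p_true``,
        and ``current_a``.
        ``samples``: measurement table at ``sample_interval`` with columns
        ``t_days``, ``c_n_aq_out``, ``od600``, one column per product
        (mol/L), and ``current_a``, with seeded multiplicative noise.
    """
    products = [p for p in _PRODUCT_ORDER if p in params.q_p]
    n_prod = len(products)
    nu = config.nu_nx
    v = config.v_tc
    f = config.f_in
    n_x0 = config.n_x0
    n_bx0 = params.inoculum_biofilm_frac * n_x0
    n_px0 = n_x0 - n_bx0
    c_n0 = config.n_n0 / v

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n_bx, n_px, c_n = y[0], y[1], y[2]
        conc = dict(zip(products, y[3:]))
        n_x = n_bx + n_px
        mu_b = (
            params.mu_max
            * (c_n / (params.k_n + c_n) if c_n > 0 else 0.0)
            * max(0.0, 1.0 - n_bx / params.n_bx_max)
        )
        growth = mu_b * n_x  # gross biomass formation, C-mol/d
        q = _active_q(params, t, conc, stoich)
        dy = np.empty(3 + n_prod)
        dy[0] = (mu_b - params.k_det - params.k_dec) * n_bx
        dy[1] = params.k_det * n_bx + mu_b * n_px - (f / v) * n_px
        # decayed biomass returns its nitrogen to the dissolved pool (lysis)
        dy[2] = (f / v) * (config.feed_nitrogen(t) - c_n) - nu * growth / v + nu * params.k_dec * n_bx / v
        for j, p in enumerate(products):
            dy[3 + j] = q[p] * n_x / stoich.carbon_number(p) / v - (f / v) * conc[p]
        return dy

    y0 = np.array([n_bx0, n_px0, c_n0] + [0.0] * n_prod)
    # integrate piecewise across known discontinuities (lag end, feed steps)
    breaks = {0.0, params.horizon}
    if 0.0 < params.lag_days < params.horizon:
        breaks.add(params.lag_days)
    if isinstance(config.c_n_in, tuple):
        breaks.update(t for t, _ in config.c_n_in if 0.0 < t < params.horizon)
    edges = sorted(breaks)

    t_dense = np.arange(0.0, params.horizon + 0.5 * params.dt_solver, params.dt_solver)
    t_dense[-1] = min(t_dense[-1], params.horizon)
    y_dense = np.empty((len(t_dense), len(y0)))
    y_cur = y0
    for a, b in zip(edges, edges[1:]):
        mask = (t_dense >= a) & (t_dense <= b)
        t_eval = np.unique(np.concatenate([[a], t_dense[mask], [b]]))
        sol = solve_ivp(
            rhs,
            (a, b),
            y_cur,
            method="LSODA",
            t_eval=t_eval,
            rtol=1e-9,
            atol=1e-12,
        )
        if not sol.success:
            raise ComputationError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
        y_interp = np.array([np.interp(t_dense[mask], sol.t, sol.y[k]) for k in range(len(y0))]).T
        y_dense[mask] = y_interp
        y_cur = sol.y[:, -1]

    n_bx = y_dense[:, 0]
    n_px = y_dense[:, 1]
    c_n = y_dense[:, 2]
    n_x = n_bx + n_px
    # instantaneous truths recomputed from the state
    mu_b = (
        params.mu_max
        * np.where(c_n > 0, c_n / (params.k_n + c_n), 0.0)
        * np.clip(1.0 - n_bx / params.n_bx_max, 0.0, None)
    )
    # net specific rate matching the estimator's target:
    # (dn_X/dt + F*c_pX)/n_X = (mu_b*n_X - k_dec*n_bX)/n_X
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_true = np.where(n_x > 0, (mu_b * n_x - params.k_dec * n_bx) / n_x, np.nan)
    q_series = np.array(
        [
            sum(
                _active_q(
                    params, t, dict(zip(products, y_dense[k, 3:])), stoich
                ).values()
            )
            for k, t in enumerate(t_dense)
        ]
    )
    e_flux = np.zeros_like(t_dense)  # mol e-/d
    for j, p in enumerate(products):
        qj = np.array(
            [
                _active_q(params, t, dict(zip(products, y_dense[k, 3:])), stoich)[p]
                for k, t in enumerate(t_dense)
            ]
        )
        e_flux += qj * n_x * stoich.electrons(p) / stoich.carbon_number(p)
    e_flux += stoich.gamma_x * mu_b * n_x
    current = -FARADAY * e_flux / 86400.0

    truth = pd.DataFrame(
        {
            "t_days": t_dense,
            "n_bx": n_bx,
            "n_px": n_px,
            "n_x_total": n_x,
            "c_px": n_px / v,
            "c_n": c_n,
            "mu_true": mu_true,
            "q_p_true": q_series,
            "current_a": current,
        }
    )
    for j, p in enumerate(products):
        truth[f"c_{p}"] = y_dense[:, 3 + j]

    samples = _observe(truth, products, params, calibration, nu)
    return truth, samples


def _observe(
    truth: pd.DataFrame,
    products: list[str],
    params: SimulationParams,
    calibration: OdNitrogenCalibration,
    nu: float,
) -> pd.DataFrame:
    """Sample the dense truth at the sampling interval with seeded noise."""
    rng = np.random.default_rng(params.seed)
    t_obs = np.arange(0.0, params.horizon + 1e-9, params.sample_interval)
    td = truth["t_days"].to_numpy()

    def at(col: str) -> np.ndarray:
        return np.interp(t_obs, td, truth[col].to_numpy())

    def noisy(values: np.ndarray, kind: str) -> np.ndarray:
        sd = params.noise_for(kind)
        if sd <= 0:
            return values.copy()
        return np.maximum(0.0, values * (1.0 + sd * rng.standard_normal(values.shape)))

    c_n_obs = noisy(at("c_n"), "tn")
    # true OD600 from the calibration line inverted on planktonic nitrogen
    c_n_px_true = nu * at("c_px")
    od_true = np.maximum(0.0, (c_n_px_true - calibration.intercept) / calibration.slope)
    od_obs = noisy(od_true, "od")
    out = pd.DataFrame({"t_days": t_obs, "c_n_aq_out": c_n_obs, "od600": od_obs})
    for p in products:
        out[p] = noisy(at(f"c_{p}"), "products")
    i_true = at("current_a")
    sd = params.noise_for("current")
    if sd > 0:
        i_obs = np.minimum(0.0, i_true * (1.0 + sd * rng.standard_normal(i_true.shape)))
    else:
        i_obs = i_true
    out["current_a"] = i_obs
    return out


def observe(
    truth: pd.DataFrame,
    params: SimulationParams,
    calibration: OdNitrogenCalibration = REFERENCE_CALIBRATION,
    nu: float = 0.2,
) -> pd.DataFrame:
    """Re-sample observations from an existing ground-truth trajectory.

    Useful for studying observation noise: many noisy measurement tables can
    be drawn (varying ``params.seed``/``params.noise``) from one ODE solve.
    """
    products = [p for p in _PRODUCT_ORDER if f"c_{p}" in truth.columns]
    return _observe(truth, products, params, calibration, nu)


def nitrogen_closure_residual(
    config: ReactorConfig, truth: pd.DataFrame
) -> float:
    """Absolute nitrogen-closure residual of a ground-truth trajectory, mol.

    feed N = exported N (dissolved + planktonic) + d(dissolved inventory)
    + d(biomass N); the residual reflects solver and trapezoid error only.
    """
    t = truth["t_days"].to_numpy()
    c_n = truth["c_n"].to_numpy()
    c_px = truth["c_px"].to_numpy()
    n_x = truth["n_x_total"].to_numpy()
    n_bx = truth["n_bx"].to_numpy()
    nu = config.nu_nx
    fed = float(np.trapezoid([config.feed_nitrogen(ti) for ti in t], t)) * config.f_in
    exported = float(np.trapezoid(config.f_in * (c_n + nu * c_px), t))
    d_dissolved = config.v_tc * float(c_n[-1] - c_n[0])
    d_biomass = nu * float(n_x[-1] - n_x[0])
    return abs(fed - exported - d_dissolved - d_biomass)


#: Named scenarios with fixed study conditions.
SCENARIOS: dict[str, SimulationParams] = {
    # biofilm colonizes the electrode and plateaus at its space capacity;
    # nitrogen runs near depletion during fast growth and rebounds after
    "growth_plateau": SimulationParams(),
    # no growth, no production: planktonic inoculum washes out exponentially
    "washout_only": SimulationParams(
        mu_max=0.0,
        k_det=0.0,
        k_dec=0.0,
        q_p={"acetate": 0.0, "butyrate": 0.0, "hexanoate": 0.0},
        inoculum_biofilm_frac=0.0,
        horizon=30.0,
    ),
    # biomass grows from day 0 but organics appear only after a long lag
    "lag_then_production": SimulationParams(lag_days=82.0, horizon=120.0),
}


def make_fixture(
    name: str,
    seed: int,
    outdir: str | Path,
    config: ReactorConfig | None = None,
    noise: float | dict[str, float] | None = None,
) -> dict[str, Path]:
    """Write a named simulation scenario to disk as CSV + YAML files.

    Produces ``config.yaml``, ``measurements.csv`` (the noisy observation
    table), ``ground_truth.csv``, and ``calibration.csv`` under
    ``outdir/name``. Deterministic for a given seed: the same seed yields
    byte-identical files.
    """
    if name not in SCENARIOS:
        raise InputError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
        )
    config = config or ReactorConfig()
    params = SCENARIOS[name].with_(seed=seed)
    if noise is not None:
        params = params.with_(noise=noise)
    truth, samples = simulate(config, params)

    root = Path(outdir) / name
    root.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": root / "config.yaml",
        "measurements": root / "measurements.csv",
        "ground_truth": root / "ground_truth.csv",
        "calibration": root / "calibration.csv",
    }
    cfg = {
        "reactor": {
            "v_tc": config.v_tc,
            "f_in": config.f_in,
            "c_n_in": (
                [list(pair) for pair in config.c_n_in]
                if isinstance(config.c_n_in, tuple)
                else config.c_n_in
            ),
            "nu_nx": config.nu_nx,
            "mw_x": config.mw_x,
            "electrode_volume": config.electrode_volume,
            "electrode_psa": config.electrode_psa,
            "electrode_thickness": config.electrode_thickness,
            "n_n0": config.n_n0,
            "inoculum_g_per_l": config.inoculum_g_per_l,
        },
        "simulation": {
            "scenario": name,
            "seed": seed,
            "mu_max": params.mu_max,
            "k_n": params.k_n,
            "n_bx_max": params.n_bx_max,
            "k_det": params.k_det,
            "k_dec": params.k_dec,
            "q_p": dict(params.q_p),
            "lag_days": params.lag_days,
            "noise": params.noise,
            "sample_interval": params.sample_interval,
            "horizon": params.horizon,
        },
        "units": {"products": "mol"},
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    samples.to_csv(paths["measurements"], index=False)
    truth.to_csv(paths["ground_truth"], index=False)
    cal = REFERENCE_CALIBRATION
    od_grid = np.linspace(0.05, 1.0, 10)
    pd.DataFrame(
        {
            "od600": od_grid,
            "c_n_px_mol_per_l": cal.slope * od_grid + cal.intercept,
        }
    ).to_csv(paths["calibration"], index=False)
    return paths
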