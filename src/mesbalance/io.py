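"""Reading and writing measurement tables, calibrations, and configuration.

All tabular I/O is plain CSV (UTF-8, "." decimal). Times are days from
inoculation; concentrations are handled internally in mol/L, with g/L
accepted at the boundary and converted using the free-acid molar masses.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .balance import validate_series
from .calibration import CalibrationSet, OdNitrogenCalibration, fit_calibration
from .config import ReactorConfig
from .errors import InputError
from .stoichiometry import DEFAULT_STOICHIOMETRY, StoichiometryTable
from .synthetic_reactor import SimulationParams

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("t_days", "c_n_aq_out", "od600")
PRODUCT_COLUMNS = ("acetate", "butyrate", "hexanoate")


def read_measurements(
    path: str | Path,
    units: str = "mol",
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
) -> pd.DataFrame:
    """Read a measurement CSV into a validated, time-sorted series.

    Expected header: ``t_days,c_n_aq_out,od600[,acetate,butyrate,hexanoate]
    [,current_a]``. ``units`` declares the product concentration unit
    (``"mol"`` or ``"g"`` per litre); g/L values are converted to mol/L.
    Out-of-order rows are sorted with a warning; duplicate timestamps are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"measurement file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if len(df) == 0:
        raise InputError(f"empty measurement file: {path}")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise InputError(f"{path}: unparseable/missing value at row {row}, column {col!r}")
    if df["t_days"].duplicated().any():
        t = df.loc[df["t_days"].duplicated(), "t_days"].iloc[0]
        raise InputError(f"{path}: duplicate timestamp t={t}")
    if not df["t_days"].is_monotonic_increasing:
        logger.warning("%s: sample times out of order; sorting", path)
        df = df.sort_values("t_days", ignore_index=True)
    if units not in ("mol", "g"):
        raise InputError(f"unknown units {units!r} (expected 'mol' or 'g')")
    if units == "g":
        for p in PRODUCT_COLUMNS:
            if p in df.columns:
                df[p] = df[p] / stoich.molar_mass(p)
    validate_series(df)
    return df


def read_calibration_table(path: str | Path) -> list[tuple[float, float]]:
    """Read a 2-column calibration CSV (``od600,c_n_px_mol_per_l``)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"calibration file not found: {path}")
    df = pd.read_csv(path)
    for col in ("od600", "c_n_px_mol_per_l"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return list(zip(df["od600"].astype(float), df["c_n_px_mol_per_l"].astype(float)))


def read_calibration(path: str | Path, valid_from: float | None = None) -> OdNitrogenCalibration:
    """Fit a calibration model from a calibration table on disk."""
    return fit_calibration(read_calibration_table(path), valid_from=valid_from)


def read_config(path: str | Path) -> tuple[ReactorConfig, SimulationParams | None]:
    """Read a YAML configuration with ``reactor`` and optional ``simulation`` blocks."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "reactor" not in raw:
        raise InputError(f"{path}: expected a mapping with a 'reactor' block")
    rblock = dict(raw["reactor"])
    if isinstance(rblock.get("c_n_in"), list):
        rblock["c_n_in"] = tuple(tuple(pair) for pair in rblock["c_n_in"])
    try:
        config = ReactorConfig(**rblock)
    except TypeError as exc:
        raise InputError(f"{path}: bad reactor config: {exc}") from exc
    params = None
    if "simulation" in raw:
        sblock = {
            k: v
            for k, v in raw["simulation"].items()
            if k in SimulationParams.__dataclass_fields__
        }
        if "thresholds" in sblock:
            sblock["thresholds"] = {
                k: tuple(v) for k, v in sblock["thresholds"].items()
            }
        params = SimulationParams(**sblock)
    return config, params


def product_units(path: str | Path) -> str:
    """Product concentration unit declared in a config file (default mol)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return str(raw.get("units", {}).get("products", "mol"))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy CSV with full float precision (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
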