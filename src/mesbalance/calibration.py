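"""Linear calibration of optical density to planktonic-cell nitrogen.

The nitrogen content of suspended cells, c_N-pX (mol/L), is obtained from the
optical density at 600 nm through an ordinary least-squares line

    c_N-pX = slope * OD600 + intercept

fitted to dilution-series measurements of cells of known total nitrogen
content. Predictions are clamped at zero from below: a slightly negative
intercept would otherwise yield negative nitrogen at very low OD, which is
non-physical.

Because the OD-to-biomass relationship can drift over a long run, several
dated calibrations may be held in a :class:`CalibrationSet`; for a sample at
time t the nearest calibration fitted at or before t applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InputError

#: Reference calibration line commonly used for mixed-culture MES catholyte:
#: slope 0.0052 mol-N/L per OD unit, intercept -2e-5 mol-N/L.
REFERENCE_SLOPE = 0.0052
REFERENCE_INTERCEPT = -0.00002


@dataclass(frozen=True)
class OdNitrogenCalibration:
    """A fitted OD600 -> mol-N/L line with fit diagnostics.

    Attributes
    ----------
    slope : float
        mol-N/L per OD unit.
    intercept : float
        mol-N/L at OD 0 (may be slightly negative; predictions are clamped).
    r_squared : float
        Coefficient of determination of the fit, in [0, 1].
    n_points : int
        Number of calibration points used.
    valid_from : float or None
        Day from which this calibration applies (None: always).
    """

    slope: float
    intercept: float
    r_squared: float = 1.0
    n_points: int = 2
    valid_from: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InputError("a fitted calibration needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InputError("r_squared must lie in [0, 1]")

    def predict(self, od600):
        """Nitrogen in planktonic cells (mol/L) at the given OD600, clamped >= 0."""
        od = np.asarray(od600, dtype=float)
        if np.any(od < 0):
            raise InputError("od600 must be non-negative")
        out = np.maximum(0.0, self.slope * od + self.intercept)
        return float(out) if np.isscalar(od600) else out


#: The reference line as a ready-made model.
REFERENCE_CALIBRATION = OdNitrogenCalibration(
    slope=REFERENCE_SLOPE, intercept=REFERENCE_INTERCEPT, r_squared=0.9989, n_points=10
)


def fit_calibration(
    points: Iterable[tuple[float, float]], valid_from: float | None = None
) -> OdNitrogenCalibration:
    """Fit the OD600 -> c_N-pX line by ordinary least squares.

    Parameters
    ----------
    points
        Pairs ``(od600, c_n_px_mol_per_l)``.
    valid_from
        Optional day from which the calibration applies.

    Returns
    -------
    OdNitrogenCalibration
        Slope, intercept (both fitted; the intercept is never forced to 0),
        and the coefficient of determination.
    """
    pts = [(float(o), float(c)) for o, c in points]
    if len(pts) < 2:
        raise InputError("calibration needs at least 2 points")
    od = np.array([p[0] for p in pts])
    cn = np.array([p[1] for p in pts])
    if np.ptp(od) == 0.0:
        raise InputError("degenerate calibration: all OD values identical")
    res = stats.linregress(od, cn)
    # linregress r is undefined when y has zero variance (perfect flat line);
    # a flat response is fit exactly, so report R^2 = 1 there.
    ss_tot = float(np.sum((cn - cn.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        pred = res.slope * od + res.intercept
        r2 = 1.0 - float(np.sum((cn - pred) ** 2)) / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return OdNitrogenCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(pts),
        valid_from=valid_from,
    )


def predict_planktonic_nitrogen(model: OdNitrogenCalibration, od600):
    """Functional alias for :meth:`OdNitrogenCalibration.predict`."""
    return model.predict(od600)


class CalibrationSet:
    """A collection of dated calibrations; nearest-preceding model wins.

    Models with ``valid_from=None`` act as a fallback valid from the start of
    the run. At least one model must be applicable to every sample time.
    """

    def __init__(self, models: Sequence[OdNitrogenCalibration]):
        if not models:
            raise InputError("CalibrationSet needs at least one model")
        key = lambda m: -np.inf if m.valid_from is None else m.valid_from
        self._models = sorted(models, key=key)

    def model_for(self, t: float) -> OdNitrogenCalibration:
        chosen = None
        for m in self._models:
            start = -np.inf if m.valid_from is None else m.valid_from
            if start <= t:
                chosen = m
            else:
                break
        if chosen is None:
            raise InputError(f"no calibration valid at t={t}")
        return chosen

    def predict(self, t: float, od600: float) -> float:
        return self.model_for(t).predict(od600)

    def __iter__(self):
        return iter(self._models)

    def __len__(self) -> int:
        return len(self._models)


def as_calibration_set(
    calib: OdNitrogenCalibration | CalibrationSet,
) -> CalibrationSet:
    if isinstance(calib, CalibrationSet):
        return calib
    return CalibrationSet([calib])
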