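"""Linear signal-to-mass calibration A = k S + b.

The NMR amplitude S (volts) of an oil or water pool is proportional to
its proton mass; reference standards of known mass fix the slope k
(mg/V) and the small instrument background b (mg) by ordinary least
squares of mass on signal. Any fixed multiplicative bias on the signals
(e.g. the uncorrected oil decay factor exp(-TE/T2_oil) of single-echo
decomposition) is absorbed into k as long as the standards are measured
the same way.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationModel",
    "SignalMassCalibration",
    "fit_calibration",
    "apply_calibration",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted signal-to-mass line: mass_mg = k * signal_v + b."""

    k_mg_per_v: float
    b_mg: float
    r_squared: float
    n_points: int
    timestamp: str | None = None  # provenance only

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


class SignalMassCalibration(RegressorMixin, BaseEstimator):
    """OLS regression of standard mass (mg) on NMR signal (V).

    The regression direction follows the calibration law A = kS + b:
    mass is the response, signal the regressor. No weighting is applied.

    Attributes
    ----------
    k_ : float
        Slope, mg per volt.
    b_ : float
        Intercept (instrument background), mg.
    r_squared_ : float
    n_points_ : int
    """

    def fit(self, signals_v, masses_mg) -> "SignalMassCalibration":
        s = np.asarray(signals_v, dtype=float).ravel()
        m = np.asarray(masses_mg, dtype=float).ravel()
        if s.size != m.size:
            raise ValueError("signals and masses must have equal length")
        if s.size < 2 or np.unique(s).size < 2:
            raise ValueError("need at least 2 distinct signal values")
        res = stats.linregress(s, m)
        self.k_ = float(res.slope)
        self.b_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_points_ = int(s.size)
        return self

    def predict(self, signals_v) -> np.ndarray:
        s = np.asarray(signals_v, dtype=float)
        if np.any(s < 0):
            raise ValueError("signal must be >= 0")
        mass = self.k_ * s + self.b_
        if np.any(mass < 0):
            warnings.warn("negative calibrated mass; clipping to 0", stacklevel=2)
            mass = np.clip(mass, 0.0, None)
        return mass

    def to_model(self) -> CalibrationModel:
        return CalibrationModel(
            k_mg_per_v=self.k_,
            b_mg=self.b_,
            r_squared=self.r_squared_,
            n_points=self.n_points_,
        )


def fit_calibration(signals_v, masses_mg) -> CalibrationModel:
    """Least-squares fit of the calibration line from standards."""
    return SignalMassCalibration().fit(signals_v, masses_mg).to_model()


def apply_calibration(model: CalibrationModel, signal_v: float) -> float:
    """Convert a signal amplitude to a mass, mass = k*S + b (clipped at 0)."""
    if np.any(np.asarray(signal_v) < 0):
        raise ValueError("signal must be >= 0")
    mass = model.k_mg_per_v * np.asarray(signal_v, dtype=float) + model.b_mg
    clipped = np.clip(mass, 0.0, None)
    if np.any(mass < 0):
        warnings.warn("negative calibrated mass; clipping to 0", stacklevel=2)
    return float(clipped) if np.isscalar(signal_v) else clipped
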