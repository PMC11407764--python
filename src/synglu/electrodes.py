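"""Ion-selective microelectrode calibration and trace conversion.

Cation-selective microelectrodes (K+ or TMA+) are calibrated against
concentration standards. Over the Nernstian range the electrode voltage is
V = E0 + s log10(c); in the low sub-millimolar range real electrodes depart
from that, which the Nicolsky-Eisenman form captures with a single apparent
interfering-background term: V = E0 + s log10(c + c_int). Activities are
approximated by concentrations throughout (calibration standards are defined
by concentration); this is a documented limitation.

Also implements the electrode quality-control rule (a ten-fold concentration
step must elicit a voltage response strictly greater than 50 mV) and the
extraction of peak concentration increases from recorded traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import FARADAY, R_GAS

__all__ = [
    "CalibrationPoint",
    "ElectrodeCalibration",
    "IonTrace",
    "nernst_slope",
    "fit_calibration",
    "voltage_to_concentration",
    "concentration_to_voltage",
    "electrode_qc",
    "max_delta",
]


@dataclass(frozen=True)
class CalibrationPoint:
    concentration_mM: float
    voltage_mV: float

    def __post_init__(self) -> None:
        if self.concentration_mM <= 0:
            raise ValueError("calibration concentration must be positive")


@dataclass(frozen=True)
class ElectrodeCalibration:
    """Fitted electrode response parameters.

    model : 'nernst' (V = E0 + s log10 c) or 'nicolsky_eisenman'
        (V = E0 + s log10(c + interference)).
    """

    model: Literal["nernst", "nicolsky_eisenman"]
    E0_mV: float
    slope_mV_per_decade: float
    interference_mM: float = 0.0
    temperature_K: float = 307.15

    def __post_init__(self) -> None:
        if self.slope_mV_per_decade <= 0:
            raise ValueError("cation electrode slope must be positive")
        if self.interference_mM < 0:
            raise ValueError("interference must be non-negative")


@dataclass
class IonTrace:
    """A time series of electrode voltage or converted ion concentration."""

    time_s: np.ndarray
    value: np.ndarray
    kind: Literal["voltage_mV", "concentration_mM"]
    ischemia_window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape or self.time_s.ndim != 1:
            raise ValueError("time and value must be equal-length 1-D arrays")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.kind not in ("voltage_mV", "concentration_mM"):
            raise ValueError("kind must be 'voltage_mV' or 'concentration_mM'")


def nernst_slope(temperature_K: float, valence: int = 1) -> float:
    """Ideal Nernst slope, mV per ten-fold concentration change."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    return math.log(10.0) * R_GAS * temperature_K / (valence * FARADAY) * 1000.0


def fit_calibration(
    points: Sequence[CalibrationPoint],
    model: Literal["nernst", "nicolsky_eisenman"] = "nernst",
    temperature_K: float = 307.15,
) -> ElectrodeCalibration:
    """Least-squares fit of the electrode response to calibration points.

    The Nernst model needs >= 2 points, Nicolsky-Eisenman >= 3 (it adds the
    interference term). All points at the same concentration raise a
    singular-fit error.
    """
    needed = 2 if model == "nernst" else 3
    if len(points) < needed:
        raise ValueError(f"{model} calibration needs at least {needed} points")
    c = np.array([p.concentration_mM for p in points])
    v = np.array([p.voltage_mV for p in points])
    if np.allclose(c, c[0]):
        raise np.linalg.LinAlgError("degenerate calibration: all concentrations equal")

    if model == "nernst":
        slope, e0 = np.polyfit(np.log10(c), v, 1)
        return ElectrodeCalibration("nernst", float(e0), float(slope), 0.0, temperature_K)

    if model != "nicolsky_eisenman":
        raise ValueError(f"unknown calibration model {model!r}")

    # start from the Nernst solution with zero interference
    slope0, e00 = np.polyfit(np.log10(c), v, 1)

    def resid(p: np.ndarray) -> np.ndarray:
        e0, slope, c_int = p
        return e0 + slope * np.log10(c + c_int) - v

    sol = least_squares(
        resid,
        [e00, max(slope0, 1.0), 0.01],
        bounds=([-np.inf, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    e0, slope, c_int = sol.x
    return ElectrodeCalibration(
        "nicolsky_eisenman", float(e0), float(slope), float(c_int), temperature_K
    )


def concentration_to_voltage(c_mM: np.ndarray | float, cal: ElectrodeCalibration) -> np.ndarray | float:
    """Forward calibration model: concentration -> electrode voltage (mV)."""
    c = np.asarray(c_mM, dtype=float)
    eff = c + cal.interference_mM if cal.model == "nicolsky_eisenman" else c
    if np.any(eff <= 0):
        raise ValueError("effective concentration must be positive")
    out = cal.E0_mV + cal.slope_mV_per_decade * np.log10(eff)
    return out if np.ndim(c_mM) else float(out)


def voltage_to_concentration(
    v_mV: np.ndarray | float, cal: ElectrodeCalibration
) -> np.ndarray | float:
    """Exact analytic inversion of the calibration model.

    The Nicolsky-Eisenman inverse can fall below zero for voltages beneath
    the interference floor; such samples are clamped to zero concentration
    with a warning reporting how many were affected.
    """
    v = np.asarray(v_mV, dtype=float)
    c = 10.0 ** ((v - cal.E0_mV) / cal.slope_mV_per_decade)
    if cal.model == "nicolsky_eisenman":
        c = c - cal.interference_mM
        n_clamped = int(np.sum(c < 0))
        if n_clamped:
            warnings.warn(
                f"{n_clamped} sample(s) below the interference floor clamped to 0 mM",
                RuntimeWarning,
                stacklevel=2,
            )
            c = np.clip(c, 0.0, None)
    return c if np.ndim(v_mV) else float(c)


def electrode_qc(
    point_low: CalibrationPoint,
    point_high: CalibrationPoint,
    threshold_mV: float = 50.0,
) -> bool:
    """Electrode acceptance rule for a ten-fold concentration step.

    Pass iff the voltage response to the 10x increase is strictly greater
    than the threshold (default 50 mV). Non-decade pairs are rejected.
    """
    ratio = point_high.concentration_mM / point_low.concentration_mM
    if not math.isclose(ratio, 10.0, rel_tol=1e-6):
        raise ValueError("QC rule requires exactly a ten-fold concentration pair")
    return (point_high.voltage_mV - point_low.voltage_mV) > threshold_mV


def max_delta(
    trace: IonTrace,
    window_s: tuple[float, float] | None = None,
    baseline_duration_s: float = 60.0,
) -> float:
    """Maximum concentration increase over a window, relative to baseline.

    Baseline is the trace mean over ``baseline_duration_s`` immediately
    preceding the window (the ischemia window by default).
    """
    if trace.kind != "concentration_mM":
        raise ValueError("max_delta requires a concentration-kind trace")
    if window_s is None:
        window_s = trace.ischemia_window_s
    if window_s is None:
        raise ValueError("no window given and trace carries no ischemia window")
    w0, w1 = window_s
    t = trace.time_s
    in_win = (t >= w0) & (t <= w1)
    if not np.any(in_win):
        raise ValueError("window contains no samples")
    pre = (t >= w0 - baseline_duration_s) & (t < w0)
    if not np.any(pre):
        raise ValueError("no samples in the pre-window baseline interval")
    baseline = float(np.mean(trace.value[pre]))
    return float(np.max(trace.value[in_win]) - baseline)
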