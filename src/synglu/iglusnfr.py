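"""iGluSnFR line-scan analysis.

Two-photon line scans (position x time, 378.8 Hz default) across an
iGluSnFR-expressing astrocyte report extracellular glutamate transients
evoked by paired synaptic stimulation. Repeats (4-6 per time point) are
averaged, the background fluorescence is subtracted, and the signal is
normalized to the pre-stimulus resting fluorescence F0 to give dF/F0.
Per-pulse peak amplitudes, the paired-pulse ratio (with the first pulse's
extrapolated exponential tail subtracted under the second), and the
mono-exponential decay time constant of the stimulus-locked transient are
extracted; the decay tau indexes glutamate clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LineScan",
    "GluTransient",
    "UnusableScanError",
    "average_repeats",
    "compute_dff",
    "fit_decay",
    "transient_ppr",
]

DEFAULT_SCAN_RATE_HZ = 378.8
DEFAULT_PEAK_WINDOW_MS = 30.0
DEFAULT_DECAY_WINDOW_MS = 500.0


class UnusableScanError(RuntimeError):
    """Raised when the background-corrected resting fluorescence is not positive."""


@dataclass
class LineScan:
    """One line scan: fluorescence[position, time] plus scan geometry."""

    fluorescence: np.ndarray
    scan_rate_hz: float = DEFAULT_SCAN_RATE_HZ
    roi: tuple[int, int] = (0, 0)
    background_roi: tuple[int, int] = (0, 0)
    stimulus_times_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be a 2-D (position x time) array")
        if self.scan_rate_hz <= 0:
            raise ValueError("scan rate must be positive")
        npos = self.fluorescence.shape[0]
        for name, (a, b) in (("roi", self.roi), ("background_roi", self.background_roi)):
            if not (0 <= a < b <= npos):
                raise ValueError(f"{name} {a, b} outside the position axis (0..{npos})")
        r, bg = self.roi, self.background_roi
        if max(r[0], bg[0]) < min(r[1], bg[1]):
            raise ValueError("signal and background ROIs must be disjoint")

    @classmethod
    def from_tiff(cls, path, **kwargs) -> "LineScan":
        """Load a position x time TIFF line scan (metadata via kwargs)."""
        import tifffile

        return cls(tifffile.imread(path), **kwargs)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.fluorescence.shape[1]) / self.scan_rate_hz


@dataclass
class GluTransient:
    """Background-corrected, normalized glutamate transient of one time point."""

    time_s: np.ndarray
    f0: float
    dff: np.ndarray
    peak_amplitudes: tuple[float, ...]
    stimulus_times_s: tuple[float, ...]
    scan_rate_hz: float
    n_averaged: int = 1
    decay_tau_ms: float | None = None
    decay_converged: bool = False


def average_repeats(scans: Sequence[LineScan]) -> LineScan:
    """Element-wise mean of repeated line scans (identical shape and rate)."""
    if not scans:
        raise ValueError("no scans given")
    first = scans[0]
    for s in scans[1:]:
        if s.fluorescence.shape != first.fluorescence.shape:
            raise ValueError("all repeats must share the same shape")
        if not math.isclose(s.scan_rate_hz, first.scan_rate_hz, rel_tol=1e-9):
            raise ValueError("all repeats must share the same scan rate")
    mean = np.mean([s.fluorescence for s in scans], axis=0)
    out = LineScan(
        mean,
        scan_rate_hz=first.scan_rate_hz,
        roi=first.roi,
        background_roi=first.background_roi,
        stimulus_times_s=first.stimulus_times_s,
    )
    out.n_averaged = len(scans)  # type: ignore[attr-defined]
    return out


def compute_dff(
    scan: LineScan,
    baseline_window_s: tuple[float, float],
    peak_window_ms: float = DEFAULT_PEAK_WINDOW_MS,
) -> GluTransient:
    """Background-subtract, normalize to F0 and measure per-pulse peaks.

    signal(t) = ROI mean - background-ROI mean; F0 = signal mean over the
    pre-stimulus baseline window; dF/F0 = (signal - F0)/F0. A non-positive F0
    marks the scan unusable (fluorescence undetectable).
    """
    t = scan.time_s
    if scan.stimulus_times_s and baseline_window_s[1] > min(scan.stimulus_times_s):
        raise ValueError("baseline window must precede the first stimulus")
    sig = scan.fluorescence[scan.roi[0] : scan.roi[1]].mean(axis=0)
    bg = scan.fluorescence[scan.background_roi[0] : scan.background_roi[1]].mean(axis=0)
    signal = sig - bg
    in_base = (t >= baseline_window_s[0]) & (t <= baseline_window_s[1])
    if not np.any(in_base):
        raise ValueError("baseline window contains no samples")
    f0 = float(np.mean(signal[in_base]))
    if f0 <= 0:
        raise UnusableScanError("non-positive resting fluorescence after background subtraction")
    dff = (signal - f0) / f0

    peaks = []
    for t_stim in scan.stimulus_times_s:
        win = (t >= t_stim) & (t <= t_stim + peak_window_ms * 1e-3)
        peaks.append(float(np.max(dff[win])) if np.any(win) else math.nan)

    return GluTransient(
        time_s=t,
        f0=f0,
        dff=dff,
        peak_amplitudes=tuple(peaks),
        stimulus_times_s=tuple(scan.stimulus_times_s),
        scan_rate_hz=scan.scan_rate_hz,
        n_averaged=getattr(scan, "n_averaged", 1),
    )


def _mono_exp(t: np.ndarray, a: float, tau: float, c: float) -> np.ndarray:
    return a * np.exp(-t / tau) + c


def _fit_exp_segment(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Fit A exp(-t/tau) + c on a segment (t relative to its first sample, s)."""
    a0 = max(y[0] - y[-1], 1e-6)
    tau0 = max((t_s[-1] - t_s[0]) / 3.0, 1e-4)
    try:
        popt, _ = curve_fit(
            _mono_exp,
            t_s,
            y,
            p0=[a0, tau0, y[-1]],
            maxfev=20000,
        )
    except RuntimeError:
        return math.nan, math.nan, math.nan, False
    a, tau, c = popt
    return float(a), float(tau), float(c), True


def fit_decay(
    transient: GluTransient,
    pulse_index: int = 1,
    fit_window_ms: float = DEFAULT_DECAY_WINDOW_MS,
) -> GluTransient:
    """Mono-exponential decay time constant of one pulse's transient.

    The fit runs from the post-peak sample of the chosen pulse (default: the
    second pulse) over ``fit_window_ms``; the offset is fitted, not fixed at
    zero. tau is reported in ms on the returned (mutated) transient; values
    outside (1 ms, 10 s) or non-convergent fits leave the flag unset.
    """
    if pulse_index >= len(transient.stimulus_times_s):
        raise ValueError("pulse index outside the stimulus list")
    t = transient.time_s
    t_stim = transient.stimulus_times_s[pulse_index]
    win_peak = (t >= t_stim) & (t <= t_stim + DEFAULT_PEAK_WINDOW_MS * 1e-3)
    i_peak = np.nonzero(win_peak)[0][int(np.argmax(transient.dff[win_peak]))]
    sel = (np.arange(len(t)) > i_peak) & (t <= t[i_peak] + fit_window_ms * 1e-3)
    if sel.sum() < 4:
        raise ValueError("decay window contains too few samples")
    tt = t[sel] - t[i_peak]
    a, tau_s, c, ok = _fit_exp_segment(tt, transient.dff[sel])
    tau_ms = tau_s * 1e3 if ok else math.nan
    transient.decay_tau_ms = tau_ms
    transient.decay_converged = bool(ok and 1.0 < tau_ms < 1e4)
    return transient


def transient_ppr(
    transient: GluTransient,
    subtract_residual: bool = True,
) -> float:
    """Paired-pulse ratio of peak dF/F0, pulse 2 over pulse 1.

    With ``subtract_residual`` (default) the first pulse's decay is fitted
    with a mono-exponential and its extrapolated tail subtracted under the
    second pulse before the second peak is measured (the 50 ms interstimulus
    interval makes the transients overlap). Undefined (NaN) when the first
    peak is ~0.
    """
    if len(transient.stimulus_times_s) < 2:
        raise ValueError("need two resolved pulses for a PPR")
    t = transient.time_s
    s1, s2 = transient.stimulus_times_s[:2]
    p1 = transient.peak_amplitudes[0]
    if not np.isfinite(p1) or p1 <= 1e-9:
        return math.nan

    win2 = (t >= s2) & (t <= s2 + DEFAULT_PEAK_WINDOW_MS * 1e-3)
    dff2 = transient.dff[win2].copy()
    if subtract_residual:
        win1 = (t >= s1) & (t <= s1 + DEFAULT_PEAK_WINDOW_MS * 1e-3)
        i_pk1 = np.nonzero(win1)[0][int(np.argmax(transient.dff[win1]))]
        between = (np.arange(len(t)) > i_pk1) & (t < s2)
        if between.sum() >= 4:
            tt = t[between] - t[i_pk1]
            a, tau_s, c, ok = _fit_exp_segment(tt, transient.dff[between])
            if ok and tau_s > 0:
                tail = _mono_exp(t[win2] - t[i_pk1], a, tau_s, 0.0)
                dff2 = dff2 - tail
    p2 = float(np.max(dff2))
    return p2 / p1
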