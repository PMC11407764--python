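"""Extracellular field-potential sweep analysis.

Paired-pulse sweeps (two stimuli 50 ms apart, digitized at 10 kHz) contain,
per stimulus: a fast biphasic stimulus artifact, the axonal fiber volley (FV,
a brief negative deflection reflecting compound action-potential firing) and
the field EPSP (fEPSP), whose initial slope indexes synaptic strength.

This module extracts per-sweep metrics (FV amplitude / half width at half
maximum / delay, fEPSP slope, paired-pulse ratio), normalizes experiment
time courses to a baseline epoch, and classifies the post-ischemia outcome:
an episode counts as postsynaptic failure when the normalized fEPSP slope
does not recover to strictly above 50% of baseline in the end epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sweep",
    "SweepMetrics",
    "ExperimentTimeline",
    "EpisodeOutcome",
    "fiber_volley_metrics",
    "fepsp_slope",
    "analyze_sweep",
    "paired_pulse_ratio",
    "normalize_to_baseline",
    "classify_outcome",
]

#: analysis windows (ms after each stimulus); configurable per call
DEFAULT_ARTIFACT_BLANK_MS = 0.5
DEFAULT_FV_WINDOW_MS = (0.5, 3.0)
DEFAULT_FEPSP_WINDOW_MS = (2.5, 20.0)
DEFAULT_SLOPE_FRACTIONS = (0.2, 0.8)


@dataclass
class Sweep:
    """One paired-pulse field-potential sweep."""

    voltage_mV: np.ndarray
    sampling_rate_hz: float = 10000.0
    stimulus_times_s: tuple[float, float] = (0.05, 0.10)
    artifact_blank_ms: float = DEFAULT_ARTIFACT_BLANK_MS

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        dur = len(self.voltage_mV) / self.sampling_rate_hz
        if any(not 0 <= s < dur for s in self.stimulus_times_s):
            raise ValueError("stimulus times must fall inside the trace")
        isi = self.stimulus_times_s[1] - self.stimulus_times_s[0]
        if not math.isclose(isi, 0.05, rel_tol=1e-6):
            raise ValueError("paired-pulse protocol requires a 50 ms interstimulus interval")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.voltage_mV)) / self.sampling_rate_hz

    def index_at(self, t_s: float) -> int:
        return int(round(t_s * self.sampling_rate_hz))


@dataclass
class SweepMetrics:
    """Per-pulse metrics of one sweep; NaN plus flag when detection fails."""

    fv_amplitude_mV: tuple[float, float]
    fv_hwhm_ms: tuple[float, float]
    fv_delay_ms: tuple[float, float]
    fepsp_slope_mV_ms: tuple[float, float]
    ppr: float
    fv_missing: tuple[bool, bool] = (False, False)
    low_confidence: tuple[bool, bool] = (False, False)


def _pre_stimulus_baseline(sweep: Sweep) -> tuple[float, float]:
    """Baseline level and robust noise sigma from the pre-stimulus segment."""
    i0 = sweep.index_at(sweep.stimulus_times_s[0])
    seg = sweep.voltage_mV[: max(i0, 2)]
    baseline = float(np.median(seg))
    mad = float(np.median(np.abs(seg - baseline)))
    return baseline, 1.4826 * mad


def _half_crossings(t_ms: np.ndarray, v: np.ndarray, i_peak: int, level: float) -> tuple[float, float] | None:
    """Linearly interpolated crossings of ``level`` on both flanks of a trough."""
    left = None
    for i in range(i_peak, 0, -1):
        if v[i - 1] >= level >= v[i]:
            frac = (level - v[i - 1]) / (v[i] - v[i - 1])
            left = t_ms[i - 1] + frac * (t_ms[i] - t_ms[i - 1])
            break
    right = None
    for i in range(i_peak, len(v) - 1):
        if v[i] <= level <= v[i + 1]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            right = t_ms[i] + frac * (t_ms[i + 1] - t_ms[i])
            break
    if left is None or right is None:
        return None
    return left, right


def fiber_volley_metrics(
    sweep: Sweep,
    pulse_index: int = 0,
    search_window_ms: tuple[float, float] = DEFAULT_FV_WINDOW_MS,
) -> tuple[float, float, float, bool]:
    """FV amplitude (mV), half width at half maximum (ms), delay (ms), missing flag.

    The FV is the first negative deflection in the post-artifact search
    window; a trough shallower than 3x the robust pre-stimulus noise is
    reported missing. The HWHM is half the interpolated full width at half
    amplitude; the delay runs from stimulus onset to the trough.
    """
    t_stim = sweep.stimulus_times_s[pulse_index]
    baseline, sigma = _pre_stimulus_baseline(sweep)
    lo = sweep.index_at(t_stim + search_window_ms[0] * 1e-3)
    hi = sweep.index_at(t_stim + search_window_ms[1] * 1e-3) + 1
    seg = sweep.voltage_mV[lo:hi]
    if len(seg) < 3:
        raise ValueError("search window contains too few samples")
    i_rel = int(np.argmin(seg))
    depth = baseline - seg[i_rel]
    if depth <= 3.0 * max(sigma, 1e-12):
        return math.nan, math.nan, math.nan, True

    i_peak = lo + i_rel
    t_ms = (sweep.time_s - t_stim) * 1e3
    half_level = baseline - depth / 2.0
    # widen the crossing search slightly beyond the window for the right flank
    hi_ext = min(hi + len(seg), len(sweep.voltage_mV))
    crossings = _half_crossings(t_ms[lo - 1 : hi_ext], sweep.voltage_mV[lo - 1 : hi_ext], i_peak - (lo - 1), half_level)
    if crossings is None:
        return float(depth), math.nan, float(t_ms[i_peak]), False
    fwhm = crossings[1] - crossings[0]
    return float(depth), float(fwhm / 2.0), float(t_ms[i_peak]), False


def fepsp_slope(
    sweep: Sweep,
    pulse_index: int = 0,
    fit_fraction_range: tuple[float, float] = DEFAULT_SLOPE_FRACTIONS,
    window_ms: tuple[float, float] = DEFAULT_FEPSP_WINDOW_MS,
) -> tuple[float, bool]:
    """Initial fEPSP slope (mV/ms, magnitude of the negative-going phase).

    A straight line is fitted over the samples of the rising (negative-going)
    phase whose amplitude lies between the configured fractions (default
    20-80%) of the trough amplitude. Returns (slope, low_confidence); a trace
    without a resolvable fEPSP yields slope 0 with the flag set. Fewer than 4
    samples in the fit range raise an insufficient-data error.
    """
    lo_f, hi_f = fit_fraction_range
    if not 0.0 <= lo_f < hi_f <= 1.0:
        raise ValueError("fit fractions must satisfy 0 <= lo < hi <= 1")
    t_stim = sweep.stimulus_times_s[pulse_index]
    baseline, sigma = _pre_stimulus_baseline(sweep)
    lo = sweep.index_at(t_stim + window_ms[0] * 1e-3)
    hi = sweep.index_at(t_stim + window_ms[1] * 1e-3) + 1
    seg = sweep.voltage_mV[lo:hi]
    i_trough = int(np.argmin(seg))
    depth = baseline - seg[i_trough]
    if depth <= 3.0 * max(sigma, 1e-12):
        return 0.0, True

    frac = (baseline - seg[: i_trough + 1]) / depth
    sel = np.nonzero((frac >= lo_f) & (frac <= hi_f))[0]
    # keep the contiguous run ending at the trough side (the rising phase)
    if len(sel) >= 2:
        breaks = np.nonzero(np.diff(sel) > 1)[0]
        if len(breaks):
            sel = sel[breaks[-1] + 1 :]
    if len(sel) < 4:
        raise ValueError("fewer than 4 samples in the slope fit range")
    t_ms = (np.arange(lo, lo + i_trough + 1) / sweep.sampling_rate_hz - t_stim) * 1e3
    coeff = np.polyfit(t_ms[sel], seg[sel], 1)
    return float(abs(coeff[0])), False


def paired_pulse_ratio(metric_pulse1: float, metric_pulse2: float) -> float:
    """PPR = pulse2 / pulse1; NaN (undefined) when pulse 1 is ~0."""
    if not np.isfinite(metric_pulse1) or abs(metric_pulse1) < 1e-12:
        return math.nan
    return metric_pulse2 / metric_pulse1


def analyze_sweep(
    sweep: Sweep,
    fv_window_ms: tuple[float, float] = DEFAULT_FV_WINDOW_MS,
    fepsp_window_ms: tuple[float, float] = DEFAULT_FEPSP_WINDOW_MS,
    fit_fraction_range: tuple[float, float] = DEFAULT_SLOPE_FRACTIONS,
) -> SweepMetrics:
    """All per-sweep metrics for both pulses, PPR on the fEPSP slope."""
    fv, hw, dl, miss, slopes, lowc = [], [], [], [], [], []
    for p in (0, 1):
        a, h, d, m = fiber_volley_metrics(sweep, p, fv_window_ms)
        fv.append(a), hw.append(h), dl.append(d), miss.append(m)
        try:
            s, flag = fepsp_slope(sweep, p, fit_fraction_range, fepsp_window_ms)
        except ValueError:
            s, flag = math.nan, True
        slopes.append(s), lowc.append(flag)
    return SweepMetrics(
        fv_amplitude_mV=(fv[0], fv[1]),
        fv_hwhm_ms=(hw[0], hw[1]),
        fv_delay_ms=(dl[0], dl[1]),
        fepsp_slope_mV_ms=(slopes[0], slopes[1]),
        ppr=paired_pulse_ratio(slopes[0], slopes[1]),
        fv_missing=(miss[0], miss[1]),
        low_confidence=(lowc[0], lowc[1]),
    )


@dataclass
class ExperimentTimeline:
    """Per-sweep metrics across one experiment (one sweep every 20 s)."""

    sweep_times_s: np.ndarray
    metrics: Sequence[SweepMetrics]
    baseline_epoch_s: tuple[float, float] = (0.0, 600.0)
    end_epoch_s: tuple[float, float] | None = None
    ischemia_window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.sweep_times_s = np.asarray(self.sweep_times_s, dtype=float)
        if len(self.sweep_times_s) != len(self.metrics):
            raise ValueError("one metrics entry per sweep time required")
        if self.end_epoch_s is None:
            t_last = float(self.sweep_times_s[-1])
            self.end_epoch_s = (t_last - 600.0, t_last)
        if self.ischemia_window_s is not None:
            if self.ischemia_window_s[0] < self.baseline_epoch_s[1]:
                raise ValueError("baseline epoch must precede the ischemia window")

    def metric_series(self, name: str, pulse_index: int = 0) -> np.ndarray:
        vals = []
        for m in self.metrics:
            v = getattr(m, name)
            vals.append(v[pulse_index] if isinstance(v, tuple) else v)
        return np.asarray(vals, dtype=float)


@dataclass
class EpisodeOutcome:
    """End/baseline ratios and the threshold classification of one episode."""

    fepsp_end_over_baseline: float
    fv_end_over_baseline: float | None
    classification: Literal["recovered", "failure"]


def normalize_to_baseline(
    timeline: ExperimentTimeline,
    metric_names: Sequence[str] = ("fepsp_slope_mV_ms", "fv_amplitude_mV"),
    pulse_index: int = 0,
    min_baseline_sweeps: int = 10,
) -> pd.DataFrame:
    """Each metric divided by its baseline-epoch mean.

    The baseline mean of the returned normalized series is exactly 1.
    """
    t = timeline.sweep_times_s
    b0, b1 = timeline.baseline_epoch_s
    in_base = (t >= b0) & (t < b1)
    if in_base.sum() < min_baseline_sweeps:
        raise ValueError(f"need at least {min_baseline_sweeps} baseline sweeps")
    out = {"time_s": t}
    for name in metric_names:
        series = timeline.metric_series(name, pulse_index)
        base = np.nanmean(series[in_base])
        if not np.isfinite(base) or base == 0.0:
            raise ValueError(f"zero or undefined baseline mean for {name}")
        out[name] = series / base
    return pd.DataFrame(out)


def classify_outcome(
    normalized: pd.DataFrame,
    end_epoch_s: tuple[float, float],
    threshold: float = 0.5,
    fepsp_column: str = "fepsp_slope_mV_ms",
    fv_column: str = "fv_amplitude_mV",
) -> EpisodeOutcome:
    """Postsynaptic-failure classification from the normalized fEPSP course.

    failure iff the end-epoch mean of the normalized fEPSP slope is <=
    threshold (the response did not recover to strictly above 50% of
    baseline); otherwise recovered.
    """
    t = normalized["time_s"].to_numpy()
    in_end = (t >= end_epoch_s[0]) & (t <= end_epoch_s[1])
    if not np.any(in_end):
        raise ValueError("end epoch contains no sweeps")
    fepsp_ratio = float(np.nanmean(normalized[fepsp_column].to_numpy()[in_end]))
    fv_ratio = (
        float(np.nanmean(normalized[fv_column].to_numpy()[in_end]))
        if fv_column in normalized
        else None
    )
    label: Literal["recovered", "failure"] = "failure" if fepsp_ratio <= threshold else "recovered"
    return EpisodeOutcome(fepsp_ratio, fv_ratio, label)
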