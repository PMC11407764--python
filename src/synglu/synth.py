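"""Seeded synthetic-data generators.

Every generator emulates the statistical structure one analysis stage
assumes — electrode calibration curves, TMA+ iontophoresis transients,
paired-pulse field-potential sweeps, whole chemical-ischemia experiments
with extracellular K+ transients, and iGluSnFR line scans — and always
returns its exact ground truth alongside the data, so that every analyzer
can be validated by round trip without any recorded data.

Scenario effect magnitudes (potentiation factor, failure residual, K+ peak
sizes) are package defaults chosen well inside the outcome-classifier
margins; they are not claimed to equal experimentally measured effect sizes.
Noise models: additive Gaussian for voltages, multiplicative Gaussian for
TMA concentrations, per-pixel Gaussian for fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np

from .ecs import DEFAULT_D_FREE_CM2_S, RtiSourceParams, TissueParams, TmaCurve, rti_forward
from .electrodes import CalibrationPoint, ElectrodeCalibration, IonTrace, concentration_to_voltage
from .ephys import ExperimentTimeline, Sweep, analyze_sweep
from .iglusnfr import DEFAULT_SCAN_RATE_HZ, LineScan

__all__ = [
    "GeneratorSpec",
    "TISSUE_SCENARIOS",
    "gen_calibration_points",
    "gen_tma_curve",
    "gen_sweep",
    "gen_experiment",
    "gen_linescan",
    "gen_k_trace",
    "alpha_epsp",
    "alpha_epsp_slope_oracle",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Top-level description of a synthetic data set (CLI / serialization)."""

    seed: int
    scenario: Literal["control", "ischemia", "ischemia_failure", "free_medium", "slice_like"]
    noise: dict = field(default_factory=dict)


#: tissue ground truths for the RTI scenarios: the agarose-like free medium
#: (volume fraction ~1, tortuosity ~1) and acute-slice-like tissue
#: (volume fraction 0.19, tortuosity 1.54).
TISSUE_SCENARIOS: dict[str, TissueParams] = {
    "free_medium": TissueParams(alpha=1.0, D_star_cm2_s=DEFAULT_D_FREE_CM2_S),
    "slice_like": TissueParams(alpha=0.19, D_star_cm2_s=DEFAULT_D_FREE_CM2_S / 1.54**2),
}


# --------------------------------------------------------------------------
# electrode calibration and ion traces
# --------------------------------------------------------------------------


def gen_calibration_points(
    cal: ElectrodeCalibration,
    concentrations_mM: Sequence[float],
    noise_mV: float = 0.0,
    seed: int = 0,
) -> tuple[list[CalibrationPoint], dict]:
    """Calibration points from the forward electrode model plus voltage noise."""
    if len(concentrations_mM) < 2:
        raise ValueError("need at least two calibration concentrations")
    rng = np.random.default_rng(seed)
    points = []
    for c in concentrations_mM:
        v = concentration_to_voltage(c, cal) + rng.normal(0.0, noise_mV)
        points.append(CalibrationPoint(concentration_mM=c, voltage_mV=float(v)))
    truth = {
        "model": cal.model,
        "E0_mV": cal.E0_mV,
        "slope_mV_per_decade": cal.slope_mV_per_decade,
        "interference_mM": cal.interference_mM,
        "noise_mV": noise_mV,
        "seed": seed,
    }
    return points, truth


def gen_k_trace(
    peak_delta_mM: float,
    window_s: tuple[float, float],
    baseline_mM: float = 3.0,
    duration_s: float | None = None,
    dt_s: float = 1.0,
    rise_s: float = 20.0,
    decay_s: float = 60.0,
    noise_mM: float = 0.05,
    seed: int = 0,
    calibration: ElectrodeCalibration | None = None,
) -> tuple[IonTrace, dict]:
    """Extracellular K+ transient confined to the (ischemia) window.

    The concentration rises saturatingly during the window and decays
    exponentially after it. With ``calibration`` given, the trace is returned
    in the voltage domain via the forward electrode model instead.
    """
    w0, w1 = window_s
    if duration_s is None:
        duration_s = w1 + 5.0 * decay_s
    t = np.arange(0.0, duration_s, dt_s)
    if w0 < t[0] or w1 > t[-1]:
        raise ValueError("window must lie within the trace")
    c = np.full_like(t, baseline_mM)
    during = (t >= w0) & (t <= w1)
    c[during] += peak_delta_mM * (1.0 - np.exp(-(t[during] - w0) / rise_s))
    after = t > w1
    peak_end = peak_delta_mM * (1.0 - math.exp(-(w1 - w0) / rise_s))
    c[after] += peak_end * np.exp(-(t[after] - w1) / decay_s)
    rng = np.random.default_rng(seed)
    c = c + rng.normal(0.0, noise_mM, size=c.shape)
    truth = {
        "peak_delta_mM": peak_delta_mM,
        "plateau_delta_mM": peak_end,
        "baseline_mM": baseline_mM,
        "window_s": window_s,
        "noise_mM": noise_mM,
        "seed": seed,
    }
    if calibration is not None:
        v = concentration_to_voltage(np.clip(c, 1e-6, None), calibration)
        return IonTrace(t, np.asarray(v), "voltage_mV", ischemia_window_s=window_s), truth
    return IonTrace(t, c, "concentration_mM", ischemia_window_s=window_s), truth


# --------------------------------------------------------------------------
# TMA iontophoresis transients
# --------------------------------------------------------------------------


def gen_tma_curve(
    tissue: TissueParams,
    source: RtiSourceParams | None = None,
    distance_um: float = 150.0,
    noise_frac: float = 0.02,
    baseline_mM: float = 1.0,
    duration_s: float = 120.0,
    dt_s: float = 0.25,
    seed: int = 0,
) -> tuple[TmaCurve, dict]:
    """Synthetic TMA+ transient: forward model + multiplicative noise + bath baseline."""
    source = source or RtiSourceParams()
    t = np.arange(dt_s, duration_s + dt_s / 2, dt_s)
    c = rti_forward(t, distance_um, source, tissue)
    rng = np.random.default_rng(seed)
    c_noisy = c * (1.0 + rng.normal(0.0, noise_frac, size=c.shape))
    curve = TmaCurve(
        time_s=t,
        concentration_mM=c_noisy + baseline_mM,
        distance_um=distance_um,
        source=source,
        baseline_mM=baseline_mM,
    )
    truth = {
        "alpha": tissue.alpha,
        "D_star_cm2_s": tissue.D_star_cm2_s,
        "lambda": tissue.tortuosity,
        "k_prime_per_s": tissue.k_prime_per_s,
        "D_free_cm2_s": tissue.D_free_cm2_s,
        "distance_um": distance_um,
        "noise_frac": noise_frac,
        "seed": seed,
    }
    return curve, truth


# --------------------------------------------------------------------------
# field-potential sweeps and experiments
# --------------------------------------------------------------------------


def alpha_epsp(t_ms: np.ndarray, amplitude_mV: float, onset_ms: float, tau_ms: float) -> np.ndarray:
    """Negative-going alpha-function EPSP: -A (t'/tau) exp(1 - t'/tau)."""
    tp = (np.asarray(t_ms, dtype=float) - onset_ms) / tau_ms
    out = np.where(tp > 0, -amplitude_mV * tp * np.exp(1.0 - np.clip(tp, None, 50.0)), 0.0)
    return out


def alpha_epsp_slope_oracle(
    amplitude_mV: float,
    tau_ms: float,
    fractions: tuple[float, float] = (0.2, 0.8),
    n_dense: int = 200001,
) -> float:
    """Rising-phase slope of the alpha EPSP by dense analytic evaluation.

    Independent oracle for the fEPSP slope analyzer: evaluates the alpha
    function on a dense grid and fits a straight line over the samples whose
    amplitude lies between the given fractions of the peak, mirroring the
    analyzer's definition. Returns the slope magnitude in mV/ms.
    """
    t = np.linspace(0.0, tau_ms, n_dense)
    y = (t / tau_ms) * np.exp(1.0 - t / tau_ms)  # normalized rising phase (0..1)
    sel = (y >= fractions[0]) & (y <= fractions[1])
    coeff = np.polyfit(t[sel], amplitude_mV * y[sel], 1)
    return float(coeff[0])


@dataclass(frozen=True)
class SweepShape:
    """Waveform parameters of one synthetic paired-pulse sweep."""

    fv_amplitude_mV: float = 0.4
    fv_hwhm_ms: float = 0.6
    fv_delay_ms: float = 1.2
    epsp_amplitude_mV: float = 1.0
    epsp_onset_ms: float = 4.0
    epsp_tau_ms: float = 3.0
    ppr: float = 1.5
    artifact_amplitude_mV: float = 2.0
    artifact_width_ms: float = 0.1
    duration_s: float = 0.3
    sampling_rate_hz: float = 10000.0
    stimulus_times_s: tuple[float, float] = (0.05, 0.10)

    def __post_init__(self) -> None:
        # components must stay ordered: artifact < FV < fEPSP onset
        if not (2.0 * self.artifact_width_ms < self.fv_delay_ms < self.epsp_onset_ms):
            raise ValueError("misordered sweep components (artifact < FV < fEPSP required)")


def gen_sweep(
    shape: SweepShape | None = None,
    noise_mV: float = 0.01,
    seed: int = 0,
) -> tuple[Sweep, dict]:
    """Synthetic paired-pulse sweep: artifact + fiber volley + alpha fEPSP + noise.

    The second pulse's EPSP is scaled by the paired-pulse ratio; the fiber
    volley repeats unscaled. Ground truth includes the analytic rising-phase
    chord slope for the default 20-80% window.
    """
    shape = shape or SweepShape()
    n = int(round(shape.duration_s * shape.sampling_rate_hz))
    t_s = np.arange(n) / shape.sampling_rate_hz
    v = np.zeros(n)
    sigma_fv_ms = shape.fv_hwhm_ms * 2.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    for i_pulse, t_stim in enumerate(shape.stimulus_times_s):
        t_ms = (t_s - t_stim) * 1e3
        # biphasic stimulus artifact (derivative-of-Gaussian)
        x = t_ms / shape.artifact_width_ms
        v += shape.artifact_amplitude_mV * x * np.exp(0.5 - 0.5 * x**2) * (t_ms >= 0)
        # fiber volley: Gaussian trough
        v -= shape.fv_amplitude_mV * np.exp(-0.5 * ((t_ms - shape.fv_delay_ms) / sigma_fv_ms) ** 2) * (t_ms >= 0)
        # fEPSP: alpha function, pulse 2 scaled by PPR
        scale = shape.ppr if i_pulse == 1 else 1.0
        v += alpha_epsp(t_ms, shape.epsp_amplitude_mV * scale, shape.epsp_onset_ms, shape.epsp_tau_ms)

    rng = np.random.default_rng(seed)
    v = v + rng.normal(0.0, noise_mV, size=n)
    sweep = Sweep(
        voltage_mV=v,
        sampling_rate_hz=shape.sampling_rate_hz,
        stimulus_times_s=shape.stimulus_times_s,
    )
    truth = dict(asdict(shape))
    truth.update(
        {
            "noise_mV": noise_mV,
            "seed": seed,
            "epsp_chord_slope_mV_ms": alpha_epsp_slope_oracle(
                shape.epsp_amplitude_mV, shape.epsp_tau_ms
            ),
        }
    )
    return sweep, truth


#: scenario template magnitudes (package defaults, see module docstring)
POTENTIATION_FACTOR = 1.3
FAILURE_RESIDUAL = 0.05
SUPPRESSION_LEVEL = 0.02
K_PEAK_DELTA_MM = {"control": 0.0, "ischemia": 8.0, "ischemia_failure": 12.0}


def _scenario_templates(
    scenario: str,
    t_s: np.ndarray,
    isch_start_s: float,
    isch_end_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative (FV, fEPSP) amplitude time courses for one scenario."""
    fv = np.ones_like(t_s)
    ep = np.ones_like(t_s)
    if scenario == "control":
        return fv, ep
    suppress_end = isch_end_s + 60.0
    during = (t_s >= isch_start_s) & (t_s < suppress_end)
    after = t_s >= suppress_end
    ta = t_s[after] - suppress_end

    fv[during] = SUPPRESSION_LEVEL
    fv[after] = 1.0 - (1.0 - SUPPRESSION_LEVEL) * np.exp(-ta / 120.0)

    ep[during] = SUPPRESSION_LEVEL
    if scenario == "ischemia":
        # recovery toward the potentiated level
        ep[after] = POTENTIATION_FACTOR - (POTENTIATION_FACTOR - SUPPRESSION_LEVEL) * np.exp(
            -ta / 300.0
        )
    elif scenario == "ischemia_failure":
        # fiber volley recovers fully, the postsynaptic response stays down
        ep[after] = FAILURE_RESIDUAL
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return fv, ep


def gen_experiment(
    scenario: Literal["control", "ischemia", "ischemia_failure"],
    duration_min: float = 60.0,
    ischemia_start_min: float = 15.0,
    ischemia_duration_min: float = 3.0,
    sweep_interval_s: float = 20.0,
    shape: SweepShape | None = None,
    amplitude_jitter: float = 0.03,
    noise_mV: float = 0.01,
    seed: int = 0,
) -> tuple[ExperimentTimeline, IonTrace, dict]:
    """A full chemical-ischemia experiment: sweeps every 20 s plus a K+ trace.

    Per-sweep FV and fEPSP amplitudes follow the scenario template
    (control: stable; ischemia: transient suppression then recovery and
    potentiation; ischemia_failure: suppression with full FV recovery but the
    fEPSP pinned near zero), with multiplicative amplitude jitter and
    waveform noise. The K+ transient peaks during the ischemia window, larger
    in the failure scenario. Sweeps are analyzed with the package's own sweep
    analyzer to build the returned timeline.
    """
    if not 2.0 <= ischemia_duration_min <= 5.0 and scenario != "control":
        raise ValueError("ischemia duration must lie in [2, 5] min")
    shape = shape or SweepShape()
    rng = np.random.default_rng(seed)
    t_sweeps = np.arange(0.0, duration_min * 60.0, sweep_interval_s)
    isch_start = ischemia_start_min * 60.0
    isch_end = isch_start + ischemia_duration_min * 60.0
    if scenario != "control" and not (0 < isch_start < isch_end < t_sweeps[-1]):
        raise ValueError("ischemia window must lie inside the recording")

    fv_tpl, ep_tpl = _scenario_templates(scenario, t_sweeps, isch_start, isch_end)
    metrics = []
    for fv_rel, ep_rel in zip(fv_tpl, ep_tpl):
        jf = 1.0 + rng.normal(0.0, amplitude_jitter)
        je = 1.0 + rng.normal(0.0, amplitude_jitter)
        sw_shape = SweepShape(
            fv_amplitude_mV=shape.fv_amplitude_mV * fv_rel * jf,
            fv_hwhm_ms=shape.fv_hwhm_ms,
            fv_delay_ms=shape.fv_delay_ms,
            epsp_amplitude_mV=shape.epsp_amplitude_mV * ep_rel * je,
            epsp_onset_ms=shape.epsp_onset_ms,
            epsp_tau_ms=shape.epsp_tau_ms,
            ppr=shape.ppr,
            artifact_amplitude_mV=shape.artifact_amplitude_mV,
            artifact_width_ms=shape.artifact_width_ms,
            duration_s=shape.duration_s,
            sampling_rate_hz=shape.sampling_rate_hz,
            stimulus_times_s=shape.stimulus_times_s,
        )
        sweep, _ = gen_sweep(sw_shape, noise_mV=noise_mV, seed=int(rng.integers(2**31)))
        metrics.append(analyze_sweep(sweep))

    timeline = ExperimentTimeline(
        sweep_times_s=t_sweeps,
        metrics=metrics,
        baseline_epoch_s=(0.0, 600.0),
        end_epoch_s=(t_sweeps[-1] - 600.0, t_sweeps[-1]),
        ischemia_window_s=(isch_start, isch_end) if scenario != "control" else None,
    )
    k_window = (isch_start, isch_end)
    k_trace, k_truth = gen_k_trace(
        K_PEAK_DELTA_MM[scenario],
        k_window,
        duration_s=duration_min * 60.0,
        seed=int(rng.integers(2**31)),
    )
    truth = {
        "scenario": scenario,
        "label": "failure" if scenario == "ischemia_failure" else "recovered",
        "potentiation_factor": POTENTIATION_FACTOR if scenario == "ischemia" else 1.0,
        "failure_residual": FAILURE_RESIDUAL if scenario == "ischemia_failure" else None,
        "fv_end_relative": 1.0 if scenario != "control" else 1.0,
        "ischemia_window_s": k_window,
        "k_peak_delta_mM": k_truth["peak_delta_mM"],
        "seed": seed,
    }
    return timeline, k_trace, truth


# --------------------------------------------------------------------------
# iGluSnFR line scans
# --------------------------------------------------------------------------


def gen_linescan(
    peak_dff: tuple[float, ...] = (0.30, 0.42),
    tau_ms: float = 40.0,
    f0: float = 100.0,
    background: float = 20.0,
    bleach_factor: float = 1.0,
    noise_sd: float = 2.0,
    n_repeats: int = 5,
    duration_s: float = 1.5,
    scan_rate_hz: float = DEFAULT_SCAN_RATE_HZ,
    n_positions: int = 64,
    roi: tuple[int, int] = (10, 40),
    background_roi: tuple[int, int] = (45, 60),
    stimulus_times_s: tuple[float, ...] = (0.5, 0.55),
    seed: int = 0,
) -> tuple[list[LineScan], dict]:
    """Repeated line scans with stimulus-locked mono-exponential transients.

    ROI pixels carry f0*(1 + dff(t)); each pulse contributes its peak dF/F0
    at the first scan line at/after the stimulus and decays with tau.
    ``bleach_factor`` scales the indicator fluorescence of this time point
    (emulating the slow resting-fluorescence decline across an experiment)
    while leaving dF/F0 unchanged; background pixels carry an unbleached
    constant offset. Per-pixel Gaussian noise; ground truth always returned.
    """
    if len(peak_dff) != len(stimulus_times_s):
        raise ValueError("one peak amplitude per stimulus required")
    rng = np.random.default_rng(seed)
    n_t = int(round(duration_s * scan_rate_hz))
    t = np.arange(n_t) / scan_rate_hz

    dff = np.zeros(n_t)
    tau_s = tau_ms * 1e-3
    for a, t_stim in zip(peak_dff, stimulus_times_s):
        i0 = int(np.searchsorted(t, t_stim))
        dff[i0:] += a * np.exp(-(t[i0:] - t[i0]) / tau_s)

    scans = []
    for _ in range(n_repeats):
        frame = np.empty((n_positions, n_t))
        frame[:] = background
        frame[roi[0] : roi[1], :] = background + f0 * bleach_factor * (1.0 + dff)
        frame += rng.normal(0.0, noise_sd, size=frame.shape)
        scans.append(
            LineScan(
                frame,
                scan_rate_hz=scan_rate_hz,
                roi=roi,
                background_roi=background_roi,
                stimulus_times_s=stimulus_times_s,
            )
        )
    truth = {
        "peak_dff": peak_dff,
        "tau_ms": tau_ms,
        "f0": f0 * bleach_factor,
        "f0_unbleached": f0,
        "bleach_factor": bleach_factor,
        "background": background,
        "noise_sd": noise_sd,
        "n_repeats": n_repeats,
        "ppr": peak_dff[1] / peak_dff[0] if len(peak_dff) > 1 and peak_dff[0] else None,
        "seed": seed,
    }
    return scans, truth
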