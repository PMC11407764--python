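"""Single-vesicle glutamate loading model.

Simulates the accumulation of glutamate in a synaptic vesicle after
endocytosis. The luminal state (glutamate, pH, chloride and - in the default
configuration - potassium) evolves under four transporter fluxes: the
vesicular glutamate transporter (VGLUT, a glutamate(-)/H+ antiporter), a Cl-
conductance through the same transporter, a passive proton leak and the
V-type H+-ATPase, plus a vesicular cation (K+) conductance and an Na+/H+
exchanger. The membrane potential is not a state variable: it follows
algebraically from the net luminal charge over the membrane capacitance, with
an impermeant background charge B fixed by charge conservation at t = 0.

Units: concentrations in mM, pH dimensionless, potentials in mV, time in s.
Fluxes are expressed in molecules/s and converted to mM/s via N_A * V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constants import FARADAY, N_A, thermal_voltage_mV

__all__ = [
    "VesicleGeometry",
    "VesicleParams",
    "CytosolConditions",
    "LuminalInitialConditions",
    "VesicleState",
    "FluxModel",
    "ScenarioSpec",
    "SimulationResult",
    "ISCHEMIA_SCENARIOS",
    "surface_corrected_concentration",
    "molecules_from_concentration",
    "concentration_from_molecules",
    "impermeant_charge",
    "membrane_potential",
    "default_flux_model",
    "rhs",
    "simulate",
    "steady_state_glutamate",
    "find_steady_state",
    "run_scenarios",
]


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails or produces non-finite derivatives."""


class NotAtSteadyStateError(RuntimeError):
    """Raised when a steady-state quantity is requested from a run that never settled."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VesicleGeometry:
    """Spherical vesicle geometry; derived volume/area/capacitance.

    radius_nm : vesicle radius in nm (default 20)
    specific_capacitance_uF_cm2 : membrane capacitance per area (default 1)
    """

    radius_nm: float = 20.0
    specific_capacitance_uF_cm2: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0 or self.specific_capacitance_uF_cm2 <= 0:
            raise ValueError("radius and specific capacitance must be positive")

    @property
    def volume_L(self) -> float:
        r_cm = self.radius_nm * 1e-7
        return (4.0 / 3.0) * math.pi * r_cm**3 * 1e-3

    @property
    def surface_area_cm2(self) -> float:
        r_cm = self.radius_nm * 1e-7
        return 4.0 * math.pi * r_cm**2

    @property
    def capacitance_F(self) -> float:
        return self.specific_capacitance_uF_cm2 * 1e-6 * self.surface_area_cm2

    @property
    def mv_per_mM(self) -> float:
        """Membrane-potential change per mM of net luminal charge (F*V/C)."""
        return FARADAY * self.volume_L * 1e-3 / self.capacitance_F * 1000.0

    @property
    def molecules_per_mM(self) -> float:
        return N_A * self.volume_L * 1e-3


@dataclass(frozen=True)
class VesicleParams:
    """Fixed vesicle parameters.

    beta_pH_mM : luminal pH buffering capacity, mM of protons per pH unit
    psi_in_mV / psi_out_mV : inner/outer leaflet surface potentials
    c_k_L_mM / c_na_L_mM : luminal K+/Na+ (initial value for K+, which is
        dynamic in the default flux model; Na+ stays clamped)
    temperature_K : absolute temperature
    """

    beta_pH_mM: float = 40.0
    psi_in_mV: float = 0.0
    psi_out_mV: float = -50.0
    c_k_L_mM: float = 5.0
    c_na_L_mM: float = 145.0
    temperature_K: float = 307.0

    def __post_init__(self) -> None:
        if self.beta_pH_mM <= 0:
            raise ValueError("beta_pH must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class CytosolConditions:
    """Cytosolic (bulk) concentrations seen by the vesicle membrane."""

    pH_c: float = 7.2
    c_glut_c_mM: float = 10.0
    c_cl_c_mM: float = 10.0
    c_k_c_mM: float = 140.0
    c_na_c_mM: float = 10.0
    atpase_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_glut_c_mM", "c_cl_c_mM", "c_k_c_mM", "c_na_c_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.atpase_scale <= 1.0:
            raise ValueError("atpase_scale must lie in [0, 1]")


@dataclass(frozen=True)
class LuminalInitialConditions:
    """Luminal contents immediately after endocytosis (external-solution-like)."""

    pH_L0: float = 7.2
    c_glut_L0_mM: float = 0.001
    c_cl_L0_mM: float = 110.0
    c_k_L0_mM: float = 5.0
    c_na_L0_mM: float = 145.0

    def __post_init__(self) -> None:
        for name in ("c_glut_L0_mM", "c_cl_L0_mM", "c_k_L0_mM", "c_na_L0_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.pH_L0 < 14.0:
            raise ValueError("pH_L0 out of range")


@dataclass
class VesicleState:
    """Instantaneous luminal state."""

    t: float
    pH_L: float
    c_glut_L_mM: float
    c_cl_L_mM: float
    c_k_L_mM: float

    def n_glut(self, geom: VesicleGeometry) -> float:
        return molecules_from_concentration(self.c_glut_L_mM, geom)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def h_conc_mM(pH: float) -> float:
    """Free proton concentration in mM for a given pH."""
    return 10.0 ** (-pH) * 1000.0


def surface_corrected_concentration(
    c_bulk_mM: float, valence: int, psi_leaflet_mV: float, temperature_K: float
) -> float:
    """Boltzmann correction of a bulk concentration at a charged leaflet.

    c_mem = c_bulk * exp(-z F psi / (R T)).
    """
    vt = thermal_voltage_mV(temperature_K)
    return c_bulk_mM * math.exp(-valence * psi_leaflet_mV / vt)


def molecules_from_concentration(c_mM: float, geom: VesicleGeometry) -> float:
    """Convert a luminal concentration to an absolute molecule count."""
    if np.any(np.asarray(c_mM) < 0):
        raise ValueError("concentration must be non-negative")
    return c_mM * geom.molecules_per_mM


def concentration_from_molecules(n: float, geom: VesicleGeometry) -> float:
    """Inverse of :func:`molecules_from_concentration` (exact round trip)."""
    if np.any(np.asarray(n) < 0):
        raise ValueError("molecule count must be non-negative")
    return n / geom.molecules_per_mM


def impermeant_charge(
    init: LuminalInitialConditions, geom: VesicleGeometry, params: VesicleParams
) -> float:
    """Impermeant luminal background charge B (mM) from charge conservation at t=0.

    B = [H+]0 + [K+]0 + [Na+]0 - [Cl-]0 - [Glut-]0 - (C/(F V)) (psi_in - psi_out),
    every term in mM. Glutamate carries a single negative charge.
    """
    ionic = (
        h_conc_mM(init.pH_L0)
        + init.c_k_L0_mM
        + init.c_na_L0_mM
        - init.c_cl_L0_mM
        - init.c_glut_L0_mM
    )
    b = ionic - (params.psi_in_mV - params.psi_out_mV) / geom.mv_per_mM
    if not math.isfinite(b):
        raise ValueError("impermeant charge is non-finite; check parameters")
    return b


def membrane_potential(
    state: VesicleState,
    geom: VesicleGeometry,
    params: VesicleParams,
    B_mM: float,
) -> float:
    """Vesicle membrane potential (mV) from the net luminal charge.

    dpsi = (F V / C) ([H+]_L + [K+]_L + [Na+]_L - [Cl-]_L - [Glut-]_L - B).
    """
    net = (
        h_conc_mM(state.pH_L)
        + state.c_k_L_mM
        + params.c_na_L_mM
        - state.c_cl_L_mM
        - state.c_glut_L_mM
        - B_mM
    )
    return geom.mv_per_mM * net


# --------------------------------------------------------------------------
# flux model
# --------------------------------------------------------------------------

#: reference concentrations used to keep rate constants in molecules/s
_C0_MM = 1.0
_H0_MM = 1e-4  # pH 7

#: calibrated default rate constants (molecules/s at unit normalized drive).
#: k_vatpase was calibrated once so that the control run plateaus at 3500
#: glutamate molecules with an acidified lumen; see docs/methods.md.
DEFAULT_RATES = {
    "k_vglut": 0.2,
    "k_vglut_cl": 0.5,
    "k_hleak": 1.0,
    "k_vatpase": 10.386424882271381,
    "k_kchan": 0.05,
    "k_nhe": 0.005,
    "dmu_max": 11.5,
}


@dataclass(frozen=True)
class FluxModel:
    """Transporter flux laws for the vesicle membrane.

    Each flux is a mass-action / Eyring-barrier expression that is continuous
    in its arguments and vanishes exactly at the transporter's own
    electrochemical equilibrium. Rate constants are in molecules/s per unit of
    normalized driving product; ``dmu_max`` is the thermodynamic stall force
    of the V-ATPase in units of RT (proton-motive force it can sustain).

    ``dynamic_k`` switches the luminal K+ state on (default); with it off the
    luminal K+ concentration stays clamped at its initial value and the model
    reduces to the strictly fixed-cation variant.
    """

    k_vglut: float = DEFAULT_RATES["k_vglut"]
    k_vglut_cl: float = DEFAULT_RATES["k_vglut_cl"]
    k_hleak: float = DEFAULT_RATES["k_hleak"]
    k_vatpase: float = DEFAULT_RATES["k_vatpase"]
    k_kchan: float = DEFAULT_RATES["k_kchan"]
    k_nhe: float = DEFAULT_RATES["k_nhe"]
    dmu_max: float = DEFAULT_RATES["dmu_max"]
    dynamic_k: bool = True

    def __post_init__(self) -> None:
        for name in ("k_vglut", "k_vglut_cl", "k_hleak", "k_vatpase", "k_kchan", "k_nhe"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate parameter {name} must be non-negative")

    def fluxes(
        self,
        state: VesicleState,
        cyt: CytosolConditions,
        dpsi_mV: float,
        params: VesicleParams,
    ) -> dict[str, float]:
        """All transporter fluxes (molecules/s, positive into the lumen).

        Membrane-adjacent cytosolic concentrations carry the Boltzmann
        correction for the outer-leaflet surface potential; luminal
        concentrations use the inner-leaflet potential.
        """
        T = params.temperature_K
        vt = thermal_voltage_mV(T)
        u = dpsi_mV / vt

        def cyt_m(c: float, z: int) -> float:
            return surface_corrected_concentration(c, z, params.psi_out_mV, T)

        def lum_m(c: float, z: int) -> float:
            return surface_corrected_concentration(c, z, params.psi_in_mV, T)

        h_L = lum_m(h_conc_mM(state.pH_L), +1) / _H0_MM
        h_c = cyt_m(h_conc_mM(cyt.pH_c), +1) / _H0_MM
        g_L = lum_m(state.c_glut_L_mM, -1) / _C0_MM
        g_c = cyt_m(cyt.c_glut_c_mM, -1) / _C0_MM
        cl_L = lum_m(state.c_cl_L_mM, -1) / _C0_MM
        cl_c = cyt_m(cyt.c_cl_c_mM, -1) / _C0_MM
        k_L = lum_m(state.c_k_L_mM, +1) / _C0_MM
        k_c = cyt_m(cyt.c_k_c_mM, +1) / _C0_MM
        na_L = lum_m(params.c_na_L_mM, +1) / _C0_MM
        na_c = cyt_m(cyt.c_na_c_mM, +1) / _C0_MM

        eu = math.exp(u)
        eu2 = math.exp(0.5 * u)

        # VGLUT: glutamate(-) in, one H+ out per cycle (net charge -2/cycle)
        j_vglut = self.k_vglut * (g_c * h_L * eu - g_L * h_c / eu)
        # Cl- conductance through VGLUT (influx favored by lumen-positive dpsi)
        j_vglut_cl = self.k_vglut_cl * (cl_c * eu2 - cl_L / eu2)
        # passive H+ leak
        j_hleak = self.k_hleak * (h_c / eu2 - h_L * eu2)
        # V-ATPase: saturating pump, stalls at proton-motive force dmu_max (RT)
        if h_L > 0 and h_c > 0:
            dmu = math.log(h_L / h_c) + u
        else:  # degenerate pH; treat as maximal drive
            dmu = -math.inf
        j_vatpase = self.k_vatpase * cyt.atpase_scale * (1.0 - math.exp(dmu - self.dmu_max))
        # cation (K+) conductance
        j_kchan = self.k_kchan * (k_c / eu2 - k_L * eu2)
        # electroneutral Na+/H+ exchanger (Na in / H out); luminal Na clamped
        j_nhe = self.k_nhe * (na_c * h_L - na_L * h_c)

        return {
            "j_vglut": j_vglut,
            "j_vglut_cl": j_vglut_cl,
            "j_hleak": j_hleak,
            "j_vatpase": j_vatpase,
            "j_kchan": j_kchan if self.dynamic_k else 0.0,
            "j_nhe": j_nhe,
        }


def default_flux_model(config: Mapping[str, float] | None = None) -> FluxModel:
    """The shipped calibrated flux model, optionally with overridden rates."""
    if config is None:
        return FluxModel()
    return FluxModel(**dict(config))


# --------------------------------------------------------------------------
# ODE right-hand side and integration
# --------------------------------------------------------------------------


def rhs(
    t: float,
    y: np.ndarray,
    geom: VesicleGeometry,
    params: VesicleParams,
    cyt: CytosolConditions,
    fluxes: FluxModel,
    B_mM: float,
) -> np.ndarray:
    """Time derivatives of (c_glut_L, pH_L, c_cl_L, c_k_L).

    The net proton molecule flux into the lumen is
    J_Hleak + J_VATPase - J_VGLUT - J_NHE; buffering converts it to a pH rate
    through beta_pH. The membrane potential is recomputed algebraically at
    every evaluation.
    """
    state = VesicleState(t=t, c_glut_L_mM=y[0], pH_L=y[1], c_cl_L_mM=y[2], c_k_L_mM=y[3])
    dpsi = membrane_potential(state, geom, params, B_mM)
    j = fluxes.fluxes(state, cyt, dpsi, params)
    conv = 1.0 / geom.molecules_per_mM  # molecules/s -> mM/s

    d_glut = j["j_vglut"] * conv
    d_cl = j["j_vglut_cl"] * conv
    d_k = j["j_kchan"] * conv
    net_h = j["j_hleak"] + j["j_vatpase"] - j["j_vglut"] - j["j_nhe"]
    d_pH = -net_h * conv / params.beta_pH_mM

    out = np.array([d_glut, d_pH, d_cl, d_k])
    if not np.all(np.isfinite(out)):
        raise IntegrationError(f"non-finite derivative at t={t}: state={y}, fluxes={j}")
    return out


@dataclass
class SimulationResult:
    """Trajectories of the vesicle run plus steady-state bookkeeping."""

    time_s: np.ndarray
    n_glut: np.ndarray
    pH_L: np.ndarray
    c_cl_L_mM: np.ndarray
    c_k_L_mM: np.ndarray
    dpsi_mV: np.ndarray
    steady_state_reached: bool
    steady_state_n_glut: float | None
    B_mM: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "n_glut": self.n_glut,
                "pH_L": self.pH_L,
                "c_cl_L_mM": self.c_cl_L_mM,
                "c_k_L_mM": self.c_k_L_mM,
                "dpsi_mV": self.dpsi_mV,
            }
        )


#: steady-state criterion: relative n_glut drift per second over a trailing window
STEADY_STATE_RELTOL_PER_S = 1e-6
STEADY_STATE_WINDOW_S = 10.0


def simulate(
    init: LuminalInitialConditions | None = None,
    geom: VesicleGeometry | None = None,
    params: VesicleParams | None = None,
    conditions: CytosolConditions | None = None,
    fluxes: FluxModel | None = None,
    t_end: float = 3000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_eval: int = 3001,
) -> SimulationResult:
    """Integrate the vesicle model to ``t_end`` with a stiff solver.

    Deterministic for fixed inputs and tolerances. Raises
    :class:`IntegrationError` on solver failure.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("solver tolerances must be positive")
    init = init or LuminalInitialConditions()
    geom = geom or VesicleGeometry()
    params = params or VesicleParams()
    conditions = conditions or CytosolConditions()
    fluxes = fluxes or default_flux_model()

    B = impermeant_charge(init, geom, params)
    y0 = np.array([init.c_glut_L0_mM, init.pH_L0, init.c_cl_L0_mM, init.c_k_L0_mM])
    t_eval = np.linspace(0.0, t_end, n_eval)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        args=(geom, params, conditions, fluxes, B),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")

    n_glut = molecules_from_concentration(np.clip(sol.y[0], 0.0, None), geom)
    dpsi = np.array(
        [
            membrane_potential(
                VesicleState(t, c_glut_L_mM=g, pH_L=p, c_cl_L_mM=c, c_k_L_mM=k),
                geom,
                params,
                B,
            )
            for t, g, p, c, k in zip(sol.t, sol.y[0], sol.y[1], sol.y[2], sol.y[3])
        ]
    )

    reached, ss_value = _steady_state_check(sol.t, n_glut)
    return SimulationResult(
        time_s=sol.t,
        n_glut=n_glut,
        pH_L=sol.y[1],
        c_cl_L_mM=sol.y[2],
        c_k_L_mM=sol.y[3],
        dpsi_mV=dpsi,
        steady_state_reached=reached,
        steady_state_n_glut=ss_value,
        B_mM=B,
    )


def _steady_state_check(t: np.ndarray, n_glut: np.ndarray) -> tuple[bool, float | None]:
    """Apply the trailing-window drift criterion to the n_glut trajectory."""
    mask = t >= t[-1] - STEADY_STATE_WINDOW_S
    if mask.sum() < 2:
        return False, None
    tail_t, tail_n = t[mask], n_glut[mask]
    mean_n = float(np.mean(tail_n))
    if mean_n == 0.0:
        # nothing accumulated and nothing changing -> steady by convention
        drift = abs(tail_n[-1] - tail_n[0]) / (tail_t[-1] - tail_t[0])
        return drift == 0.0, 0.0
    drift = abs(tail_n[-1] - tail_n[0]) / (tail_t[-1] - tail_t[0]) / mean_n
    if drift < STEADY_STATE_RELTOL_PER_S:
        return True, mean_n
    return False, None


def steady_state_glutamate(result: SimulationResult) -> float:
    """Steady-state glutamate molecule count (trailing-window average)."""
    if not result.steady_state_reached or result.steady_state_n_glut is None:
        raise NotAtSteadyStateError(
            "trajectory did not satisfy the steady-state criterion at t_end"
        )
    return result.steady_state_n_glut


def find_steady_state(
    init: LuminalInitialConditions | None = None,
    geom: VesicleGeometry | None = None,
    params: VesicleParams | None = None,
    conditions: CytosolConditions | None = None,
    fluxes: FluxModel | None = None,
    t_end: float = 3000.0,
) -> tuple[VesicleState, float]:
    """Polish the steady state to machine precision.

    Integrates to ``t_end`` and refines the endpoint with a damped Newton root
    solve of rhs = 0 (in log-glutamate/log-chloride coordinates to preserve
    positivity). Returns the steady state and its molecule count.
    """
    init = init or LuminalInitialConditions()
    geom = geom or VesicleGeometry()
    params = params or VesicleParams()
    conditions = conditions or CytosolConditions()
    fluxes = fluxes or default_flux_model()
    B = impermeant_charge(init, geom, params)

    res = simulate(init, geom, params, conditions, fluxes, t_end=t_end)
    y_end = np.array(
        [res.n_glut[-1] / geom.molecules_per_mM, res.pH_L[-1], res.c_cl_L_mM[-1], res.c_k_L_mM[-1]]
    )

    dyn_k = fluxes.dynamic_k

    def fun(z: np.ndarray) -> np.ndarray:
        g, ph, cl = math.exp(z[0]), z[1], math.exp(z[2])
        k = math.exp(z[3]) if dyn_k else y_end[3]
        y = np.array([g, ph, cl, k])
        d = rhs(0.0, y, geom, params, conditions, fluxes, B)
        return d[:4] if dyn_k else d[:3]

    z0 = [math.log(max(y_end[0], 1e-12)), y_end[1], math.log(max(y_end[2], 1e-12))]
    if dyn_k:
        z0.append(math.log(max(y_end[3], 1e-12)))
    solroot = root(fun, np.array(z0), method="hybr", tol=1e-13)
    if not solroot.success:
        # fall back to the integrated endpoint
        state = VesicleState(
            t=res.time_s[-1],
            c_glut_L_mM=y_end[0],
            pH_L=y_end[1],
            c_cl_L_mM=y_end[2],
            c_k_L_mM=y_end[3],
        )
        return state, float(res.n_glut[-1])
    z = solroot.x
    g, ph, cl = math.exp(z[0]), z[1], math.exp(z[2])
    k = math.exp(z[3]) if dyn_k else y_end[3]
    state = VesicleState(t=math.inf, c_glut_L_mM=g, pH_L=ph, c_cl_L_mM=cl, c_k_L_mM=k)
    return state, molecules_from_concentration(g, geom)


# --------------------------------------------------------------------------
# scenario runner
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides applied before simulation.

    Override keys are dotted paths into the configuration:
    ``cytosol.<field>``, ``init.<field>`` or ``flux.<field>``. An empty
    override set reproduces the control run bit-for-bit.
    """

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)


#: ischemia-like single perturbations plus the alkalinization control.
#: Magnitudes are package defaults (see docs/methods.md), not measured values.
ISCHEMIA_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("control", {}),
    ScenarioSpec("cytosolic_acidification", {"cytosol.pH_c": 6.8}),
    ScenarioSpec("raised_cytosolic_na", {"cytosol.c_na_c_mM": 30.0}),
    ScenarioSpec("raised_cytosolic_cl", {"cytosol.c_cl_c_mM": 20.0}),
    ScenarioSpec("lowered_cytosolic_k", {"cytosol.c_k_c_mM": 100.0}),
    ScenarioSpec("lowered_initial_luminal_ph", {"init.pH_L0": 6.9}),
    ScenarioSpec("reduced_atpase", {"cytosol.atpase_scale": 0.5}),
    ScenarioSpec("cytosolic_alkalinization", {"cytosol.pH_c": 7.4}),
)


def _apply_overrides(
    overrides: Mapping[str, float],
    init: LuminalInitialConditions,
    cyt: CytosolConditions,
    fluxes: FluxModel,
) -> tuple[LuminalInitialConditions, CytosolConditions, FluxModel]:
    for path, value in overrides.items():
        scope, _, name = path.partition(".")
        if scope == "cytosol":
            cyt = replace(cyt, **{name: value})
        elif scope == "init":
            init = replace(init, **{name: value})
        elif scope == "flux":
            fluxes = replace(fluxes, **{name: value})
        else:
            raise ValueError(f"unknown override scope {scope!r} in {path!r}")
    return init, cyt, fluxes


def run_scenarios(
    scenarios: Sequence[ScenarioSpec] = ISCHEMIA_SCENARIOS,
    init: LuminalInitialConditions | None = None,
    geom: VesicleGeometry | None = None,
    params: VesicleParams | None = None,
    conditions: CytosolConditions | None = None,
    fluxes: FluxModel | None = None,
    t_end: float = 3000.0,
) -> pd.DataFrame:
    """Steady-state glutamate loading for each scenario, relative to control.

    Steady states are polished with a root solve so that even sub-ppm
    perturbation effects (e.g. through the impermeant-charge term) resolve.
    Scenarios that fail to settle are flagged, never dropped.
    """
    init = init or LuminalInitialConditions()
    geom = geom or VesicleGeometry()
    params = params or VesicleParams()
    conditions = conditions or CytosolConditions()
    fluxes = fluxes or default_flux_model()

    names = [s.name for s in scenarios]
    if "control" not in names:
        scenarios = (ScenarioSpec("control", {}), *scenarios)

    rows = []
    control_n: float | None = None
    for spec in scenarios:
        s_init, s_cyt, s_flux = _apply_overrides(spec.overrides, init, conditions, fluxes)
        flagged = False
        try:
            state, n = find_steady_state(s_init, geom, params, s_cyt, s_flux, t_end=t_end)
        except (IntegrationError, NotAtSteadyStateError):
            flagged, state, n = True, None, math.nan
        if spec.name == "control" and not spec.overrides:
            control_n = n
        rows.append(
            {
                "name": spec.name,
                "steady_state_n_glut": n,
                "pH_L": state.pH_L if state else math.nan,
                "dpsi_mV": membrane_potential(state, geom, params, impermeant_charge(s_init, geom, params))
                if state
                else math.nan,
                "flagged": flagged,
            }
        )
    if control_n is None or not math.isfinite(control_n):
        raise RuntimeError("control scenario did not converge; relative changes undefined")
    df = pd.DataFrame(rows)
    df["relative_change"] = df["steady_state_n_glut"] / control_n - 1.0
    return df
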