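"""Real-time iontophoresis (RTI) estimation of extracellular-space properties.

A tetramethylammonium (TMA+) point source driven by a constant iontophoresis
current emits tracer into brain tissue; a nearby ion-selective electrode
records the concentration transient. In a porous medium with volume fraction
alpha, effective diffusion coefficient D* and optional first-order clearance
k', the during-pulse solution for a constant point source is

    C(r, t) = Q / (8 pi D* alpha r) *
        [ exp( r sqrt(k'/D*)) erfc( r/(2 sqrt(D* t)) + sqrt(k' t) )
        + exp(-r sqrt(k'/D*)) erfc( r/(2 sqrt(D* t)) - sqrt(k' t) ) ]

and the post-pulse trace is the on-solution superposition
C_on(t) - C_on(t - T). With k' = 0 this reduces to the classical
erfc solution with steady state Q / (4 pi D* alpha r). Fitting the forward
model to a measured transient yields alpha and D*, and the tortuosity
lambda = sqrt(D_free / D*).

All diffusion math is CGS (cm, s, mol/cm^3); distances are micrometres and
concentrations mM at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc

from .constants import FARADAY

__all__ = [
    "RtiSourceParams",
    "TissueParams",
    "TmaCurve",
    "RtiFit",
    "DEFAULT_D_FREE_CM2_S",
    "rti_forward",
    "fit_rti",
    "tortuosity",
    "compare_fits",
]

#: free-medium TMA+ diffusion coefficient at 34-35 C (cm^2/s). Configurable;
#: values in this range are standard for TMA at recording temperature. A
#: different recording temperature can be accommodated by scaling with
#: T/T_ref times the viscosity ratio (Stokes-Einstein convention).
DEFAULT_D_FREE_CM2_S = 1.31e-5


@dataclass(frozen=True)
class RtiSourceParams:
    """Iontophoresis source: current pulse and electrochemical efficiency."""

    current_nA: float = 100.0
    pulse_duration_s: float = 30.0
    transport_number: float = 0.3
    valence: int = 1

    def __post_init__(self) -> None:
        if self.current_nA <= 0 or self.pulse_duration_s <= 0:
            raise ValueError("current and pulse duration must be positive")
        if not 0 < self.transport_number <= 1:
            raise ValueError("transport number must lie in (0, 1]")

    @property
    def molar_rate_mol_s(self) -> float:
        """Source strength Q = I n_t / (z F) in mol/s."""
        return self.current_nA * 1e-9 * self.transport_number / (self.valence * FARADAY)


@dataclass(frozen=True)
class TissueParams:
    """Porous-medium transport parameters of the extracellular space."""

    alpha: float
    D_star_cm2_s: float
    k_prime_per_s: float = 0.0
    D_free_cm2_s: float = DEFAULT_D_FREE_CM2_S

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.D_star_cm2_s <= self.D_free_cm2_s:
            raise ValueError("require 0 < D* <= D_free")
        if self.k_prime_per_s < 0:
            raise ValueError("clearance rate must be non-negative")

    @property
    def tortuosity(self) -> float:
        return tortuosity(self.D_free_cm2_s, self.D_star_cm2_s)


@dataclass
class TmaCurve:
    """A recorded (or synthetic) TMA+ transient at a fixed electrode distance.

    ``concentration_mM`` is above-baseline unless ``baseline_mM`` is set, in
    which case the recorded bath baseline is subtracted on access.
    """

    time_s: np.ndarray
    concentration_mM: np.ndarray
    distance_um: float
    source: RtiSourceParams = field(default_factory=RtiSourceParams)
    baseline_mM: float = 0.0
    valid_distance_um: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.concentration_mM = np.asarray(self.concentration_mM, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.concentration_mM.shape:
            raise ValueError("time and concentration must be equal-length 1-D arrays")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        lo, hi = self.valid_distance_um
        if not lo <= self.distance_um <= hi:
            raise ValueError(
                f"distance {self.distance_um} um outside validity range {lo}-{hi} um"
            )

    @property
    def above_baseline_mM(self) -> np.ndarray:
        return self.concentration_mM - self.baseline_mM


@dataclass
class RtiFit:
    """Result of fitting the RTI forward model to a TMA transient."""

    alpha: float
    D_star_cm2_s: float
    lam: float
    k_prime_per_s: float
    residual_norm: float
    converged: bool
    covariance: np.ndarray | None
    D_free_cm2_s: float


def tortuosity(D_free_cm2_s: float, D_star_cm2_s: float) -> float:
    """lambda = sqrt(D_free / D*); raises if the fit is unphysical (D* > D_free)."""
    if D_star_cm2_s <= 0:
        raise ValueError("D* must be positive")
    if D_star_cm2_s > D_free_cm2_s:
        raise ValueError("D* exceeds D_free: unphysical (lambda < 1)")
    return math.sqrt(D_free_cm2_s / D_star_cm2_s)


def _c_on(t: np.ndarray, r_cm: float, Q_mol_s: float, alpha: float, D: float, k: float) -> np.ndarray:
    """During-pulse constant-point-source solution, in mol/cm^3; zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    pref = Q_mol_s / (8.0 * math.pi * D * alpha * r_cm)
    a = r_cm / (2.0 * np.sqrt(D * tp))
    if k > 0:
        b = math.sqrt(k / D) * r_cm
        s = np.sqrt(k * tp)
        out[pos] = pref * (math.exp(b) * erfc(a + s) + math.exp(-b) * erfc(a - s))
    else:
        out[pos] = 2.0 * pref * erfc(a)
    return out


def rti_forward(
    time_s: np.ndarray,
    distance_um: float,
    source: RtiSourceParams,
    tissue: TissueParams,
) -> np.ndarray:
    """Above-baseline TMA+ concentration (mM) on the given time grid.

    Post-pulse values follow by exact superposition of the on-solution.
    """
    time_s = np.asarray(time_s, dtype=float)
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    if np.any(time_s < 0):
        raise ValueError("time must be non-negative")
    r_cm = distance_um * 1e-4
    Q = source.molar_rate_mol_s
    c = _c_on(time_s, r_cm, Q, tissue.alpha, tissue.D_star_cm2_s, tissue.k_prime_per_s)
    c = c - _c_on(
        time_s - source.pulse_duration_s,
        r_cm,
        Q,
        tissue.alpha,
        tissue.D_star_cm2_s,
        tissue.k_prime_per_s,
    )
    return c * 1e6  # mol/cm^3 -> mM


def fit_rti(
    curve: TmaCurve,
    D_free_cm2_s: float = DEFAULT_D_FREE_CM2_S,
    fit_k_prime: bool = False,
    initial_guesses: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> RtiFit:
    """Trust-region least squares of the forward model over (alpha, D*[, k']).

    Multi-start from a 3-point coarse grid (unless explicit initial guesses
    are given); ties broken by lowest residual norm. Non-convergence yields a
    flagged result, not an exception.
    """
    t = curve.time_s
    if t[-1] <= curve.source.pulse_duration_s:
        raise ValueError("curve must cover both the pulse and the decay phase")
    y = curve.above_baseline_mM

    lo_a, hi_a = (bounds or {}).get("alpha", (1e-3, 1.0))
    lo_d, hi_d = (bounds or {}).get("D_star", (1e-8, D_free_cm2_s))
    lo_k, hi_k = (bounds or {}).get("k_prime", (0.0, 1.0))

    def residuals(p: np.ndarray) -> np.ndarray:
        alpha, d_star = p[0], p[1]
        k = p[2] if fit_k_prime else 0.0
        tissue = TissueParams.__new__(TissueParams)  # bypass bound checks inside solver
        object.__setattr__(tissue, "alpha", alpha)
        object.__setattr__(tissue, "D_star_cm2_s", d_star)
        object.__setattr__(tissue, "k_prime_per_s", k)
        object.__setattr__(tissue, "D_free_cm2_s", D_free_cm2_s)
        return rti_forward(t, curve.distance_um, curve.source, tissue) - y

    if initial_guesses is not None:
        starts = [
            (
                initial_guesses.get("alpha", 0.2),
                initial_guesses.get("D_star", 0.5 * D_free_cm2_s),
                initial_guesses.get("k_prime", 1e-3),
            )
        ]
    else:
        starts = [
            (0.1, D_free_cm2_s / 4.0, 1e-3),
            (0.3, D_free_cm2_s / 2.0, 1e-3),
            (0.8, D_free_cm2_s * 0.9, 1e-3),
        ]

    lb = [lo_a, lo_d] + ([lo_k] if fit_k_prime else [])
    ub = [hi_a, hi_d] + ([hi_k] if fit_k_prime else [])

    best = None
    for a0, d0, k0 in starts:
        p0 = [a0, d0] + ([k0] if fit_k_prime else [])
        try:
            sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return RtiFit(
            alpha=math.nan,
            D_star_cm2_s=math.nan,
            lam=math.nan,
            k_prime_per_s=math.nan,
            residual_norm=math.inf,
            converged=False,
            covariance=None,
            D_free_cm2_s=D_free_cm2_s,
        )

    alpha, d_star = best.x[0], best.x[1]
    k_prime = best.x[2] if fit_k_prime else 0.0
    resid = best.fun
    dof = max(len(resid) - len(best.x), 1)
    cov = None
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * (resid @ resid) / dof
    except np.linalg.LinAlgError:
        pass
    return RtiFit(
        alpha=float(alpha),
        D_star_cm2_s=float(d_star),
        lam=tortuosity(D_free_cm2_s, min(d_star, D_free_cm2_s)),
        k_prime_per_s=float(k_prime),
        residual_norm=float(np.linalg.norm(resid)),
        converged=bool(best.success),
        covariance=cov,
        D_free_cm2_s=D_free_cm2_s,
    )


def compare_fits(before: RtiFit, after: RtiFit) -> dict[str, tuple[float, float]]:
    """Relative changes (after/before - 1) of alpha and D*, with 1-sigma errors.

    Uncertainties are propagated from the fit covariances assuming
    independence of the two recordings. Refuses unconverged inputs.
    """
    if not (before.converged and after.converged):
        raise ValueError("both fits must have converged to compare them")

    def rel(idx: int, b_val: float, a_val: float) -> tuple[float, float]:
        change = a_val / b_val - 1.0
        var = 0.0
        for fit, val in ((before, b_val), (after, a_val)):
            if fit.covariance is not None and fit.covariance.shape[0] > idx:
                var += fit.covariance[idx, idx] / val**2
        return change, abs(a_val / b_val) * math.sqrt(var)

    return {
        "alpha": rel(0, before.alpha, after.alpha),
        "D_star": rel(1, before.D_star_cm2_s, after.D_star_cm2_s),
    }
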