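"""Independent finite-difference oracle for point-source diffusion in tissue.

Solves the spherically symmetric porous-medium diffusion equation

    dC/dt = D* (d2C/dr2 + (2/r) dC/dr) - k' C

with a constant molar source Q imposed as a flux boundary condition on a
small inner sphere (radius r0) and a zero far-field boundary, using the
substitution v = r C (which reduces the operator to a plain 1-D Laplacian)
and implicit (backward-Euler) time stepping on a uniform radial grid.

This solver shares no code with the package's closed-form erfc solution; it
exists purely as a numerical cross-check of the forward model.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


def fd_point_source(
    eval_times_s: np.ndarray,
    r_eval_cm: float,
    Q_mol_s: float,
    alpha: float,
    D_cm2_s: float,
    k_per_s: float = 0.0,
    pulse_s: float = 30.0,
    r0_cm: float = 2e-4,
    r_max_cm: float = 0.2,
    dr_cm: float = 5e-5,
    dt_s: float = 0.02,
) -> np.ndarray:
    """Concentration (mol/cm^3) at r_eval for each requested time."""
    r = np.arange(r0_cm, r_max_cm + dr_cm / 2, dr_cm)
    n = len(r)
    lam = D_cm2_s * dt_s / dr_cm**2

    # interior rows: (1 + dt k) v - lam (v_{i-1} - 2 v_i + v_{i+1}) = v_old
    main = np.full(n, 1.0 + dt_s * k_per_s + 2.0 * lam)
    lower = np.full(n - 1, -lam)
    upper = np.full(n - 1, -lam)
    # inner flux BC (second-order one-sided derivative):
    #   r0 (-3 v0 + 4 v1 - v2)/(2 dr) - v0 = -q,  q = Q/(4 pi D alpha)
    # encoded as row 0 of the system (time-independent).
    a0 = -3.0 * r0_cm / (2.0 * dr_cm) - 1.0
    a1 = 4.0 * r0_cm / (2.0 * dr_cm)
    a2 = -r0_cm / (2.0 * dr_cm)
    # outer Dirichlet v=0
    rows, cols, vals = [], [], []
    for i in range(1, n - 1):
        rows += [i, i, i]
        cols += [i - 1, i, i + 1]
        vals += [-lam, main[i], -lam]
    rows += [0, 0, 0]
    cols += [0, 1, 2]
    vals += [a0, a1, a2]
    rows += [n - 1]
    cols += [n - 1]
    vals += [1.0]
    A = sp.csc_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
    lu = splu(A)

    q = Q_mol_s / (4.0 * np.pi * D_cm2_s * alpha)
    v = np.zeros(n)
    eval_times_s = np.asarray(eval_times_s, dtype=float)
    out = np.zeros_like(eval_times_s)
    next_eval = 0
    t = 0.0
    n_steps = int(np.ceil(eval_times_s.max() / dt_s))
    order = np.argsort(eval_times_s)
    sorted_times = eval_times_s[order]

    for step in range(n_steps + 1):
        t = step * dt_s
        while next_eval < len(sorted_times) and sorted_times[next_eval] <= t + 1e-9:
            out[order[next_eval]] = np.interp(r_eval_cm, r, v / r)
            next_eval += 1
        if next_eval >= len(sorted_times):
            break
        rhs = v.copy()
        rhs[0] = -q if t < pulse_s else 0.0
        rhs[-1] = 0.0
        v = lu.solve(rhs)
    while next_eval < len(sorted_times):  # times beyond the last full step
        out[order[next_eval]] = np.interp(r_eval_cm, r, v / r)
        next_eval += 1
    return out
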