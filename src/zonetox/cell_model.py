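"""Per-hepatocyte APAP metabolism and injury dynamics.

Ten coupled states per cell, all amounts in moles per cell, time in
seconds:

    Plob  extracellular APAP available to the cell
    Pin   intracellular APAP
    S     PAPS (sulfation co-substrate)
    N     NAPQI (toxic oxidative metabolite)
    G     glutathione
    C     NAPQI-Cys protein adduct
    H     healthy fraction of the cell
    Z     damaged fraction
    L     lysed fraction
    R     cumulative regenerated fraction

Intracellular APAP is cleared by sulfation (second order in PAPS),
glucuronidation (first order) and CYP450 oxidation (the three isoenzyme
rates averaged), partially returned by reverse oxidation; NAPQI is
detoxified by GSH conjugation or forms protein adducts that drive the
healthy fraction into damage, lysis and (slowly) regeneration.  The
identity dH + dZ + dL = 0 holds term by term, so H + Z + L is a conserved
quantity of the flow.

Two exposure modes are provided.  In the default *transport* mode the
extracellular pool is an externally prescribed forcing (the transport
surrogate's per-cell time course) and its own depletion equation is
inactive.  In *local-pool* mode each cell owns an extracellular pool,
initialized from its exposure peak, that depletes through uptake
(dPlob/dt = -ku * Plob).

Single cells integrate with SciPy's Radau implicit Runge-Kutta method
(stiff); whole-lobule batches use a fixed-step RK4 kernel compiled with
numba, validated against the Radau path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .errors import GridMismatchError, IntegrationError, InvalidParameterError
from .lobule import ExposureField, LobuleLattice
from .zonation import PARAM_NAMES, MetabolicParameters

STATE_NAMES = ("Plob", "Pin", "S", "N", "G", "C", "H", "Z", "L", "R")

#: classification codes
HEALTHY, DAMAGED, NECROSED, REGENERATED = 0, 1, 2, 3
LABELS = ("healthy", "damaged", "necrosed", "regenerated")

#: default absolute tolerances: molar pools live at the 1e-13..1e-15
#: scale, the H/Z/L/R fractions at order one
_ATOL_MOLAR = 1e-21
_ATOL_FRACTION = 1e-12


@dataclass(frozen=True)
class StateThresholds:
    """Cut-offs mapping continuous cell state to a discrete label.

    A cell is *necrosed* once its lysed fraction reaches ``necrosed_L``
    (a fully lysed cell is always necrosed), else *damaged* above
    ``damaged_Z``, else *regenerated* above ``regenerated_R``, else
    *healthy*.  The rule order makes lysis dominate.  Config-owned
    defaults; the discretization itself is a modeling choice.
    """

    necrosed_L: float = 0.5
    damaged_Z: float = 0.25
    regenerated_R: float = 0.05


@dataclass(frozen=True)
class CellTrajectory:
    """Time grid and the (n_times, 10) state matrix of one cell."""

    t: np.ndarray
    states: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]


def default_atol() -> np.ndarray:
    atol = np.full(10, _ATOL_MOLAR)
    atol[6:] = _ATOL_FRACTION
    return atol


def params_to_row(p: MetabolicParameters) -> np.ndarray:
    return np.array([getattr(p, name) for name in PARAM_NAMES])


def rhs(state: np.ndarray, p: MetabolicParameters | np.ndarray,
        plobule_forcing: float | None = None) -> np.ndarray:
    """Time derivative of the 10-state cell vector.

    With ``plobule_forcing`` given (transport mode) the extracellular pool
    equation is disabled and uptake draws on the forcing value; with
    ``None`` (local-pool mode) uptake draws on the state's own Plob, which
    depletes first order.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise InvalidParameterError("state must be finite")
    row = p if isinstance(p, np.ndarray) else params_to_row(p)
    if np.any(row < 0) or not np.all(np.isfinite(row)):
        raise InvalidParameterError("metabolic parameters must be finite and >= 0")
    local = plobule_forcing is None
    plob = state[0] if local else float(plobule_forcing)
    dy = np.empty(10)
    _rhs_py(state, row, plob, local, dy)
    return dy


def _rhs_py(y, p, plob, local_pool, dy):
    """Reference (pure python) right-hand side; mirrors the numba kernel."""
    ku, kS, kG = p[0], p[1], p[2]
    kcyp = (p[3] + p[4] + p[5]) / 3.0
    kN, kGSH, kPSH = p[6], p[7], p[8]
    bS, dS, bG, dG, dC = p[9], p[10], p[11], p[12], p[13]
    r, eta, deltaZ = p[14], p[15], p[16]
    Pin, S, N, G, C, H, Z = y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    regen = r * H * (1.0 - (H + Z))
    dy[0] = -ku * plob if local_pool else 0.0
    dy[1] = -kS * S * Pin - kG * Pin - kcyp * Pin + kN * N + ku * plob
    dy[2] = -kS * S * Pin + bS - dS * S
    dy[3] = kcyp * Pin - kN * N - kGSH * N * G - kPSH * N
    dy[4] = -kGSH * N * G + bG - dG * G
    dy[5] = kPSH * N - dC * C
    dy[6] = regen - eta * C * H
    dy[7] = eta * C * H - deltaZ * Z
    dy[8] = deltaZ * Z - regen
    dy[9] = regen


def initial_state(p: MetabolicParameters, plob0: float = 0.0) -> np.ndarray:
    """H = 1, GSH and PAPS at their starting pools, everything else zero."""
    y0 = np.zeros(10)
    y0[0] = plob0
    y0[2] = p.S0
    y0[4] = p.G0
    y0[6] = 1.0
    return y0


def integrate_cell(p: MetabolicParameters,
                   exposure: tuple[np.ndarray, np.ndarray] | float | None,
                   t_out: np.ndarray,
                   rtol: float = 1e-6,
                   atol: np.ndarray | float | None = None,
                   mode: str = "transport") -> CellTrajectory:
    """Integrate one hepatocyte with the Radau stiff solver.

    ``exposure`` is either a ``(t, c)`` pair sampling the extracellular
    forcing (linearly interpolated), a constant, or ``None`` for zero
    exposure.  In local-pool mode the pool starts at the exposure peak and
    the forcing is otherwise ignored.
    """
    t_out = np.asarray(t_out, dtype=float)
    if len(t_out) < 2:
        raise InvalidParameterError("t_out needs at least two points")
    if not (rtol > 0):
        raise InvalidParameterError("rtol must be > 0")
    if atol is None:
        atol = default_atol()

    if exposure is None:
        def forcing(t): return 0.0
        peak = 0.0
    elif isinstance(exposure, (int, float)):
        c0 = float(exposure)

        def forcing(t, c0=c0): return c0
        peak = c0
    else:
        ft, fc = np.asarray(exposure[0], float), np.asarray(exposure[1], float)
        if t_out[0] < ft[0] - 1e-9 or t_out[-1] > ft[-1] + 1e-9:
            raise GridMismatchError("t_out extends beyond the exposure grid")

        def forcing(t, ft=ft, fc=fc): return float(np.interp(t, ft, fc))
        peak = float(fc.max())

    local = mode == "local_pool"
    row = params_to_row(p)
    y0 = initial_state(p, plob0=peak if local else 0.0)

    def f(t, y):
        dy = np.empty(10)
        _rhs_py(y, row, y[0] if local else forcing(t), local, dy)
        return dy

    sol = solve_ivp(f, (t_out[0], t_out[-1]), y0, method="Radau",
                    t_eval=t_out, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"Radau failed: {sol.message}", t=sol.t[-1] if
                               len(sol.t) else t_out[0])
    states = sol.y.T.copy()
    if not local:
        states[:, 0] = [forcing(t) for t in sol.t]
    return CellTrajectory(t=sol.t, states=states)


@njit(cache=False)
def _forcing_at(F, i, t, dt_f):
    nf = F.shape[1]
    pos = t / dt_f
    j = int(pos)
    if j >= nf - 1:
        return F[i, nf - 1]
    frac = pos - j
    return F[i, j] * (1.0 - frac) + F[i, j + 1] * frac


@njit(cache=False)
def _rhs_nb(y, p, plob, local_pool, dy):
    ku, kS, kG = p[0], p[1], p[2]
    kcyp = (p[3] + p[4] + p[5]) / 3.0
    kN, kGSH, kPSH = p[6], p[7], p[8]
    bS, dS, bG, dG, dC = p[9], p[10], p[11], p[12], p[13]
    r, eta, deltaZ = p[14], p[15], p[16]
    Pin, S, N, G, C, H, Z = y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    regen = r * H * (1.0 - (H + Z))
    dy[0] = -ku * plob if local_pool else 0.0
    dy[1] = -kS * S * Pin - kG * Pin - kcyp * Pin + kN * N + ku * plob
    dy[2] = -kS * S * Pin + bS - dS * S
    dy[3] = kcyp * Pin - kN * N - kGSH * N * G - kPSH * N
    dy[4] = -kGSH * N * G + bG - dG * G
    dy[5] = kPSH * N - dC * C
    dy[6] = regen - eta * C * H
    dy[7] = eta * C * H - deltaZ * Z
    dy[8] = deltaZ * Z - regen
    dy[9] = regen


@njit(cache=False)
def _integrate_batch(P, F, plob0, dt_f, n_steps, dt, out_stride, local_pool):
    """Fixed-step RK4 over all cells; returns (n, n_out, 10) states."""
    n = P.shape[0]
    n_out = n_steps // out_stride + 1
    out = np.empty((n, n_out, 10))
    y = np.zeros((n, 10))
    for i in range(n):
        if local_pool:
            y[i, 0] = plob0[i]
        y[i, 2] = P[i, 18]
        y[i, 4] = P[i, 17]
        y[i, 6] = 1.0
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    yt = np.empty(10)
    for i in range(n):
        if not local_pool:
            y[i, 0] = _forcing_at(F, i, 0.0, dt_f)
        out[i, 0] = y[i]
    iout = 1
    for step in range(n_steps):
        t = step * dt
        th = t + 0.5 * dt
        t1 = t + dt
        for i in range(n):
            yi = y[i]
            pi = P[i]
            if local_pool:
                _rhs_nb(yi, pi, yi[0], True, k1)
                for s in range(10):
                    yt[s] = yi[s] + 0.5 * dt * k1[s]
                _rhs_nb(yt, pi, yt[0], True, k2)
                for s in range(10):
                    yt[s] = yi[s] + 0.5 * dt * k2[s]
                _rhs_nb(yt, pi, yt[0], True, k3)
                for s in range(10):
                    yt[s] = yi[s] + dt * k3[s]
                _rhs_nb(yt, pi, yt[0], True, k4)
            else:
                f0 = _forcing_at(F, i, t, dt_f)
                fh = _forcing_at(F, i, th, dt_f)
                f1 = _forcing_at(F, i, t1, dt_f)
                _rhs_nb(yi, pi, f0, False, k1)
                for s in range(10):
                    yt[s] = yi[s] + 0.5 * dt * k1[s]
                _rhs_nb(yt, pi, fh, False, k2)
                for s in range(10):
                    yt[s] = yi[s] + 0.5 * dt * k2[s]
                _rhs_nb(yt, pi, fh, False, k3)
                for s in range(10):
                    yt[s] = yi[s] + dt * k3[s]
                _rhs_nb(yt, pi, f1, False, k4)
            for s in range(10):
                yi[s] = yi[s] + (dt / 6.0) * (k1[s] + 2.0 * k2[s]
                                              + 2.0 * k3[s] + k4[s])
            if not local_pool:
                yi[0] = f1
        if (step + 1) % out_stride == 0:
            for i in range(n):
                out[i, iout] = y[i]
            iout += 1
    return out


@dataclass(frozen=True)
class LobuleResult:
    """Trajectories and discrete labels for every cell of a lobule run."""

    t: np.ndarray            # (n_out,)
    states: np.ndarray       # (n_cells, n_out, 10)
    labels: np.ndarray       # (n_cells, n_out) int8 codes

    def necrosed_series(self) -> np.ndarray:
        return (self.labels == NECROSED).sum(axis=0)


def classify_cell(state: np.ndarray,
                  thresholds: StateThresholds | None = None) -> str:
    """Discrete label of one cell state (pure function of state and cuts)."""
    th = thresholds or StateThresholds()
    return LABELS[_classify(np.asarray(state, float)[None, None, :], th)[0, 0]]


def _classify(states: np.ndarray, th: StateThresholds) -> np.ndarray:
    L, Z, R = states[..., 8], states[..., 7], states[..., 9]
    labels = np.full(L.shape, HEALTHY, dtype=np.int8)
    labels[R >= th.regenerated_R] = REGENERATED
    labels[Z >= th.damaged_Z] = DAMAGED
    labels[L >= th.necrosed_L] = NECROSED
    return labels


def run_lobule(lattice: LobuleLattice, field, exposure: ExposureField,
               batch_dt: float = 5.0, output_dt: float = 1800.0,
               thresholds: StateThresholds | None = None,
               mode: str = "transport") -> LobuleResult:
    """Integrate every hepatocyte of the lobule (one-way coupled).

    Cells are independent given their exposure rows; results are invariant
    under reordering of cells.  ``field`` is the per-cell parameter
    DataFrame from :func:`zonetox.zonation.build_parameter_field`.
    """
    P = np.ascontiguousarray(field.to_numpy(dtype=float))
    if P.shape[0] != lattice.n_cells or exposure.n_cells != lattice.n_cells:
        raise GridMismatchError(
            f"lattice ({lattice.n_cells}), field ({P.shape[0]}) and exposure "
            f"({exposure.n_cells}) disagree on cell count")
    if np.any(P < 0) or not np.all(np.isfinite(P)):
        raise InvalidParameterError("parameter field must be finite and >= 0")
    if batch_dt <= 0 or output_dt <= 0:
        raise InvalidParameterError("time steps must be > 0")

    F = np.ascontiguousarray(exposure.c)
    dt_f = float(exposure.t[1] - exposure.t[0])
    horizon = float(exposure.t[-1])
    out_stride = max(1, int(round(output_dt / batch_dt)))
    n_steps = int(round(horizon / batch_dt))
    n_steps -= n_steps % out_stride  # land outputs on the grid exactly
    plob0 = F.max(axis=1)
    local = mode == "local_pool"

    states = _integrate_batch(P, F, plob0, dt_f, n_steps, batch_dt,
                              out_stride, local)
    t = np.arange(states.shape[1]) * batch_dt * out_stride
    bad = np.where(~np.isfinite(states).all(axis=(1, 2)))[0]
    if len(bad):
        raise IntegrationError(
            f"integration produced non-finite states for cells {bad[:10]}"
            + ("..." if len(bad) > 10 else ""), cell_id=int(bad[0]))
    labels = _classify(states, thresholds or StateThresholds())
    return LobuleResult(t=t, states=states, labels=labels)
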