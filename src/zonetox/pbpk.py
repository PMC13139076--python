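"""Whole-body pharmacokinetics of an oral acetaminophen (APAP) overdose.

A minimal linear compartment surrogate (gut lumen -> portal vein -> liver ->
systemic circulation) produces the concentration of APAP entering the liver
over time.  The only contractually exact piece is the liver-inflow relation

    C_liver = (Q_liver * C_art + Q_gut * C_pv) / V_liver

which combines hepatic-arterial and portal-venous delivery; everything else
(flows, volumes, first-order absorption and clearance constants) is a
documented configuration default with literature-typical magnitudes, not a
published parameter set.

The portal vein is treated as a flow-through mixing point with no storage:
its concentration is the arterial concentration plus the absorbed drug flux
divided by portal flow.  The remaining system is linear with constant
coefficients, so trajectories are propagated exactly with a matrix
exponential; total drug (compartments plus cumulative eliminated and
metabolized amounts) is conserved to machine precision.

All times are seconds; drug amounts are moles (doses in grams are converted
with the APAP molar mass, 151.16 g/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import InvalidParameterError

#: molar mass of acetaminophen, g/mol
APAP_MOLAR_MASS = 151.16

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class PatientProfile:
    """An overdose case: ingested dose and simulation horizon.

    ``horizon_days`` is the time since intake covered by the simulation;
    internally everything runs in seconds (``horizon_s``).
    """

    id: str
    dose_g: float
    horizon_days: float

    def __post_init__(self):
        if not (self.dose_g >= 0 and math.isfinite(self.dose_g)):
            raise InvalidParameterError(f"dose must be >= 0, got {self.dose_g}")
        if not (self.horizon_days > 0 and math.isfinite(self.horizon_days)):
            raise InvalidParameterError(
                f"horizon must be > 0 days, got {self.horizon_days}")

    @property
    def dose_mol(self) -> float:
        return self.dose_g / APAP_MOLAR_MASS

    @property
    def horizon_s(self) -> float:
        return self.horizon_days * SECONDS_PER_DAY


@dataclass(frozen=True)
class PBPKParameters:
    """Constants of the compartmental surrogate (configuration defaults,
    literature-typical magnitudes rather than a published parameter set).

    QLiver : hepatic arterial blood flow, L/s
    QGut   : portal (splanchnic) blood flow, L/s
    VLiver : liver volume, L
    ka     : first-order gut absorption rate, 1/s
    Vart   : systemic (arterial) distribution volume, L
    kelim  : extra-hepatic (renal) elimination rate, 1/s
    khep   : hepatic metabolic clearance rate, 1/s
    """

    QLiver: float = 6.5e-3
    QGut: float = 1.75e-2
    VLiver: float = 1.8
    ka: float = 5.0e-4
    Vart: float = 42.0
    kelim: float = 4.0e-5
    khep: float = 2.0e-4

    def __post_init__(self):
        for name in ("QLiver", "QGut", "VLiver", "ka", "Vart", "kelim", "khep"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        if self.VLiver <= 0:
            raise InvalidParameterError("VLiver must be > 0")
        if self.Vart <= 0:
            raise InvalidParameterError("Vart must be > 0")


@dataclass(frozen=True)
class LiverInputSeries:
    """Time grid (s) and the APAP concentration entering the liver."""

    t: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "c", c)
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidParameterError("t and c must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("time grid must be strictly increasing")
        if np.any(c < 0):
            raise InvalidParameterError("liver input concentration must be >= 0")


def liver_inflow_concentration(c_art: float, c_pv: float,
                               p: PBPKParameters) -> float:
    """APAP concentration entering the liver from its two afferent supplies.

    Exact algebraic relation ``(QLiver*c_art + QGut*c_pv) / VLiver``.
    """
    if p.VLiver <= 0:
        raise InvalidParameterError("VLiver must be > 0")
    return (p.QLiver * c_art + p.QGut * c_pv) / p.VLiver


def _system_matrix(p: PBPKParameters) -> np.ndarray:
    """Generator of the closed linear system.

    State order: [A_gut, A_liver, A_sys, A_metabolized, A_excreted]
    (amounts, mol).  Portal vein is flow-through: the absorbed flux
    ka*A_gut rides portal flow straight into the liver, so every column
    sums to zero and total drug is conserved.
    """
    qsum = p.QGut + p.QLiver
    A = np.zeros((5, 5))
    A[0, 0] = -p.ka
    A[1, 0] = p.ka
    A[1, 1] = -(qsum / p.VLiver + p.khep)
    A[1, 2] = qsum / p.Vart
    A[2, 1] = qsum / p.VLiver
    A[2, 2] = -(qsum / p.Vart + p.kelim)
    A[3, 1] = p.khep
    A[4, 2] = p.kelim
    return A


def simulate_pbpk_full(patient: PatientProfile, p: PBPKParameters,
                       dt: float = 300.0):
    """Propagate the compartment system and return (t, amounts, series).

    ``amounts`` is (n_times, 5): gut, liver, systemic, cumulative
    metabolized, cumulative excreted -- their sum equals the dose at every
    step up to matrix-exponential round-off.  ``series`` is the
    :class:`LiverInputSeries` evaluated through
    :func:`liver_inflow_concentration` at every grid point.
    """
    if not (dt > 0 and math.isfinite(dt)):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if dt >= patient.horizon_s:
        raise InvalidParameterError("dt must be much smaller than the horizon")
    if p.QGut <= 0:
        raise InvalidParameterError(
            "QGut must be > 0: absorbed drug reaches the liver via portal flow")

    n = int(np.floor(patient.horizon_s / dt)) + 1
    t = np.arange(n) * dt
    A = _system_matrix(p)
    prop = expm(A * dt)

    amounts = np.empty((n, 5))
    y = np.array([patient.dose_mol, 0.0, 0.0, 0.0, 0.0])
    for i in range(n):
        amounts[i] = y
        y = prop @ y
    amounts = np.clip(amounts, 0.0, None)

    c_art = amounts[:, 2] / p.Vart
    c_pv = c_art + p.ka * amounts[:, 0] / p.QGut
    c = np.array([liver_inflow_concentration(a, v, p)
                  for a, v in zip(c_art, c_pv)])
    return t, amounts, LiverInputSeries(t=t, c=c)


def simulate_pbpk(patient: PatientProfile, p: PBPKParameters,
                  dt: float = 300.0) -> LiverInputSeries:
    """Liver-input APAP concentration over [0, horizon] for one patient."""
    return simulate_pbpk_full(patient, p, dt)[2]


def patient_fixtures() -> list[PatientProfile]:
    """The four representative overdose cases (low to high)."""
    return [
        PatientProfile(id="A", dose_g=6.1, horizon_days=3.9),
        PatientProfile(id="B", dose_g=10.5, horizon_days=3.4),
        PatientProfile(id="C", dose_g=20.5, horizon_days=3.4),
        PatientProfile(id="D", dose_g=27.1, horizon_days=4.5),
    ]
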