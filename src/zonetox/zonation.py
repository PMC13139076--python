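"""Zonated metabolic parameter fields for the liver lobule.

Seven hypotheses of metabolic zonation are studied, each varying one
mechanistic handle of the hepatocyte APAP model along the portal->central
axis at a controlled level (0, 20, 50 or 80 %):

    H1  APAP uptake rate ku            higher pericentrally
    H2  sulfation rate kS              higher periportally
    H3  glucuronidation rate kG        higher pericentrally
    H4  CYP450 oxidation (1A2/2E1/3A4) higher pericentrally, nonlinear
    H5  GSH pool (G0 and bG, coupled)  higher periportally
    H6  GSH-NAPQI binding rate kGSH    higher periportally
    H7  NAPQI-Cys formation rate kPSH  higher pericentrally

All gradients are mean-preserving: linear hypotheses pin the favored end
at baseline*(1+level) and the opposite end at baseline*(1-level), so the
average over the rank-normalized lattice equals the baseline exactly.  The
CYP isoenzymes (H4) use a monotone logistic profile pinned to measured
endpoint activities per level, with the midpoint located by bracketed
root-finding so the lattice mean equals the baseline.

Baseline rate constants are stored at one more significant digit than the
published three-significant-figure endpoint table where required for the
regenerated table to reproduce every printed cell (see docs/methods.md);
parameters the source tables do not constrain (kN, bS, dS, dG, dC, r, eta,
deltaZ, S0) are documented defaults, not published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import (InfeasibleProfileError, InvalidLevelError,
                     InvalidParameterError)
from .lobule import LobuleLattice

ZONATION_LEVELS = (0.0, 0.2, 0.5, 0.8)

CENTRAL_HIGH = "central_high"
PORTAL_HIGH = "portal_high"

#: hypothesis -> (impacted parameter names, direction)
HYPOTHESES: dict[str, tuple[tuple[str, ...], str]] = {
    "H1": (("ku",), CENTRAL_HIGH),
    "H2": (("kS",), PORTAL_HIGH),
    "H3": (("kG",), CENTRAL_HIGH),
    "H4": (("kCYP1A2", "kCYP2E1", "kCYP3A4"), CENTRAL_HIGH),
    "H5": (("G0", "bG"), PORTAL_HIGH),
    "H6": (("kGSH",), PORTAL_HIGH),
    "H7": (("kPSH",), CENTRAL_HIGH),
}

#: published per-level (portal, central) endpoint activities for the CYP
#: isoenzymes, model rate units (1/s)
CYP_ENDPOINTS: dict[str, dict[float, tuple[float, float]]] = {
    "kCYP1A2": {0.2: (2.34e-06, 2.87e-06),
                0.5: (1.88e-06, 3.20e-06),
                0.8: (1.43e-06, 3.54e-06)},
    "kCYP2E1": {0.2: (2.28e-06, 2.86e-06),
                0.5: (1.53e-06, 2.99e-06),
                0.8: (7.80e-07, 3.12e-06)},
    "kCYP3A4": {0.2: (4.55e-06, 6.30e-06),
                0.5: (3.06e-06, 7.43e-06),
                0.8: (1.56e-06, 8.55e-06)},
}


@dataclass(frozen=True)
class MetabolicParameters:
    """Per-hepatocyte kinetic constants of the APAP metabolism/injury model.

    Units are per-cell molar amounts and seconds.  ``ku, kS, kG, kCYP*,
    kGSH, kPSH, G0, bG`` carry the published non-zonated baselines (at
    working precision); the rest are configuration defaults.
    """

    ku: float = 8.333333e-05        # APAP uptake, 1/s
    kS: float = 2.615e+09           # sulfation, 1/(mol PAPS * s)
    kG: float = 3.46e-05            # glucuronidation, 1/s
    kCYP1A2: float = 2.60e-06       # oxidation, 1/s
    kCYP2E1: float = 2.80e-06
    kCYP3A4: float = 5.60e-06
    kN: float = 1.0e-04             # reverse oxidation, 1/s (default)
    kGSH: float = 1.852e+13         # NAPQI-GSH conjugation, 1/(mol GSH * s)
    kPSH: float = 1.274e-03         # NAPQI-Cys adduct formation, 1/s
    bS: float = 1.0e-19             # PAPS production, mol/s (default)
    dS: float = 2.0e-05             # PAPS degradation, 1/s (default)
    bG: float = 1.59e-19            # GSH production, mol/s
    dG: float = 1.59e-19 / 6.87e-15  # GSH degradation, 1/s (steady start)
    dC: float = 1.0e-04             # adduct clearance, 1/s (default)
    r: float = 2.0e-06              # regeneration, 1/s (default)
    eta: float = 8.0e+09            # damage per adduct, 1/(mol C * s) (default)
    deltaZ: float = 1.0e-04         # damaged -> lysed, 1/s (default)
    G0: float = 6.87e-15            # initial GSH, mol
    S0: float = 5.0e-15             # initial PAPS, mol

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(
                    f"{f.name} must be finite and >= 0, got {v}")

    def steady_start_consistent(self, rel: float = 1e-9) -> bool:
        """True when G0 == bG/dG and S0 == bS/dS (production/degradation
        steady state), within relative tolerance."""
        g_ok = self.dG > 0 and abs(self.G0 - self.bG / self.dG) <= rel * self.G0
        s_ok = self.dS > 0 and abs(self.S0 - self.bS / self.dS) <= rel * self.S0
        return g_ok and s_ok


PARAM_NAMES = tuple(f.name for f in fields(MetabolicParameters))


@dataclass(frozen=True)
class ZonationSpec:
    """One hypothesis at one zonation level."""

    hypothesis: str
    level: float
    steady_start: bool = True

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise InvalidParameterError(
                f"unknown hypothesis {self.hypothesis!r}; expected H1..H7")
        if not 0 <= self.level < 1:
            raise InvalidLevelError(
                f"zonation level must be in [0, 1), got {self.level}")
        if self.hypothesis == "H4" and self.level not in (0.0, 0.2, 0.5, 0.8):
            raise InvalidLevelError(
                "H4 endpoints are tabulated only for levels 0/0.2/0.5/0.8")

    @property
    def profile(self) -> str:
        return "cyp_nonlinear" if self.hypothesis == "H4" else "linear"

    @property
    def direction(self) -> str:
        return HYPOTHESES[self.hypothesis][1]

    @property
    def impacted(self) -> tuple[str, ...]:
        return HYPOTHESES[self.hypothesis][0]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Operates on the shortest decimal representation of the float so that
    printed-table values such as 3.435e-15 round up to 3.44e-15.
    """
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    exp = d.adjusted()
    q = d.scaleb(-exp).quantize(Decimal(1).scaleb(-(sig - 1)),
                                rounding=ROUND_HALF_UP)
    return float(q.scaleb(exp))


def linear_gradient(baseline: float, level: float, direction: str,
                    x: np.ndarray) -> np.ndarray:
    """Mean-preserving linear gradient along the portal->central axis.

    The favored end evaluates to ``baseline * (1 + level)``, the opposite
    end to ``baseline * (1 - level)``; on a uniformly spaced rank lattice
    the mean equals ``baseline`` exactly.
    """
    if not 0 <= level < 1:
        raise InvalidLevelError(
            f"level must be in [0, 1) to keep rates positive, got {level}")
    x = np.asarray(x, dtype=float)
    if direction == CENTRAL_HIGH:
        return baseline * (1.0 - level + 2.0 * level * x)
    if direction == PORTAL_HIGH:
        return baseline * (1.0 + level - 2.0 * level * x)
    raise InvalidParameterError(f"unknown direction {direction!r}")


def _logistic_profile(x: np.ndarray, m: float, w: float) -> np.ndarray:
    """Normalized logistic ramp: 0 at x=0, 1 at x=1, midpoint near m."""
    s = expit((x - m) / w)
    s0 = expit(-m / w)
    s1 = expit((1.0 - m) / w)
    return (s - s0) / (s1 - s0)


def cyp_gradient(baseline: float, central_endpoint: float,
                 portal_endpoint: float, x: np.ndarray,
                 width: float = 0.08) -> np.ndarray:
    """Monotone sigmoid pinned at both lobule ends, mean equal to baseline.

    The profile interpolates ``portal_endpoint`` at x=0 to
    ``central_endpoint`` at x=1 through a logistic ramp of fixed width;
    its midpoint is solved by bracketed root-finding (brentq) so that the
    lattice mean matches ``baseline`` to <= 1e-6 relative.  Requires the
    baseline to lie strictly between the endpoints (otherwise no
    mean-preserving monotone profile exists).
    """
    x = np.asarray(x, dtype=float)
    if central_endpoint == portal_endpoint:
        if not np.isclose(baseline, central_endpoint, rtol=1e-12):
            raise InfeasibleProfileError(
                "equal endpoints require baseline == endpoint value")
        return np.full_like(x, baseline)
    lo, hi = sorted((portal_endpoint, central_endpoint))
    if not lo < baseline < hi:
        raise InfeasibleProfileError(
            f"baseline {baseline} outside endpoint interval ({lo}, {hi})")

    span = central_endpoint - portal_endpoint

    def mean_err(m: float, w: float) -> float:
        v = portal_endpoint + span * _logistic_profile(x, m, w)
        return float(np.mean(v) - baseline)

    # sharpen the ramp if the requested width cannot reach the target mean
    # (relevant on coarse lattices, where the attainable mean fraction is
    # bounded by the pinned end values)
    a, b = -0.6, 1.6
    for w in (width, 0.05, 0.03, 0.02, 0.012):
        fa, fb = mean_err(a, w), mean_err(b, w)
        if fa * fb <= 0:
            m = brentq(mean_err, a, b, args=(w,), xtol=1e-13, rtol=8.9e-16)
            return portal_endpoint + span * _logistic_profile(x, m, w)
    raise InfeasibleProfileError(
        "no mean-preserving monotone profile: baseline mean unreachable "
        f"with pinned endpoints on this lattice (n={len(x)})")


def build_parameter_field(spec: ZonationSpec, lattice: LobuleLattice,
                          base: MetabolicParameters | None = None,
                          ) -> pd.DataFrame:
    """Per-cell metabolic parameter matrix for one zonation scenario.

    Only the hypothesis's impacted parameters vary across cells; the rest
    are uniform at baseline.  H5 applies a single gradient multiplier
    jointly to the GSH production rate bG and, in steady-start mode, the
    initial pool G0 = bG/dG (dG held fixed), keeping the pool at its
    production/degradation steady state in every cell.
    """
    base = base if base is not None else MetabolicParameters()
    x = lattice.x
    n = lattice.n_cells
    cols = {name: np.full(n, getattr(base, name)) for name in PARAM_NAMES}

    if spec.level > 0:
        if spec.hypothesis == "H4":
            for name in spec.impacted:
                portal, central = CYP_ENDPOINTS[name][spec.level]
                cols[name] = cyp_gradient(getattr(base, name), central,
                                          portal, x)
        elif spec.hypothesis == "H5":
            mult = linear_gradient(1.0, spec.level, spec.direction, x)
            cols["bG"] = base.bG * mult
            if spec.steady_start:
                cols["G0"] = cols["bG"] / base.dG
            else:
                cols["G0"] = base.G0 * mult
        else:
            for name in spec.impacted:
                cols[name] = linear_gradient(getattr(base, name), spec.level,
                                             spec.direction, x)

    field = pd.DataFrame(cols, index=pd.Index(lattice.cell_id, name="cell_id"))
    return field


#: (row label, hypothesis, parameter attribute, direction) of the linear
#: endpoint table, in publication order
LINEAR_TABLE_ROWS = (
    ("APAP uptake", "H1", "ku", CENTRAL_HIGH),
    ("Sulfation", "H2", "kS", PORTAL_HIGH),
    ("Glucuronidation", "H3", "kG", CENTRAL_HIGH),
    ("GSH initial concentration", "H5", "G0", PORTAL_HIGH),
    ("GSH production", "H5", "bG", PORTAL_HIGH),
    ("GSH binding", "H6", "kGSH", PORTAL_HIGH),
    ("NAPQI-Cys formation", "H7", "kPSH", CENTRAL_HIGH),
)


def zonation_table(base: MetabolicParameters | None = None,
                   levels: tuple[float, ...] = ZONATION_LEVELS,
                   ) -> pd.DataFrame:
    """Central/portal endpoint values of every linear hypothesis and level.

    Values are rounded to three significant figures (half away from zero),
    matching the publication style of the endpoint table.
    """
    base = base if base is not None else MetabolicParameters()
    rows = []
    for label, hyp, attr, direction in LINEAR_TABLE_ROWS:
        b = getattr(base, attr)
        for level in levels:
            central = linear_gradient(b, level, direction, np.array([1.0]))[0]
            portal = linear_gradient(b, level, direction, np.array([0.0]))[0]
            rows.append({
                "parameter": label, "hypothesis": hyp, "level": level,
                "central": round_sig(central), "portal": round_sig(portal),
            })
    return pd.DataFrame(rows)


def cyp_table(base: MetabolicParameters | None = None) -> pd.DataFrame:
    """Tabulated CYP endpoint activities per isoenzyme and level (3 s.f.)."""
    base = base if base is not None else MetabolicParameters()
    rows = []
    for name, per_level in CYP_ENDPOINTS.items():
        b = getattr(base, name)
        rows.append({"parameter": name, "level": 0.0,
                     "central": round_sig(b), "portal": round_sig(b)})
        for level, (portal, central) in per_level.items():
            rows.append({"parameter": name, "level": level,
                         "central": round_sig(central),
                         "portal": round_sig(portal)})
    return pd.DataFrame(rows)
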