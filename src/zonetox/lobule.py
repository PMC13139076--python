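"""Synthetic liver-lobule geometry, per-hepatocyte drug exposure and cohorts.

The lobule is reduced to its portal->central axis: each hepatocyte gets a
rank-normalized coordinate x in [0, 1] (0 = periportal, 1 = pericentral)
and one of three contiguous zones.  The default lattice carries 5,114
cells split 1,705 / 1,704 / 1,705 across zones 1-3.

Per-cell extracellular APAP exposure is produced by a one-dimensional
advection-dispersion-loss surrogate for sinusoidal blood flow: a cell at
coordinate x sees the liver-input signal delayed by ``x * transit_time``,
attenuated by ``exp(-uptake_loss * x * transit_time)`` (upstream cellular
uptake), and smoothed by a Gaussian dispersion kernel whose width grows
with the distance travelled.  The operator is linear in the inflow signal
and strictly attenuating along x whenever ``uptake_loss > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import (GridMismatchError, InvalidParameterError,
                     InvalidRangeError, InvalidSizeError)
from .pbpk import LiverInputSeries, PatientProfile

DEFAULT_N_CELLS = 5114


@dataclass(frozen=True)
class LobuleLattice:
    """Hepatocyte ids, portal->central coordinates and zone labels."""

    cell_id: np.ndarray
    x: np.ndarray
    zone: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cell_id)

    def zone_sizes(self) -> tuple[int, int, int]:
        return tuple(int(np.sum(self.zone == z)) for z in (1, 2, 3))


@dataclass(frozen=True)
class TransportParameters:
    """Constants of the 1-D sinusoid transport surrogate (package defaults,
    no published values exist for this lumped representation).

    transit_time : portal->central plasma transit time, s
    dispersion   : dimensionless axial mixing coefficient; the Gaussian
                   kernel applied at coordinate x has std
                   ``dispersion * x * transit_time`` seconds
    uptake_loss  : first-order loss rate along the path representing
                   upstream cellular uptake, 1/s
    """

    transit_time: float = 60.0
    dispersion: float = 0.2
    uptake_loss: float = 0.035

    def __post_init__(self):
        if not (self.transit_time > 0 and math.isfinite(self.transit_time)):
            raise InvalidParameterError("transit_time must be > 0")
        if self.dispersion < 0:
            raise InvalidParameterError("dispersion must be >= 0")
        if self.uptake_loss < 0:
            raise InvalidParameterError("uptake_loss must be >= 0")


@dataclass(frozen=True)
class ExposureField:
    """Shared time grid plus a (cells x time) extracellular APAP matrix."""

    t: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        if self.c.shape[1] != len(self.t):
            raise GridMismatchError(
                f"exposure matrix has {self.c.shape[1]} columns for "
                f"{len(self.t)} time points")

    @property
    def n_cells(self) -> int:
        return self.c.shape[0]


def build_lattice(n_cells: int = DEFAULT_N_CELLS) -> LobuleLattice:
    """Rank-normalized lattice with three contiguous, near-equal zones.

    Cells are ordered portal to central with ``x[i] = i / (n_cells - 1)``.
    The remainder of ``n_cells // 3`` goes to the outer zones first (so
    5,114 -> 1,705 / 1,704 / 1,705), keeping the mid-lobule band centered.
    """
    if n_cells < 3:
        raise InvalidSizeError(f"need at least 3 cells, got {n_cells}")
    q, r = divmod(n_cells, 3)
    if r == 0:
        sizes = (q, q, q)
    elif r == 1:
        sizes = (q + 1, q, q)
    else:
        sizes = (q + 1, q, q + 1)
    zone = np.repeat([1, 2, 3], sizes)
    x = np.arange(n_cells) / (n_cells - 1)
    return LobuleLattice(cell_id=np.arange(n_cells), x=x, zone=zone)


def transport_exposure(inflow: LiverInputSeries, lattice: LobuleLattice,
                       tp: TransportParameters,
                       scale: float = 1.0) -> ExposureField:
    """Per-cell exposure time courses from the liver-input signal.

    ``scale`` converts the inflow signal into a per-hepatocyte
    extracellular amount (a lumped sinusoid-volume x residence-time
    factor, configuration-owned); with the default 1.0 the output keeps
    the inflow's units.  The exposure grid equals the inflow grid (no
    resampling).
    """
    t = inflow.t
    if len(t) < 2:
        raise GridMismatchError("inflow series needs at least two time points")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt):
        raise GridMismatchError("inflow time grid must be uniform")

    n = lattice.n_cells
    out = np.empty((n, len(t)))
    for i in range(n):
        delay = lattice.x[i] * tp.transit_time
        delayed = np.interp(t - delay, t, inflow.c,
                            left=inflow.c[0], right=inflow.c[-1])
        sigma = tp.dispersion * delay / dt  # kernel std in samples
        if sigma > 0:
            delayed = gaussian_filter1d(delayed, sigma, mode="nearest")
        out[i] = delayed * math.exp(-tp.uptake_loss * delay)
    np.clip(out, 0.0, None, out=out)
    return ExposureField(t=t, c=out * scale)


def generate_cohort(n: int, dose_range_g: tuple[float, float],
                    horizon_range_days: tuple[float, float],
                    seed: int) -> list[PatientProfile]:
    """Random virtual patients with doses/horizons uniform in range."""
    if n < 0:
        raise InvalidRangeError(f"cohort size must be >= 0, got {n}")
    if dose_range_g[0] > dose_range_g[1]:
        raise InvalidRangeError(f"inverted dose range {dose_range_g}")
    if horizon_range_days[0] > horizon_range_days[1]:
        raise InvalidRangeError(f"inverted horizon range {horizon_range_days}")
    rng = np.random.default_rng(seed)
    doses = rng.uniform(*dose_range_g, size=n)
    horizons = rng.uniform(*horizon_range_days, size=n)
    return [PatientProfile(id=f"V{i:03d}", dose_g=float(d),
                           horizon_days=float(h))
            for i, (d, h) in enumerate(zip(doses, horizons))]
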