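"""Exception hierarchy for the zonetox pipeline."""


class ZonetoxError(Exception):
    """Base class for all zonetox-specific errors."""


class InvalidParameterError(ZonetoxError, ValueError):
    """A physical or kinetic parameter is out of its admissible range."""


class InvalidSizeError(ZonetoxError, ValueError):
    """Requested lattice size cannot hold three zones."""


class InvalidRangeError(ZonetoxError, ValueError):
    """A (low, high) sampling range is inverted."""


class InvalidLevelError(ZonetoxError, ValueError):
    """Zonation level outside [0, 1) would produce negative rates."""


class InfeasibleProfileError(ZonetoxError, ValueError):
    """No mean-preserving monotone profile exists for the given endpoints."""


class GridMismatchError(ZonetoxError, ValueError):
    """Time grids or array shapes of coupled stages do not agree."""


class DegenerateTableError(ZonetoxError, ValueError):
    """Contingency table has a zero row or column margin."""


class IntegrationError(ZonetoxError, RuntimeError):
    """The ODE integrator failed; carries the failing cell id and time."""

    def __init__(self, message: str, cell_id: int | None = None,
                 t: float | None = None):
        super().__init__(message)
        self.cell_id = cell_id
        self.t = t
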