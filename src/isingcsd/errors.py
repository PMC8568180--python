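"""Exception types shared across the package."""


class IsingCSDError(Exception):
    """Base class for package-specific errors."""


class SimulationDivergedError(IsingCSDError):
    """A simulated state became non-finite (divergent parameters)."""


class NoBistableRegionError(IsingCSDError):
    """Fold points requested for a coupling without bistability."""


class ConstantSeriesError(IsingCSDError):
    """An indicator requiring variance was given a constant series."""


class EstimationError(IsingCSDError):
    """The bifurcation estimator received degenerate input."""
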