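"""Exception hierarchy shared across the package."""


class BsakitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BsakitError, ValueError):
    """A simulation or filter parameter is out of its valid range."""


class SimulationError(BsakitError, RuntimeError):
    """The simulator could not satisfy a construction constraint."""


class SamplingError(BsakitError, RuntimeError):
    """Not enough individuals of the requested class to form a pool."""


class ConfigError(BsakitError, ValueError):
    """Invalid filter/run configuration."""


class UsageError(BsakitError, ValueError):
    """An operation was called in a way its contract forbids."""


class DataIntegrityError(BsakitError, ValueError):
    """Input data contradicts the reference it claims to derive from."""


class CoordinateError(BsakitError, ValueError):
    """A genomic coordinate falls outside the reference."""


class ChemistryError(BsakitError, ValueError):
    """A formula or fragmentation request is chemically inconsistent."""


class FormatError(BsakitError, ValueError):
    """A file does not conform to the expected format."""


class FitError(BsakitError, RuntimeError):
    """A regression/fit is degenerate (e.g. zero slope, no x-variance)."""
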