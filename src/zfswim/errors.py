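"""Exception hierarchy shared across the analysis stages."""


class ZfswimError(Exception):
    """Base class for all package errors."""


class InvalidConditionError(ZfswimError, ValueError):
    """Physical conditions (temperature, pressure, speed...) out of the valid domain."""


class InsufficientDataError(ZfswimError, ValueError):
    """Too few observations for the requested estimate."""


class TraceFormatError(ZfswimError, ValueError):
    """Malformed oxygen trace (non-monotone timestamps, bad phase flag, ...)."""


class ProtocolError(ZfswimError, ValueError):
    """Incremental-velocity trial record violates the stepped protocol."""


class MeasurementMissingError(ZfswimError, ValueError):
    """A morphometric needed for a conversion was not recorded."""


class UnderdeterminedError(ZfswimError, ValueError):
    """Not enough distinct support points to fit the requested curve."""


class NoMinimumError(ZfswimError, ValueError):
    """The fitted cost-of-transport parabola opens downward: no interior optimum."""


class NormalizationError(ZfswimError, ValueError):
    """Target and housekeeping wells come from incompatible primer sets."""


class PlateFormatError(ZfswimError, ValueError):
    """qPCR well group does not hold exactly three replicates."""


class DegenerateDataError(ZfswimError, ValueError):
    """Zero-variance sample where a spread-based statistic is required."""


class PairingError(ZfswimError, ValueError):
    """Paired comparison requested but pre/post fish identities do not match."""


class ConfigError(ZfswimError, ValueError):
    """Run configuration is inconsistent or references missing inputs."""
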