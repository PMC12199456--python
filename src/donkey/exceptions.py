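"""Exception hierarchy for the donkey package."""


class DonkeyError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandwidthError(DonkeyError):
    """Covariance matrix is not symmetric positive definite."""


class InsufficientDataError(DonkeyError):
    """Operation requires more data points than were supplied."""


class ParameterError(DonkeyError):
    """A tuning parameter is outside its valid range."""


class TrajectoryFormatError(DonkeyError):
    """A trajectory file could not be parsed or is inconsistent."""


class MissingIntermediatesError(DonkeyError):
    """A warm restart was requested but the stored intermediates are absent."""
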