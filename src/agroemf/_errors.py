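"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`AgroemfError`, so callers can catch one type at pipeline level.
"""


class AgroemfError(Exception):
    """Base class for all agroemf errors."""


class InvalidDesignError(AgroemfError):
    """The experimental design table violates a structural invariant."""


class UnsupportedDesignError(AgroemfError):
    """The design is valid but outside what the analysis supports (e.g. unbalanced)."""


class ConfigurationError(AgroemfError):
    """A configuration value is missing, unknown or inconsistent."""


class MissingDataError(AgroemfError):
    """A required observation (plot, year, function, component) is absent."""


class InsufficientDataError(AgroemfError):
    """Too few observations for the requested estimate."""


class DomainError(AgroemfError, ValueError):
    """An input value lies outside the operation's mathematical domain."""


class DegenerateRangeError(DomainError):
    """All values identical: min-max normalization is undefined."""


class EmptyCommunityError(DomainError):
    """All taxon counts are zero: diversity is undefined."""


class MassGainError(DomainError):
    """Litterbag final mass exceeds the initial mass."""


class CollinearityError(AgroemfError):
    """Design matrix is rank deficient; coefficients not identifiable."""


class FixtureError(AgroemfError):
    """A synthetic fixture would be built with corrupted ground truth."""
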