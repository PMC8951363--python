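"""Exception hierarchy shared across the pipeline.

Every error raised deliberately by venomscale derives from
:class:`VenomscaleError`, so callers (including the CLI) can distinguish
user/data problems from genuine bugs.
"""


class VenomscaleError(Exception):
    """Base class for all errors raised by venomscale."""


class UnitError(VenomscaleError):
    """An LD50 unit token is not recognized."""


class MissingMassError(VenomscaleError):
    """A per-animal dose cannot be converted without the subject's body mass."""


class ValidationError(VenomscaleError):
    """A record or table violates a structural invariant."""


class ConfigurationError(VenomscaleError):
    """A configuration value (proxy table, generator config, MCMC settings) is invalid."""


class NewickParseError(VenomscaleError):
    """A Newick string could not be parsed."""


class PhylogenyError(VenomscaleError):
    """A tree operation received an invalid tree or tip set."""
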