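"""Exception hierarchy shared across the pipeline stages."""


class SeedfolioError(Exception):
    """Base class for all package errors."""


class ConfigError(SeedfolioError):
    """Invalid configuration (bad rates, empty grids, degenerate bounds...)."""


class SchemaError(SeedfolioError):
    """A required column is missing or malformed; the message names it."""


class AllVarietiesEliminatedError(SeedfolioError):
    """The yield-ratio filter removed every variety; selection is undefined."""


class NumericalError(SeedfolioError):
    """A numerical contract was violated (zero variance, non-PSD input...)."""
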