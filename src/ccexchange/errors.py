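"""Exception hierarchy for ccexchange.

Everything derives from :class:`CCExchangeError` so callers can catch the
package's failures with one clause; the concrete classes mirror the distinct
failure modes of the pipeline (bad domain values, malformed files, fits that
cannot converge, degenerate assay data).
"""


class CCExchangeError(Exception):
    """Base class for all ccexchange errors."""


class DomainError(CCExchangeError, ValueError):
    """A numeric argument is outside its physically meaningful domain."""


class InvalidOligomerError(DomainError):
    """Oligomer state or topology is not supported (n < 2, non-parallel)."""


class InputError(CCExchangeError, ValueError):
    """Structurally invalid input (wrong shape, too few points, non-monotone
    time grid, non-square matrix, ...)."""


class SchemaError(InputError):
    """A file or record set does not match the expected schema."""


class ConfigError(CCExchangeError, ValueError):
    """A run configuration contains unknown or inconsistent keys."""


class IntegrationError(CCExchangeError, RuntimeError):
    """The ODE integrator failed; the message carries solver diagnostics."""


class FitFailureError(CCExchangeError, RuntimeError):
    """A nonlinear fit did not converge after the bounded restart schedule,
    or the data cannot constrain the rate within the searched range."""


class DegenerateTraceError(InputError):
    """A time course has no resolvable signal development (amplitude
    indistinguishable from baseline noise)."""


class AnchorError(InputError):
    """Required normalization anchor records are missing for a peptide."""


class DegenerateAnchorError(AnchorError):
    """Anchor records exist but max_anchor <= min_anchor."""
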