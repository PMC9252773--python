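"""Exception hierarchy shared across the package.

Validation and parse errors indicate bad user input (CLI exit code 1);
anything else bubbling out of an analysis is a runtime error (exit code 2).
"""


class OmicPathsError(Exception):
    """Base class for all package errors."""


class ParseError(OmicPathsError):
    """A flat file could not be parsed; the message names the line."""


class ValidationError(OmicPathsError):
    """Input violated a structural invariant (duplicate IDs, bad edge, ...)."""


class ConfigurationError(OmicPathsError):
    """An analysis cannot run as configured (e.g. no measured genes)."""


class UndefinedTestError(OmicPathsError):
    """A statistical test is undefined for the given counts (e.g. n = 0)."""


class NotApplicableError(OmicPathsError):
    """Operation does not apply (e.g. too few features for a metagene)."""
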