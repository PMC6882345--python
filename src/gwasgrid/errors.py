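"""Exception hierarchy shared across the package.

Each class maps to a distinct non-zero exit code in the CLI.
"""


class GwasGridError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(GwasGridError):
    """A configuration file or column mapping is wrong (missing column,
    duplicate rule index, uncovered flag combination, bad colour)."""

    exit_code = 3


class InputError(GwasGridError):
    """An input file is missing, unreadable or empty."""

    exit_code = 4


class ValidationError(GwasGridError):
    """A data value violates an invariant (p-value outside (0,1],
    odds ratio <= 0, unknown novelty term, ...)."""

    exit_code = 5


class CapacityError(GwasGridError):
    """Table annotation mode was requested with more loci than fit."""

    exit_code = 6


class ClassificationError(GwasGridError):
    """No classification rule matches a cell (only reachable with a rule
    set that bypassed validation)."""

    exit_code = 5


class RenderError(GwasGridError):
    """Figure could not be written."""

    exit_code = 7
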