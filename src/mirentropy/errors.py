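"""Exception hierarchy shared across the package.

Every error raised by mirentropy derives from :class:`MirEntropyError`, so
callers (and the CLI) can distinguish package failures from programming
errors.  Each subclass maps to a distinct CLI exit status.
"""


class MirEntropyError(Exception):
    """Base class for all mirentropy errors."""

    exit_code = 1


class FormatError(MirEntropyError):
    """An input file or text block violates its declared dialect."""

    exit_code = 3


class ValidationError(MirEntropyError):
    """Parsed data violates a domain invariant (bad counts, bad windows...)."""

    exit_code = 4


class ConfigurationError(MirEntropyError):
    """Invalid parameter combination (thresholds, fractions, offset grids)."""

    exit_code = 5


class EmptyCohortError(MirEntropyError):
    """No mature miRNA survived the depth filter."""

    exit_code = 6


class DegenerateDataError(MirEntropyError):
    """A statistical test received data it cannot operate on
    (all-zero differences, zero variance)."""

    exit_code = 7
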