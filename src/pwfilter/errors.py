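"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: :class:`InputError` and subclasses map to
exit status 2, :class:`ParameterError` to exit status 3.
"""


class PWFilterError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class InputError(PWFilterError):
    """Invalid input data (bad file, bad samples, too few beats)."""

    exit_code = 2


class FormatError(InputError):
    """A file does not follow the expected layout (e.g. missing columns)."""


class SamplingError(InputError):
    """Timestamps are not uniformly spaced within tolerance."""


class InsufficientBeatsError(InputError):
    """Fewer than two R-peaks available, so beats cannot be delimited."""


class ParameterError(PWFilterError):
    """An invalid configuration parameter (e.g. cutoff above Nyquist)."""

    exit_code = 3
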