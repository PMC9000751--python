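"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are 2 (click's default),
:class:`DataFormatError` is 3, :class:`PreconditionError` and
:class:`ConfigError` are 4.
"""


class RanksigError(Exception):
    """Base class for all package errors."""


class DataFormatError(RanksigError):
    """A file or in-memory container violates its format contract."""


class PreconditionError(RanksigError):
    """An operation was called with arguments outside its contract."""


class ConfigError(RanksigError):
    """A simulation or pipeline configuration is internally inconsistent."""


class PipelineError(RanksigError):
    """A pipeline stage cannot run, e.g. a required upstream artifact is missing."""
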