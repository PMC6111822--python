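"""Exception hierarchy shared across the package.

All readers and computational routines raise one of these instead of letting
bare ``ValueError``/``KeyError`` leak, so callers (and the pipeline driver)
can report which stage failed and why.
"""


class RevmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RevmapError):
    """A simulation or run configuration field is invalid."""


class InputError(RevmapError):
    """Caller supplied inconsistent or incomplete inputs."""


class FormatError(RevmapError):
    """A file on disk does not conform to its declared dialect."""


class EstimationError(RevmapError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
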