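"""Exception hierarchy shared by all pipeline stages.

The distinction matters at the command line, where each class maps to a
distinct exit code (parameter 2, format 3, integrity 4, pipeline 5).
"""


class RefscaffError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class ParameterError(RefscaffError):
    """A caller-supplied parameter is out of its documented domain."""

    exit_code = 2


class FormatError(RefscaffError):
    """An input file violates its declared format (names the record)."""

    exit_code = 3


class IntegrityError(RefscaffError):
    """Internally inconsistent data, e.g. an alignment overrunning its target."""

    exit_code = 4


class PipelineError(RefscaffError):
    """A stage could not produce its contract output (e.g. empty assembly)."""

    exit_code = 5
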