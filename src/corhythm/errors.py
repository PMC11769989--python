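"""Exception hierarchy shared across the package.

``ValidationError`` signals malformed inputs or configuration (CLI exit
code 2); ``AnalysisError`` signals a failure during computation on valid
inputs (CLI exit code 1).
"""


class CorhythmError(Exception):
    """Base class for all package errors."""


class ValidationError(CorhythmError, ValueError):
    """Invalid input data, file format, or configuration."""


class AnalysisError(CorhythmError, RuntimeError):
    """A computation could not be carried out on otherwise valid input."""
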