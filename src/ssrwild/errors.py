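"""Exception hierarchy.

``ValidationError`` marks malformed input or violated invariants (CLI exit 2);
``PipelineError`` marks a runtime failure inside a pipeline stage (CLI exit 1).
"""


class SSRWildError(Exception):
    """Base class for all package errors."""


class ValidationError(SSRWildError, ValueError):
    """Invalid input data, configuration, or violated domain invariant."""


class PipelineError(SSRWildError, RuntimeError):
    """A pipeline stage failed at run time."""
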