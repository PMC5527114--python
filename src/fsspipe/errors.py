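"""Exception hierarchy shared across the pipeline.

Validation errors map to CLI exit code 2, computation errors to 3.
"""


class FsspipeError(Exception):
    """Base class for all package errors."""


class ValidationError(FsspipeError):
    """Invalid inputs, configuration, or domain-constraint violations."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending line where possible."""


class ComputationError(FsspipeError):
    """A statistical routine could not produce a result (degenerate design,
    monomorphic marker, undefined LD, ...)."""
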