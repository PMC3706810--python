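"""Exception hierarchy shared across the simulator."""


class PopseqError(Exception):
    """Base class for all popseqsim errors."""


class ParseError(PopseqError):
    """A configuration or data file could not be parsed.

    The message names the offending file and line.
    """


class ValidationError(PopseqError):
    """An in-memory object or parameter set violates its invariants."""
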