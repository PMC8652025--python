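"""Exception hierarchy.

``VssError`` is the base class for every error raised deliberately by this
package; the CLI maps it to exit code 1 (data/validation problems), while
argument misuse surfaces as the usual usage errors (exit code 2).
"""


class VssError(Exception):
    """Base class for all errors raised by vss."""


class ParseError(VssError):
    """A file could not be parsed (message includes the offending line)."""


class ValidationError(VssError):
    """Input data violated an invariant (overlap, sign, coverage, ...)."""
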