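"""Exception hierarchy shared across the toolkit.

Validation problems (bad values, broken invariants) and schema problems
(missing columns/keys, malformed files) are kept distinct so callers —
in particular the CLI — can map them to exit codes and messages.
"""


class SBRError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(SBRError):
    """A file or mapping does not have the expected structure."""


class ValidationError(SBRError):
    """Structurally well-formed input violates a domain invariant."""
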