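"""Exception hierarchy with stable machine-readable codes.

Document invariant violations are *reported* (see :mod:`bcokit.model`), never
raised; exceptions are reserved for operations that cannot produce a partial
result (parsing, sealing, lifecycle actions, kit execution).
"""

from __future__ import annotations


class BcoError(Exception):
    """Base class; every instance carries a stable ``code`` token."""

    code: str = "ERROR"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class BcoParseError(BcoError):
    """Malformed JSON (``PARSE_ERROR``) or repeated member (``DUPLICATE_KEY``)."""

    code = "PARSE_ERROR"

    def __init__(self, message: str, *, code: str | None = None,
                 line: int | None = None, column: int | None = None):
        super().__init__(message, code=code)
        self.line = line
        self.column = column


class EmitError(BcoError):
    code = "EMIT_ERROR"


class UnsignedError(BcoError):
    """Signature verification requested on an envelope with no signature."""

    code = "UNSIGNED"


class LifecycleError(BcoError):
    """Illegal derivation, transition, edit or version string."""

    code = "LIFECYCLE_ERROR"


class LineageError(BcoError):
    """``DANGLING_ANCESTOR`` or ``CYCLE`` while walking inheritance."""

    code = "LINEAGE_ERROR"


class KitError(BcoError):
    """Verification-kit failures: missing files, checksum or runner problems."""

    code = "KIT_ERROR"


class ForgeBoundsError(BcoError):
    code = "FORGE_BOUNDS"
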