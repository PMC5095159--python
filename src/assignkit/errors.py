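"""Exception hierarchy.

Everything raised deliberately by assignkit derives from :class:`AssignKitError`
so callers (and the CLI) can distinguish domain errors from genuine bugs.
"""


class AssignKitError(Exception):
    """Base class for all assignkit domain errors."""


class PidError(AssignKitError, ValueError):
    """A PID string is syntactically malformed."""


class PidLookupError(AssignKitError, KeyError):
    """A well-formed PID does not resolve to an object in this project."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return str(self.args[0]) if self.args else ""


class ConflictError(AssignKitError):
    """An operation would violate uniqueness or adjacency constraints."""


class TypeMismatchError(ConflictError):
    """Residue types disagree between an NmrResidue and its assignment target."""


class UnsupportedFormatError(AssignKitError):
    """A file format outside the supported subset was requested."""


class UnsupportedNefBlockError(UnsupportedFormatError):
    """A mandatory NEF saveframe category is not implemented."""


class SpectrumFormatError(AssignKitError, ValueError):
    """A gridded-spectrum file is corrupt or inconsistent."""
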