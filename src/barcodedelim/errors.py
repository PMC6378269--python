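"""Exception hierarchy shared across the package."""


class BarcodeDelimError(Exception):
    """Base class for all package errors."""


class InputError(BarcodeDelimError, ValueError):
    """Unreadable, empty, or structurally invalid input."""


class AlignmentError(InputError):
    """Sequences violate the fixed-length alignment contract."""


class IdentifierError(InputError):
    """Duplicate or unknown sample identifiers."""


class ConfigurationError(BarcodeDelimError, ValueError):
    """Invalid analysis configuration."""


class AssignmentError(BarcodeDelimError, ValueError):
    """A partition does not cover the required identifier universe."""


class DegeneratePairError(BarcodeDelimError, ValueError):
    """A sequence pair shares no valid (unambiguous) columns."""


class TreeError(BarcodeDelimError, ValueError):
    """Malformed tree input or violated tree precondition."""
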