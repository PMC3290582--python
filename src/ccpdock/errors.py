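"""Exception hierarchy for ccpdock."""


class CCPDockError(Exception):
    """Base class for all ccpdock errors."""


class PDBParseError(CCPDockError):
    """Raised when PDB text cannot be parsed into atom records."""


class EmptyInterfaceError(CCPDockError):
    """Raised when an operation requires a nonzero interaction profile."""


class WeightModelError(CCPDockError):
    """Raised when a weight-model file is malformed."""
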