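"""Exception hierarchy."""


class ProtQAError(Exception):
    """Base class for all package errors."""


class PDBError(ProtQAError):
    """Unreadable or unwritable structure file."""


class EmptyStructureError(PDBError):
    """A structure file yielded zero standard residues."""


class GeometryError(ProtQAError):
    """Degenerate geometry (e.g. undefined dihedral)."""


class SuperpositionError(ProtQAError):
    """Too few points, or otherwise impossible superposition."""


class PairingError(ProtQAError):
    """Model and reference share fewer than 3 pairable residues."""


class TableError(ProtQAError):
    """Preference tables could not be built or loaded."""


class ValidationError(ProtQAError):
    """Invalid numeric input (non-finite values, bad shapes, bad ranges)."""


class ModelIOError(ProtQAError):
    """Model archive missing, corrupted, or of an incompatible version."""


class GroupingError(ProtQAError):
    """Cross-validation asked for more folds than distinct groups."""
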