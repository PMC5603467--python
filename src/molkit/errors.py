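"""Exception hierarchy.

Every error raised on a documented failure path derives from :class:`MolkitError`
so callers (and the CLI) can distinguish data/format problems from programming
bugs with a single ``except`` clause.
"""


class MolkitError(Exception):
    """Base class for all molkit errors."""


class SelectionBoundsError(MolkitError, IndexError):
    """A selection references an atom index outside [0, n_atoms)."""


class SelectionMismatchError(MolkitError):
    """Binary selection-algebra operands refer to different molecule sizes."""


class EmptySelectionError(MolkitError):
    """An operation that requires at least one selected atom got none."""


class SelectionOverlapError(MolkitError):
    """Two selections required to be disjoint overlap."""


class FrameBoundsError(MolkitError, IndexError):
    """A frame index is outside the molecule's trajectory."""


class AtomBoundsError(MolkitError, IndexError):
    """An atom index is outside [0, n_atoms)."""


class RecordParseError(MolkitError):
    """A fixed-column record could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TrajectoryConsistencyError(MolkitError):
    """MODEL blocks disagree on atom count or ordering."""


class FieldOverflowError(MolkitError):
    """A value cannot be rendered inside its fixed-width text field."""


class PymFormatError(MolkitError):
    """Byte stream is not a valid PYM container (bad magic/version/flags)."""


class PymTruncationError(PymFormatError):
    """PYM stream ended early; carries the byte offset where data ran out."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


class CriteriaError(MolkitError):
    """A selection criterion names an unknown column or has a bad shape."""


class InvalidBranchError(MolkitError):
    """Branch selection requested for a root/away_from pair that is not bonded."""


class DegenerateAxisError(MolkitError):
    """Rotation axis endpoints coincide (zero-length axis)."""


class EmptyPairingError(MolkitError):
    """A pairing-based operation received zero atom pairs."""


class NoCorrespondenceError(EmptyPairingError):
    """The pairing heuristic found no atoms with matching keys."""


class EmptyMoleculeError(MolkitError):
    """An operation requires a non-empty molecule."""


class MergeShapeError(MolkitError):
    """Molecules to merge have different frame counts."""


class AnnotationError(MolkitError):
    """A per-atom annotation does not match the molecule's shape."""


class ParameterError(MolkitError, ValueError):
    """A generator or operation received an out-of-domain parameter."""
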