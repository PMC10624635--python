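"""Exception hierarchy shared across the toolkit."""


class PloopkitError(Exception):
    """Base class for all toolkit errors."""


class StructureIOError(PloopkitError):
    """Unreadable or unwritable structure file."""


class FormatError(PloopkitError):
    """Unknown or undeclared structure file format."""


class EmptyModelError(PloopkitError):
    """A structure contains no polymer residues where some are required."""


class ChainLookupError(PloopkitError, KeyError):
    """Requested chain id is not present in the model."""


class GeometryError(PloopkitError):
    """Degenerate geometry: collinear dihedral points, rank-deficient
    superposition, or too few paired atoms."""


class AtomError(PloopkitError):
    """A referenced atom could not be resolved."""


class SpecError(PloopkitError, ValueError):
    """Invalid user-supplied specification (ranges, angles, presets)."""


class RadiusError(PloopkitError):
    """No van-der-Waals radius known for an element."""


class FeasibilityError(PloopkitError):
    """A constraint set admits no satisfying pose."""
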