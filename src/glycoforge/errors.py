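"""Exception hierarchy shared across the package."""


class GlycoforgeError(Exception):
    """Base class for all package errors."""


class UnsupportedSugarError(GlycoforgeError):
    """A sugar name, or a (config, ring, anomer) combination, is not in the registry."""


class TopologyError(GlycoforgeError):
    """A graph edit would violate the tree/linkage invariants."""


class NotationError(GlycoforgeError):
    """IUPAC-condensed text could not be parsed or written.

    Carries ``offset`` (character position) when raised by the parser.
    """

    def __init__(self, message, offset=None):
        super().__init__(message)
        self.offset = offset


class ComponentError(GlycoforgeError):
    """Chemical-component parsing or editing failed."""


class JobError(GlycoforgeError):
    """An AlphaFold 3 job could not be assembled."""


class StructureError(GlycoforgeError):
    """A coordinate file could not be read or interpreted."""


class GeometryError(GlycoforgeError):
    """Degenerate or infeasible geometry (collinear ring, rank-deficient point set...)."""
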