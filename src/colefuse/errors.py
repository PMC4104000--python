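"""Exception taxonomy shared by all colefuse modules."""


class ColefuseError(Exception):
    """Base class for all toolkit errors."""


class PdbParseError(ColefuseError):
    """A PDB file could not be parsed (malformed record, bad coordinates)."""


class PdbFormatError(ColefuseError):
    """A Structure cannot be serialized to legal PDB (e.g. multi-char chain id)."""


class TopologyError(ColefuseError):
    """Coordinate frames disagree on atom count or order."""


class SelectionError(ColefuseError):
    """A selection expression names an unknown field or is malformed."""


class InsufficientPointsError(ColefuseError):
    """Fewer than three points supplied to a rigid-body superposition."""


class DegenerateGeometryError(ColefuseError):
    """Point set is collinear (or otherwise rank-deficient) — rotation undetermined."""


class SuperpositionAtomsError(ColefuseError):
    """A windowed nucleotide lacks one of the atoms needed for superposition."""


class EmptyInputError(ColefuseError):
    """An operation requiring a non-empty collection received an empty one."""


class AlphabetError(ColefuseError):
    """A nucleotide string contains characters outside A/C/G/T."""


class CompositionError(ColefuseError):
    """A fusion composition violates X + Y < 131 or related bookkeeping rules."""


class RangeError(ColefuseError):
    """A residue position lies outside the nuclease numbering 446-576."""


class MappingError(ColefuseError):
    """A catalytic-residue mapping names an atom absent from the topology."""


class ParameterError(ColefuseError):
    """Nonbonded parameters are missing for an atom in an evaluated group."""


class GraftError(ColefuseError):
    """Linker grafting left an unresolvable steric clash."""


class InputError(ColefuseError):
    """Generic invalid numeric/structural input (negative counts, bad lengths)."""
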