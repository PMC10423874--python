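"""Exception types shared across the package."""


class FodmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FodmError):
    """A structure file could not be read or parsed."""


class EmptyUnitError(FodmError):
    """A parsed structure contains no standard amino-acid residues."""


class UnknownResidueError(FodmError):
    """A residue code is not covered by the hydrophobicity scale."""


class DegenerateProfileError(FodmError):
    """An observed profile has zero total mass (no contacts, or all-zero H)."""


class DegenerateSelectionError(FodmError):
    """A residue selection is too small or resolves to nothing."""


class UndefinedRDError(FodmError):
    """RD is undefined because both divergences vanish (O = T = R)."""


class MappingError(FodmError):
    """A residue correspondence leaves selection members unmapped."""
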