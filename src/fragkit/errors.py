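"""Exception hierarchy shared across the package."""


class FragkitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FragkitError):
    """A coordinate or table file could not be parsed."""


class EmptyStructureError(ParseError):
    """Input contained no ATOM/HETATM records."""


class LigandNotFoundError(FragkitError, LookupError):
    """A ligand selection resolved to no heavy atoms."""


class InsufficientPairsError(FragkitError):
    """Fewer than three complete backbone residue pairs for superposition."""


class UndefinedIdentityError(FragkitError):
    """Sequence identity requested over zero countable columns."""


class ConfigError(FragkitError):
    """A run configuration failed validation."""


class SpecError(FragkitError):
    """A synthetic-data generator spec is internally inconsistent."""
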