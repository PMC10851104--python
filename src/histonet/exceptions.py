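"""Exception hierarchy for histonet."""


class HistonetError(Exception):
    """Base class for all histonet errors."""


class StructureParseError(HistonetError):
    """Structure file could not be parsed in the declared dialect."""


class EmptyStructureError(HistonetError):
    """A structure contains no polymer chains (or none were kept)."""


class MappingConflictError(HistonetError):
    """A residue-number mapping table contains duplicate (chain, residue) rows."""


class UnknownChainError(HistonetError):
    """A chain id was requested that does not exist in the structure."""


class ConfigurationError(HistonetError):
    """A configuration table is empty or malformed."""


class GranularityMismatchError(HistonetError):
    """Networks of different granularities cannot be merged."""


class NodeClassConflictError(HistonetError):
    """Two networks assign conflicting classes to the same node id."""


class MissingResolutionError(HistonetError):
    """Resolution is required to arbitrate a redundancy group but is absent."""


class StrandMismatchError(HistonetError):
    """DNA strand lengths differ by more than the pairing tolerance."""


class VariantMissingError(HistonetError):
    """A histone variant is absent from the consensus alignment."""


class MissingColumnError(HistonetError):
    """An input table lacks a required column."""


class TmbUnderivableError(HistonetError):
    """Tumor mutation burden could not be obtained or derived for samples."""


class DegenerateGroupsError(HistonetError):
    """Fewer than two groups (or groups with <2 values) for a group comparison."""


class DegenerateDegreeError(HistonetError):
    """Degree distribution too narrow for a power-law decay check."""


class InfeasibleSpecError(HistonetError):
    """A synthetic-data spec could not be realized geometrically."""
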