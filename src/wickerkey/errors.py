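"""Exception hierarchy.

Domain errors all derive from :class:`WickerkeyError` so the CLI can map
them to a single exit status.
"""


class WickerkeyError(Exception):
    """Base class for all domain errors raised by this package."""


class UnknownTokenError(WickerkeyError):
    """A character-state token outside the grammar (usually a transcription fault)."""


class MatrixShapeError(WickerkeyError):
    """Ragged or otherwise malformed character matrix."""


class UnknownSpeciesError(WickerkeyError):
    """A species name not present in the matrix at hand."""


class KeySchemaError(WickerkeyError):
    """A key document that does not conform to the key file schema."""


class StructureError(WickerkeyError):
    """A key whose couplet graph violates structural invariants."""


class NameMismatchError(WickerkeyError):
    """Key leaves and matrix species that cannot be aligned by name."""

    def __init__(self, key_only, matrix_only):
        self.key_only = sorted(key_only)
        self.matrix_only = sorted(matrix_only)
        super().__init__(
            f"unmatched names: key-only={self.key_only}, matrix-only={self.matrix_only}"
        )


class IndistinguishableTaxaError(WickerkeyError):
    """A taxon set no character can split during key construction."""

    def __init__(self, taxa):
        self.taxa = sorted(taxa)
        super().__init__(f"no character splits taxa: {self.taxa}")


class UniverseMismatchError(WickerkeyError):
    """Two keys compared over different species universes."""


class UnmappedPlaceError(WickerkeyError):
    """Localities that the continent mapping cannot resolve."""

    def __init__(self, places):
        self.places = sorted(places)
        super().__init__(f"unmapped localities: {self.places}")


class DuplicateSpeciesError(WickerkeyError):
    """An addition that duplicates a species already in the occurrence table."""


class InvalidYearError(WickerkeyError):
    """A discovery year outside the plausible range."""


class InfeasibleSpecError(WickerkeyError):
    """A synthetic-matrix spec whose distinguishability guarantee cannot be met."""
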