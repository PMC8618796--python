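"""Access to the packaged reference fixtures.

The package ships a cleaned transcription of the published summary data
for the genus *Wickerhamomyces*: the 38 × 22 phenotypic character matrix,
the 37-couplet identification key, the 36-species occurrence table, the
default place → continent mapping, and specimen profiles for the two
newly described Thai species. Fixtures are installed package data,
addressable by name, so tests and the CLI never juggle paths.
"""

from __future__ import annotations

from importlib import resources

from .key import DichotomousKey, parse_key
from .matrix import (
    CharacterMatrix,
    SpecimenProfile,
    parse_matrix,
    parse_profile,
    parse_vocabulary,
)
from .occurrences import OccurrenceRecord, OccurrenceTable, parse_mapping, parse_occurrences

__all__ = [
    "FIXTURES",
    "fixture_text",
    "load_vocabulary",
    "load_matrix",
    "load_key",
    "load_occurrences",
    "load_mapping",
    "load_profile",
    "new_species_records",
]

FIXTURES = {
    "characters": "wickerhamomyces_characters.tsv",
    "matrix": "wickerhamomyces_matrix.tsv",
    "key": "wickerhamomyces_key.json",
    "occurrences": "wickerhamomyces_occurrences.tsv",
    "mapping": "continent_mapping.tsv",
    "profile-lannaensis": "profile_lannaensis.tsv",
    "profile-nanensis": "profile_nanensis.tsv",
}


def fixture_text(name: str) -> str:
    """Raw text of a packaged fixture (key of :data:`FIXTURES` or filename)."""
    filename = FIXTURES.get(name, name)
    return (resources.files("wickerkey") / "data" / filename).read_text(encoding="utf-8")


def load_vocabulary():
    return parse_vocabulary(fixture_text("characters"))


def load_matrix() -> CharacterMatrix:
    return parse_matrix(fixture_text("matrix"), vocabulary=load_vocabulary())


def load_key() -> DichotomousKey:
    return parse_key(fixture_text("key"))


def load_occurrences() -> OccurrenceTable:
    return parse_occurrences(fixture_text("occurrences"))


def load_mapping() -> dict[str, str]:
    return parse_mapping(fixture_text("mapping"))


def load_profile(name: str) -> SpecimenProfile:
    """A packaged specimen profile: 'lannaensis' or 'nanensis'."""
    key = name if name.startswith("profile-") else f"profile-{name}"
    return parse_profile(fixture_text(key))


def new_species_records() -> list[OccurrenceRecord]:
    """Occurrence records for the two newly described Thai soil species."""
    return [
        OccurrenceRecord(
            species="W. lannaensis",
            localities=frozenset({"Thailand"}),
            source="Soil from Assam tea plantation",
        ),
        OccurrenceRecord(
            species="W. nanensis",
            localities=frozenset({"Thailand"}),
            source="Soil from Assam tea plantation",
        ),
    ]
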