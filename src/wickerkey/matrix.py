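"""Character vocabularies, species × character matrices, specimen profiles.

The on-disk dialect is deliberately plain: tab-separated UTF-8, one header
row of character codes, first column species names, ``#`` comment lines.
Character codes are ASCII-normalized (``DXy``, ``NO3``, ``g37C`` …) because
subscripts and degree signs are hostile to file headers; the original
labels live in the vocabulary file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import MatrixShapeError, UnknownSpeciesError, UnknownTokenError
from .states import CharacterState, parse_state_token, states_distinct

__all__ = [
    "CharacterDefinition",
    "CharacterMatrix",
    "SpecimenProfile",
    "parse_matrix",
    "write_matrix",
    "parse_vocabulary",
    "parse_profile",
    "write_profile",
    "distinguishing_characters",
    "normalize_species_name",
]

_KINDS = ("assimilation", "growth-condition", "morphology")


@dataclass(frozen=True)
class CharacterDefinition:
    """One phenotypic character: a short code, a label, and its assay kind."""

    code: str
    label: str
    kind: str = "assimilation"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")


def normalize_species_name(name: str) -> str:
    """Canonicalize a species name for matching.

    Genus abbreviation and full genus name compare equal ("W. alni" ==
    "Wickerhamomyces alni"); whitespace collapses. No fuzzy matching.
    """
    parts = name.split()
    if parts and parts[0].rstrip(".").lower() in ("w", "wickerhamomyces"):
        parts[0] = "W."
    return " ".join(parts)


@dataclass
class SpecimenProfile:
    """Observed outcomes for one strain over a subset of characters."""

    outcomes: dict[str, CharacterState]
    identifier: str = ""

    @classmethod
    def from_tokens(cls, tokens: Mapping[str, str], identifier: str = "") -> "SpecimenProfile":
        return cls(
            outcomes={code: parse_state_token(tok) for code, tok in tokens.items()},
            identifier=identifier,
        )


@dataclass
class CharacterMatrix:
    """Rectangular grid of :class:`CharacterState` over a character vocabulary."""

    vocabulary: list[CharacterDefinition]
    species: list[str]
    cells: dict[str, dict[str, CharacterState]] = field(repr=False)

    def __post_init__(self):
        codes = [c.code for c in self.vocabulary]
        if len(set(codes)) != len(codes):
            raise MatrixShapeError("duplicate character codes in vocabulary")
        if len(set(self.species)) != len(self.species):
            raise MatrixShapeError("duplicate species names")
        for sp in self.species:
            row = self.cells.get(sp)
            if row is None or set(row) != set(codes):
                raise MatrixShapeError(f"row for {sp!r} does not cover the vocabulary")

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.vocabulary]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_characters(self) -> int:
        return len(self.vocabulary)

    def row(self, species: str) -> dict[str, CharacterState]:
        sp = self._resolve(species)
        return dict(self.cells[sp])

    def state(self, species: str, code: str) -> CharacterState:
        return self.cells[self._resolve(species)][code]

    def _resolve(self, species: str) -> str:
        if species in self.cells:
            return species
        want = normalize_species_name(species)
        for sp in self.species:
            if normalize_species_name(sp) == want:
                return sp
        raise UnknownSpeciesError(f"species {species!r} not in matrix")

    def profile(self, species: str, identifier: str = "") -> SpecimenProfile:
        """A specimen profile copied verbatim from a matrix row (no-data dropped)."""
        row = self.row(species)
        return SpecimenProfile(
            outcomes={c: s for c, s in row.items() if not s.is_no_data},
            identifier=identifier or species,
        )


def parse_vocabulary(text: str) -> list[CharacterDefinition]:
    """Read a vocabulary TSV (columns: code, label, kind)."""
    defs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "code":  # header
            continue
        if len(fields) < 3:
            raise MatrixShapeError(f"vocabulary line needs 3 columns: {line!r}")
        defs.append(CharacterDefinition(code=fields[0], label=fields[1], kind=fields[2]))
    return defs


def parse_matrix(text: str, vocabulary: Iterable[CharacterDefinition] | None = None) -> CharacterMatrix:
    """Parse the TSV matrix dialect into a validated :class:`CharacterMatrix`.

    Cell-level parse failures are reported with species/character
    coordinates so a transcription fault can be found in the source table.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise MatrixShapeError("empty matrix source")
    header = lines[0].rstrip("\n").split("\t")
    codes = header[1:]
    if not codes:
        raise MatrixShapeError("matrix header has no character columns")
    if vocabulary is not None:
        vocab = list(vocabulary)
        if [c.code for c in vocab] != codes:
            raise MatrixShapeError(
                "matrix header does not match the supplied vocabulary: "
                f"{codes} vs {[c.code for c in vocab]}"
            )
    else:
        vocab = [CharacterDefinition(code=c, label=c) for c in codes]

    species: list[str] = []
    cells: dict[str, dict[str, CharacterState]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(codes) + 1:
            raise MatrixShapeError(
                f"line {lineno}: expected {len(codes) + 1} columns, got {len(fields)}"
            )
        name = fields[0].strip()
        if name in cells:
            raise MatrixShapeError(f"duplicate species {name!r}")
        row = {}
        for code, token in zip(codes, fields[1:]):
            try:
                row[code] = parse_state_token(token)
            except UnknownTokenError as exc:
                raise UnknownTokenError(f"species {name!r}, character {code!r}: {exc}") from None
        species.append(name)
        cells[name] = row
    return CharacterMatrix(vocabulary=vocab, species=species, cells=cells)


def write_matrix(matrix: CharacterMatrix, canonical: bool = True) -> str:
    """Serialize to the TSV dialect; canonical tokens round-trip bit-exactly."""
    buf = io.StringIO()
    buf.write("species\t" + "\t".join(matrix.codes) + "\n")
    for sp in matrix.species:
        row = matrix.cells[sp]
        toks = [
            row[c].canonical_token() if canonical else (row[c].raw_token or row[c].canonical_token())
            for c in matrix.codes
        ]
        buf.write(sp + "\t" + "\t".join(toks) + "\n")
    return buf.getvalue()


def parse_profile(text: str) -> SpecimenProfile:
    """Read a specimen-profile TSV (lines ``code<TAB>token``).

    A comment line ``# identifier: <text>`` names the specimen.
    """
    identifier = ""
    tokens: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("identifier:"):
                identifier = body.split(":", 1)[1].strip()
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "character":
            continue
        if len(fields) < 2:
            raise MatrixShapeError(f"profile line needs 2 columns: {line!r}")
        tokens[fields[0].strip()] = fields[1].strip()
    return SpecimenProfile.from_tokens(tokens, identifier=identifier)


def write_profile(profile: SpecimenProfile) -> str:
    buf = io.StringIO()
    if profile.identifier:
        buf.write(f"# identifier: {profile.identifier}\n")
    buf.write("character\tstate\n")
    for code, state in profile.outcomes.items():
        buf.write(f"{code}\t{state.canonical_token()}\n")
    return buf.getvalue()


def distinguishing_characters(matrix: CharacterMatrix, species_a: str, species_b: str) -> set[str]:
    """Characters on which the two species can always be told apart.

    Comparison is atom-level: a character distinguishes iff the two states
    share no possible concrete outcome. Variable and no-data states expand
    to every outcome, so they never distinguish; alternations sharing an
    atom never distinguish.
    """
    row_a = matrix.row(species_a)
    row_b = matrix.row(species_b)
    return {c for c in matrix.codes if states_distinct(row_a[c], row_b[c])}
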