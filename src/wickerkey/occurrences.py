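"""Occurrence tables and diversity bookkeeping.

A literature-compiled distribution table maps each species to the set of
places it has been isolated from. Summaries count distinct species per
continent (a species counts once per continent where it has at least one
locality, and may count in several continents), per country, and —
given discovery years — per decade.

Localities are stored verbatim from the source (including non-country
places such as "King George Island") and resolved to continents only
through an explicit, user-editable mapping.
"""

from __future__ import annotations

import datetime
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import DuplicateSpeciesError, InvalidYearError, UnmappedPlaceError

__all__ = [
    "OccurrenceRecord",
    "OccurrenceTable",
    "CONTINENTS",
    "parse_occurrences",
    "write_occurrences",
    "parse_mapping",
    "continent_counts",
    "species_in_country",
    "species_totals",
    "decade_histogram",
]

CONTINENTS = (
    "Africa",
    "Antarctica",
    "Asia",
    "Europe",
    "North America",
    "Oceania",
    "South America",
)


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    localities: frozenset[str]
    source: str = ""
    year: int | None = None

    def __post_init__(self):
        if not self.localities:
            raise ValueError(f"record for {self.species!r} has no localities")


@dataclass
class OccurrenceTable:
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __post_init__(self):
        names = [r.species for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateSpeciesError(f"duplicate species in table: {dupes}")

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    @property
    def localities(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.localities
        return out

    def __len__(self) -> int:
        return len(self.records)


def parse_occurrences(text: str) -> OccurrenceTable:
    """Read the occurrence TSV (species, ';'-joined localities, source, [year])."""
    records = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "species":
            continue
        species, locs = fields[0], fields[1]
        source = fields[2] if len(fields) > 2 else ""
        year = int(fields[3]) if len(fields) > 3 and fields[3].strip() else None
        records.append(
            OccurrenceRecord(
                species=species,
                localities=frozenset(p.strip() for p in locs.split(";") if p.strip()),
                source=source,
                year=year,
            )
        )
    return OccurrenceTable(records=records)


def write_occurrences(table: OccurrenceTable) -> str:
    buf = io.StringIO()
    buf.write("species\tlocalities\tsource\tyear\n")
    for r in table.records:
        buf.write(
            f"{r.species}\t{';'.join(sorted(r.localities))}\t{r.source}\t"
            f"{r.year if r.year is not None else ''}\n"
        )
    return buf.getvalue()


def parse_mapping(text: str) -> dict[str, str]:
    """Read a two-column place → continent TSV."""
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "place":
            continue
        place, continent = fields[0].strip(), fields[1].strip()
        if continent not in CONTINENTS:
            raise ValueError(f"unknown continent {continent!r} for {place!r}")
        mapping[place] = continent
    return mapping


def continent_counts(table: OccurrenceTable, mapping: Mapping[str, str]) -> dict[str, int]:
    """Distinct species per continent; multi-continent species count in each."""
    unmapped = {p for p in table.localities if p not in mapping}
    if unmapped:
        raise UnmappedPlaceError(unmapped)
    per: dict[str, set[str]] = {c: set() for c in CONTINENTS}
    for rec in table.records:
        for place in rec.localities:
            per[mapping[place]].add(rec.species)
    return {c: len(per[c]) for c in CONTINENTS}


def species_in_country(table: OccurrenceTable, country: str) -> set[str]:
    """Species with the country among their localities (unknown country → empty)."""
    return {r.species for r in table.records if country in r.localities}


def species_totals(
    table: OccurrenceTable,
    additions: Iterable[OccurrenceRecord] = (),
) -> dict:
    """Bookkeeping after adding newly described species to the table.

    Additions must be disjoint from the table; per-country totals include
    the additions' stated localities.
    """
    additions = list(additions)
    existing = set(table.species)
    for rec in additions:
        if rec.species in existing:
            raise DuplicateSpeciesError(f"addition {rec.species!r} already in table")
    combined = OccurrenceTable(records=table.records + additions)
    per_country: dict[str, int] = {}
    for place in sorted(combined.localities):
        per_country[place] = len(species_in_country(combined, place))
    return {
        "table_count": len(set(table.species)),
        "grand_total": len(set(combined.species)),
        "per_country": per_country,
    }


def decade_histogram(years: Mapping[str, int]) -> dict[int, int]:
    """Count species per discovery decade (decade = floor(year/10)*10)."""
    current = datetime.date.today().year
    hist: dict[int, int] = {}
    for species, year in years.items():
        if year < 1800 or year > current:
            raise InvalidYearError(f"{species}: implausible year {year}")
        decade = (year // 10) * 10
        hist[decade] = hist.get(decade, 0) + 1
    return dict(sorted(hist.items()))
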