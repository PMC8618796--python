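"""Synthetic matrices, specimens, and occurrence tables.

Generators for controlled test data that mirrors the structure of real
phenotypic tables: the same state-token mix (definite, weak, variable,
latent, slow, no-data, alternations), pairwise-distinguishable rows on
request, and occurrence tables with multi-country species. Every
generator is a pure function of its seed (one ``numpy`` Generator per
call), so identical calls yield identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InfeasibleSpecError, UnknownSpeciesError
from .matrix import (
    CharacterDefinition,
    CharacterMatrix,
    SpecimenProfile,
    distinguishing_characters,
)
from .occurrences import OccurrenceRecord, OccurrenceTable
from .states import Atom, CharacterState, parse_state_token

__all__ = ["MatrixSpec", "gen_matrix", "gen_specimen", "gen_occurrences", "empirical_state_mix"]

#: Cell categories a synthetic matrix draws from.
STATE_CATEGORIES = (
    "definite-positive",
    "definite-negative",
    "weak",
    "variable",
    "latent",
    "slow",
    "no-data",
    "alternation",
)

_CATEGORY_TOKEN = {
    "definite-positive": "+",
    "definite-negative": "-",
    "weak": "w",
    "variable": "v",
    "latent": "l",
    "slow": "s",
    "no-data": "n",
}

_ALTERNATION_ATOMS = ["+", "w", "l", "s", "-"]


@dataclass(frozen=True)
class MatrixSpec:
    """Recipe for one synthetic character matrix."""

    n_species: int
    n_characters: int
    state_mix: dict[str, float] = field(
        default_factory=lambda: {"definite-positive": 0.5, "definite-negative": 0.5}
    )
    guarantee_distinguishable: bool = True
    seed: int = 0
    retry_cap: int = 64

    def __post_init__(self):
        unknown = set(self.state_mix) - set(STATE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown state categories {sorted(unknown)}")
        total = sum(self.state_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"state_mix probabilities sum to {total}, not 1")
        if self.n_species < 1 or self.n_characters < 1:
            raise ValueError("need at least one species and one character")
        if self.guarantee_distinguishable and self.n_characters < int(
            np.ceil(np.log2(max(self.n_species, 2)))
        ):
            raise InfeasibleSpecError(
                f"{self.n_characters} characters cannot distinguish {self.n_species} species"
            )


def empirical_state_mix(matrix: CharacterMatrix) -> dict[str, float]:
    """Token-category frequencies of a real matrix, for realistic synthesis."""
    counts = dict.fromkeys(STATE_CATEGORIES, 0)
    n = 0
    for sp in matrix.species:
        for state in matrix.cells[sp].values():
            n += 1
            if len(state.atoms) > 1:
                counts["alternation"] += 1
            else:
                atom = next(iter(state.atoms))
                counts[
                    {
                        Atom.POSITIVE: "definite-positive",
                        Atom.NEGATIVE: "definite-negative",
                        Atom.WEAK: "weak",
                        Atom.VARIABLE: "variable",
                        Atom.LATENT: "latent",
                        Atom.SLOW: "slow",
                        Atom.NO_DATA: "no-data",
                    }[atom]
                ] += 1
    return {k: v / n for k, v in counts.items()}


def _draw_token(rng: np.random.Generator, categories: list[str], probs: np.ndarray) -> str:
    cat = categories[int(rng.choice(len(categories), p=probs))]
    if cat == "alternation":
        pair = rng.choice(len(_ALTERNATION_ATOMS), size=2, replace=False)
        return "/".join(_ALTERNATION_ATOMS[i] for i in sorted(pair))
    return _CATEGORY_TOKEN[cat]


def gen_matrix(spec: MatrixSpec) -> CharacterMatrix:
    """Generate a matrix per spec; reproducible from ``spec.seed``.

    With ``guarantee_distinguishable`` the generator resamples rows of
    violating pairs (respecting the state mix) until every species pair
    has at least one distinguishing character, up to ``retry_cap`` rounds;
    mixes that cannot distinguish at all (e.g. all no-data) exhaust the
    cap and raise :class:`InfeasibleSpecError`.
    """
    rng = np.random.default_rng(spec.seed)
    categories = list(spec.state_mix)
    probs = np.asarray([spec.state_mix[c] for c in categories], dtype=float)
    probs = probs / probs.sum()
    species = [f"Sp{i + 1:03d}" for i in range(spec.n_species)]
    codes = [f"ch{j + 1:02d}" for j in range(spec.n_characters)]
    vocab = [CharacterDefinition(code=c, label=f"Synthetic character {c}") for c in codes]

    def sample_row() -> dict[str, CharacterState]:
        return {c: parse_state_token(_draw_token(rng, categories, probs)) for c in codes}

    cells = {sp: sample_row() for sp in species}
    matrix = CharacterMatrix(vocabulary=vocab, species=species, cells=cells)
    if not spec.guarantee_distinguishable:
        return matrix

    for _ in range(spec.retry_cap):
        violating = None
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                if not distinguishing_characters(matrix, a, b):
                    violating = (a, b)
                    break
            if violating:
                break
        if violating is None:
            return matrix
        # resample one of the offending rows, keeping the state mix honest
        victim = violating[int(rng.integers(2))]
        cells[victim] = sample_row()
        matrix = CharacterMatrix(vocabulary=vocab, species=species, cells=cells)
    raise InfeasibleSpecError(
        f"could not make all pairs distinguishable within {spec.retry_cap} retries"
    )


def gen_specimen(matrix: CharacterMatrix, species: str, resolution_seed: int = 0) -> SpecimenProfile:
    """Resolve a matrix row into one concrete specimen.

    Uncertain states (variable, alternations) resolve uniformly at random
    to one concrete outcome they admit; no-data cells are left out of the
    profile entirely, mimicking a test that was never run.
    """
    if species not in matrix.cells:
        raise UnknownSpeciesError(f"species {species!r} not in matrix")
    rng = np.random.default_rng(resolution_seed)
    outcomes: dict[str, CharacterState] = {}
    for code in matrix.codes:
        state = matrix.cells[species][code]
        if state.is_no_data:
            continue
        if state.is_definite:
            outcomes[code] = state
            continue
        choices = sorted(state.possible_atoms(), key=lambda a: a.value)
        atom = choices[int(rng.integers(len(choices)))]
        outcomes[code] = CharacterState(atoms=frozenset({atom}), raw_token=atom.value)
    return SpecimenProfile(outcomes=outcomes, identifier=f"{species}:seed={resolution_seed}")


def gen_occurrences(
    n_species: int,
    country_pool: Sequence[str],
    multi_country_rate: float = 0.2,
    year_range: tuple[int, int] = (1891, 2021),
    seed: int = 0,
) -> tuple[OccurrenceTable, dict[str, int]]:
    """Generate an occurrence table plus per-species discovery years."""
    if not country_pool:
        raise ValueError("country pool must be non-empty")
    if not 0 <= multi_country_rate <= 1:
        raise ValueError("multi_country_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = list(country_pool)
    records = []
    years: dict[str, int] = {}
    for i in range(n_species):
        sp = f"Synthsp{i + 1:03d}"
        if len(pool) > 1 and rng.random() < multi_country_rate:
            k = int(rng.integers(2, min(len(pool), 3) + 1))
            idx = rng.choice(len(pool), size=k, replace=False)
            locs = frozenset(pool[j] for j in idx)
        else:
            locs = frozenset({pool[int(rng.integers(len(pool)))]})
        records.append(OccurrenceRecord(species=sp, localities=locs, source="synthetic"))
        years[sp] = int(rng.integers(year_range[0], year_range[1] + 1))
    return OccurrenceTable(records=records), years
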