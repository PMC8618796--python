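"""Checking a key against the character matrix it is meant to summarize.

Consistency is existential: a species passes when *some* resolution of its
matrix row reaches its own leaf. Strain-variable states describe real
within-species variation, and published keys separate such species by
other characters downstream, so demanding that every resolution reach the
leaf would fail keys that are perfectly usable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NameMismatchError
from .key import DichotomousKey, reachable_leaves
from .matrix import CharacterMatrix, normalize_species_name
from .states import PolarityRule, state_supports

__all__ = ["ConsistencyReport", "KeyMetrics", "check_consistency", "ambiguity_report", "key_metrics"]


@dataclass
class SpeciesRecord:
    species: str
    own_leaf_reachable: bool
    reachable_set: frozenset[str]
    witness_path: list[tuple[int, str]] | None = None
    conflict: dict | None = None  # {couplet, character, state, asserted}

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "own_leaf_reachable": self.own_leaf_reachable,
            "reachable_set": sorted(self.reachable_set),
            "witness_path": (
                [{"couplet": c, "lead": l} for c, l in self.witness_path]
                if self.witness_path
                else None
            ),
            "conflict": self.conflict,
        }


@dataclass
class ConsistencyReport:
    records: list[SpeciesRecord]
    key_only: list[str] = field(default_factory=list)
    matrix_only: list[str] = field(default_factory=list)

    @property
    def n_consistent(self) -> int:
        return sum(r.own_leaf_reachable for r in self.records)

    @property
    def all_consistent(self) -> bool:
        return all(r.own_leaf_reachable for r in self.records)

    def to_dict(self) -> dict:
        return {
            "summary": {
                "species_checked": len(self.records),
                "consistent": self.n_consistent,
                "inconsistent": len(self.records) - self.n_consistent,
                "key_only": self.key_only,
                "matrix_only": self.matrix_only,
            },
            "records": [r.to_dict() for r in self.records],
        }


@dataclass
class KeyMetrics:
    couplet_count: int
    leaf_count: int
    max_depth: int
    mean_depth: float
    characters_used: set[str]

    def to_dict(self) -> dict:
        return {
            "couplet_count": self.couplet_count,
            "leaf_count": self.leaf_count,
            "max_depth": self.max_depth,
            "mean_depth": self.mean_depth,
            "characters_used": sorted(self.characters_used),
        }


def _leaf_paths(key: DichotomousKey) -> dict[str, list[tuple[int, str]]]:
    """Root-to-leaf path for every species leaf (unique in a tree)."""
    paths: dict[str, list[tuple[int, str]]] = {}

    def walk(num: int, prefix: list[tuple[int, str]]):
        for lead in key.couplets[num].leads:
            step = prefix + [(num, lead.label)]
            if lead.is_leaf:
                paths[lead.target_species] = step
            else:
                walk(lead.target_couplet, step)

    walk(key.root, [])
    return paths


def check_consistency(
    key: DichotomousKey,
    matrix: CharacterMatrix,
    polarity: PolarityRule | str = PolarityRule.DEFAULT,
    strict_names: bool = False,
) -> ConsistencyReport:
    """Can every matrix species reach its own leaf in the key?

    For a failing species the conflict cites the first couplet on its
    root-to-leaf path where the matrix row contradicts the required lead.
    Names match after genus-abbreviation/whitespace normalization only.
    """
    if isinstance(polarity, str):
        polarity = PolarityRule(polarity)
    leaf_norm = {normalize_species_name(s): s for s in key.species_leaves}
    mat_norm = {normalize_species_name(s): s for s in matrix.species}
    key_only = sorted(leaf_norm[k] for k in leaf_norm.keys() - mat_norm.keys())
    matrix_only = sorted(mat_norm[k] for k in mat_norm.keys() - leaf_norm.keys())
    if strict_names and (key_only or matrix_only):
        raise NameMismatchError(key_only, matrix_only)

    paths = _leaf_paths(key)
    records = []
    for norm in sorted(leaf_norm.keys() & mat_norm.keys(), key=lambda n: matrix.species.index(mat_norm[n])):
        sp_mat = mat_norm[norm]
        sp_key = leaf_norm[norm]
        row = matrix.row(sp_mat)
        reach = reachable_leaves(key, row, polarity)
        ok = sp_key in reach
        conflict = None
        witness = None
        if ok:
            witness = paths[sp_key]
        else:
            for num, label in paths[sp_key]:
                couplet = key.couplets[num]
                lead = couplet.leads[0] if label == "a" else couplet.leads[1]
                state = row.get(couplet.character)
                if state is not None and not state_supports(state, lead.outcome, polarity):
                    conflict = {
                        "couplet": num,
                        "character": couplet.character,
                        "state": state.canonical_token(),
                        "asserted": lead.outcome,
                    }
                    break
        records.append(
            SpeciesRecord(
                species=sp_mat,
                own_leaf_reachable=ok,
                reachable_set=frozenset(reach),
                witness_path=witness,
                conflict=conflict,
            )
        )
    return ConsistencyReport(records=records, key_only=key_only, matrix_only=matrix_only)


def ambiguity_report(
    key: DichotomousKey,
    matrix: CharacterMatrix,
    polarity: PolarityRule | str = PolarityRule.DEFAULT,
) -> dict[str, set[str]]:
    """Invert reachability: for each leaf, which matrix species can reach it."""
    inverted: dict[str, set[str]] = {leaf: set() for leaf in key.species_leaves}
    for sp in matrix.species:
        for leaf in reachable_leaves(key, matrix.row(sp), polarity):
            inverted.setdefault(leaf, set()).add(sp)
    return inverted


def key_metrics(key: DichotomousKey) -> KeyMetrics:
    """Size and depth statistics; depth counts couplets on a root-to-leaf path."""
    depths = key.leaf_depths()
    return KeyMetrics(
        couplet_count=len(key.couplets),
        leaf_count=len(depths),
        max_depth=max(depths.values()),
        mean_depth=sum(depths.values()) / len(depths),
        characters_used=key.characters_used,
    )
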