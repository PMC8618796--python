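"""Dichotomous identification keys: model, JSON I/O, validation, traversal.

A key is a binary tree of numbered couplets. Each couplet carries exactly
two leads, ``a`` and ``b``, asserting opposite binary outcomes of one
character; each lead points at another couplet or terminates at a species
leaf. Printed keys also annotate each couplet with its parent couplet
("26.(24) …"); these annotations are recorded as metadata and *checked*,
never trusted — the lead targets are authoritative.

Traversal is uncertainty-aware. A specimen state that admits both outcomes
of a couplet's character (strain-variable, no-data, some alternations)
forks the walk; forks are expanded with per-character commitments, so the
set of reachable leaves equals the union over all concrete resolutions of
the specimen's uncertain states — a character cannot be read as positive
at one couplet and negative at another on the same path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import KeySchemaError, StructureError
from .matrix import SpecimenProfile, normalize_species_name
from .states import (
    Atom,
    CharacterState,
    NO_DATA_STATE,
    PolarityRule,
    state_supports,
)

__all__ = [
    "Lead",
    "Couplet",
    "DichotomousKey",
    "IdentificationResult",
    "StructureReport",
    "parse_key",
    "serialize_key",
    "validate_structure",
    "identify",
    "reachable_leaves",
]

KEY_SCHEMA = "wickerkey.key/1"

_OUTCOMES = ("positive", "negative")


@dataclass(frozen=True)
class Lead:
    """One of a couplet's two alternatives."""

    label: str  # "a" | "b"
    character: str
    outcome: str  # "positive" | "negative"
    target_couplet: int | None = None
    target_species: str | None = None

    def __post_init__(self):
        if self.label not in ("a", "b"):
            raise KeySchemaError(f"lead label must be 'a' or 'b', got {self.label!r}")
        if self.outcome not in _OUTCOMES:
            raise KeySchemaError(f"lead outcome must be positive/negative, got {self.outcome!r}")
        if (self.target_couplet is None) == (self.target_species is None):
            raise KeySchemaError("a lead targets exactly one of couplet or species")

    @property
    def is_leaf(self) -> bool:
        return self.target_species is not None


@dataclass(frozen=True)
class Couplet:
    number: int
    leads: tuple[Lead, Lead]
    parent_annotation: int | None = None  # the printed "(k)", metadata only

    def __post_init__(self):
        a, b = self.leads
        if (a.label, b.label) != ("a", "b"):
            raise KeySchemaError(f"couplet {self.number}: leads must be labeled a then b")
        if a.character != b.character:
            raise KeySchemaError(
                f"couplet {self.number}: leads test different characters "
                f"({a.character!r} vs {b.character!r})"
            )
        if a.outcome == b.outcome:
            raise KeySchemaError(f"couplet {self.number}: leads must assert opposite outcomes")

    @property
    def character(self) -> str:
        return self.leads[0].character


@dataclass
class DichotomousKey:
    """A validated single-access key."""

    couplets: dict[int, Couplet]
    root: int
    name: str = ""

    @property
    def species_leaves(self) -> list[str]:
        """All species names reachable as leaves (document order)."""
        out = []
        for num in sorted(self.couplets):
            for lead in self.couplets[num].leads:
                if lead.is_leaf:
                    out.append(lead.target_species)
        return out

    @property
    def characters_used(self) -> set[str]:
        return {c.character for c in self.couplets.values()}

    def leaf_depths(self) -> dict[str, int]:
        """Depth (couplets on the path) of every species leaf."""
        depths: dict[str, int] = {}

        def walk(num: int, depth: int):
            for lead in self.couplets[num].leads:
                if lead.is_leaf:
                    depths[lead.target_species] = depth
                else:
                    walk(lead.target_couplet, depth + 1)

        walk(self.root, 1)
        return depths


@dataclass
class IdentificationResult:
    """Outcome of walking a specimen through a key."""

    status: str  # "identified" | "ambiguous" | "stalled"
    species: str | None
    candidates: frozenset[str]
    path: list[tuple[int, str]]  # (couplet number, lead label) pairs
    stalled_at: int | None = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "species": self.species,
            "candidates": sorted(self.candidates),
            "path": [{"couplet": c, "lead": l} for c, l in self.path],
            "stalled_at": self.stalled_at,
        }


@dataclass
class StructureReport:
    violations: list[str]
    annotation_discrepancies: list[dict]

    @property
    def ok(self) -> bool:
        return not self.violations and not self.annotation_discrepancies


# ---------------------------------------------------------------------------
# construction / structural validation


def _check_structure(couplets: dict[int, Couplet]) -> tuple[int, nx.DiGraph]:
    """Verify the couplet graph is a rooted tree; return (root, graph)."""
    graph = nx.DiGraph()
    graph.add_nodes_from(couplets)
    referenced: dict[int, list[int]] = {}
    for num, couplet in couplets.items():
        for lead in couplet.leads:
            if lead.is_leaf:
                continue
            tgt = lead.target_couplet
            if tgt not in couplets:
                raise StructureError(f"couplet {num} targets missing couplet {tgt}")
            referenced.setdefault(tgt, []).append(num)
            graph.add_edge(num, tgt)
    multi = {t: src for t, src in referenced.items() if len(src) > 1}
    if multi:
        raise StructureError(f"couplets referenced by more than one lead: {multi}")
    roots = [n for n in couplets if n not in referenced]
    if len(roots) != 1:
        raise StructureError(f"expected exactly one root couplet, found {sorted(roots)}")
    root = roots[0]
    if not nx.is_directed_acyclic_graph(graph):
        raise StructureError("couplet graph contains a cycle")
    unreachable = set(couplets) - set(nx.descendants(graph, root)) - {root}
    if unreachable:
        raise StructureError(f"couplets unreachable from root: {sorted(unreachable)}")
    return root, graph


def make_key(couplets: Iterable[Couplet], name: str = "") -> DichotomousKey:
    """Assemble and structurally validate a key from couplets."""
    by_num: dict[int, Couplet] = {}
    for c in couplets:
        if c.number in by_num:
            raise StructureError(f"duplicate couplet number {c.number}")
        by_num[c.number] = c
    if not by_num:
        raise KeySchemaError("a key needs at least one couplet")
    root, _ = _check_structure(by_num)
    return DichotomousKey(couplets=by_num, root=root, name=name)


def parse_key(source: str) -> DichotomousKey:
    """Parse the JSON key document (schema ``wickerkey.key/1``)."""
    try:
        doc = json.loads(source)
    except json.JSONDecodeError as exc:
        raise KeySchemaError(f"key file is not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or "couplets" not in doc:
        raise KeySchemaError("key document must be an object with a 'couplets' list")
    schema = doc.get("schema", KEY_SCHEMA)
    if schema != KEY_SCHEMA:
        raise KeySchemaError(f"unsupported key schema {schema!r}")
    couplets = []
    for entry in doc["couplets"]:
        try:
            leads = tuple(
                Lead(
                    label=ld["label"],
                    character=ld["character"],
                    outcome=ld["outcome"],
                    target_couplet=ld.get("couplet"),
                    target_species=ld.get("species"),
                )
                for ld in entry["leads"]
            )
            if len(leads) != 2:
                raise KeySchemaError(
                    f"couplet {entry.get('number')}: exactly two leads required"
                )
            couplets.append(
                Couplet(
                    number=int(entry["number"]),
                    leads=leads,
                    parent_annotation=entry.get("parent"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise KeySchemaError(f"malformed couplet entry {entry!r}: {exc}") from None
    return make_key(couplets, name=doc.get("name", ""))


def serialize_key(key: DichotomousKey) -> str:
    """Serialize to the JSON document; ``parse_key`` round-trips it."""
    doc = {
        "schema": KEY_SCHEMA,
        "name": key.name,
        "couplets": [
            {
                "number": num,
                "parent": key.couplets[num].parent_annotation,
                "leads": [
                    {
                        "label": ld.label,
                        "character": ld.character,
                        "outcome": ld.outcome,
                        **(
                            {"species": ld.target_species}
                            if ld.is_leaf
                            else {"couplet": ld.target_couplet}
                        ),
                    }
                    for ld in key.couplets[num].leads
                ],
            }
            for num in sorted(key.couplets)
        ],
    }
    return json.dumps(doc, indent=1, ensure_ascii=False) + "\n"


def validate_structure(key: DichotomousKey) -> StructureReport:
    """Report invariant violations and parent-annotation discrepancies.

    The actual parent of couplet *k* is the couplet whose lead targets *k*;
    a printed annotation that disagrees is reported, not repaired.
    """
    violations: list[str] = []
    try:
        _check_structure(key.couplets)
    except StructureError as exc:  # report-only entry point
        violations.append(str(exc))

    actual_parent: dict[int, int] = {}
    for num, couplet in key.couplets.items():
        for lead in couplet.leads:
            if not lead.is_leaf:
                actual_parent[lead.target_couplet] = num

    discrepancies = []
    for num in sorted(key.couplets):
        printed = key.couplets[num].parent_annotation
        actual = actual_parent.get(num)
        if printed is not None and printed != actual:
            discrepancies.append({"couplet": num, "printed": printed, "actual": actual})

    n_leaves = len(key.species_leaves)
    if n_leaves != len(key.couplets) + 1:
        violations.append(
            f"leaf arithmetic broken: {n_leaves} leaves for {len(key.couplets)} couplets"
        )
    return StructureReport(violations=violations, annotation_discrepancies=discrepancies)


# ---------------------------------------------------------------------------
# traversal


def identify(
    key: DichotomousKey,
    specimen: SpecimenProfile,
    polarity: PolarityRule | str = PolarityRule.DEFAULT,
) -> IdentificationResult:
    """Walk a specimen through the key from the root.

    At each couplet the unique lead the specimen's state supports is taken.
    A state supporting both leads (variable / no-data) forks the walk: the
    result is ``ambiguous`` and carries the frontier of species reachable
    from the fork. A character absent from the profile stalls the walk —
    the remedy there is to run the test, not to guess.
    """
    if isinstance(polarity, str):
        polarity = PolarityRule(polarity)
    path: list[tuple[int, str]] = []
    num = key.root
    commitments: dict[str, str] = {}
    while True:
        couplet = key.couplets[num]
        code = couplet.character
        state = specimen.outcomes.get(code)
        if state is None:
            return IdentificationResult(
                status="stalled",
                species=None,
                candidates=frozenset(),
                path=path,
                stalled_at=num,
            )
        supported = [
            ld for ld in couplet.leads
            if commitments.get(code, ld.outcome) == ld.outcome
            and state_supports(state, ld.outcome, polarity)
        ]
        if len(supported) == 2:
            frontier = _expand(key, num, specimen.outcomes, commitments, polarity,
                               missing_is_no_data=False)
            if frontier is None:  # a deeper couplet needs a missing character
                return IdentificationResult(
                    status="stalled", species=None, candidates=frozenset(),
                    path=path, stalled_at=num,
                )
            return IdentificationResult(
                status="ambiguous",
                species=None,
                candidates=frozenset(frontier),
                path=path,
            )
        lead = supported[0]
        path.append((num, lead.label))
        commitments[code] = lead.outcome
        if lead.is_leaf:
            return IdentificationResult(
                status="identified",
                species=lead.target_species,
                candidates=frozenset({lead.target_species}),
                path=path,
            )
        num = lead.target_couplet


def _expand(
    key: DichotomousKey,
    start: int,
    outcomes: Mapping[str, CharacterState],
    commitments: dict[str, str],
    polarity: PolarityRule,
    missing_is_no_data: bool,
) -> set[str] | None:
    """Union of species leaves over all resolution-consistent walks.

    Returns ``None`` when ``missing_is_no_data`` is false and some branch
    needs a character the profile lacks (the caller reports a stall).
    """
    leaves: set[str] = set()

    def walk(num: int, committed: dict[str, str]) -> bool:
        couplet = key.couplets[num]
        code = couplet.character
        state = outcomes.get(code)
        if state is None:
            if not missing_is_no_data:
                return False
            state = NO_DATA_STATE
        for lead in couplet.leads:
            if committed.get(code, lead.outcome) != lead.outcome:
                continue
            if not state_supports(state, lead.outcome, polarity):
                continue
            if lead.is_leaf:
                leaves.add(lead.target_species)
            else:
                sub = dict(committed)
                sub[code] = lead.outcome
                if not walk(lead.target_couplet, sub):
                    return False
        return True

    ok = walk(start, dict(commitments))
    return leaves if ok else None


def reachable_leaves(
    key: DichotomousKey,
    state_row: Mapping[str, CharacterState],
    polarity: PolarityRule | str = PolarityRule.DEFAULT,
) -> set[str]:
    """Every species leaf some concrete resolution of the row can reach.

    Characters missing from the row are treated as no-data (both outcomes
    possible). Equivalent to enumerating all per-character outcome
    assignments consistent with the row and collecting the leaf each
    deterministic walk ends at.
    """
    if isinstance(polarity, str):
        polarity = PolarityRule(polarity)
    result = _expand(key, key.root, state_row, {}, polarity, missing_is_no_data=True)
    assert result is not None
    return result
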