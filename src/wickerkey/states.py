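"""Character-state algebra for phenotypic test outcomes.

Yeast growth/assimilation tests are scored with a small token vocabulary:
strong positive ``+``, negative ``‒``, weak ``w``, strain-variable ``v``,
latent positive ``l``, slow positive ``s`` and no-data ``n``.  Published
tables additionally print alternations such as ``w/+`` ("weak or positive")
or ``+,‒`` ("positive or negative").  A :class:`CharacterState` holds the
set of atomic outcomes a cell admits and provides the two comparison
semantics everything downstream relies on:

* :func:`state_supports` — does the state admit a binary ("assimilated" /
  "not assimilated") reading?  Used for key traversal and key building.
* :meth:`CharacterState.possible_atoms` — the atom-level expansion used to
  decide whether two states can ever be told apart.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import UnknownTokenError

__all__ = [
    "Atom",
    "CharacterState",
    "PolarityRule",
    "parse_state_token",
    "state_supports",
]


class Atom(enum.Enum):
    """One atomic test outcome."""

    POSITIVE = "+"
    WEAK = "w"
    LATENT = "l"
    SLOW = "s"
    VARIABLE = "v"
    NEGATIVE = "-"
    NO_DATA = "n"


#: Canonical serialization order for alternation atoms.
_CANONICAL_ORDER = [
    Atom.POSITIVE,
    Atom.WEAK,
    Atom.LATENT,
    Atom.SLOW,
    Atom.VARIABLE,
    Atom.NEGATIVE,
    Atom.NO_DATA,
]

#: Every dash glyph that shows up in published tables; all mean "negative".
_DASHES = {"-", "‐", "‑", "‒", "–", "—", "―", "−"}

#: The five concrete outcomes a test can actually produce.  ``variable`` and
#: ``no-data`` are bookkeeping states that stand for "any of these".
_DEFINITE_ATOMS = frozenset(
    {Atom.POSITIVE, Atom.WEAK, Atom.LATENT, Atom.SLOW, Atom.NEGATIVE}
)


class PolarityRule(enum.Enum):
    """How qualified positives map onto the binary lead outcomes.

    ``DEFAULT`` treats weak/latent/slow as positive — species descriptions
    report "weak" and "delayed positive" assimilation as assimilation.
    ``STRICT`` lets a weak outcome support either lead, for auditing cells
    where weak growth is borderline.
    """

    DEFAULT = "default"
    STRICT = "strict"


def _support_set(atom: Atom, polarity: PolarityRule) -> frozenset[str]:
    if atom in (Atom.POSITIVE, Atom.LATENT, Atom.SLOW):
        return frozenset({"positive"})
    if atom is Atom.WEAK:
        if polarity is PolarityRule.STRICT:
            return frozenset({"positive", "negative"})
        return frozenset({"positive"})
    if atom is Atom.NEGATIVE:
        return frozenset({"negative"})
    # variable and no-data admit both readings
    return frozenset({"positive", "negative"})


@dataclass(frozen=True)
class CharacterState:
    """An observed (possibly uncertain) outcome of one phenotypic test."""

    atoms: frozenset[Atom]
    raw_token: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a CharacterState needs at least one atom")
        if Atom.NO_DATA in self.atoms and len(self.atoms) > 1:
            raise ValueError("no-data never mixes with other atoms")
        object.__setattr__(self, "atoms", frozenset(self.atoms))

    @property
    def is_definite(self) -> bool:
        """True when the state pins down a single concrete outcome."""
        return len(self.atoms) == 1 and next(iter(self.atoms)) in _DEFINITE_ATOMS

    @property
    def is_no_data(self) -> bool:
        return Atom.NO_DATA in self.atoms

    def canonical_token(self) -> str:
        """Serialize to the canonical token (atoms ordered, '/' separated)."""
        ordered = [a for a in _CANONICAL_ORDER if a in self.atoms]
        return "/".join(a.value for a in ordered)

    def possible_atoms(self) -> frozenset[Atom]:
        """Concrete outcomes this state could resolve to, atom by atom.

        ``variable`` and ``no-data`` expand to all five concrete outcomes —
        they can never be told apart from anything.
        """
        out: set[Atom] = set()
        for a in self.atoms:
            if a in (Atom.VARIABLE, Atom.NO_DATA):
                out |= _DEFINITE_ATOMS
            else:
                out.add(a)
        return frozenset(out)

    def supports(self, outcome: str, polarity: PolarityRule = PolarityRule.DEFAULT) -> bool:
        """Whether any atom of this state admits the binary ``outcome``."""
        if outcome not in ("positive", "negative"):
            raise ValueError(f"outcome must be 'positive' or 'negative', got {outcome!r}")
        return any(outcome in _support_set(a, polarity) for a in self.atoms)

    def supported_outcomes(self, polarity: PolarityRule = PolarityRule.DEFAULT) -> frozenset[str]:
        out: set[str] = set()
        for a in self.atoms:
            out |= _support_set(a, polarity)
        return frozenset(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_token()


def _parse_atom(glyph: str) -> Atom:
    if glyph in _DASHES:
        return Atom.NEGATIVE
    for atom in _CANONICAL_ORDER:
        if glyph == atom.value:
            return atom
    raise UnknownTokenError(f"unknown state glyph {glyph!r}")


def parse_state_token(token: str) -> CharacterState:
    """Parse one table cell into a :class:`CharacterState`.

    Both ``/`` and ``,`` separate alternation atoms (tables mix ``w/+`` and
    ``+,‒``); every Unicode dash variant normalizes to negative.

    Raises
    ------
    UnknownTokenError
        For tokens outside the grammar — in a transcribed table this almost
        always flags a transcription fault, so the message carries the token.
    """
    raw = token
    stripped = token.strip()
    if not stripped:
        raise UnknownTokenError("empty state token")
    parts = [p.strip() for p in stripped.replace(",", "/").split("/")]
    if any(not p for p in parts):
        raise UnknownTokenError(f"malformed alternation token {raw!r}")
    atoms = set()
    for part in parts:
        try:
            atoms.add(_parse_atom(part))
        except UnknownTokenError:
            raise UnknownTokenError(f"unknown state token {raw!r} (glyph {part!r})") from None
    if Atom.NO_DATA in atoms and len(atoms) > 1:
        raise UnknownTokenError(f"no-data cannot appear in an alternation: {raw!r}")
    return CharacterState(atoms=frozenset(atoms), raw_token=raw)


def state_supports(
    state: CharacterState,
    outcome: str,
    polarity: PolarityRule | str = PolarityRule.DEFAULT,
) -> bool:
    """Binary bridge between table states and key leads.

    Under the default polarity rule positive/weak/latent/slow atoms support
    "positive", negative supports "negative", and variable/no-data support
    both; an alternation supports an outcome if any of its atoms does.
    """
    if isinstance(polarity, str):
        polarity = PolarityRule(polarity)
    return state.supports(outcome, polarity)


def states_distinct(a: CharacterState, b: CharacterState) -> bool:
    """True when the two states share no possible concrete outcome."""
    return not (a.possible_atoms() & b.possible_atoms())


#: Parsed constants used throughout for "missing" cells.
NO_DATA_STATE = CharacterState(atoms=frozenset({Atom.NO_DATA}), raw_token="n")
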