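"""Greedy construction of dichotomous keys from character matrices.

At each node the builder scores every character by the expected
log-reduction in taxon count its binary split achieves, penalizing
characters whose uncertain states (variable, no-data, weak-or-positive
alternations straddling both outcomes) force taxa onto both sides, and
recurses on the best split. Greedy, not optimal: minimal-expected-depth
key construction is NP-hard, and greedy information gain is the standard
workhorse for single-access key generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import IndistinguishableTaxaError, UniverseMismatchError
from .key import Couplet, DichotomousKey, Lead, make_key
from .matrix import CharacterMatrix, normalize_species_name
from .states import PolarityRule, state_supports
from .validation import key_metrics

__all__ = ["BuilderConfig", "BuildResult", "build_key", "compare_keys"]

#: Species that land in a multi-species leaf are joined with this separator.
MULTI_LEAF_SEP = " | "


@dataclass(frozen=True)
class BuilderConfig:
    """Knobs for the greedy builder.

    duplication_penalty is subtracted from a split's score once per taxon
    that must go to both sides (default 0.5), discouraging variable and
    no-data characters without forbidding them. Ties break by vocabulary
    (column) order, which makes construction deterministic.
    """

    scoring: str = "information-gain"  # or "worst-case-balance"
    duplication_penalty: float = 0.5
    max_depth: int | None = None
    allow_multi_species_leaves: bool = False
    polarity: PolarityRule = PolarityRule.DEFAULT

    def __post_init__(self):
        if self.scoring not in ("information-gain", "worst-case-balance"):
            raise ValueError(f"unknown scoring {self.scoring!r}")
        if self.duplication_penalty < 0:
            raise ValueError("duplication_penalty must be >= 0")


@dataclass
class BuildResult:
    key: DichotomousKey
    log: list[dict] = field(default_factory=list)


def _split(matrix, code, taxa, polarity):
    """Partition taxa by binary support: (positive side, negative side, both)."""
    pos, neg, both = [], [], []
    for sp in taxa:
        state = matrix.state(sp, code)
        p = state_supports(state, "positive", polarity)
        n = state_supports(state, "negative", polarity)
        if p and n:
            both.append(sp)
        elif p:
            pos.append(sp)
        else:
            neg.append(sp)
    return pos, neg, both


def _score(config: BuilderConfig, n: int, na: int, nb: int, n_both: int) -> float:
    if config.scoring == "worst-case-balance":
        return -float(max(na, nb)) - config.duplication_penalty * n_both
    # expected log-reduction in taxon count over the two sides
    gain = math.log(n) - (na * math.log(na) + nb * math.log(nb)) / (na + nb)
    return gain - config.duplication_penalty * n_both


def build_key(
    matrix: CharacterMatrix,
    config: BuilderConfig | None = None,
    name: str = "",
) -> BuildResult:
    """Construct a key over all matrix species.

    Taxa whose state supports both outcomes of the chosen character follow
    both leads (the key must work whichever way the strain behaves). A
    split is admissible only if both sides are non-empty and neither side
    keeps the full taxon set, which guarantees termination. Lead ``a``
    always carries the positive outcome, matching printed convention.

    Raises
    ------
    IndistinguishableTaxaError
        When a taxon set admits no split and multi-species leaves are
        disallowed (e.g. two identical rows).
    """
    config = config or BuilderConfig()
    if matrix.n_species < 2:
        raise ValueError("need at least 2 species to build a key")
    log: list[dict] = []
    couplets: list[Couplet] = []
    counter = {"next": 1}

    def leaf_for(taxa: list[str]) -> str:
        if len(taxa) == 1:
            return taxa[0]
        if not config.allow_multi_species_leaves:
            raise IndistinguishableTaxaError(taxa)
        log.append({"event": "multi-species-leaf", "taxa": sorted(taxa)})
        return MULTI_LEAF_SEP.join(sorted(taxa))

    def best_split(taxa: list[str]):
        best = None
        for idx, code in enumerate(matrix.codes):
            pos, neg, both = _split(matrix, code, taxa, config.polarity)
            na, nb = len(pos) + len(both), len(neg) + len(both)
            if na == 0 or nb == 0 or max(na, nb) >= len(taxa):
                continue  # degenerate: no reduction on one side
            score = _score(config, len(taxa), na, nb, len(both))
            if best is None or score > best[0]:  # strict > keeps column-order ties
                best = (score, idx, code, pos + both, neg + both, both)
        return best

    def recurse(taxa: list[str], depth: int, parent: int | None) -> tuple[str, int | None, str | None]:
        """Returns ('couplet', number, None) or ('species', None, name)."""
        if len(taxa) == 1:
            return ("species", None, taxa[0])
        if config.max_depth is not None and depth > config.max_depth:
            return ("species", None, leaf_for(taxa))
        found = best_split(taxa)
        if found is None:
            return ("species", None, leaf_for(taxa))
        score, _, code, side_a, side_b, both = found
        number = counter["next"]
        counter["next"] += 1
        log.append(
            {
                "event": "split",
                "couplet": number,
                "character": code,
                "score": score,
                "side_a": len(side_a),
                "side_b": len(side_b),
                "duplicated": sorted(both),
            }
        )
        kind_a, num_a, sp_a = recurse(side_a, depth + 1, number)
        kind_b, num_b, sp_b = recurse(side_b, depth + 1, number)
        couplets.append(
            Couplet(
                number=number,
                parent_annotation=parent,
                leads=(
                    Lead("a", code, "positive", target_couplet=num_a, target_species=sp_a),
                    Lead("b", code, "negative", target_couplet=num_b, target_species=sp_b),
                ),
            )
        )
        return ("couplet", number, None)

    kind, _, sp = recurse(list(matrix.species), 1, None)
    if kind == "species":  # no character splits the full set
        raise IndistinguishableTaxaError(list(matrix.species))
    return BuildResult(key=make_key(couplets, name=name), log=log)


def _universe(key: DichotomousKey) -> set[str]:
    out: set[str] = set()
    for leaf in key.species_leaves:
        for sp in leaf.split(MULTI_LEAF_SEP):
            out.add(normalize_species_name(sp))
    return out


def compare_keys(key_a: DichotomousKey, key_b: DichotomousKey) -> dict:
    """Metric deltas, character overlap, and per-species depth differences."""
    ua, ub = _universe(key_a), _universe(key_b)
    if ua != ub:
        raise UniverseMismatchError(
            f"species universes differ: only-a={sorted(ua - ub)}, only-b={sorted(ub - ua)}"
        )
    ma, mb = key_metrics(key_a), key_metrics(key_b)
    inter = ma.characters_used & mb.characters_used
    union = ma.characters_used | mb.characters_used
    da = {normalize_species_name(s): d for s, d in key_a.leaf_depths().items()}
    db = {normalize_species_name(s): d for s, d in key_b.leaf_depths().items()}
    per_species = {
        sp: {"depth_a": da[sp], "depth_b": db[sp], "delta": db[sp] - da[sp]}
        for sp in sorted(da.keys() & db.keys())
    }
    return {
        "metrics_a": ma.to_dict(),
        "metrics_b": mb.to_dict(),
        "couplet_delta": mb.couplet_count - ma.couplet_count,
        "max_depth_delta": mb.max_depth - ma.max_depth,
        "mean_depth_delta": mb.mean_depth - ma.mean_depth,
        "character_jaccard": (len(inter) / len(union)) if union else 1.0,
        "per_species_depth": per_species,
    }
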