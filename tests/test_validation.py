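"""Key-vs-matrix consistency, ambiguity bookkeeping, and metrics.

The traversal oracle here is independent of the implementation: it
enumerates every per-character outcome assignment a row admits and walks
the key deterministically for each, collecting the leaves.
"""

import itertools

import numpy as np
import pytest

from wickerkey.builder import build_key
from wickerkey.key import reachable_leaves
from wickerkey.matrix import parse_matrix
from wickerkey.states import NO_DATA_STATE, PolarityRule
from wickerkey.synth import MatrixSpec, gen_matrix
from wickerkey.validation import ambiguity_report, check_consistency, key_metrics


def brute_force_reachable(key, row, polarity=PolarityRule.DEFAULT):
    """Enumerate all outcome resolutions of the row; walk each one."""
    codes = sorted({c.character for c in key.couplets.values()})
    options = [
        sorted(row.get(c, NO_DATA_STATE).supported_outcomes(polarity)) for c in codes
    ]
    leaves = set()
    for combo in itertools.product(*options):
        assign = dict(zip(codes, combo))
        num = key.root
        while True:
            couplet = key.couplets[num]
            lead = next(l for l in couplet.leads if l.outcome == assign[couplet.character])
            if lead.is_leaf:
                leaves.add(lead.target_species)
                break
            num = lead.target_couplet
    return leaves


class TestCheckConsistency:
    def test_every_fixture_species_reaches_its_own_leaf(self, key, matrix):
        report = check_consistency(key, matrix)
        assert not report.key_only and not report.matrix_only
        assert report.all_consistent

    @pytest.mark.parametrize("species", ["W. lannaensis", "W. nanensis"])
    def test_new_species_witness_paths(self, key, matrix, species):
        report = check_consistency(key, matrix)
        rec = next(r for r in report.records if r.species == species)
        assert rec.own_leaf_reachable
        expected = {
            "W. lannaensis": [(1, "b"), (7, "b"), (19, "b"), (21, "b"), (23, "b"),
                              (27, "b"), (28, "a"), (29, "b"), (36, "b"), (37, "b")],
            "W. nanensis": [(1, "b"), (7, "b"), (19, "b"), (21, "b"),
                            (23, "a"), (24, "b"), (25, "b"), (26, "a")],
        }[species]
        assert rec.witness_path == expected

    def test_contradicting_row_reports_first_conflicting_couplet(self, toy_key):
        # Sp. beta's leaf needs Mlb negative, but its row says positive.
        m = parse_matrix("species\tMlb\nSp. alpha\t+\nSp. beta\t+\n")
        report = check_consistency(toy_key, m)
        rec = next(r for r in report.records if r.species == "Sp. beta")
        assert not rec.own_leaf_reachable
        assert rec.conflict == {
            "couplet": 1, "character": "Mlb", "state": "+", "asserted": "negative"
        }


class TestAmbiguityReport:
    def test_definite_distinct_rows_map_each_leaf_to_itself(self, toy_matrix):
        built = build_key(toy_matrix).key
        report = ambiguity_report(built, toy_matrix)
        assert report == {sp: {sp} for sp in toy_matrix.species}

    def test_all_variable_row_reaches_every_leaf(self):
        definite = parse_matrix("species\tc1\tc2\nA\t+\t+\nB\t-\t+\n")
        built = build_key(definite).key
        m = parse_matrix("species\tc1\tc2\nA\t+\t+\nB\t-\t+\nC\tv\tv\n")
        report = ambiguity_report(built, m)
        for leaf, reaching in report.items():
            assert "C" in reaching

    def test_conservation_forward_equals_inverted(self, key, matrix):
        """Sum over leaves of reaching species equals sum over species of
        reachable leaves."""
        inverted = ambiguity_report(key, matrix)
        forward_total = sum(
            len(reachable_leaves(key, matrix.row(sp))) for sp in matrix.species
        )
        assert sum(len(v) for v in inverted.values()) == forward_total


class TestKeyMetrics:
    def test_fixture_metrics(self, key, matrix):
        m = key_metrics(key)
        assert m.couplet_count == 37
        assert m.leaf_count == 38
        assert m.characters_used <= set(matrix.codes)

    def test_single_couplet_metrics(self, toy_key):
        m = key_metrics(toy_key)
        assert (m.couplet_count, m.leaf_count, m.max_depth, m.mean_depth) == (1, 2, 1, 1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_reachable_leaves_matches_resolution_enumeration(self, seed):
        """On small matrices, the traversal equals brute-force enumeration of
        every outcome resolution, for rows full of uncertain states."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        k = int(rng.integers(3, 7))
        base = gen_matrix(MatrixSpec(n_species=n, n_characters=k, seed=seed))
        built = build_key(base).key
        tokens = ["+", "-", "w", "v", "n", "l", "s", "w/+", "+/-", "l/-"]
        for _ in range(8):
            row_tokens = [tokens[i] for i in rng.integers(0, len(tokens), size=k)]
            m = parse_matrix(
                "species\t" + "\t".join(base.codes) + "\nQ\t" + "\t".join(row_tokens) + "\n"
            )
            row = m.row("Q")
            assert reachable_leaves(built, row) == brute_force_reachable(built, row)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_on_the_fixture_key_with_uncertain_rows(self, key, matrix, seed):
        """Fixture-key traversal agrees with enumeration when a species row is
        blurred by extra no-data cells (kept few enough to enumerate)."""
        rng = np.random.default_rng(100 + seed)
        # keep enumeration tractable: start from a mostly definite row
        crisp = [
            sp for sp in matrix.species
            if sum(not s.is_definite for s in matrix.row(sp).values()) <= 4
        ]
        species = crisp[int(rng.integers(len(crisp)))]
        row = matrix.row(species)
        definite = [c for c in matrix.codes if row[c].is_definite]
        for code in rng.choice(definite, size=3, replace=False):
            row[code] = NO_DATA_STATE
        assert reachable_leaves(key, row) == brute_force_reachable(key, row)
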