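"""Key model: parsing, structure, serialization, and traversal."""

import json

import pytest

from wickerkey import fixtures
from wickerkey.errors import KeySchemaError, StructureError
from wickerkey.key import (
    Couplet,
    Lead,
    identify,
    make_key,
    parse_key,
    reachable_leaves,
    serialize_key,
    validate_structure,
)
from wickerkey.matrix import SpecimenProfile
from wickerkey.states import NO_DATA_STATE, parse_state_token


def _key_doc(couplets):
    return json.dumps({"schema": "wickerkey.key/1", "couplets": couplets})


class TestParseKey:
    def test_fixture_counts(self, key):
        assert len(key.couplets) == 37
        assert len(key.species_leaves) == 38
        assert key.root == 1

    def test_leaf_arithmetic(self, key, toy_key):
        for k in (key, toy_key):
            assert len(k.species_leaves) == len(k.couplets) + 1

    def test_single_couplet_toy(self, toy_key):
        assert toy_key.species_leaves == ["Sp. alpha", "Sp. beta"]

    def test_doubly_referenced_couplet_rejected(self):
        doc = _key_doc(
            [
                {"number": 1, "leads": [
                    {"label": "a", "character": "c", "outcome": "positive", "couplet": 2},
                    {"label": "b", "character": "c", "outcome": "negative", "couplet": 2},
                ]},
                {"number": 2, "leads": [
                    {"label": "a", "character": "d", "outcome": "positive", "species": "X"},
                    {"label": "b", "character": "d", "outcome": "negative", "species": "Y"},
                ]},
            ]
        )
        with pytest.raises(StructureError, match="more than one lead"):
            parse_key(doc)

    def test_cycle_rejected(self):
        doc = _key_doc(
            [
                {"number": 1, "leads": [
                    {"label": "a", "character": "c", "outcome": "positive", "couplet": 2},
                    {"label": "b", "character": "c", "outcome": "negative", "species": "X"},
                ]},
                {"number": 2, "leads": [
                    {"label": "a", "character": "d", "outcome": "positive", "couplet": 1},
                    {"label": "b", "character": "d", "outcome": "negative", "species": "Y"},
                ]},
            ]
        )
        with pytest.raises(StructureError):
            parse_key(doc)

    def test_leads_must_oppose_on_one_character(self):
        with pytest.raises(KeySchemaError):
            Couplet(
                number=1,
                leads=(
                    Lead("a", "c1", "positive", target_species="X"),
                    Lead("b", "c2", "negative", target_species="Y"),
                ),
            )
        with pytest.raises(KeySchemaError):
            Couplet(
                number=1,
                leads=(
                    Lead("a", "c1", "positive", target_species="X"),
                    Lead("b", "c1", "positive", target_species="Y"),
                ),
            )


class TestSerializeKey:
    def test_fixture_roundtrip(self, key):
        assert serialize_key(parse_key(serialize_key(key))) == serialize_key(key)

    def test_annotations_preserved(self, key):
        reparsed = parse_key(serialize_key(key))
        assert reparsed.couplets[26].parent_annotation == 24  # printed value, kept verbatim

    def test_toy_roundtrip(self, toy_key):
        reparsed = parse_key(serialize_key(toy_key))
        assert reparsed.species_leaves == toy_key.species_leaves


class TestValidateStructure:
    def test_fixture_has_exactly_one_annotation_discrepancy(self, key):
        report = validate_structure(key)
        assert report.violations == []
        assert report.annotation_discrepancies == [
            {"couplet": 26, "printed": 24, "actual": 25}
        ]

    def test_correct_annotations_yield_empty_report(self):
        k = make_key(
            [
                Couplet(1, (
                    Lead("a", "c", "positive", target_couplet=2),
                    Lead("b", "c", "negative", target_species="X"),
                )),
                Couplet(2, (
                    Lead("a", "d", "positive", target_species="Y"),
                    Lead("b", "d", "negative", target_species="Z"),
                ), parent_annotation=1),
            ]
        )
        assert validate_structure(k).ok


class TestIdentify:
    def test_lannaensis_profile_follows_the_printed_path(self, key):
        result = identify(key, fixtures.load_profile("lannaensis"))
        assert result.status == "identified"
        assert result.species == "W. lannaensis"
        assert result.path == [
            (1, "b"), (7, "b"), (19, "b"), (21, "b"), (23, "b"),
            (27, "b"), (28, "a"), (29, "b"), (36, "b"), (37, "b"),
        ]

    def test_nanensis_profile_follows_the_printed_path(self, key):
        result = identify(key, fixtures.load_profile("nanensis"))
        assert result.status == "identified"
        assert result.species == "W. nanensis"
        assert result.path == [
            (1, "b"), (7, "b"), (19, "b"), (21, "b"),
            (23, "a"), (24, "b"), (25, "b"), (26, "a"),
        ]

    def test_missing_first_character_stalls_at_root(self, key):
        profile = fixtures.load_profile("nanensis")
        del profile.outcomes["Mlb"]
        result = identify(key, profile)
        assert result.status == "stalled"
        assert result.stalled_at == 1
        assert result.path == []

    def test_variable_state_forks_and_reports_frontier(self, toy_key):
        profile = SpecimenProfile(outcomes={"Mlb": parse_state_token("v")})
        result = identify(toy_key, profile)
        assert result.status == "ambiguous"
        assert result.candidates == {"Sp. alpha", "Sp. beta"}


class TestReachableLeaves:
    def test_all_no_data_reaches_every_species(self, key, matrix):
        row = {c: NO_DATA_STATE for c in matrix.codes}
        assert reachable_leaves(key, row) == set(matrix.species)

    def test_nanensis_row_reaches_its_own_leaf(self, key, matrix):
        assert "W. nanensis" in reachable_leaves(key, matrix.row("W. nanensis"))

    def test_definite_distinct_row_reaches_singleton(self, toy_key):
        assert reachable_leaves(toy_key, {"Mlb": parse_state_token("+")}) == {"Sp. alpha"}

    def test_missing_codes_treated_as_no_data(self, toy_key):
        assert reachable_leaves(toy_key, {}) == {"Sp. alpha", "Sp. beta"}

    def test_adding_information_never_enlarges_the_frontier(self, key, matrix):
        """Monotonicity: replacing no-data with a definite state shrinks
        (or keeps) the reachable set."""
        for species in ("W. edaphicus", "W. tratensis", "W. chaumierensis"):
            row = matrix.row(species)
            vague = dict(row)
            no_data_codes = [c for c, s in row.items() if s.is_no_data]
            baseline = reachable_leaves(key, vague)
            for code in no_data_codes:
                sharper = dict(vague)
                sharper[code] = parse_state_token("+")
                assert reachable_leaves(key, sharper) <= baseline
                sharper[code] = parse_state_token("-")
                assert reachable_leaves(key, sharper) <= baseline

    def test_lead_a_always_asserts_positive_in_the_fixture(self, key):
        """Transcription QC: the printed key phrases every first lead as the
        positive outcome."""
        for couplet in key.couplets.values():
            assert couplet.leads[0].outcome == "positive"
            assert couplet.leads[1].outcome == "negative"
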