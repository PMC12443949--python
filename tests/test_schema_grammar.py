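import json
import random
import re

import pytest

from _oracles import (
    mutate,
    random_record,
    random_schema,
    record_oracle,
    serialize_with_padding,
)
from clinext import gbnf, schema as sc
from clinext.errors import GrammarError, OutputParseError, SchemaError


def make_schema(*specs):
    return sc.validate_schema(list(specs))


SIDE = sc.LabelSpec("embolism_side", "categorical", ("left", "right", "bilateral"))
COUGH = sc.LabelSpec("cough", "boolean")


class TestSchemaValidation:
    def test_embolism_side_schema_valid(self):
        schema = make_schema(SIDE)
        assert schema.names == ("embolism_side",)

    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            make_schema(COUGH, sc.LabelSpec("cough", "string", max_length=5))

    def test_single_category_rejected(self):
        with pytest.raises(SchemaError, match=">= 2"):
            make_schema(sc.LabelSpec("x", "categorical", ("yes",)))

    def test_illegal_name_rejected(self):
        with pytest.raises(SchemaError, match="illegal"):
            make_schema(sc.LabelSpec("bad-name!", "boolean"))

    def test_string_requires_max_length(self):
        with pytest.raises(SchemaError, match="max_length"):
            make_schema(sc.LabelSpec("s", "string"))

    def test_empty_schema_rejected(self):
        with pytest.raises(SchemaError):
            sc.validate_schema([])


class TestJsonSchema:
    def test_boolean_property_required(self):
        doc = json.loads(sc.schema_to_json_schema(make_schema(COUGH)))
        assert doc["properties"]["cough"] == {"type": "boolean"}
        assert doc["required"] == ["cough"]
        assert doc["additionalProperties"] is False

    def test_categorical_enum_exact(self):
        doc = json.loads(sc.schema_to_json_schema(make_schema(SIDE)))
        assert doc["properties"]["embolism_side"]["enum"] == [
            "left", "right", "bilateral",
        ]

    def test_string_max_length_rejects_overlong(self):
        spec = sc.LabelSpec("s", "string", max_length=5)
        doc = json.loads(sc.schema_to_json_schema(make_schema(spec)))
        assert doc["properties"]["s"]["maxLength"] == 5
        assert len("abcdef") > doc["properties"]["s"]["maxLength"]

    def test_number_pattern_is_bounded_digit_string(self):
        spec = sc.LabelSpec("n", "number", max_length=3)
        doc = json.loads(sc.schema_to_json_schema(make_schema(spec)))
        pattern = doc["properties"]["n"]["pattern"]
        assert re.match(pattern, "017")
        assert re.match(pattern, "1.5")
        assert not re.match(pattern, "1234")
        assert not re.match(pattern, "1..2")
        assert not re.match(pattern, ".")


class TestGbnfGeneration:
    def test_boolean_grammar_accepts_and_rejects(self):
        g = sc.schema_to_gbnf(make_schema(COUGH))
        assert gbnf.recognize(g, '{"cough": true}')
        assert gbnf.recognize(g, '{"cough":false}')
        assert not gbnf.recognize(g, '{"cough": "yes"}')

    def test_quoted_category_escape_round_trip(self):
        spec = sc.LabelSpec("size", "categorical", ('6"', "8 cm"))
        schema = make_schema(spec)
        g = sc.schema_to_gbnf(schema)
        serialized = sc.serialize_record(schema, {"size": '6"'})
        assert gbnf.recognize(g, serialized)
        assert sc.parse_and_validate_output(serialized, schema)["size"] == '6"'

    def test_fixed_key_order_enforced(self):
        schema = make_schema(
            sc.LabelSpec("a", "boolean"), sc.LabelSpec("b", "boolean")
        )
        g = sc.schema_to_gbnf(schema)
        assert gbnf.recognize(g, '{"a": true, "b": false}')
        assert not gbnf.recognize(g, '{"b": false, "a": true}')

    def test_empty_candidate_rejected(self):
        assert not gbnf.recognize(sc.schema_to_gbnf(make_schema(COUGH)), "")

    def test_padding_zero_or_one_space_only(self):
        g = sc.schema_to_gbnf(make_schema(SIDE))
        assert gbnf.recognize(g, '{"embolism_side":"left"}')
        assert gbnf.recognize(g, '{"embolism_side": "left"}')
        assert not gbnf.recognize(g, '{"embolism_side":  "left"}')
        assert not gbnf.recognize(g, '{ "embolism_side": "left"}')

    def test_string_length_budget_enforced(self):
        schema = make_schema(sc.LabelSpec("s", "string", max_length=3))
        g = sc.schema_to_gbnf(schema)
        assert gbnf.recognize(g, '{"s": "abc"}')
        assert gbnf.recognize(g, '{"s": ""}')
        assert not gbnf.recognize(g, '{"s": "abcd"}')

    def test_number_language_forms(self):
        schema = make_schema(sc.LabelSpec("n", "number", max_length=3))
        g = sc.schema_to_gbnf(schema)
        for good in ("0", "017", "1.5", ".5", "12."):
            assert gbnf.recognize(g, f'{{"n": "{good}"}}'), good
        for bad in ("1234", "1..2", ".", "", "-1", "1e3"):
            assert not gbnf.recognize(g, f'{{"n": "{bad}"}}'), bad


class TestRecognizerEngine:
    def test_recursive_grammar_rejected(self):
        g = gbnf.GrammarText('root ::= "a" root | "b"\n')
        with pytest.raises(GrammarError, match="recursive"):
            gbnf.recognize(g, "ab")

    def test_undefined_rule_rejected(self):
        with pytest.raises(GrammarError, match="undefined"):
            gbnf.recognize(gbnf.GrammarText("root ::= missing\n"), "x")

    def test_general_constructs(self):
        g = gbnf.GrammarText('root ::= ("a" | [0-9])+ "end"? [^z]*\n')
        assert gbnf.recognize(g, "a7aend")
        assert gbnf.recognize(g, "5")
        assert gbnf.recognize(g, "aendqqq")
        assert not gbnf.recognize(g, "z")
        assert not gbnf.recognize(g, "")


class TestParseAndValidate:
    def test_well_formed_output_parses(self):
        schema = make_schema(COUGH, SIDE)
        out = sc.parse_and_validate_output(
            '{"cough": true, "embolism_side": "left"}', schema
        )
        assert out == {"cough": True, "embolism_side": "left"}

    def test_truncated_output_raises_with_raw_preserved(self):
        with pytest.raises(OutputParseError) as exc:
            sc.parse_and_validate_output('{"cough": tru', make_schema(COUGH))
        assert exc.value.raw == '{"cough": tru'

    def test_missing_and_extra_keys_reported(self):
        schema = make_schema(COUGH, SIDE)
        with pytest.raises(OutputParseError, match="embolism_side"):
            sc.parse_and_validate_output('{"cough": true}', schema)
        with pytest.raises(OutputParseError, match="extra"):
            sc.parse_and_validate_output(
                '{"cough": true, "embolism_side": "left", "x": 1}', schema
            )

    def test_out_of_enum_category_rejected(self):
        with pytest.raises(OutputParseError, match="not in categories"):
            sc.parse_and_validate_output(
                '{"embolism_side": "up"}', make_schema(SIDE)
            )

    def test_number_normalization_strips_leading_zeros(self):
        schema = make_schema(sc.LabelSpec("n_nodes", "number", max_length=5))
        out = sc.parse_and_validate_output('{"n_nodes": "017"}', schema)
        assert out["n_nodes"] == 17
        assert sc.normalize_number("017") == (17, "17")
        assert sc.normalize_number("01.50")[0] == 1.5


class TestConfigRoundTrip:
    def test_save_load_identity(self, tmp_path):
        schema = make_schema(
            COUGH, SIDE,
            sc.LabelSpec("note", "string", max_length=40),
            sc.LabelSpec("n_nodes", "number", max_length=3),
        )
        sc.save_schema_config(schema, tmp_path / "s.csv")
        assert sc.load_schema_config(tmp_path / "s.csv") == schema

    def test_categories_kind_synonym_accepted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "label,kind,categories,max_length\nside,categories,\"left,right\",\n"
        )
        schema = sc.load_schema_config(p)
        assert schema["side"].kind == "categorical"
        assert schema["side"].categories == ("left", "right")

    def test_category_with_comma_survives(self, tmp_path):
        schema = make_schema(
            sc.LabelSpec("x", "categorical", ("a,b", "c", "d\\e"))
        )
        sc.save_schema_config(schema, tmp_path / "s.csv")
        assert sc.load_schema_config(tmp_path / "s.csv") == schema

    def test_unknown_kind_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("label,kind,categories,max_length\nx,integer,,3\n")
        with pytest.raises(SchemaError, match="unknown kind"):
            sc.load_schema_config(p)

    def test_random_schemas_round_trip(self, tmp_path):
        rng = random.Random(7)
        for i in range(25):
            schema = random_schema(rng)
            path = tmp_path / f"s{i}.csv"
            sc.save_schema_config(schema, path)
            assert sc.load_schema_config(path) == schema


class TestLanguageEquivalence:
    """recognize() must agree with the JSON-parse + constraint-check oracle."""

    def test_valid_records_accepted_and_mutants_agree(self):
        rng = random.Random(11)
        for _ in range(50):
            schema = random_schema(rng)
            g = sc.schema_to_gbnf(schema)
            for _ in range(3):
                values = random_record(schema, rng)
                s = serialize_with_padding(schema, values, rng)
                assert record_oracle(schema, s), s
                assert gbnf.recognize(g, s), s
                for _ in range(4):
                    m = mutate(s, rng)
                    assert gbnf.recognize(g, m) == record_oracle(schema, m), m

    def test_serializer_output_always_recognized(self):
        rng = random.Random(13)
        for _ in range(30):
            schema = random_schema(rng)
            g = sc.schema_to_gbnf(schema)
            values = random_record(schema, rng)
            s = sc.serialize_record(schema, values)
            assert gbnf.recognize(g, s)
            parsed = sc.parse_and_validate_output(s, schema)
            for spec in schema.labels:
                if spec.kind == "number":
                    assert parsed[spec.name] == sc.normalize_number(
                        values[spec.name]
                    )[0]
                else:
                    assert parsed[spec.name] == values[spec.name]
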