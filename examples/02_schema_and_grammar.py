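"""Define an extraction schema and compile it to JSON schema + GBNF.

The grammar's language is exactly the set of single-line JSON objects the
schema permits, so a grammar-constrained decoder can only emit parseable
records; the recognizer lets you check candidate outputs offline.
"""

import clinext as cx

schema = cx.validate_schema(
    [
        cx.LabelSpec("cough", "boolean"),
        cx.LabelSpec("embolism_side", "categorical", ("left", "right", "bilateral")),
        cx.LabelSpec("nodes_examined", "number", max_length=3),
    ]
)

print("--- JSON schema ---")
print(cx.schema_to_json_schema(schema))

grammar = cx.schema_to_gbnf(schema)
print("--- GBNF grammar (llama.cpp dialect) ---")
print(grammar.text)

for candidate in (
    '{"cough": true, "embolism_side": "left", "nodes_examined": "17"}',
    '{"cough": "yes", "embolism_side": "left", "nodes_examined": "17"}',
    '{"embolism_side": "left", "cough": true, "nodes_examined": "17"}',
):
    print(f"{cx.recognize(grammar, candidate)!s:>5}  {candidate}")
# True: well-formed record in schema key order.  False: a non-boolean value
# or out-of-order keys fall outside the grammar's language.

parsed = cx.parse_and_validate_output(
    '{"cough": true, "embolism_side": "left", "nodes_examined": "017"}', schema
)
print("parsed with number normalization:", parsed)  # "017" -> 17
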