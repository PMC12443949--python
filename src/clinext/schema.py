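"""Declarative extraction schemas and their compiled forms.

An :class:`ExtractionSchema` is an ordered list of labels, each with a kind
(string, boolean, categorical, number) and constraints.  A schema compiles
to two artifacts:

* a JSON schema describing the single-object output the model must emit, and
* a GBNF grammar whose language is exactly the set of single-line JSON
  objects with the schema's keys in schema order — the grammar handed to a
  constrained decoder so every completion is parseable by construction.

Numbers are treated as bounded digit strings (one optional decimal point)
rather than full JSON numbers: the schema constraint is a character budget,
and values are normalized by stripping leading zeros after parsing.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Any, Sequence

from .errors import OutputParseError, SchemaError
from .gbnf import GrammarText

KINDS = ("string", "boolean", "categorical", "number")
_KIND_SYNONYMS = {"categories": "categorical", "bool": "boolean"}
_NAME_RE = re.compile(r"^[A-Za-z0-9_ ]+$")


@dataclass(frozen=True)
class LabelSpec:
    """One feature to extract: a name, a kind, and kind-specific constraints."""

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    max_length: int | None = None

    def validate(self) -> None:
        if not self.name or not _NAME_RE.match(self.name):
            raise SchemaError(
                f"illegal label name {self.name!r}: use letters, digits, "
                "underscore or space"
            )
        if self.kind not in KINDS:
            raise SchemaError(f"label {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.categories) < 2:
                raise SchemaError(
                    f"label {self.name!r}: categorical needs >= 2 categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"label {self.name!r}: duplicate categories")
            if any(not c for c in self.categories):
                raise SchemaError(f"label {self.name!r}: empty category value")
            if self.max_length is not None:
                raise SchemaError(
                    f"label {self.name!r}: max_length applies to string/number only"
                )
        elif self.kind == "boolean":
            if self.categories or self.max_length is not None:
                raise SchemaError(
                    f"label {self.name!r}: boolean takes no categories/max_length"
                )
        else:  # string, number
            if self.categories:
                raise SchemaError(
                    f"label {self.name!r}: categories apply to categorical only"
                )
            if self.max_length is None or self.max_length < 1:
                raise SchemaError(
                    f"label {self.name!r}: {self.kind} needs max_length >= 1"
                )


@dataclass(frozen=True)
class ExtractionSchema:
    """An ordered, validated collection of labels.

    Order is significant: it fixes the key order of output objects and the
    column order of result tables.
    """

    labels: tuple[LabelSpec, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.labels)

    def __getitem__(self, name: str) -> LabelSpec:
        for l in self.labels:
            if l.name == name:
                return l
        raise KeyError(name)


def validate_schema(labels: Sequence[LabelSpec]) -> ExtractionSchema:
    """Validate label specs and return the schema; raise per offending label."""
    if not labels:
        raise SchemaError("schema needs at least one label")
    for spec in labels:
        spec.validate()
    names = [l.name for l in labels]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise SchemaError(f"duplicate label names: {dupes}")
    return ExtractionSchema(tuple(labels))


# --- JSON schema ------------------------------------------------------------


def _number_pattern(max_length: int) -> str:
    # digit string with at most one decimal point, >= 1 digit, length bounded
    return rf"^(?=.{{1,{max_length}}}$)(\d+\.?\d*|\.\d+)$"


def schema_to_json_schema(schema: ExtractionSchema) -> str:
    """Compile a schema to JSON-schema text (object with required properties)."""
    props: dict[str, Any] = {}
    for spec in schema.labels:
        if spec.kind == "boolean":
            props[spec.name] = {"type": "boolean"}
        elif spec.kind == "categorical":
            props[spec.name] = {"type": "string", "enum": list(spec.categories)}
        elif spec.kind == "string":
            props[spec.name] = {"type": "string", "maxLength": spec.max_length}
        else:  # number: a bounded digit string
            props[spec.name] = {
                "type": "string",
                "maxLength": spec.max_length,
                "pattern": _number_pattern(spec.max_length),
            }
    doc = {
        "type": "object",
        "properties": props,
        "required": list(schema.names),
        "additionalProperties": False,
    }
    return json.dumps(doc, indent=2, ensure_ascii=False)


# --- GBNF -------------------------------------------------------------------


def _gbnf_escape(s: str) -> str:
    out = []
    for ch in s:
        if ch == "\\":
            out.append("\\\\")
        elif ch == '"':
            out.append('\\"')
        elif ch == "\n":
            out.append("\\n")
        elif ch == "\r":
            out.append("\\r")
        elif ch == "\t":
            out.append("\\t")
        elif ord(ch) < 0x20:
            out.append(f"\\x{ord(ch):02x}")
        else:
            out.append(ch)
    return out and "".join(out) or ""


def _json_escape(s: str) -> str:
    # the two escapes the output language permits
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _number_rule(max_length: int) -> str:
    # digit strings of total length <= L with at most one '.', >= 1 digit
    alts = [f"[0-9]{{1,{max_length}}}"]
    if max_length >= 2:
        alts.append(f'"." [0-9]{{1,{max_length - 1}}}')
    for i in range(1, max_length):
        tail = max_length - 1 - i
        if tail > 0:
            alts.append(f'[0-9]{{{i}}} "." [0-9]{{0,{tail}}}')
        else:
            alts.append(f'[0-9]{{{i}}} "."')
    return " | ".join(alts)


def schema_to_gbnf(schema: ExtractionSchema) -> GrammarText:
    """Compile a schema to a GBNF grammar over single-line JSON objects.

    Keys appear in schema order; a single optional space is permitted after
    each ``:`` and ``,``; strings exclude raw control characters and support
    only the ``\\"`` and ``\\\\`` escapes, keeping outputs CSV-safe.
    """
    lines = ['ws ::= " "?']
    lines.append('str-char ::= [^"\\\\\\x00-\\x1f] | "\\\\" ["\\\\]')
    kv_rules = []
    for idx, spec in enumerate(schema.labels):
        vrule = f"val-{idx}"
        if spec.kind == "boolean":
            lines.append(f'{vrule} ::= "true" | "false"')
        elif spec.kind == "categorical":
            literals = " | ".join(
                f'"\\"{_gbnf_escape(_json_escape(c))}\\""' for c in spec.categories
            )
            lines.append(f"{vrule} ::= {literals}")
        elif spec.kind == "string":
            lines.append(f'{vrule} ::= "\\"" str-char{{0,{spec.max_length}}} "\\""')
        else:  # number
            lines.append(f"num-{idx} ::= {_number_rule(spec.max_length)}")
            lines.append(f'{vrule} ::= "\\"" num-{idx} "\\""')
        key_lit = f'"\\"{_gbnf_escape(_json_escape(spec.name))}\\":"'
        lines.append(f"kv-{idx} ::= {key_lit} ws {vrule}")
        kv_rules.append(f"kv-{idx}")
    body = ' "," ws '.join(kv_rules)
    lines.insert(0, f'root ::= "{{" {body} "}}"')
    return GrammarText("\n".join(lines) + "\n", "root")


# --- serialization & parsing ------------------------------------------------


def serialize_record(schema: ExtractionSchema, values: dict[str, Any]) -> str:
    """Serialize a typed record into the canonical sentence of the grammar.

    The result is always accepted by ``recognize`` on ``schema_to_gbnf``:
    keys in schema order, one space after each ``:`` and ``,``, values
    rendered per kind (numbers as quoted digit strings).
    """
    parts = []
    for spec in schema.labels:
        if spec.name not in values:
            raise SchemaError(f"missing value for label {spec.name!r}")
        v = values[spec.name]
        if spec.kind == "boolean":
            if not isinstance(v, bool):
                raise SchemaError(f"label {spec.name!r}: expected bool, got {v!r}")
            rendered = "true" if v else "false"
        elif spec.kind == "categorical":
            if v not in spec.categories:
                raise SchemaError(f"label {spec.name!r}: {v!r} not a category")
            rendered = f'"{_json_escape(str(v))}"'
        elif spec.kind == "number":
            s = str(v)
            if not re.match(_number_pattern(spec.max_length), s):
                raise SchemaError(
                    f"label {spec.name!r}: {s!r} is not a digit string of "
                    f"length <= {spec.max_length}"
                )
            rendered = f'"{s}"'
        else:  # string
            s = str(v)
            if len(s) > spec.max_length:
                raise SchemaError(
                    f"label {spec.name!r}: value exceeds max_length "
                    f"{spec.max_length}"
                )
            if any(ord(c) < 0x20 for c in s):
                raise SchemaError(f"label {spec.name!r}: control characters")
            rendered = f'"{_json_escape(s)}"'
        parts.append(f'"{_json_escape(spec.name)}": {rendered}')
    return "{" + ", ".join(parts) + "}"


def normalize_number(raw: str) -> tuple[int | float, str]:
    """Parse a digit-string number; return (value, normalized form)."""
    try:
        d = Decimal(raw)
    except InvalidOperation:
        raise OutputParseError(f"not a number: {raw!r}", raw) from None
    if d == d.to_integral_value():
        iv = int(d)
        return iv, str(iv)
    fv = float(d)
    return fv, repr(fv)


def parse_and_validate_output(raw: str, schema: ExtractionSchema) -> dict[str, Any]:
    """Parse a completion as JSON and coerce values to the schema's kinds.

    All failure modes raise :class:`OutputParseError` carrying the raw text;
    the extraction engine records these as per-chunk failures instead of
    aborting the run.
    """
    try:
        obj = json.loads(raw)
    except (json.JSONDecodeError, ValueError) as exc:
        raise OutputParseError(f"malformed JSON: {exc}", raw) from None
    if not isinstance(obj, dict):
        raise OutputParseError("output is not a JSON object", raw)
    expected = set(schema.names)
    got = set(obj)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise OutputParseError(
            f"schema mismatch: missing keys {missing}, extra keys {extra}", raw
        )
    values: dict[str, Any] = {}
    for spec in schema.labels:
        v = obj[spec.name]
        if spec.kind == "boolean":
            if not isinstance(v, bool):
                raise OutputParseError(
                    f"label {spec.name!r}: expected boolean, got {v!r}", raw
                )
            values[spec.name] = v
        elif spec.kind == "categorical":
            if v not in spec.categories:
                raise OutputParseError(
                    f"label {spec.name!r}: {v!r} not in categories", raw
                )
            values[spec.name] = str(v)
        elif spec.kind == "number":
            if not isinstance(v, str):
                raise OutputParseError(
                    f"label {spec.name!r}: expected quoted number, got {v!r}", raw
                )
            value, _ = normalize_number(v)
            values[spec.name] = value
        else:  # string
            if not isinstance(v, str):
                raise OutputParseError(
                    f"label {spec.name!r}: expected string, got {v!r}", raw
                )
            if len(v) > spec.max_length:
                raise OutputParseError(
                    f"label {spec.name!r}: exceeds max_length {spec.max_length}",
                    raw,
                )
            values[spec.name] = v
    return values


# --- schema-config CSV ------------------------------------------------------


def _join_categories(categories: Sequence[str]) -> str:
    return ",".join(c.replace("\\", "\\\\").replace(",", "\\,") for c in categories)


def _split_categories(cell: str) -> tuple[str, ...]:
    out, buf, i = [], [], 0
    while i < len(cell):
        c = cell[i]
        if c == "\\" and i + 1 < len(cell):
            buf.append(cell[i + 1])
            i += 2
        elif c == ",":
            out.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(c)
            i += 1
    out.append("".join(buf))
    return tuple(x for x in out if x != "") if cell else ()


def save_schema_config(schema: ExtractionSchema, path: str | Path) -> Path:
    """Write the schema as a config CSV (label, kind, categories, max_length)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "kind", "categories", "max_length"])
        for spec in schema.labels:
            writer.writerow(
                [
                    spec.name,
                    spec.kind,
                    _join_categories(spec.categories),
                    "" if spec.max_length is None else spec.max_length,
                ]
            )
    return path


def load_schema_config(path: str | Path) -> ExtractionSchema:
    """Load a schema config CSV; ``kind="categories"`` is accepted as a synonym."""
    labels = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            kind = row["kind"].strip().lower()
            kind = _KIND_SYNONYMS.get(kind, kind)
            if kind not in KINDS:
                raise SchemaError(f"unknown kind {row['kind']!r} in {path}")
            ml = row.get("max_length", "").strip()
            labels.append(
                LabelSpec(
                    name=row["label"],
                    kind=kind,
                    categories=_split_categories(row.get("categories", "")),
                    max_length=int(ml) if ml else None,
                )
            )
    return validate_schema(labels)
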