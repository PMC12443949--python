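"""Independent oracles used by the test suite.

Everything here is deliberately implemented without touching the package's
own code paths for the quantity under test: per-character confusion tallies
by explicit loops, JSON-record validity by json.loads plus direct
constraint checks, metric formulas as plain arithmetic.
"""

from __future__ import annotations

import json
import random
import re
import string

from clinext.schema import ExtractionSchema, LabelSpec, validate_schema

# --- brute-force character tally -------------------------------------------


def brute_char_confusion(length, mask, spans, restrict_label=None):
    """Per-character TP/FP/TN/FN by an explicit loop over every character."""
    tp = fp = tn = fn = 0
    for i in range(length):
        in_any = any(s.start <= i < s.end for s in spans)
        if restrict_label is None:
            in_gold = in_any
        else:
            in_gold = any(
                s.start <= i < s.end and s.label == restrict_label for s in spans
            )
        m = bool(mask[i])
        if m and in_gold:
            tp += 1
        elif (not m) and in_gold:
            fn += 1
        elif m and not in_any:
            fp += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_metrics(tp, fp, tn, fn):
    """Metric formulas as straight arithmetic; None for 0/0."""

    def div(a, b):
        return None if b == 0 else a / b

    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": div(tp + tn, tp + fp + tn + fn),
        "precision": precision,
        "recall": recall,
        "specificity": div(tn, tn + fp),
        "f1": f1,
        "fpr": div(fp, fp + tn),
        "fnr": div(fn, fn + tp),
    }


# --- random schemas and records ---------------------------------------------

_NAME_ALPHABET = string.ascii_letters + string.digits + "_"
_CATEGORY_ALPHABET = (
    string.ascii_letters + string.digits + " _-.:/" + '"' + "\\" + "{}[],"
)
_STRING_ALPHABET = string.ascii_letters + string.digits + " .,-" + '"' + "\\"


def random_schema(rng: random.Random) -> ExtractionSchema:
    n_labels = rng.randint(1, 4)
    labels = []
    used = set()
    for i in range(n_labels):
        while True:
            name = f"l{i}_" + "".join(
                rng.choice(_NAME_ALPHABET) for _ in range(rng.randint(1, 6))
            )
            if name not in used:
                used.add(name)
                break
        kind = rng.choice(["boolean", "categorical", "string", "number"])
        if kind == "categorical":
            cats = set()
            while len(cats) < rng.randint(2, 4):
                cats.add(
                    "".join(
                        rng.choice(_CATEGORY_ALPHABET)
                        for _ in range(rng.randint(1, 8))
                    )
                )
            labels.append(LabelSpec(name, kind, tuple(sorted(cats))))
        elif kind == "boolean":
            labels.append(LabelSpec(name, kind))
        else:
            labels.append(LabelSpec(name, kind, max_length=rng.randint(1, 8)))
    return validate_schema(labels)


def random_record(schema: ExtractionSchema, rng: random.Random) -> dict:
    values = {}
    for spec in schema.labels:
        if spec.kind == "boolean":
            values[spec.name] = rng.random() < 0.5
        elif spec.kind == "categorical":
            values[spec.name] = rng.choice(spec.categories)
        elif spec.kind == "number":
            length = rng.randint(1, spec.max_length)
            digits = "".join(rng.choice(string.digits) for _ in range(length))
            if length >= 2 and rng.random() < 0.3:
                pos = rng.randint(1, length - 1)
                digits = digits[:pos] + "." + digits[pos + 1 :]
            values[spec.name] = digits
        else:
            length = rng.randint(0, spec.max_length)
            values[spec.name] = "".join(
                rng.choice(_STRING_ALPHABET) for _ in range(length)
            )
    return values


def serialize_with_padding(
    schema: ExtractionSchema, values: dict, rng: random.Random
) -> str:
    """Independent serializer using randomized legal padding (0/1 spaces)."""

    def esc(s: str) -> str:
        return s.replace("\\", "\\\\").replace('"', '\\"')

    parts = []
    for spec in schema.labels:
        v = values[spec.name]
        if spec.kind == "boolean":
            rendered = "true" if v else "false"
        else:
            rendered = f'"{esc(str(v))}"'
        pad = " " if rng.random() < 0.5 else ""
        parts.append(f'"{esc(spec.name)}":{pad}{rendered}')
    seps = [("," + (" " if rng.random() < 0.5 else "")) for _ in parts[:-1]]
    body = parts[0] + "".join(s + p for s, p in zip(seps, parts[1:]))
    return "{" + body + "}"


_NUMBER_RE = re.compile(r"\d+\.?\d*$|\.\d+$")


def record_oracle(schema: ExtractionSchema, candidate: str) -> bool:
    """Membership oracle for the grammar's language.

    json.loads for structure, direct constraint checks for values, and a
    character scan for the surface rules (key order via colon/comma counts,
    single-space padding, restricted escapes, no control characters).
    """
    try:
        obj = json.loads(candidate)
    except (json.JSONDecodeError, ValueError):
        return False
    if not isinstance(obj, dict):
        return False
    if list(obj.keys()) != list(schema.names):
        return False
    for spec in schema.labels:
        v = obj[spec.name]
        if spec.kind == "boolean":
            if not isinstance(v, bool):
                return False
        elif spec.kind == "categorical":
            if not isinstance(v, str) or v not in spec.categories:
                return False
        elif spec.kind == "number":
            if (
                not isinstance(v, str)
                or len(v) > spec.max_length
                or not _NUMBER_RE.fullmatch(v)
            ):
                return False
        else:
            if (
                not isinstance(v, str)
                or len(v) > spec.max_length
                or any(ord(c) < 0x20 for c in v)
            ):
                return False
    return _surface_ok(candidate, len(schema.labels))


def _surface_ok(s: str, n_labels: int) -> bool:
    in_str = False
    colons = commas = 0
    i = 0
    while i < len(s):
        c = s[i]
        if in_str:
            if ord(c) < 0x20:
                return False
            if c == "\\":
                if i + 1 >= len(s) or s[i + 1] not in '"\\':
                    return False
                i += 2
                continue
            if c == '"':
                in_str = False
            i += 1
            continue
        if c == '"':
            in_str = True
            i += 1
            continue
        if c in "{}":
            i += 1
            continue
        if c in ":,":
            colons += c == ":"
            commas += c == ","
            i += 1
            if i < len(s) and s[i] == " ":
                i += 1
            continue
        if s.startswith("true", i):
            i += 4
            continue
        if s.startswith("false", i):
            i += 5
            continue
        return False
    # exactly one pair per label (guards json.loads's duplicate-key collapse)
    return not in_str and colons == n_labels and commas == n_labels - 1


def mutate(s: str, rng: random.Random) -> str:
    """One random single-character mutation: delete, substitute, or insert."""
    alphabet = string.printable[:95] + '■"\\'
    op = rng.choice(("delete", "substitute", "insert"))
    if not s:
        return rng.choice(alphabet)
    i = rng.randrange(len(s))
    if op == "delete":
        return s[:i] + s[i + 1 :]
    if op == "substitute":
        ch = rng.choice(alphabet)
        while ch == s[i]:
            ch = rng.choice(alphabet)
        return s[:i] + ch + s[i + 1 :]
    return s[:i] + rng.choice(alphabet) + s[i:]
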