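"""GBNF (llama.cpp grammar dialect) parsing and recognition.

Grammar-based sampling guarantees that a constrained decoder only emits
strings inside a formal language.  This module provides the test-side
counterpart: a recognizer that decides membership of a candidate string in
the language of a generated grammar, used to verify that schema-compiled
grammars accept exactly the intended JSON records.

Supported constructs (everything the schema compiler emits, and the common
core of the dialect): rule references without recursion, quoted literals
with escapes, character classes with ranges and negation, alternation,
grouping, and the repetition operators ``?``, ``*``, ``+`` and bounded
``{m}`` / ``{m,}`` / ``{m,n}``.  Recognition is a backtracking descent over
sets of input positions, memoized on (rule, position), so it is total and
polynomial for non-recursive grammars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .errors import GrammarError


@dataclass(frozen=True)
class GrammarText:
    """A GBNF grammar as text plus the name of its start rule."""

    text: str
    root_rule: str = "root"


# --- AST --------------------------------------------------------------------


@dataclass(frozen=True)
class Lit:
    value: str


@dataclass(frozen=True)
class CharClass:
    negated: bool
    singles: frozenset[str]
    ranges: tuple[tuple[str, str], ...]

    def matches(self, ch: str) -> bool:
        hit = ch in self.singles or any(lo <= ch <= hi for lo, hi in self.ranges)
        return hit != self.negated


@dataclass(frozen=True)
class Ref:
    name: str


@dataclass(frozen=True)
class Rep:
    item: object
    lo: int
    hi: int | None  # None = unbounded


@dataclass(frozen=True)
class Seq:
    items: tuple


@dataclass(frozen=True)
class Alt:
    options: tuple


# --- tokenizer / parser -----------------------------------------------------

_ESCAPES = {"n": "\n", "r": "\r", "t": "\t", '"': '"', "\\": "\\",
            "[": "[", "]": "]", "^": "^", "-": "-"}


def _read_escape(text: str, i: int) -> tuple[str, int]:
    # i points at the char after the backslash
    if i >= len(text):
        raise GrammarError("dangling backslash in grammar")
    c = text[i]
    if c in _ESCAPES:
        return _ESCAPES[c], i + 1
    if c == "x":
        return chr(int(text[i + 1 : i + 3], 16)), i + 3
    if c == "u":
        return chr(int(text[i + 1 : i + 5], 16)), i + 5
    raise GrammarError(f"unsupported grammar feature: escape \\{c}")


def _tokenize(text: str) -> list[tuple[str, object]]:
    tokens: list[tuple[str, object]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "#":  # comment to end of line
            while i < n and text[i] != "\n":
                i += 1
        elif c.isspace():
            i += 1
        elif text.startswith("::=", i):
            tokens.append(("ASSIGN", None))
            i += 3
        elif c.isalpha():
            j = i
            while j < n and (text[j].isalnum() or text[j] in "-_"):
                j += 1
            tokens.append(("NAME", text[i:j]))
            i = j
        elif c == '"':
            i += 1
            buf = []
            while i < n and text[i] != '"':
                if text[i] == "\\":
                    ch, i = _read_escape(text, i + 1)
                    buf.append(ch)
                else:
                    buf.append(text[i])
                    i += 1
            if i >= n:
                raise GrammarError("unterminated literal")
            tokens.append(("LIT", "".join(buf)))
            i += 1
        elif c == "[":
            i += 1
            negated = False
            if i < n and text[i] == "^":
                negated = True
                i += 1
            singles: set[str] = set()
            ranges: list[tuple[str, str]] = []
            while i < n and text[i] != "]":
                if text[i] == "\\":
                    ch, i = _read_escape(text, i + 1)
                else:
                    ch = text[i]
                    i += 1
                if i < n - 1 and text[i] == "-" and text[i + 1] != "]":
                    i += 1
                    if text[i] == "\\":
                        hi, i = _read_escape(text, i + 1)
                    else:
                        hi = text[i]
                        i += 1
                    ranges.append((ch, hi))
                else:
                    singles.add(ch)
            if i >= n:
                raise GrammarError("unterminated character class")
            i += 1
            tokens.append(
                ("CLASS", CharClass(negated, frozenset(singles), tuple(ranges)))
            )
        elif c == "{":
            j = text.index("}", i)
            spec = text[i + 1 : j].replace(" ", "")
            if "," in spec:
                lo_s, hi_s = spec.split(",", 1)
                lo = int(lo_s) if lo_s else 0
                hi = int(hi_s) if hi_s else None
            else:
                lo = hi = int(spec)
            tokens.append(("REP", (lo, hi)))
            i = j + 1
        elif c in "()|?*+":
            tokens.append((c, None))
            i += 1
        else:
            raise GrammarError(f"unsupported grammar feature: character {c!r}")
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, object]]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> tuple[str, object] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, object]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_rules(self) -> dict[str, Alt]:
        rules: dict[str, Alt] = {}
        while self.peek() is not None:
            kind, name = self.next()
            if kind != "NAME":
                raise GrammarError(f"expected rule name, got {kind}")
            kind2, _ = self.next()
            if kind2 != "ASSIGN":
                raise GrammarError(f"expected '::=' after rule name {name!r}")
            rules[str(name)] = self.parse_alternation()
        return rules

    def _at_rule_start(self) -> bool:
        tok = self.peek()
        if tok is None or tok[0] != "NAME":
            return False
        nxt = (
            self.tokens[self.pos + 1] if self.pos + 1 < len(self.tokens) else None
        )
        return nxt is not None and nxt[0] == "ASSIGN"

    def parse_alternation(self) -> Alt:
        options = [self.parse_sequence()]
        while self.peek() is not None and self.peek()[0] == "|":
            self.next()
            options.append(self.parse_sequence())
        return Alt(tuple(options))

    def parse_sequence(self) -> Seq:
        items = []
        while True:
            tok = self.peek()
            if tok is None or tok[0] in ("|", ")") or self._at_rule_start():
                break
            items.append(self.parse_item())
        return Seq(tuple(items))

    def parse_item(self):
        kind, value = self.next()
        if kind == "LIT":
            node = Lit(str(value))
        elif kind == "CLASS":
            node = value
        elif kind == "NAME":
            node = Ref(str(value))
        elif kind == "(":
            node = self.parse_alternation()
            closing = self.next()
            if closing[0] != ")":
                raise GrammarError("unbalanced parentheses in grammar")
        else:
            raise GrammarError(f"unsupported grammar feature: token {kind}")
        tok = self.peek()
        if tok is not None:
            if tok[0] == "?":
                self.next()
                node = Rep(node, 0, 1)
            elif tok[0] == "*":
                self.next()
                node = Rep(node, 0, None)
            elif tok[0] == "+":
                self.next()
                node = Rep(node, 1, None)
            elif tok[0] == "REP":
                self.next()
                lo, hi = tok[1]
                node = Rep(node, lo, hi)
        return node


def _check_rules(rules: dict[str, Alt]) -> None:
    """Reject undefined references and recursion (generated grammars are finite)."""

    def refs_of(node) -> set[str]:
        if isinstance(node, Ref):
            return {node.name}
        if isinstance(node, Rep):
            return refs_of(node.item)
        if isinstance(node, Seq):
            return set().union(*(refs_of(i) for i in node.items)) if node.items else set()
        if isinstance(node, Alt):
            return set().union(*(refs_of(o) for o in node.options))
        return set()

    graph = {name: refs_of(body) for name, body in rules.items()}
    for name, deps in graph.items():
        for d in deps:
            if d not in rules:
                raise GrammarError(f"undefined rule reference: {d!r}")
    # iterative DFS cycle detection
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {name: WHITE for name in graph}
    for start in graph:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(graph[start]))]
        color[start] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for d in it:
                if color[d] == GRAY:
                    raise GrammarError(
                        f"unsupported grammar feature: recursive rule {d!r}"
                    )
                if color[d] == WHITE:
                    color[d] = GRAY
                    stack.append((d, iter(graph[d])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()


@lru_cache(maxsize=256)
def parse_grammar(text: str) -> dict[str, Alt]:
    """Parse GBNF text into an AST rule table (cached per grammar text)."""
    rules = _Parser(_tokenize(text)).parse_rules()
    if not rules:
        raise GrammarError("grammar defines no rules")
    _check_rules(rules)
    return rules


# --- recognition ------------------------------------------------------------


class _Matcher:
    def __init__(self, rules: dict[str, Alt], text: str):
        self.rules = rules
        self.text = text
        self.memo: dict[tuple[str, int], frozenset[int]] = {}

    def match_rule(self, name: str, pos: int) -> frozenset[int]:
        key = (name, pos)
        cached = self.memo.get(key)
        if cached is not None:
            return cached
        ends = frozenset(self.match(self.rules[name], {pos}))
        self.memo[key] = ends
        return ends

    def match(self, node, positions: set[int]) -> set[int]:
        text = self.text
        if isinstance(node, Lit):
            v = node.value
            return {p + len(v) for p in positions if text.startswith(v, p)}
        if isinstance(node, CharClass):
            return {p + 1 for p in positions if p < len(text) and node.matches(text[p])}
        if isinstance(node, Ref):
            out: set[int] = set()
            for p in positions:
                out |= self.match_rule(node.name, p)
            return out
        if isinstance(node, Seq):
            cur = set(positions)
            for item in node.items:
                if not cur:
                    break
                cur = self.match(item, cur)
            return cur
        if isinstance(node, Alt):
            out = set()
            for opt in node.options:
                out |= self.match(opt, set(positions))
            return out
        if isinstance(node, Rep):
            out = set(positions) if node.lo == 0 else set()
            cur = set(positions)
            seen = set(positions)
            k = 0
            while cur:
                cur = self.match(node.item, cur)
                k += 1
                if k >= node.lo:
                    out |= cur
                if node.hi is not None and k >= node.hi:
                    break
                if node.hi is None:
                    # nullable items could loop forever; stop once no new
                    # position appears
                    fresh = cur - seen
                    if not fresh:
                        break
                    seen |= cur
            return out
        raise GrammarError(f"unsupported grammar feature: node {type(node).__name__}")


def recognize(grammar: GrammarText, candidate: str) -> bool:
    """True iff ``candidate`` is in the grammar's language."""
    rules = parse_grammar(grammar.text)
    if grammar.root_rule not in rules:
        raise GrammarError(f"root rule {grammar.root_rule!r} not defined")
    matcher = _Matcher(rules, candidate)
    return len(candidate) in matcher.match_rule(grammar.root_rule, 0)
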