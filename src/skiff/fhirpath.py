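"""A small FHIRPath engine for attribute extraction.

FHIRPath evaluation is collection-based: every step maps a collection of JSON
nodes to a new collection, member access over a list element flattens one
level, and a missing member yields the empty collection rather than an error.
This module implements the navigation subset used for column extraction plus
a handful of functions:

    member access          name.family
    resource-type routing  Patient.birthDate   (empty unless resourceType matches)
    integer indexing       name[0].given
    where(member = 'lit')  identifier.where(system = 'urn:x').value
    exists() / empty() / count() / first()
    replace('a', 'b') / join(', ')

Anything outside this grammar raises :class:`~skiff.errors.PathSyntaxError`
with the character position of the offending token.  The grammar boundary is
deliberate; the ``where`` predicate, for instance, supports only equality
against a single string or numeric literal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Any, Union

from .errors import PathSyntaxError, PathTypeError

# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Member:
    name: str

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True)
class Index:
    index: int

    def unparse(self) -> str:
        return f"[{self.index}]"


@dataclass(frozen=True)
class Func:
    name: str
    args: tuple = ()

    def unparse(self) -> str:
        if self.name == "where":
            member_path, literal = self.args
            inner = ".".join(member_path)
            return f"where({inner} = {_unparse_literal(literal)})"
        rendered = ", ".join(_unparse_literal(a) for a in self.args)
        return f"{self.name}({rendered})"


Segment = Union[Member, Index, Func]


def _unparse_literal(value: Any) -> str:
    if isinstance(value, str):
        return "'" + value.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return repr(value)


@dataclass(frozen=True)
class PathExpression:
    """A parsed path: optional resource-type qualifier plus ordered segments."""

    qualifier: str | None
    segments: tuple[Segment, ...]
    source_text: str

    def unparse(self) -> str:
        parts: list[str] = []
        if self.qualifier:
            parts.append(self.qualifier)
        for seg in self.segments:
            if isinstance(seg, Index):
                if parts:
                    parts[-1] += seg.unparse()
                else:
                    parts.append(seg.unparse())
            else:
                parts.append(seg.unparse())
        return ".".join(parts)


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<number>\d+\.\d+|\d+)
  | (?P<string>'(?:\\.|[^'\\])*')
  | (?P<sym>[.\[\](),=])
    """,
    re.VERBOSE,
)

_NO_ARG_FUNCS = ("exists", "empty", "first", "count")


@dataclass
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(expr: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(expr):
        match = _TOKEN_RE.match(expr, pos)
        if not match:
            raise PathSyntaxError(f"unexpected character {expr[pos]!r}", pos)
        kind = match.lastgroup
        if kind != "ws":
            tokens.append(_Token(kind, match.group(), pos))
        pos = match.end()
    return tokens


def _decode_string(raw: str) -> str:
    body = raw[1:-1]
    return body.replace("\\'", "'").replace("\\\\", "\\")


class _Parser:
    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise PathSyntaxError("unexpected end of expression", len(self.expr))
        self.i += 1
        return tok

    def expect(self, kind: str, value: str | None = None) -> _Token:
        tok = self.next()
        if tok.kind != kind or (value is not None and tok.value != value):
            expected = value or kind
            raise PathSyntaxError(f"expected {expected!r}, got {tok.value!r}", tok.pos)
        return tok

    def parse(self) -> PathExpression:
        segments: list[Segment] = []
        segments.extend(self._element())
        while self.peek() is not None:
            tok = self.next()
            if tok.kind != "sym" or tok.value != ".":
                raise PathSyntaxError(f"expected '.', got {tok.value!r}", tok.pos)
            if self.peek() is None:
                raise PathSyntaxError("empty segment", tok.pos + 1)
            segments.extend(self._element())
        qualifier = None
        if segments and isinstance(segments[0], Member) and segments[0].name[0].isupper():
            qualifier = segments[0].name
            segments = segments[1:]
        return PathExpression(qualifier, tuple(segments), self.expr)

    def _element(self) -> list[Segment]:
        tok = self.peek()
        if tok is None or tok.kind != "name":
            pos = tok.pos if tok else len(self.expr)
            found = tok.value if tok else "end of expression"
            raise PathSyntaxError(f"expected a name, got {found!r}", pos)
        self.next()
        out: list[Segment]
        follow = self.peek()
        if follow and follow.kind == "sym" and follow.value == "(":
            out = [self._function(tok)]
        else:
            out = [Member(tok.value)]
        follow = self.peek()
        while follow and follow.kind == "sym" and follow.value == "[":
            self.next()
            num = self.expect("number")
            if "." in num.value:
                raise PathSyntaxError("index must be an integer", num.pos)
            self.expect("sym", "]")
            out.append(Index(int(num.value)))
            follow = self.peek()
        return out

    def _function(self, name_tok: _Token) -> Func:
        name = name_tok.value
        self.expect("sym", "(")
        if name in _NO_ARG_FUNCS:
            self.expect("sym", ")")
            return Func(name)
        if name == "replace":
            first = self._literal()
            self.expect("sym", ",")
            second = self._literal()
            self.expect("sym", ")")
            if not (isinstance(first, str) and isinstance(second, str)):
                raise PathSyntaxError("replace() takes two string literals", name_tok.pos)
            return Func("replace", (first, second))
        if name == "join":
            sep = self._literal()
            self.expect("sym", ")")
            if not isinstance(sep, str):
                raise PathSyntaxError("join() takes a string literal", name_tok.pos)
            return Func("join", (sep,))
        if name == "where":
            member_path = [self.expect("name").value]
            tok = self.peek()
            while tok and tok.kind == "sym" and tok.value == ".":
                self.next()
                member_path.append(self.expect("name").value)
                tok = self.peek()
            self.expect("sym", "=")
            literal = self._literal()
            self.expect("sym", ")")
            return Func("where", (tuple(member_path), literal))
        raise PathSyntaxError(f"unsupported function {name!r}", name_tok.pos)

    def _literal(self) -> Any:
        tok = self.next()
        if tok.kind == "string":
            return _decode_string(tok.value)
        if tok.kind == "number":
            return float(tok.value) if "." in tok.value else int(tok.value)
        raise PathSyntaxError(f"expected a literal, got {tok.value!r}", tok.pos)


@lru_cache(maxsize=4096)
def parse_path(expr: str) -> PathExpression:
    """Parse ``expr`` into a :class:`PathExpression`.

    ``parse_path(p.unparse())`` is a fixpoint: re-parsing the canonical form
    yields an equivalent expression whose canonical form is unchanged.
    """
    if not expr or not expr.strip():
        raise PathSyntaxError("empty expression", 0)
    return _Parser(expr).parse()


# ---------------------------------------------------------------------------
# Evaluator


def _member(coll: list, name: str) -> list:
    out: list = []
    for node in coll:
        if isinstance(node, dict) and name in node:
            value = node[name]
            if isinstance(value, list):
                out.extend(value)  # collection semantics: flatten one level
            elif value is not None:
                out.append(value)
    return out


def _where_matches(node: Any, member_path: tuple[str, ...], literal: Any) -> bool:
    values = [node]
    for name in member_path:
        values = _member(values, name)
    for value in values:
        if isinstance(literal, (int, float)) and isinstance(value, (int, float)):
            if not isinstance(value, bool) and float(value) == float(literal):
                return True
        elif value == literal:
            return True
    return False


def evaluate(path: PathExpression | str, resource: dict) -> list:
    """Evaluate ``path`` against one resource; always returns a flat list.

    Pure and deterministic.  A resource-type qualifier that does not match
    ``resource['resourceType']`` short-circuits to the empty collection, which
    ``exists()``/``empty()``/``count()`` then turn into ``[False]``/``[True]``/
    ``[0]`` respectively.
    """
    if isinstance(path, str):
        path = parse_path(path)
    if not isinstance(resource, dict):
        raise PathTypeError("evaluate() expects a JSON object resource")
    if path.qualifier is not None and resource.get("resourceType") != path.qualifier:
        coll: list = []
    else:
        coll = [resource]
    for seg in path.segments:
        if isinstance(seg, Member):
            coll = _member(coll, seg.name)
        elif isinstance(seg, Index):
            coll = coll[seg.index : seg.index + 1] if seg.index >= 0 else []
        elif isinstance(seg, Func):
            coll = _apply_func(coll, seg)
    return coll


def _apply_func(coll: list, func: Func) -> list:
    if func.name == "exists":
        return [len(coll) > 0]
    if func.name == "empty":
        return [len(coll) == 0]
    if func.name == "count":
        return [len(coll)]
    if func.name == "first":
        return coll[:1]
    if func.name == "where":
        member_path, literal = func.args
        return [node for node in coll if _where_matches(node, member_path, literal)]
    if func.name == "replace":
        old, new = func.args
        _require_strings(coll, "replace")
        return [s.replace(old, new) for s in coll]
    if func.name == "join":
        if not coll:
            return []
        _require_strings(coll, "join")
        return [func.args[0].join(coll)]
    raise PathSyntaxError(f"unsupported function {func.name!r}", 0)


def _require_strings(coll: list, fname: str) -> None:
    for item in coll:
        if not isinstance(item, str):
            raise PathTypeError(
                f"{fname}() requires string values, got {type(item).__name__}"
            )
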