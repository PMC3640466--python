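"""Selection mini-language: parsing and evaluation against entities and views.

The language combines property predicates with Boolean logic::

    aname=CA,CB and rnum=10:20 and not rname=HOH
    5 <> [rname=HEM]            # atoms within 5 Å of any HEM atom
    3.5 <> {1.0, 2.0, 3.0}      # atoms within 3.5 Å of a literal point
    gr:conservation>0.5         # residue-level generic property

Built-in properties: ``aname`` (atom name), ``rname`` (residue name),
``rnum`` (residue number), ``cname`` (chain name), ``ele`` (element),
``occ`` (occupancy), ``abfac`` (isotropic B factor), ``ishetatm``,
``charge``.  Generic properties are addressed with level prefixes
``ga:``/``gr:``/``gc:`` (atom/residue/chain).  Comparison operators are
``= != < <= > >=``; string-valued properties support only ``=``/``!=``.
Comma lists are disjunctions; ``lo:hi`` is an inclusive numeric range.
``not`` binds tighter than ``and``, which binds tighter than ``or``;
parentheses group.  The full grammar ships in ``docs/query-language.md``.

Residue- and chain-level predicates hold for *all atoms* of matching
residues/chains; matching is otherwise a strict atom-set semantics, and
``within`` promotes exactly the matched atoms (no residue promotion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .mol import Atom, Entity, EntityView, SpatialGrid, create_view

__all__ = [
    "QueryError",
    "QuerySyntaxError",
    "parse_query",
    "evaluate",
    "select",
    "Pred",
    "And",
    "Or",
    "Not",
    "Within",
]


class QueryError(Exception):
    """Semantic error in a query (unknown property, type mismatch)."""


class QuerySyntaxError(QueryError):
    """Malformed query text; carries the 1-based column of the error."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pred:
    """(property, op, values); values are strings, numbers, bools or
    (lo, hi) range tuples — a list is an implicit disjunction."""
    prop: str                     # built-in name or "ga:key"/"gr:key"/"gc:key"
    op: str
    values: tuple


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Not:
    operand: "Node"


@dataclass(frozen=True)
class Within:
    radius: float
    reference: Union["Node", tuple]   # sub-AST or literal (x, y, z)


Node = Union[Pred, And, Or, Not, Within]

# property id -> (type, level)
_BUILTINS = {
    "aname": (str, "atom"),
    "rname": (str, "residue"),
    "rnum": (int, "residue"),
    "cname": (str, "chain"),
    "ele": (str, "atom"),
    "occ": (float, "atom"),
    "abfac": (float, "atom"),
    "ishetatm": (bool, "atom"),
    "charge": (float, "atom"),
}

_GENERIC_PREFIXES = ("ga", "gr", "gc")


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_PUNCT = {"(": "LPAREN", ")": "RPAREN", "[": "LBRACK", "]": "RBRACK",
          "{": "LBRACE", "}": "RBRACE", ",": "COMMA", ":": "COLON"}

_WORD_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
                  "0123456789'*_.+")


@dataclass
class _Token:
    kind: str      # OP, WORD or a punctuation kind
    text: str
    col: int       # 1-based start column


def _tokenize(text: str) -> list[_Token]:
    toks: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        col = i + 1
        if text.startswith("<>", i):
            toks.append(_Token("OP", "<>", col))
            i += 2
        elif text.startswith("!=", i) or text.startswith("<=", i) or \
                text.startswith(">=", i):
            toks.append(_Token("OP", text[i:i + 2], col))
            i += 2
        elif c in "=<>":
            toks.append(_Token("OP", c, col))
            i += 1
        elif c in _PUNCT:
            toks.append(_Token(_PUNCT[c], c, col))
            i += 1
        elif c in _WORD_CHARS or (c == "-" and i + 1 < n and
                                  (text[i + 1].isdigit() or text[i + 1] == ".")):
            j = i + 1
            while j < n and text[j] in _WORD_CHARS:
                j += 1
            toks.append(_Token("WORD", text[i:j], col))
            i = j
        else:
            raise QuerySyntaxError(f"unexpected character {c!r}", col)
    toks.append(_Token("EOF", "", n + 1))
    return toks


def _as_number(word: str) -> Optional[float]:
    try:
        return float(word)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Parser (recursive descent, LL(1) with one spot of 2-token lookahead
# to distinguish `5 <> [...]` from a predicate)
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, toks: list[_Token]):
        self.toks = toks
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.toks[self.i]

    def peek(self, k: int = 1) -> _Token:
        return self.toks[min(self.i + k, len(self.toks) - 1)]

    def advance(self) -> _Token:
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        if self.cur.kind != kind:
            raise QuerySyntaxError(f"expected {what}", self.cur.col)
        return self.advance()

    # query := or_expr EOF
    def parse(self) -> Node:
        node = self.or_expr()
        if self.cur.kind != "EOF":
            raise QuerySyntaxError(
                f"unexpected token {self.cur.text!r}", self.cur.col)
        return node

    def or_expr(self) -> Node:
        node = self.and_expr()
        while self.cur.kind == "WORD" and self.cur.text == "or":
            self.advance()
            node = Or(node, self.and_expr())
        return node

    def and_expr(self) -> Node:
        node = self.not_expr()
        while self.cur.kind == "WORD" and self.cur.text == "and":
            self.advance()
            node = And(node, self.not_expr())
        return node

    def not_expr(self) -> Node:
        if self.cur.kind == "WORD" and self.cur.text == "not":
            self.advance()
            return Not(self.not_expr())
        return self.primary()

    def primary(self) -> Node:
        tok = self.cur
        if tok.kind == "LPAREN":
            self.advance()
            node = self.or_expr()
            self.expect("RPAREN", "')'")
            return node
        if tok.kind == "WORD":
            if self.peek().kind == "OP" and self.peek().text == "<>":
                return self.within()
            return self.predicate()
        raise QuerySyntaxError("expected predicate, 'not', '(' or within-clause",
                               tok.col)

    def within(self) -> Within:
        rtok = self.advance()
        radius = _as_number(rtok.text)
        if radius is None:
            raise QuerySyntaxError(f"invalid radius {rtok.text!r}", rtok.col)
        if radius < 0:
            raise QuerySyntaxError("radius must be non-negative", rtok.col)
        self.expect("OP", "'<>'")
        if self.cur.kind == "LBRACK":
            self.advance()
            sub = self.or_expr()
            self.expect("RBRACK", "']'")
            return Within(radius, sub)
        if self.cur.kind == "LBRACE":
            self.advance()
            coords = []
            for k in range(3):
                w = self.expect("WORD", "a coordinate")
                v = _as_number(w.text)
                if v is None:
                    raise QuerySyntaxError(f"invalid coordinate {w.text!r}", w.col)
                coords.append(v)
                if k < 2:
                    self.expect("COMMA", "','")
            self.expect("RBRACE", "'}'")
            return Within(radius, tuple(coords))
        raise QuerySyntaxError("expected '[' subquery or '{' point after '<>'",
                               self.cur.col)

    def predicate(self) -> Pred:
        ptok = self.advance()
        prop = ptok.text
        if prop in _GENERIC_PREFIXES and self.cur.kind == "COLON":
            self.advance()
            key = self.expect("WORD", "generic property key")
            prop = f"{prop}:{key.text}"
            ptype = None
        elif prop in _BUILTINS:
            ptype = _BUILTINS[prop][0]
        else:
            raise QuerySyntaxError(f"unknown property {prop!r}", ptok.col)

        if self.cur.kind != "OP" or self.cur.text == "<>":
            raise QuerySyntaxError("expected comparison operator", self.cur.col)
        op = self.advance().text

        if ptype in (str, bool) and op not in ("=", "!="):
            raise QueryError(
                f"property {prop!r} supports only '='/'!=', not {op!r}")

        values = [self._value(prop, ptype, op)]
        while self.cur.kind == "COMMA":
            self.advance()
            values.append(self._value(prop, ptype, op))
        return Pred(prop, op, tuple(values))

    def _value(self, prop: str, ptype, op: str):
        tok = self.expect("WORD", "a value")
        if ptype is str:
            return tok.text
        if ptype is bool:
            low = tok.text.lower()
            if low in ("true", "1"):
                return True
            if low in ("false", "0"):
                return False
            raise QuerySyntaxError(f"invalid boolean {tok.text!r}", tok.col)
        num = _as_number(tok.text)
        if ptype in (int, float):
            if num is None:
                raise QuerySyntaxError(
                    f"property {prop!r} needs a numeric value, got {tok.text!r}",
                    tok.col)
        if num is not None and self.cur.kind == "COLON":
            if op not in ("=", "!="):
                raise QuerySyntaxError("ranges are only valid with '='/'!='",
                                       self.cur.col)
            self.advance()
            hi_tok = self.expect("WORD", "range upper bound")
            hi = _as_number(hi_tok.text)
            if hi is None:
                raise QuerySyntaxError(f"invalid range bound {hi_tok.text!r}",
                                       hi_tok.col)
            if num > hi:
                raise QuerySyntaxError("range lower bound exceeds upper bound",
                                       hi_tok.col)
            return (num, hi)
        if ptype in (int, float):
            return num
        # generic property: number if it parses, else string
        return tok.text if num is None else num


def parse_query(text: str) -> Node:
    """Parse query text into an AST; pure, needs no entity."""
    return _Parser(_tokenize(text)).parse()


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _atom_prop(atom: Atom, prop: str):
    """Value of a built-in or generic property for one atom; None = absent."""
    if prop == "aname":
        return atom.name
    if prop == "rname":
        return atom.residue.name
    if prop == "rnum":
        return atom.residue.number
    if prop == "cname":
        return atom.residue.chain.name
    if prop == "ele":
        return atom.element
    if prop == "occ":
        return atom.occupancy
    if prop == "abfac":
        return atom.b_factor
    if prop == "ishetatm":
        return atom.is_hetatm
    if prop == "charge":
        return atom.charge
    level, key = prop.split(":", 1)
    holder = {"ga": atom, "gr": atom.residue, "gc": atom.residue.chain}[level]
    return holder.get_prop(key, None)


def _match_pred(atom: Atom, pred: Pred) -> bool:
    actual = _atom_prop(atom, pred.prop)
    if actual is None:
        return False        # absent generic property: no match, no error
    generic = ":" in pred.prop
    for value in pred.values:
        if isinstance(value, tuple):        # inclusive range
            if not isinstance(actual, (int, float)) or isinstance(actual, bool):
                raise QueryError(
                    f"range comparison on non-numeric property {pred.prop!r}")
            inside = value[0] <= actual <= value[1]
            if (inside and pred.op == "=") or (not inside and pred.op == "!="):
                return True
            continue
        if generic:
            if isinstance(value, float):
                if isinstance(actual, bool) or not isinstance(actual, (int, float)):
                    raise QueryError(
                        f"numeric comparison on non-numeric generic property "
                        f"{pred.prop!r}")
            else:
                if not isinstance(actual, str):
                    raise QueryError(
                        f"string comparison on non-string generic property "
                        f"{pred.prop!r}")
                if pred.op not in ("=", "!="):
                    raise QueryError(
                        f"property {pred.prop!r} supports only '='/'!='")
        if _compare(actual, pred.op, value):
            return True
    return False


def _compare(actual, op: str, value) -> bool:
    if op == "=":
        return actual == value
    if op == "!=":
        return actual != value
    if op == "<":
        return actual < value
    if op == "<=":
        return actual <= value
    if op == ">":
        return actual > value
    return actual >= value


def _eval_set(atoms: list[Atom], node: Node,
              ref_atoms: list[Atom]) -> set[int]:
    """Matching atoms (by id) among ``atoms`` for an AST node.

    ``ref_atoms`` is the pool a ``within`` reference sub-query is matched
    against — the full entity, so proximity targets need not themselves be
    part of a chained selection (this keeps selection idempotent).
    """
    if isinstance(node, Pred):
        return {id(a) for a in atoms if _match_pred(a, node)}
    if isinstance(node, And):
        return (_eval_set(atoms, node.left, ref_atoms)
                & _eval_set(atoms, node.right, ref_atoms))
    if isinstance(node, Or):
        return (_eval_set(atoms, node.left, ref_atoms)
                | _eval_set(atoms, node.right, ref_atoms))
    if isinstance(node, Not):
        return {id(a) for a in atoms} - _eval_set(atoms, node.operand, ref_atoms)
    if isinstance(node, Within):
        if isinstance(node.reference, tuple):
            centers = [np.asarray(node.reference, dtype=float)]
        else:
            ref_ids = _eval_set(ref_atoms, node.reference, ref_atoms)
            centers = [a.pos for a in ref_atoms if id(a) in ref_ids]
        if not centers:
            return set()
        grid = SpatialGrid(atoms, node.radius if node.radius > 0 else 1.0)
        matched: set[int] = set()
        for c in centers:
            matched.update(id(a) for a in grid.query(c, node.radius))
        return matched
    raise TypeError(f"not a query AST node: {node!r}")


def evaluate(target, ast: Node) -> EntityView:
    """Evaluate an AST against an entity or view, returning a view.

    On a view, only the view's atoms are candidates (chaining semantics):
    ``evaluate(evaluate(E, q1), q2)`` equals ``evaluate(E, q1 and q2)``.
    ``within`` reference sub-queries are matched against the underlying
    entity, so chained selections stay idempotent.
    """
    if isinstance(target, EntityView):
        atoms = [a.handle for a in target.atoms]
        entity = target.entity
    else:
        atoms = list(target.atoms)
        entity = target
    matched = _eval_set(atoms, ast, list(entity.atoms))
    return create_view(entity, [a for a in atoms if id(a) in matched])


def select(target, text: str) -> EntityView:
    """Convenience composition: ``evaluate(target, parse_query(text))``."""
    return evaluate(target, parse_query(text))
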