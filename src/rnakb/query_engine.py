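"""Class-expression queries over a saturated knowledge graph.

A small Manchester-syntax subset is parsed into an AST and evaluated
under closed-world semantics against the materialized (saturated) graph:

* ``'label'`` or a bare token — a named class;
* ``that`` / ``and`` — conjunction; ``or`` — disjunction;
* ``'prop' some EXPR`` — existential restriction;
* ``'prop' exactly n EXPR`` — qualified cardinality (counted over
  asserted + saturated fillers of exactly that property — in practice
  the non-transitive sub-properties such as 'has proper part', since
  transitive roles may not appear in cardinality restrictions);
* ``inv('prop') some EXPR`` — inverse existential;
* ``{'individual', ...}`` — nominals.

Saturation materializes: sub-property and inverse closures, symmetric
closure ('externally connected to'), transitive closure ('part of' /
'has part') and type subsumption including membership of the
agglomerating sub-edge union classes.  Existential restrictions also
apply the schema's existential axioms as a TBox shortcut, so an
individual asserted only as e.g. a hoogsteen-watson sub-edge is found by
``'part of' some 'hoogsteen edge'`` without any anonymous individual.
For the positive existential fragment used here this reproduces the
answers a description-logic reasoner certifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kb_builder import KBGraph
from .schema import SchemaCatalog, UnresolvedLabelError, load_schema

__all__ = [
    "ClassExpression",
    "NamedClass",
    "And",
    "Or",
    "Some",
    "Exactly",
    "Nominal",
    "QueryResult",
    "QueryParseError",
    "UnsupportedExpressionError",
    "parse_class_expression",
    "saturate",
    "evaluate",
    "TEMPLATES",
    "run_template_query",
]


class QueryParseError(ValueError):
    """Syntax error in a class expression; message carries the position."""


class UnsupportedExpressionError(ValueError):
    """Expression outside the supported fragment."""


# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassExpression:
    pass


@dataclass(frozen=True)
class NamedClass(ClassExpression):
    label: str


@dataclass(frozen=True)
class And(ClassExpression):
    operands: tuple[ClassExpression, ...]


@dataclass(frozen=True)
class Or(ClassExpression):
    operands: tuple[ClassExpression, ...]


@dataclass(frozen=True)
class Some(ClassExpression):
    prop: str
    filler: ClassExpression
    inverse: bool = False


@dataclass(frozen=True)
class Exactly(ClassExpression):
    n: int
    prop: str
    filler: ClassExpression
    inverse: bool = False


@dataclass(frozen=True)
class Nominal(ClassExpression):
    labels: tuple[str, ...]


@dataclass(frozen=True)
class QueryResult:
    individuals: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.individuals)


# --------------------------------------------------------------------------
# tokenizer + recursive-descent parser
# --------------------------------------------------------------------------

_KEYWORDS = {"that", "and", "or", "some", "exactly", "inv"}


@dataclass
class _Token:
    kind: str  # label | bare | int | punct
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "'":
            j = text.find("'", i + 1)
            if j < 0:
                raise QueryParseError(f"unbalanced quote at position {i}")
            tokens.append(_Token("label", text[i + 1:j], i))
            i = j + 1
        elif ch in "(){},":
            tokens.append(_Token("punct", ch, i))
            i += 1
        elif ch.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            tokens.append(_Token("int", text[i:j], i))
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            word = text[i:j]
            tokens.append(_Token("bare", word, i))
            i = j
        else:
            raise QueryParseError(f"unexpected character {ch!r} at position {i}")
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        t = self.peek()
        if t is None:
            raise QueryParseError("unexpected end of expression")
        self.i += 1
        return t

    def _at_keyword(self, word: str) -> bool:
        t = self.peek()
        return t is not None and t.kind == "bare" and t.value == word

    def expect_punct(self, ch: str) -> None:
        t = self.next()
        if t.kind != "punct" or t.value != ch:
            raise QueryParseError(f"expected {ch!r} at position {t.pos}, got {t.value!r}")

    # grammar: or_expr := and_expr (OR and_expr)*
    #          and_expr := restriction ((AND|THAT) restriction)*
    #          restriction := primary [SOME primary | EXACTLY n primary]
    #          primary := label | bare | nominal | ( or_expr ) | inv(label) ...
    def parse(self) -> ClassExpression:
        e = self.or_expr()
        t = self.peek()
        if t is not None:
            raise QueryParseError(f"trailing input at position {t.pos}: {t.value!r}")
        return e

    def or_expr(self) -> ClassExpression:
        parts = [self.and_expr()]
        while self._at_keyword("or"):
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> ClassExpression:
        parts = [self.restriction()]
        while self._at_keyword("and") or self._at_keyword("that"):
            self.next()
            parts.append(self.restriction())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def restriction(self) -> ClassExpression:
        inverse = False
        if self._at_keyword("inv"):
            pos = self.next().pos
            self.expect_punct("(")
            prop_tok = self.next()
            if prop_tok.kind not in ("label", "bare"):
                raise QueryParseError(f"expected property label at position {prop_tok.pos}")
            self.expect_punct(")")
            inverse = True
            prop = prop_tok.value
            return self._restriction_tail(prop, inverse, pos)
        t = self.peek()
        if t is None:
            raise QueryParseError("unexpected end of expression")
        if t.kind in ("label", "bare") and self._lookahead_is_restriction():
            self.next()
            return self._restriction_tail(t.value, False, t.pos)
        return self.primary()

    def _lookahead_is_restriction(self) -> bool:
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
        return nxt is not None and nxt.kind == "bare" and nxt.value in ("some", "exactly")

    def _restriction_tail(self, prop: str, inverse: bool, pos: int) -> ClassExpression:
        t = self.next()
        if t.kind != "bare" or t.value not in ("some", "exactly"):
            raise QueryParseError(f"expected 'some' or 'exactly' at position {t.pos}")
        if t.value == "some":
            return Some(prop=prop, filler=self.primary(), inverse=inverse)
        n_tok = self.next()
        if n_tok.kind != "int":
            raise QueryParseError(f"expected integer after 'exactly' at position {n_tok.pos}")
        return Exactly(n=int(n_tok.value), prop=prop, filler=self.primary(), inverse=inverse)

    def primary(self) -> ClassExpression:
        t = self.next()
        if t.kind == "punct" and t.value == "(":
            e = self.or_expr()
            self.expect_punct(")")
            return e
        if t.kind == "punct" and t.value == "{":
            labels = []
            while True:
                lt = self.next()
                if lt.kind not in ("label", "bare"):
                    raise QueryParseError(f"expected individual label at position {lt.pos}")
                labels.append(lt.value)
                sep = self.next()
                if sep.kind == "punct" and sep.value == "}":
                    break
                if not (sep.kind == "punct" and sep.value == ","):
                    raise QueryParseError(f"expected ',' or '}}' at position {sep.pos}")
            return Nominal(tuple(labels))
        if t.kind in ("label", "bare"):
            if t.kind == "bare" and t.value in _KEYWORDS:
                raise QueryParseError(f"unexpected keyword {t.value!r} at position {t.pos}")
            return NamedClass(t.value)
        raise QueryParseError(f"unexpected token {t.value!r} at position {t.pos}")


def parse_class_expression(text: str) -> ClassExpression:
    """Parse the Manchester-subset text into an AST."""
    tokens = _tokenize(text)
    if not tokens:
        raise QueryParseError("empty expression")
    return _Parser(tokens, text).parse()


# --------------------------------------------------------------------------
# saturation
# --------------------------------------------------------------------------

def saturate(g: KBGraph, schema: SchemaCatalog | None = None) -> KBGraph:
    """Materialize entailed triples and types (idempotent fixed point)."""
    schema = schema or load_schema()
    out = g.copy()
    props = schema.properties

    changed = True
    while changed:
        changed = False
        new = set()
        for (s, p, o) in out.triples:
            pd = props.get(p)
            if pd is None:
                continue
            for q in schema.property_ancestors(p):
                if q != p:
                    new.add((s, q, o))
            if pd.inverse:
                new.add((o, pd.inverse, s))
            if pd.symmetric:
                new.add((o, p, s))
        if not new <= out.triples:
            out.triples |= new
            changed = True
        # transitive closure per transitive property
        for pid, pd in props.items():
            if not pd.transitive:
                continue
            succ: dict[str, set[str]] = {}
            for (s, p, o) in out.triples:
                if p == pid:
                    succ.setdefault(s, set()).add(o)
            add = set()
            for start in succ:
                seen: set[str] = set()
                frontier = list(succ[start])
                while frontier:
                    x = frontier.pop()
                    if x in seen:
                        continue
                    seen.add(x)
                    frontier.extend(succ.get(x, ()))
                for x in seen:
                    if (start, pid, x) not in out.triples:
                        add.add((start, pid, x))
            if add:
                out.triples |= add
                changed = True

    for uri, classes in out.types.items():
        closure: set[str] = set()
        for c in classes:
            if c in schema.classes:
                closure |= schema.superclasses_of(c)
            else:
                closure.add(c)
        out.types[uri] = closure
    return out


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def _named_class_ids(e: ClassExpression, schema: SchemaCatalog, g: KBGraph) -> list[str] | None:
    """Class ids named by e when e is a named class or a union of them."""
    if isinstance(e, NamedClass):
        cid = schema.resolve_label(e.label, g)
        return [cid] if cid in schema.classes else None
    if isinstance(e, Or):
        ids = []
        for part in e.operands:
            sub = _named_class_ids(part, schema, g)
            if sub:
                ids.extend(sub)
        return ids or None
    return None


def evaluate(e: ClassExpression, g: KBGraph, schema: SchemaCatalog | None = None) -> QueryResult:
    """Evaluate a class expression over a saturated graph."""
    schema = schema or load_schema()
    result = _eval(e, g, schema)
    return QueryResult(individuals=tuple(sorted(result)))


def _eval(e: ClassExpression, g: KBGraph, schema: SchemaCatalog) -> set[str]:
    if isinstance(e, NamedClass):
        cid = schema.resolve_label(e.label, g)
        if cid in schema.classes:
            return {uri for uri, classes in g.types.items() if cid in classes}
        # a label resolving to an individual behaves as a singleton nominal
        return {cid}
    if isinstance(e, And):
        sets = [_eval(p, g, schema) for p in e.operands]
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    if isinstance(e, Or):
        out: set[str] = set()
        for p in e.operands:
            out |= _eval(p, g, schema)
        return out
    if isinstance(e, Nominal):
        out = set()
        for label in e.labels:
            uri = schema.resolve_label(label, g)
            out.add(uri)
        return out
    if isinstance(e, Some):
        return _eval_some(e, g, schema)
    if isinstance(e, Exactly):
        pid = _resolve_prop(e.prop, schema)
        filler = _eval(e.filler, g, schema)
        counts: dict[str, int] = {}
        for (s, p, o) in g.triples:
            if p != pid:
                continue
            x, y = (o, s) if e.inverse else (s, o)
            if y in filler:
                counts[x] = counts.get(x, 0) + 1
        if e.n == 0:
            return {uri for uri in g.individuals() if counts.get(uri, 0) == 0}
        return {x for x, c in counts.items() if c == e.n}
    raise UnsupportedExpressionError(f"unsupported expression node {type(e).__name__}")


def _resolve_prop(label: str, schema: SchemaCatalog) -> str:
    pid = schema.resolve_label(label)
    if pid not in schema.properties:
        raise UnresolvedLabelError(label, [])
    return pid


def _eval_some(e: Some, g: KBGraph, schema: SchemaCatalog) -> set[str]:
    pid = _resolve_prop(e.prop, schema)
    filler = _eval(e.filler, g, schema)
    out: set[str] = set()
    for (s, p, o) in g.triples:
        if p != pid:
            continue
        x, y = (o, s) if e.inverse else (s, o)
        if y in filler:
            out.add(x)

    # TBox shortcut via existential axioms (forward direction only)
    relevant = [ax for ax in schema.existential_axioms if ax[1] == pid] if not e.inverse else []
    if relevant:
        named = _named_class_ids(e.filler, schema, g)
        if named is None and not isinstance(e.filler, Nominal):
            raise UnsupportedExpressionError(
                "existential axioms apply to this property but the filler is a "
                "complex expression; use a named class or a union of named classes")
        if named:
            targets = set(named)
            for (sub_cls, _prop, ax_filler) in relevant:
                if schema.superclasses_of(ax_filler) & targets:
                    out |= {uri for uri, cl in g.types.items() if sub_cls in cl}
    return out


# --------------------------------------------------------------------------
# bundled query templates
# --------------------------------------------------------------------------

#: Example question templates (Manchester-subset text); ``{pdb_id}`` is the
#: lowercase PDB identifier.  A and F are intentionally the same template
#: (the same question asked twice).
TEMPLATES: dict[str, str] = {
    "A": "'structure model' that 'is represented by' some "
         "{{'Molecular Structure File PDB:{pdb_id}'}}",
    "B": "'nucleotide base pair' that 'has part' some (('hoogsteen edge' or "
         "'part of' some 'hoogsteen edge') and externally_connected_to some "
         "('nucleotide edge' or 'part of' some 'nucleotide edge'))",
    "C": "'nucleotide base pair' that 'has part' some (('hoogsteen edge' or "
         "'part of' some 'hoogsteen edge') and 'part of' some "
         "'GMP residue [chebi:50324]' and externally_connected_to some "
         "('nucleotide edge' or 'part of' some 'nucleotide edge'))",
    "D": "'nucleotide base pair' that ('has part' some ('watson watson sub edge' "
         "and externally_connected_to some 'hoogsteen hoogsteen sub edge'))",
    "E": "'nucleotide base pair' that 'has part' some (('hoogsteen edge' or "
         "'part of' some 'hoogsteen edge') and externally_connected_to some "
         "('nucleotide edge' or 'part of' some 'nucleotide edge')) and "
         "inv('is about') some ('structure model' that 'is represented by' some "
         "{{'Molecular Structure File PDB:{pdb_id}'}})",
    "F": "'structure model' that 'is represented by' some "
         "{{'Molecular Structure File PDB:{pdb_id}'}}",
}

def run_template_query(which: str, g: KBGraph, schema: SchemaCatalog | None = None,
                       pdb_id: str = "1am0") -> QueryResult:
    """Evaluate one of the bundled templates over a saturated graph."""
    schema = schema or load_schema()
    if which not in TEMPLATES:
        raise KeyError(f"unknown template {which!r}; choose from {sorted(TEMPLATES)}")
    text = TEMPLATES[which].format(pdb_id=pdb_id.lower())
    return evaluate(parse_class_expression(text), g, schema)
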