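"""DL-style class-expression queries over a knowledge base.

Supports the small fragment the competency queries need::

    hasPhenotype some 'parvalbumin (indicator)'
    hasPhenotype some 'somatostatin (indicator)' and
        hasSomaLocatedIn some (neocortex or 'part of' some neocortex)
    (NeuronHuang2017 or NeuronMarkram2015) and hasPhenotype some 'Basket phenotype'
    NeuronEBM and hasPhenotype some 'Martinotti phenotype'

Grammar: identifiers and quoted labels, ``some``, ``and``, ``or``, ``not``,
parentheses, and the partonomy idiom ``'part of' some X`` inside a value
expression.  Names are resolved case-sensitively against term display
labels first, hidden labels second, synonyms third, then curies; ambiguity
is an error rather than a silent pick.

``not`` uses set complement over the neuron universe (closed world at the
query level) while phenotype-level negation stays open world; no
competency query uses ``not``, so the choice affects none of them.

The parser is a hand-written tokenizer + recursive descent — the grammar
is a dozen productions, well under the size where a parser generator pays
for itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional, Union

from .core_model import (
    KnowledgeBase,
    LogicalPhenotype,
    NeuronType,
    Phenotype,
    SOURCE_CLASSES,
    resolve_indicator,
)
from .reasoner import (
    ExpandedBag,
    _matches_positive,
    _pred_closure,
    entails,
    expand,
)

__all__ = [
    "QuerySyntaxError",
    "UnresolvedNameError",
    "AmbiguousNameError",
    "parse_query",
    "evaluate",
    "run_competency_suite",
    "COMPETENCY_QUERIES",
    "CompetencyReport",
]


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"syntax error at position {position}: {message}")
        self.position = position


class UnresolvedNameError(KeyError):
    pass


class AmbiguousNameError(KeyError):
    pass


# -- AST --------------------------------------------------------------------


@dataclass(frozen=True)
class Named:
    name: str


@dataclass(frozen=True)
class Some:
    predicate: str
    value: "ValueExpr"


@dataclass(frozen=True)
class And:
    parts: tuple["QueryExpr", ...]


@dataclass(frozen=True)
class Or:
    parts: tuple["QueryExpr", ...]


@dataclass(frozen=True)
class Not:
    part: "QueryExpr"


@dataclass(frozen=True)
class VTerm:
    name: str


@dataclass(frozen=True)
class VPartOf:
    name: str


@dataclass(frozen=True)
class VOr:
    parts: tuple["ValueExpr", ...]


QueryExpr = Union[Named, Some, And, Or, Not]
ValueExpr = Union[VTerm, VPartOf, VOr]


# -- tokenizer --------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<quoted>'[^']*')|(?P<lpar>\()|(?P<rpar>\))"
    r"|(?P<word>[A-Za-z0-9_:\-\./]+))"
)

_KEYWORDS = {"some", "and", "or", "not"}


@dataclass(frozen=True)
class _Tok:
    kind: str  # 'name' | 'quoted' | '(' | ')' | keyword
    text: str
    pos: int


def _tokenize(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m or m.end() == i:
            rest = text[i:].strip()
            if not rest:
                break
            raise QuerySyntaxError(f"unexpected character {text[i]!r}", i)
        if m.group("quoted"):
            toks.append(_Tok("quoted", m.group("quoted")[1:-1], m.start("quoted")))
        elif m.group("lpar"):
            toks.append(_Tok("(", "(", m.start("lpar")))
        elif m.group("rpar"):
            toks.append(_Tok(")", ")", m.start("rpar")))
        else:
            w = m.group("word")
            kind = w if w in _KEYWORDS else "name"
            toks.append(_Tok(kind, w, m.start("word")))
        i = m.end()
    return toks


# -- parser -----------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self) -> Optional[_Tok]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Tok:
        tok = self.next()
        if tok.kind != kind:
            raise QuerySyntaxError(f"expected {kind!r}, got {tok.text!r}", tok.pos)
        return tok

    # expr := or_expr
    def parse(self) -> QueryExpr:
        expr = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise QuerySyntaxError(f"trailing input {tok.text!r}", tok.pos)
        return expr

    def or_expr(self) -> QueryExpr:
        parts = [self.and_expr()]
        while (tok := self.peek()) and tok.kind == "or":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> QueryExpr:
        parts = [self.unary()]
        while (tok := self.peek()) and tok.kind == "and":
            self.next()
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def unary(self) -> QueryExpr:
        tok = self.peek()
        if tok and tok.kind == "not":
            self.next()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> QueryExpr:
        tok = self.next()
        if tok.kind == "(":
            inner = self.or_expr()
            self.expect(")")
            return inner
        if tok.kind in ("name", "quoted"):
            nxt = self.peek()
            if nxt and nxt.kind == "some":
                self.next()
                return Some(tok.text, self.value_atom())
            return Named(tok.text)
        raise QuerySyntaxError(f"unexpected {tok.text!r}", tok.pos)

    # value-expr := value_or inside parens, else a single value atom
    def value_atom(self) -> ValueExpr:
        tok = self.next()
        if tok.kind == "(":
            parts = [self.value_disjunct()]
            while (t := self.peek()) and t.kind == "or":
                self.next()
                parts.append(self.value_disjunct())
            self.expect(")")
            return parts[0] if len(parts) == 1 else VOr(tuple(parts))
        if tok.kind in ("name", "quoted"):
            return self._maybe_part_of(tok)
        raise QuerySyntaxError(f"unexpected {tok.text!r} in value", tok.pos)

    def value_disjunct(self) -> ValueExpr:
        tok = self.next()
        if tok.kind in ("name", "quoted"):
            return self._maybe_part_of(tok)
        if tok.kind == "(":
            inner = self.value_disjunct()
            self.expect(")")
            return inner
        raise QuerySyntaxError(f"unexpected {tok.text!r} in value", tok.pos)

    def _maybe_part_of(self, tok: _Tok) -> ValueExpr:
        if tok.text == "part of":
            nxt = self.peek()
            if nxt and nxt.kind == "some":
                self.next()
                target = self.next()
                if target.kind not in ("name", "quoted"):
                    raise QuerySyntaxError(
                        f"expected a region after 'part of' some", target.pos
                    )
                return VPartOf(target.text)
        return VTerm(tok.text)


def parse_query(text: str) -> QueryExpr:
    """Parse a DL-style class expression into an AST."""
    return _Parser(text).parse()


# -- name resolution --------------------------------------------------------


def _resolve_value(kb: KnowledgeBase, name: str) -> str:
    """Resolve a quoted label or identifier to a term/indicator curie."""
    hits = [t.curie for t in kb.terms.values() if t.label == name]
    hits += [i.id for i in kb.indicators.values() if i.class_label == name]
    if not hits:
        hits = [t.curie for t in kb.terms.values() if t.hidden_label == name]
        hits += [i.id for i in kb.indicators.values() if i.short_name == name]
    if not hits:
        hits = [t.curie for t in kb.terms.values() if name in t.synonyms]
        hits += [i.id for i in kb.indicators.values() if name in i.known_names()]
    if not hits and (name in kb.terms or name in kb.indicators):
        hits = [name]
    if not hits:
        raise UnresolvedNameError(f"cannot resolve value name {name!r}")
    uniq = sorted(set(hits))
    if len(uniq) > 1:
        raise AmbiguousNameError(
            f"name {name!r} is ambiguous: {', '.join(uniq)}"
        )
    return uniq[0]


def _resolve_predicate(kb: KnowledgeBase, name: str) -> str:
    if name in kb.predicates:
        return name
    raise UnresolvedNameError(f"unknown predicate {name!r}")


# -- evaluation -------------------------------------------------------------


class _Evaluator:
    def __init__(self, kb: KnowledgeBase):
        self.kb = kb
        self.universe = set(kb.neurons)
        self._ebs: dict[str, ExpandedBag] = {}

    def eb(self, nid: str) -> ExpandedBag:
        if nid not in self._ebs:
            self._ebs[nid] = expand(self.kb, self.kb.neurons[nid])
        return self._ebs[nid]

    def eval(self, q: QueryExpr) -> set[str]:
        kb = self.kb
        if isinstance(q, And):
            out = self.universe
            for p in q.parts:
                out = out & self.eval(p)
            return out
        if isinstance(q, Or):
            out: set[str] = set()
            for p in q.parts:
                out |= self.eval(p)
            return out
        if isinstance(q, Not):
            return self.universe - self.eval(q.part)
        if isinstance(q, Named):
            return self.eval_named(q.name)
        if isinstance(q, Some):
            pred = _resolve_predicate(kb, q.predicate)
            return {
                nid
                for nid in self.universe
                if self.match_value(nid, pred, q.value)
            }
        raise TypeError(f"unknown query node {q!r}")

    def eval_named(self, name: str) -> set[str]:
        kb = self.kb
        if name in SOURCE_CLASSES:
            return {
                nid
                for nid in self.universe
                if name in self.eb(nid).source_classes
            }
        target: Optional[NeuronType] = kb.neurons.get(name)
        if target is None:
            hits = [
                n
                for n in kb.neurons.values()
                if n.orig_label == name or name == n.id
            ]
            if len(hits) > 1:
                raise AmbiguousNameError(f"neuron name {name!r} is ambiguous")
            target = hits[0] if hits else None
        if target is None:
            raise UnresolvedNameError(f"unknown class name {name!r}")
        # the named class plus everything that classifies under it
        return {target.id} | {
            nid
            for nid in self.universe
            if nid != target.id
            and entails(
                kb, kb.neurons[nid], target.equivalence_bag, _eb=self.eb(nid)
            )
        }

    def match_value(self, nid: str, pred: str, v: ValueExpr) -> bool:
        kb = self.kb
        if isinstance(v, VOr):
            return any(self.match_value(nid, pred, p) for p in v.parts)
        if isinstance(v, VPartOf):
            region = _resolve_value(kb, v.name)
            eb = self.eb(nid)
            inside = kb.hierarchy.part_descendants(region)
            return any(
                (pred in _pred_closure(kb, p)) and val in inside
                for (p, val) in eb.positives()
            ) or any(
                pred in _pred_closure(kb, upred)
                and all(m in inside for m in members)
                for (upred, members) in eb.union_atoms
            )
        curie = _resolve_value(kb, v.name)
        return _matches_positive(kb, self.eb(nid), pred, curie)


def evaluate(kb: KnowledgeBase, q: Union[QueryExpr, str]) -> list[str]:
    """Evaluate a query; returns matching neuron ids sorted by curie."""
    if isinstance(q, str):
        q = parse_query(q)
    return sorted(_Evaluator(kb).eval(q))


# -- competency suite -------------------------------------------------------

COMPETENCY_QUERIES = {
    "CQ1": "hasPhenotype some 'parvalbumin (indicator)'",
    "CQ2": (
        "hasPhenotype some 'somatostatin (indicator)' and "
        "hasSomaLocatedIn some (neocortex or 'part of' some neocortex)"
    ),
    "CQ3": (
        "(NeuronHuang2017 or NeuronMarkram2015) and "
        "hasPhenotype some 'Basket phenotype'"
    ),
    "CQ4": "NeuronEBM and hasPhenotype some 'Martinotti phenotype'",
}


@dataclass
class CompetencyReport:
    results: dict[str, list[str]]
    counts: dict[str, int]
    cq4_classified: list[str]
    martinotti_cut: Optional[str]

    def summary(self) -> str:
        lines = []
        for name in sorted(self.results):
            ids = self.results[name]
            lines.append(f"{name}\t{len(ids)}\t{','.join(ids)}")
        lines.append(
            "CQ4-classification\t%d\t%s"
            % (len(self.cq4_classified), ",".join(self.cq4_classified))
        )
        return "\n".join(lines)


def _find_martinotti_cut(kb: KnowledgeBase) -> Optional[str]:
    try:
        marti = _resolve_value(kb, "Martinotti phenotype")
    except (UnresolvedNameError, AmbiguousNameError):
        return None
    for nid in sorted(kb.neurons):
        n = kb.neurons[nid]
        if n.is_cut and any(
            isinstance(p, Phenotype) and p.value == marti
            for p in n.equivalence_bag
        ):
            return nid
    return None


def run_competency_suite(kb: KnowledgeBase) -> CompetencyReport:
    """Run CQ1–CQ4.

    CQ4 is answered two ways, mirroring its two phrasings: as the DL query
    over EBTs with a Martinotti phenotype, and as classification under the
    Martinotti CUT (the subclass list from the inferred hierarchy).
    """
    from .reasoner import classify  # local import to avoid cycle at module load

    results: dict[str, list[str]] = {}
    for name, text in COMPETENCY_QUERIES.items():
        try:
            results[name] = evaluate(kb, text)
        except (UnresolvedNameError, AmbiguousNameError):
            results[name] = []
    cut = _find_martinotti_cut(kb)
    classified: list[str] = []
    if cut is not None and kb.neurons:
        hier = classify(kb)
        classified = sorted(hier.subclasses_of(cut))
    return CompetencyReport(
        results=results,
        counts={k: len(v) for k, v in results.items()},
        cq4_classified=classified,
        martinotti_cut=cut,
    )
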