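"""Deterministic Turtle serialization of a knowledge base, and a reader
for the same dialect.

The writer emits a fixed axiom pattern so that identical canonical KBs
produce byte-identical documents (stable prefix block, subjects sorted by
curie, fixed predicate order, 2-space indentation):

* each neuron class is an ``owl:Class`` whose ``owl:equivalentClass`` is
  the intersection of existential restrictions over the canonical bag;
  negative phenotypes become ``owl:complementOf`` a restriction;
* ``subclass_phenotypes`` are plain ``rdfs:subClassOf`` restrictions;
* entailed negatives are *annotated* subclass axioms (``owl:Axiom``
  reification carrying ``ilxtr:axiomKind "entailed-negative"``) — they are
  bookkeeping entailments, not defining restrictions;
* generated names ride along as annotation properties: ``rdfs:label``
  (normalized), ``skos:prefLabel``, and custom ``ilxtr:localLabel`` /
  ``ilxtr:origLabel`` properties; indicators carry their short name as
  ``skos:hiddenLabel``;
* the ontology header records provenance as a ``prov:wasGeneratedBy``
  string: tool id plus the SHA-256 of the canonical KB content.

The reader inverts the writer (``read_kb(write_kb(kb))`` is
canonical-identity); ``lax=True`` additionally maps common equivalents
(alternate label properties, part-of as an existential restriction) onto
the dialect for best-effort import of external files.  Unknown axiom
shapes are collected into a warnings list, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from . import __version__
from .core_model import (
    DisjointnessAxiom,
    KnowledgeBase,
    LogicalPhenotype,
    NeuronType,
    OntTerm,
    Phenotype,
    PhenotypeBearer,
    PhenotypeIndicator,
    PredicateDef,
    SOURCE_CLASSES,
    canonical_bag,
    validate,
)
from .naming import label_set

__all__ = ["TtlDocument", "ReadResult", "ParseError", "DialectError",
           "write_kb", "read_kb"]

BASE = "http://phenoneuron.example.org/"

PREFIXES = {
    "fix": BASE + "fix/",
    "ilxtr": "http://uri.interlex.org/tgbugs/uris/readable/",
    "nifext": "http://uri.neuinfo.org/nif/nifstd/nifext_",
    "npokb": "http://uri.neuinfo.org/nif/nifstd/npokb/",
    "owl": str(OWL),
    "prov": "http://www.w3.org/ns/prov#",
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "skos": str(SKOS),
}

ONTOLOGY_IRI = BASE + "ontology/kb"
_ILXTR = PREFIXES["ilxtr"]
_PROV = PREFIXES["prov"]

_ANNOTATIONS = ("localLabel", "origLabel", "sourceTag", "dimension",
                "indicatorName", "synonym", "partOf", "axiomKind",
                "provenance")

_LAX_LABELS = [
    str(SKOS.prefLabel),
    "http://www.w3.org/2004/02/skos/core#altLabel",
    "http://purl.obolibrary.org/obo/IAO_0000111",
]
_LAX_PARTOF = {
    "http://purl.obolibrary.org/obo/BFO_0000050",
    _ILXTR + "partOf",
    "http://purl.org/sig/ont/fma/part_of",
}


class ParseError(ValueError):
    pass


class DialectError(ValueError):
    pass


@dataclass(frozen=True)
class TtlDocument:
    text: str

    def __str__(self) -> str:
        return self.text


@dataclass
class ReadResult:
    kb: KnowledgeBase
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _esc(s: str) -> str:
    return (
        s.replace("\\", "\\\\").replace('"', '\\"')
        .replace("\n", "\\n").replace("\r", "\\r")
    )


def _lit(s: str) -> str:
    return f'"{_esc(s)}"'


def _pred_curie(pid: str) -> str:
    return f"ilxtr:{pid}"


def _collect_prefixes(kb: KnowledgeBase) -> dict[str, str]:
    used = {"owl", "rdf", "rdfs", "skos", "prov", "ilxtr"}
    for curie in list(kb.terms) + list(kb.indicators) + list(kb.neurons):
        used.add(curie.split(":", 1)[0])
    out = {}
    for p in sorted(used):
        out[p] = PREFIXES.get(p, f"{BASE}curie/{p}/")
    return out


def _restriction(p: PhenotypeBearer, indent: str) -> str:
    pred = _pred_curie(p.predicate)
    if isinstance(p, LogicalPhenotype):
        members = " ".join(p.members)
        filler = (
            f"[ a owl:Class ; owl:{p.operator} ( {members} ) ]"
        )
        return (
            f"[ a owl:Restriction ; owl:onProperty {pred} ; "
            f"owl:someValuesFrom {filler} ]"
        )
    core = (
        f"[ a owl:Restriction ; owl:onProperty {pred} ; "
        f"owl:someValuesFrom {p.value} ]"
    )
    if p.negative:
        return f"[ a owl:Class ; owl:complementOf {core} ]"
    return core


def write_kb(kb: KnowledgeBase, tool_id: str = "phenoneuron") -> TtlDocument:
    """Serialize a valid KB; raises ``ValueError`` when validation fails."""
    violations = validate(kb)
    if violations:
        lines = "; ".join(f"{v.subject}: {v.message}" for v in violations[:5])
        raise ValueError(f"cannot serialize invalid KB: {lines}")

    out: list[str] = []
    prefixes = _collect_prefixes(kb)
    for p, uri in sorted(prefixes.items()):
        out.append(f"@prefix {p}: <{uri}> .")
    out.append("")

    gen = f"{tool_id} {__version__} sha256:{kb.content_hash()}"
    out.append(f"<{ONTOLOGY_IRI}> a owl:Ontology ;")
    out.append(f"  prov:wasGeneratedBy {_lit(gen)} .")
    out.append("")

    empty = not (kb.terms or kb.predicates or kb.indicators or kb.neurons)
    if empty:
        return TtlDocument("\n".join(out) + "\n")

    for ann in sorted(set(_ANNOTATIONS)):
        out.append(f"ilxtr:{ann} a owl:AnnotationProperty .")
    out.append("")

    # source-class scaffolding used by any neuron in the KB
    used_sources = sorted(
        {n.source_class for n in kb.neurons.values() if n.source_class}
    )
    if used_sources:
        scaffold = sorted(set(used_sources) | {"NeuronEBM"}
                          if any(s not in ("NeuronCUT", "NeuronEBM")
                                 for s in used_sources)
                          else set(used_sources))
        for sc in scaffold:
            line = f"ilxtr:{sc} a owl:Class ; rdfs:label {_lit(sc)}"
            if sc not in ("NeuronCUT", "NeuronEBM"):
                line += " ; rdfs:subClassOf ilxtr:NeuronEBM"
            out.append(line + " .")
        out.append("")

    for pid in sorted(kb.predicates):
        pr = kb.predicates[pid]
        lines = [f"{_pred_curie(pid)} a owl:ObjectProperty"]
        if pr.parent:
            lines.append(f"  rdfs:subPropertyOf {_pred_curie(pr.parent)}")
        if pr.dimension:
            lines.append(f"  ilxtr:dimension {_lit(pr.dimension)}")
        out.append(" ;\n".join(lines) + " .")
    out.append("")

    subtype_up: dict[str, list[str]] = {}
    for sub, sup in kb.hierarchy.subtype_edges:
        subtype_up.setdefault(sub, []).append(sup)
    partof_up: dict[str, list[str]] = {}
    for child, parent in kb.hierarchy.part_of_edges:
        partof_up.setdefault(child, []).append(parent)

    for curie in sorted(kb.terms):
        t = kb.terms[curie]
        lines = [f"{curie} a owl:Class", f"  rdfs:label {_lit(t.label)}"]
        if t.hidden_label:
            lines.append(f"  skos:hiddenLabel {_lit(t.hidden_label)}")
        for syn in sorted(t.synonyms):
            lines.append(f"  ilxtr:synonym {_lit(syn)}")
        for sup in sorted(subtype_up.get(curie, ())):
            lines.append(f"  rdfs:subClassOf {sup}")
        for parent in sorted(partof_up.get(curie, ())):
            lines.append(f"  ilxtr:partOf {parent}")
        out.append(" ;\n".join(lines) + " .")
    out.append("")

    for iid in sorted(kb.indicators):
        ind = kb.indicators[iid]
        lines = [
            f"{iid} a owl:Class",
            f"  rdfs:label {_lit(ind.class_label)}",
            f"  skos:hiddenLabel {_lit(ind.short_name)}",
        ]
        if ind.name:
            lines.append(f"  ilxtr:indicatorName {_lit(ind.name)}")
        members = " ".join(sorted(ind.members))
        lines.append(
            "  owl:equivalentClass [ a owl:Class ; "
            f"owl:unionOf ( {members} ) ]"
        )
        out.append(" ;\n".join(lines) + " .")
    out.append("")

    axiom_blocks: list[str] = []
    for nid in sorted(kb.neurons):
        n = kb.neurons[nid]
        labels = label_set(kb, n)
        lines = [f"{nid} a owl:Class"]
        if n.source_class:
            lines.append(f"  rdfs:subClassOf ilxtr:{n.source_class}")
        eq = canonical_bag(n, kb, include_subclass=False,
                           include_entailed=False)
        restrictions = "\n".join(
            f"      {_restriction(p, '      ')}" for p in eq
        )
        lines.append(
            "  owl:equivalentClass [ a owl:Class ;\n"
            "    owl:intersectionOf (\n"
            f"{restrictions}\n"
            "    ) ]"
        )
        sub = [p for p in canonical_bag(n, kb, include_entailed=False)
               if p in n.subclass_phenotypes]
        for p in sub:
            lines.append(f"  rdfs:subClassOf {_restriction(p, '  ')}")
        lines.append(f"  rdfs:label {_lit(labels.normalized)}")
        lines.append(f"  skos:prefLabel {_lit(labels.pref)}")
        lines.append(f"  ilxtr:localLabel {_lit(labels.local)}")
        if labels.orig:
            lines.append(f"  ilxtr:origLabel {_lit(labels.orig)}")
        if n.source_tag:
            lines.append(f"  ilxtr:sourceTag {_lit(n.source_tag)}")
        out.append(" ;\n".join(lines) + " .")

        ent = [p for p in canonical_bag(n, kb, include_subclass=False)
               if p in n.entailed_negatives]
        for p in ent:
            axiom_blocks.append(
                "[] a owl:Axiom ;\n"
                f"  owl:annotatedSource {nid} ;\n"
                "  owl:annotatedProperty rdfs:subClassOf ;\n"
                f"  owl:annotatedTarget {_restriction(p, '  ')} ;\n"
                f"  ilxtr:axiomKind {_lit('entailed-negative')} ."
            )
    out.append("")
    out.extend(axiom_blocks)
    if axiom_blocks:
        out.append("")

    for ax in sorted(kb.disjointness, key=lambda a: sorted(a.terms)):
        members = " ".join(sorted(ax.terms, key=_disjoint_key(kb)))
        block = (
            "[] a owl:AllDisjointClasses ;\n"
            f"  owl:members ( {members} )"
        )
        if ax.provenance:
            block += f" ;\n  ilxtr:provenance {_lit(ax.provenance)}"
        out.append(block + " .")

    text = "\n".join(out).rstrip("\n") + "\n"
    return TtlDocument(text)


def _disjoint_key(kb: KnowledgeBase):
    def key(t: str) -> str:
        return f"ilxtr:{t}" if t in SOURCE_CLASSES and ":" not in t else t
    return key


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _uri_to_curie(uri: str, prefixes: dict[str, str],
                  warnings: list[str]) -> str:
    best_p, best_ns = None, ""
    for p, ns in prefixes.items():
        if uri.startswith(ns) and len(ns) > len(best_ns):
            best_p, best_ns = p, ns
    if best_p is None:
        local = uri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
        msg = f"no prefix for <{uri}>; using ext:{local}"
        if msg not in warnings:
            warnings.append(msg)
        return f"ext:{local}"
    return f"{best_p}:{uri[len(best_ns):]}"


def read_kb(doc, lax: bool = False) -> ReadResult:
    """Parse a Turtle document in the writer's dialect back into a KB.

    Accepts a ``TtlDocument`` or a string of Turtle text.  Raises
    ``ParseError`` for malformed Turtle and ``DialectError`` for
    constructs the strict dialect forbids; with ``lax=True`` out-of-dialect
    constructs become warnings instead.
    """
    text = doc.text if isinstance(doc, TtlDocument) else str(doc)
    g = Graph()
    try:
        g.parse(data=text, format="turtle")
    except Exception as e:  # rdflib raises several parser exception types
        raise ParseError(f"turtle parse error: {e}") from None

    warnings: list[str] = []
    prefixes = dict(PREFIXES)
    for p, ns in g.namespaces():
        prefixes.setdefault(str(p), str(ns))

    def curie(u) -> str:
        return _uri_to_curie(str(u), prefixes, warnings)

    def local(u) -> str:
        c = curie(u)
        return c.split(":", 1)[1]

    kb = KnowledgeBase()

    for s in g.subjects(RDF.type, OWL.Ontology):
        for o in g.objects(s, URIRef(_PROV + "wasGeneratedBy")):
            kb.metadata["generated_by"] = str(o)

    # predicates
    for s in sorted(g.subjects(RDF.type, OWL.ObjectProperty)):
        pid = local(s)
        parent = None
        for o in g.objects(s, RDFS.subPropertyOf):
            parent = local(o)
        dim = None
        for o in g.objects(s, URIRef(_ILXTR + "dimension")):
            dim = str(o)
        try:
            kb.add_predicate(PredicateDef(pid, dim, parent))
        except ValueError as e:
            if lax:
                warnings.append(f"skipping predicate {pid}: {e}")
            else:
                raise DialectError(str(e)) from None

    def get_label(s) -> str | None:
        for o in g.objects(s, RDFS.label):
            return str(o)
        if lax:
            for lp in _LAX_LABELS:
                for o in g.objects(s, URIRef(lp)):
                    return str(o)
        return None

    def phenotype_from(node, polarity="positive") -> PhenotypeBearer:
        comp = list(g.objects(node, OWL.complementOf))
        if comp:
            inner = phenotype_from(comp[0])
            if not isinstance(inner, Phenotype):
                raise DialectError(
                    "complement of a logical phenotype is not supported"
                )
            return Phenotype(inner.predicate, inner.value, "negative")
        props = list(g.objects(node, OWL.onProperty))
        fillers = list(g.objects(node, OWL.someValuesFrom))
        if not props or not fillers:
            raise DialectError("restriction without onProperty/someValuesFrom")
        pred = local(props[0])
        filler = fillers[0]
        if isinstance(filler, BNode):
            for op in ("intersectionOf", "unionOf"):
                lst = list(g.objects(filler, OWL[op]))
                if lst:
                    members = tuple(
                        curie(m) for m in Collection(g, lst[0])
                    )
                    return LogicalPhenotype(op, pred, members)
            raise DialectError("unsupported someValuesFrom filler")
        return Phenotype(pred, curie(filler), polarity)

    # classify named owl:Class subjects
    neurons_raw = []
    for s in sorted(set(g.subjects(RDF.type, OWL.Class))):
        if isinstance(s, BNode):
            continue
        c = curie(s)
        if c.split(":", 1)[-1] in SOURCE_CLASSES or c.split(":", 1)[-1] in (
            "Neuron",
        ):
            continue
        eq_nodes = [o for o in g.objects(s, OWL.equivalentClass)]
        inter = union = None
        for node in eq_nodes:
            if isinstance(node, BNode):
                i = list(g.objects(node, OWL.intersectionOf))
                u = list(g.objects(node, OWL.unionOf))
                if i:
                    inter = i[0]
                if u:
                    union = u[0]
        label = get_label(s)
        if union is not None and label and label.endswith(" (indicator)"):
            short = None
            for o in g.objects(s, SKOS.hiddenLabel):
                short = str(o)
            name = None
            for o in g.objects(s, URIRef(_ILXTR + "indicatorName")):
                name = str(o)
            members = frozenset(curie(m) for m in Collection(g, union))
            kb.add_indicator(PhenotypeIndicator(
                c, short or label[: -len(" (indicator)")], members, name=name
            ))
        elif inter is not None:
            neurons_raw.append((s, c, inter))
        else:
            hidden = None
            for o in g.objects(s, SKOS.hiddenLabel):
                hidden = str(o)
            syns = tuple(sorted(
                str(o) for o in g.objects(s, URIRef(_ILXTR + "synonym"))
            ))
            if label is None:
                warnings.append(f"class {c} has no label; skipped")
                continue
            kb.add_term(OntTerm(c, label, hidden, syns))
            for o in g.objects(s, RDFS.subClassOf):
                if isinstance(o, URIRef):
                    oc = curie(o)
                    if oc.split(":", 1)[-1] not in SOURCE_CLASSES:
                        kb.hierarchy.add_subtype(c, oc)
            for o in g.objects(s, URIRef(_ILXTR + "partOf")):
                kb.hierarchy.add_part_of(c, curie(o))
            if lax:
                for o in g.objects(s, RDFS.subClassOf):
                    if isinstance(o, BNode):
                        props = [str(x) for x in g.objects(o, OWL.onProperty)]
                        if props and props[0] in _LAX_PARTOF:
                            for f in g.objects(o, OWL.someValuesFrom):
                                if isinstance(f, URIRef):
                                    kb.hierarchy.add_part_of(c, curie(f))

    # entailed-negative axioms, grouped by source neuron
    entailed: dict[str, list[Phenotype]] = {}
    for ax in g.subjects(RDF.type, OWL.Axiom):
        kinds = [str(o) for o in g.objects(ax, URIRef(_ILXTR + "axiomKind"))]
        srcs = list(g.objects(ax, OWL.annotatedSource))
        tgts = list(g.objects(ax, OWL.annotatedTarget))
        if "entailed-negative" in kinds and srcs and tgts:
            ph = phenotype_from(tgts[0])
            entailed.setdefault(curie(srcs[0]), []).append(ph)
        else:
            warnings.append("unrecognized owl:Axiom annotation; ignored")

    for s, c, inter in neurons_raw:
        bag: list[PhenotypeBearer] = []
        for item in Collection(g, inter):
            if isinstance(item, URIRef):
                ic = curie(item)
                if ic.split(":", 1)[-1] in SOURCE_CLASSES + ("Neuron",):
                    continue
                if lax:
                    warnings.append(
                        f"neuron {c}: named conjunct {ic} ignored"
                    )
                    continue
                raise DialectError(
                    f"neuron {c}: named class {ic} inside intersection"
                )
            bag.append(phenotype_from(item))
        source = None
        subclass: list[PhenotypeBearer] = []
        for o in g.objects(s, RDFS.subClassOf):
            if isinstance(o, URIRef):
                name = curie(o).split(":", 1)[-1]
                if name in SOURCE_CLASSES:
                    source = name
                else:
                    warnings.append(
                        f"neuron {c}: unexpected named parent {curie(o)}"
                    )
            else:
                if lax:
                    props = [str(x) for x in g.objects(o, OWL.onProperty)]
                    if props and props[0] in _LAX_PARTOF:
                        continue
                try:
                    subclass.append(phenotype_from(o))
                except DialectError as e:
                    if lax:
                        warnings.append(f"neuron {c}: {e}")
                    else:
                        raise
        orig = None
        for o in g.objects(s, URIRef(_ILXTR + "origLabel")):
            orig = str(o)
        tag = None
        for o in g.objects(s, URIRef(_ILXTR + "sourceTag")):
            tag = str(o)
        neg = entailed.get(c, [])
        kb.neurons[c] = NeuronType(
            id=c,
            equivalence_bag=frozenset(bag),
            source_class=source,
            subclass_phenotypes=frozenset(subclass),
            entailed_negatives=frozenset(neg),
            orig_label=orig,
            source_tag=tag,
        )

    for ax in g.subjects(RDF.type, OWL.AllDisjointClasses):
        lst = list(g.objects(ax, OWL.members))
        if not lst:
            warnings.append("AllDisjointClasses without owl:members; ignored")
            continue
        terms = frozenset(
            curie(m).split(":", 1)[-1]
            if curie(m).split(":", 1)[-1] in SOURCE_CLASSES
            and curie(m).startswith("ilxtr:")
            else curie(m)
            for m in Collection(g, lst[0])
        )
        prov = ""
        for o in g.objects(ax, URIRef(_ILXTR + "provenance")):
            prov = str(o)
        kb.disjointness.append(DisjointnessAxiom(terms, prov))

    return ReadResult(kb=kb, warnings=warnings)
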