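"""Human-editable structured document format for a knowledge base.

One YAML (or JSON — YAML is a superset) document per KB, with sections
``terms``, ``predicates``, ``indicators``, ``neurons``, ``part_of``,
``subtypes``, ``disjoint``.  Each neuron is::

    id: npokb:112
    source: NeuronMarkram2015        # optional
    orig_label: Nest basket cell     # optional
    source_tag: Markram2015          # optional
    equivalent:
      - [hasSomaLocatedIn, ilxtr:S1, positive]
      - {op: intersectionOf, predicate: hasElectrophysiologicalPhenotype,
         members: [ilxtr:petilla-AC, ilxtr:petilla-b]}
    subclass: []                     # optional, same entry shapes
    entailed_negative:               # optional, atomic negatives only
      - [hasExpressionPhenotype, ilxtr:SST, negative]

Dumping is deterministic (sorted sections and keys), so a loaded-and-
redumped document is stable.
"""

from __future__ import annotations

from typing import Any

import yaml

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
    add_neuron,
)

__all__ = ["load_kb", "loads_kb", "dump_kb", "dumps_kb"]


def _phenotype_to_obj(p: PhenotypeBearer) -> Any:
    if isinstance(p, Phenotype):
        return [p.predicate, p.value, p.polarity]
    return {
        "op": p.operator,
        "predicate": p.predicate,
        "members": list(p.members),
    }


def _phenotype_from_obj(obj: Any) -> PhenotypeBearer:
    if isinstance(obj, dict):
        return LogicalPhenotype(
            obj["op"], obj["predicate"], tuple(obj["members"])
        )
    if isinstance(obj, (list, tuple)):
        if len(obj) == 2:
            pred, value = obj
            return Phenotype(pred, value, "positive")
        pred, value, polarity = obj
        # reader accepts both ASCII hyphen and unicode minus spellings
        polarity = {"-": "negative", "−": "negative",
                    "+": "positive"}.get(polarity, polarity)
        return Phenotype(pred, value, polarity)
    raise ValueError(f"bad phenotype entry: {obj!r}")


def loads_kb(text: str) -> KnowledgeBase:
    doc = yaml.safe_load(text) or {}
    kb = KnowledgeBase()
    for k, v in (doc.get("meta") or {}).items():
        kb.metadata[str(k)] = str(v)
    for row in doc.get("predicates") or []:
        kb.add_predicate(PredicateDef(
            row["id"], row.get("dimension"), row.get("parent")
        ))
    for row in doc.get("terms") or []:
        kb.add_term(OntTerm(
            row["id"], row["label"], row.get("hidden"),
            tuple(row.get("synonyms") or ()),
        ))
    for row in doc.get("indicators") or []:
        kb.add_indicator(PhenotypeIndicator(
            row["id"], row["short_name"], frozenset(row["members"]),
            name=row.get("name"),
        ))
    for child, parent in doc.get("part_of") or []:
        kb.hierarchy.add_part_of(child, parent)
    for sub, sup in doc.get("subtypes") or []:
        kb.hierarchy.add_subtype(sub, sup)
    for row in doc.get("neurons") or []:
        n = NeuronType(
            id=row["id"],
            equivalence_bag=frozenset(
                _phenotype_from_obj(o) for o in row.get("equivalent") or []
            ),
            source_class=row.get("source"),
            subclass_phenotypes=frozenset(
                _phenotype_from_obj(o) for o in row.get("subclass") or []
            ),
            entailed_negatives=frozenset(
                _phenotype_from_obj(o)
                for o in row.get("entailed_negative") or []
            ),
            orig_label=row.get("orig_label"),
            source_tag=row.get("source_tag"),
        )
        add_neuron(kb, n)
    for row in doc.get("disjoint") or []:
        kb.disjointness.append(DisjointnessAxiom(
            frozenset(row["terms"]), row.get("provenance", "")
        ))
    return kb


def load_kb(path: str) -> KnowledgeBase:
    with open(path, "r", encoding="utf-8") as f:
        return loads_kb(f.read())


def dumps_kb(kb: KnowledgeBase) -> str:
    doc: dict[str, Any] = {}
    if kb.metadata:
        doc["meta"] = dict(sorted(kb.metadata.items()))
    doc["predicates"] = [
        {
            "id": p.id,
            **({"parent": p.parent} if p.parent else {}),
            **({"dimension": p.dimension} if p.dimension else {}),
        }
        for p in (kb.predicates[i] for i in sorted(kb.predicates))
    ]
    doc["terms"] = [
        {
            "id": t.curie,
            "label": t.label,
            **({"hidden": t.hidden_label} if t.hidden_label else {}),
            **({"synonyms": sorted(t.synonyms)} if t.synonyms else {}),
        }
        for t in (kb.terms[c] for c in sorted(kb.terms))
    ]
    doc["indicators"] = [
        {
            "id": i.id,
            "short_name": i.short_name,
            **({"name": i.name} if i.name else {}),
            "members": sorted(i.members),
        }
        for i in (kb.indicators[c] for c in sorted(kb.indicators))
    ]
    doc["neurons"] = []
    for nid in sorted(kb.neurons):
        n = kb.neurons[nid]
        row: dict[str, Any] = {"id": n.id}
        if n.source_class:
            row["source"] = n.source_class
        if n.orig_label:
            row["orig_label"] = n.orig_label
        if n.source_tag:
            row["source_tag"] = n.source_tag
        row["equivalent"] = [
            _phenotype_to_obj(p)
            for p in sorted(n.equivalence_bag, key=repr)
        ]
        if n.subclass_phenotypes:
            row["subclass"] = [
                _phenotype_to_obj(p)
                for p in sorted(n.subclass_phenotypes, key=repr)
            ]
        if n.entailed_negatives:
            row["entailed_negative"] = [
                _phenotype_to_obj(p)
                for p in sorted(n.entailed_negatives, key=repr)
            ]
        doc["neurons"].append(row)
    doc["part_of"] = [list(e) for e in sorted(kb.hierarchy.part_of_edges)]
    doc["subtypes"] = [list(e) for e in sorted(kb.hierarchy.subtype_edges)]
    doc["disjoint"] = [
        {
            "terms": sorted(ax.terms),
            **({"provenance": ax.provenance} if ax.provenance else {}),
        }
        for ax in sorted(kb.disjointness, key=lambda a: sorted(a.terms))
    ]
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True,
                          default_flow_style=None)


def dump_kb(kb: KnowledgeBase, path: str) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write(dumps_kb(kb))
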