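"""EL-style bag expansion and subsumption classification.

The reasoning fragment is deliberately small — existential restrictions,
conjunction, value/predicate hierarchies, asserted negation, and
disjointness *checks* — which is exactly what classifying bag-of-phenotype
neuron types needs.  A neuron's asserted bag is closed under three
monotone expansion rules:

R1 (indicator normalization)
    a positive molecular atom whose value belongs to a phenotype indicator
    also holds with the indicator itself as value, so a query or CUT
    condition phrased against the indicator matches regardless of whether a
    gene, protein, or transgenic line was measured;
R2 (partonomy)
    a soma/axon location in a region entails location in every region the
    part-of closure reaches (soma in S1 -> soma in neocortex);
R3 (hierarchy generalization)
    subtype edges over values (nest basket -> basket phenotype) and parent
    edges over predicates (hasExpressionPhenotype -> hasMolecularPhenotype
    -> hasPhenotype) add the generalized atoms.

Negative atoms are never expanded: under the open-world reading a missing
assertion says nothing, and generalizing a negation would be unsound
("no parvalbumin protein" does not imply "no parvalbumin evidence at all").

Classification then reduces to set containment between expanded bags:
neuron *n* classifies under class *m* iff every necessary-and-sufficient
condition of *m* is entailed by *n*'s expanded bag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .core_model import (
    EBT_SOURCE_CLASSES,
    KnowledgeBase,
    LogicalPhenotype,
    NeuronType,
    Phenotype,
    PhenotypeBearer,
    Violation,
    resolve_indicator,
)

__all__ = [
    "ExpandedBag",
    "InferredHierarchy",
    "expand",
    "entails",
    "classify",
    "check_consistency",
]

_LOCATION_PREDICATES = ("hasSomaLocatedIn", "hasAxonLocatedIn")


@dataclass(frozen=True)
class ExpandedBag:
    """Closure of a neuron's asserted bag.

    ``atoms`` — positive and (unexpanded) negative (predicate, value,
    polarity) triples; ``union_atoms`` — asserted disjunctions kept intact,
    as (predicate, member-tuple); ``source_classes`` — source-class
    memberships including the implied NeuronEBM for per-project tags.
    """

    atoms: frozenset[tuple[str, str, str]]
    union_atoms: frozenset[tuple[str, tuple[str, ...]]]
    source_classes: frozenset[str]

    def positives(self) -> set[tuple[str, str]]:
        return {(p, v) for (p, v, pol) in self.atoms if pol == "positive"}

    def negatives(self) -> set[tuple[str, str]]:
        return {(p, v) for (p, v, pol) in self.atoms if pol == "negative"}


def _value_closure(kb: KnowledgeBase, pred: str, value: str) -> set[str]:
    """All values entailed by a positive atom's value: the value itself,
    its indicator (R1), partonomy ancestors for location predicates (R2),
    and subtype supertypes (R3), iterated to fixpoint."""
    out = {value}
    frontier = {value}
    is_location = pred in _LOCATION_PREDICATES
    while frontier:
        nxt: set[str] = set()
        for v in frontier:
            ind = resolve_indicator(kb, v)
            if ind is not None and ind != v:
                nxt.add(ind)
            if is_location:
                nxt |= kb.hierarchy.part_ancestors(v)
            nxt |= kb.hierarchy.supertypes(v)
        frontier = nxt - out
        out |= nxt
    return out


def _pred_closure(kb: KnowledgeBase, pred: str) -> set[str]:
    return {pred} | kb.predicate_ancestors(pred)


def expand(kb: KnowledgeBase, n: NeuronType) -> ExpandedBag:
    """Close a neuron's bag under R1–R3.

    Idempotent: expanding an already-expanded atom set adds nothing, since
    every rule is applied to fixpoint.  Raises a cycle error (from the
    hierarchy closure) if the part-of or subtype relation is cyclic.
    """
    atoms: set[tuple[str, str, str]] = set()
    unions: set[tuple[str, tuple[str, ...]]] = set()

    def add_positive(pred: str, value: str) -> None:
        preds = _pred_closure(kb, pred)
        values = _value_closure(kb, pred, value)
        for p in preds:
            for v in values:
                atoms.add((p, v, "positive"))

    for ph in n.all_phenotypes():
        if isinstance(ph, LogicalPhenotype):
            if ph.operator == "intersectionOf":
                # a conjunction asserts every member
                for m in ph.members:
                    add_positive(ph.predicate, m)
            else:
                unions.add((ph.predicate, ph.members))
                # whatever holds of every disjunct holds outright
                common: Optional[set[str]] = None
                for m in ph.members:
                    vc = _value_closure(kb, ph.predicate, m)
                    common = vc if common is None else (common & vc)
                for v in common or ():
                    add_positive(ph.predicate, v)
        elif ph.negative:
            atoms.add((ph.predicate, ph.value, "negative"))
        else:
            add_positive(ph.predicate, ph.value)

    sources: set[str] = set()
    if n.source_class:
        sources.add(n.source_class)
        if n.source_class in EBT_SOURCE_CLASSES:
            sources.add("NeuronEBM")
    return ExpandedBag(
        atoms=frozenset(atoms),
        union_atoms=frozenset(unions),
        source_classes=frozenset(sources),
    )


def _matches_positive(
    kb: KnowledgeBase, eb: ExpandedBag, pred: str, value: str
) -> bool:
    """Does the expanded bag entail 'pred some value' positively?"""
    if (pred, value, "positive") in eb.atoms:
        return True
    # an asserted disjunction entails the condition if every disjunct does
    for upred, members in eb.union_atoms:
        if pred in _pred_closure(kb, upred) and all(
            value in _value_closure(kb, upred, m) for m in members
        ):
            return True
    return False


def _matches_negative(
    kb: KnowledgeBase, n: NeuronType, pred: str, value: str
) -> bool:
    """A negative condition is satisfied only by an explicit asserted
    negative whose value equals the condition's after mapping both to
    indicators when possible.  No subtype expansion (unsound direction);
    open world: absence never satisfies a negative."""
    want = resolve_indicator(kb, value) or value
    for neg in n.asserted_negatives():
        have = resolve_indicator(kb, neg.value) or neg.value
        if have != want:
            continue
        if pred == neg.predicate or pred in kb.predicate_ancestors(neg.predicate):
            return True
    return False


def entails(
    kb: KnowledgeBase,
    sub: NeuronType,
    conditions: Iterable[PhenotypeBearer],
    _eb: Optional[ExpandedBag] = None,
) -> bool:
    """True iff ``sub`` satisfies every condition phenotype.

    Positive atomic conditions must be in ``expand(sub)``; intersectionOf
    requires all members, unionOf at least one; negative conditions need an
    explicit matching negative assertion on ``sub``.
    """
    eb = _eb if _eb is not None else expand(kb, sub)
    for c in conditions:
        if isinstance(c, LogicalPhenotype):
            if c.operator == "intersectionOf":
                if not all(
                    _matches_positive(kb, eb, c.predicate, m) for m in c.members
                ):
                    return False
            else:
                if not any(
                    _matches_positive(kb, eb, c.predicate, m) for m in c.members
                ):
                    # a weaker asserted disjunction also suffices: every
                    # asserted disjunct must land inside some condition member
                    ok = False
                    for upred, members in eb.union_atoms:
                        if c.predicate in _pred_closure(kb, upred) and all(
                            any(
                                m in _value_closure(kb, upred, am)
                                for m in c.members
                            )
                            for am in members
                        ):
                            ok = True
                            break
                    if not ok:
                        return False
        elif c.negative:
            if not _matches_negative(kb, sub, c.predicate, c.value):
                return False
        else:
            if not _matches_positive(kb, eb, c.predicate, c.value):
                return False
    return True


@dataclass
class InferredHierarchy:
    """Result of classification: transitive reduction of the subsumption
    relation, with equivalent classes merged into one node.

    ``edges`` run subtype -> supertype over node ids; a node id is a neuron
    curie (the representative of its equivalence group) or a source-class
    name.  ``members`` maps each representative to every neuron id merged
    into it.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def representative(self, neuron_id: str) -> str:
        for rep, mem in self.members.items():
            if neuron_id in mem:
                return rep
        return neuron_id

    def closure(self) -> set[tuple[str, str]]:
        g = nx.DiGraph(self.edges)
        out: set[tuple[str, str]] = set()
        for node in g.nodes:
            for anc in nx.descendants(g, node):
                out.add((node, anc))
        return out

    def superclasses(self, neuron_id: str) -> set[str]:
        rep = self.representative(neuron_id)
        return {b for (a, b) in self.closure() if a == rep}

    def subclasses_of(self, class_id: str) -> set[str]:
        """All neuron ids strictly below ``class_id`` (expanding merged
        nodes back into their member ids)."""
        rep = self.representative(class_id)
        below = {a for (a, b) in self.closure() if b == rep}
        out: set[str] = set()
        for node in below:
            out.update(self.members.get(node, (node,)))
        out |= set(self.members.get(rep, ())) - {class_id}
        return out


def classify(kb: KnowledgeBase) -> InferredHierarchy:
    """Compute the inferred subsumption hierarchy over all neuron types.

    Edge n -> m iff n entails m's equivalence bag; mutually-entailing
    neurons are merged; source-class edges (EBT -> its project class ->
    NeuronEBM, CUT -> NeuronCUT) are axiomatic.  The stored edge set is the
    transitive reduction; the full closure is derivable via ``closure()``.
    """
    ids = sorted(kb.neurons)
    ebs = {i: expand(kb, kb.neurons[i]) for i in ids}
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for i in ids:
        for j in ids:
            if i != j and entails(
                kb, kb.neurons[i], kb.neurons[j].equivalence_bag, _eb=ebs[i]
            ):
                g.add_edge(i, j)

    # merge equivalence groups (cycles of mutual entailment)
    members: dict[str, tuple[str, ...]] = {}
    mapping: dict[str, str] = {}
    for comp in nx.strongly_connected_components(g):
        rep = min(comp)
        members[rep] = tuple(sorted(comp))
        for node in comp:
            mapping[node] = rep
    h = nx.DiGraph()
    h.add_nodes_from(members)
    for a, b in g.edges:
        ra, rb = mapping[a], mapping[b]
        if ra != rb:
            h.add_edge(ra, rb)

    # axiomatic source-class scaffolding
    for rep, mem in members.items():
        for nid in mem:
            sc = kb.neurons[nid].source_class
            if sc:
                h.add_edge(rep, sc)
                if sc in EBT_SOURCE_CLASSES:
                    h.add_edge(sc, "NeuronEBM")

    reduced = nx.transitive_reduction(h)
    return InferredHierarchy(edges=set(reduced.edges), members=members)


def check_consistency(kb: KnowledgeBase) -> list[Violation]:
    """Report open-world inconsistencies.

    (a) a neuron entailing two classes declared disjoint (neuron-class
    axioms) or expanding to two disjoint phenotype values; (b) a neuron
    whose expanded positives collide with its own asserted negatives after
    indicator normalization.  Disjointness is never used to *infer*
    negatives — it only flags collisions.
    """
    out: list[Violation] = []
    ids = sorted(kb.neurons)
    ebs = {i: expand(kb, kb.neurons[i]) for i in ids}

    neuron_axioms = []
    value_axioms = []
    for ax in kb.disjointness:
        if any(t in kb.neurons for t in ax.terms):
            neuron_axioms.append(ax)
        else:
            value_axioms.append(ax)

    hier = None
    if neuron_axioms:
        hier = classify(kb)
        closure = hier.closure()
        under: dict[str, set[str]] = {i: set() for i in ids}
        for i in ids:
            rep = hier.representative(i)
            under[i] = {rep} | {b for (a, b) in closure if a == rep}
            # membership in a merged node means membership in every id of it
            expanded: set[str] = set()
            for u in under[i]:
                expanded.update(hier.members.get(u, (u,)))
            under[i] = expanded | under[i]
        for ax in neuron_axioms:
            for i in ids:
                hit = sorted(t for t in ax.terms if t in under[i] and t != i)
                own = [t for t in ax.terms if t == i]
                hits = sorted(set(hit) | set(own))
                if len(hits) >= 2:
                    out.append(
                        Violation(
                            "disjoint-classification",
                            i,
                            "classifies under disjoint classes "
                            + ", ".join(hits),
                        )
                    )

    for ax in value_axioms:
        for i in ids:
            pos_vals = {v for (_p, v) in ebs[i].positives()}
            hits = sorted(ax.terms & pos_vals)
            if len(hits) >= 2:
                out.append(
                    Violation(
                        "disjoint-values",
                        i,
                        "expanded bag contains disjoint values "
                        + ", ".join(hits),
                    )
                )

    for i in ids:
        n = kb.neurons[i]
        pos_norm: dict[tuple[str, str], tuple[str, str]] = {}
        for (p, v) in ebs[i].positives():
            key = (p, resolve_indicator(kb, v) or v)
            pos_norm.setdefault(key, (p, v))
        for neg in sorted(n.asserted_negatives(), key=lambda x: (x.predicate, x.value)):
            want = resolve_indicator(kb, neg.value) or neg.value
            for p in sorted(_pred_closure(kb, neg.predicate)):
                if (p, want) in pos_norm:
                    out.append(
                        Violation(
                            "polarity-collision",
                            i,
                            f"asserted negative ({neg.predicate}, {neg.value}) "
                            f"collides with expanded positive "
                            f"{pos_norm[(p, want)]}",
                        )
                    )
                    break
    return out
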