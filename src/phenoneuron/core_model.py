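"""Domain model for bag-of-phenotypes neuron types.

A neuron type is represented as a *bag of signed phenotypes*: a set of
(predicate, value) restrictions, each positive ("has some X") or negative
("has no X"), whose intersection defines the class.  Two flavours of type
live side by side in one knowledge base:

* **CUTs** (common usage types) — classical types such as "neocortex basket
  cell", defined by a minimal, positive-only set of necessary-and-sufficient
  phenotypes so that data-driven types can classify under them.
* **EBTs** (evidence-based types) — types proposed by a single study or
  resource, encoded exactly as measured (genes vs proteins vs transgenic
  lines, explicit negatives, censored dimensions), and tagged with a source
  class such as ``NeuronMarkram2015``.

Molecular evidence is normalized across measurement modality through
*phenotype indicators*: an indicator groups a gene, its protein product,
reporter lines, etc. under one class with a short display name (e.g. all of
Sst/SST/SOM/Sst-IRES-Cre fall under the somatostatin indicator, shown "Sst").

This module holds the record types, the knowledge-base container and its
registries, validation, and the canonical ordering of a phenotype bag that
downstream naming and serialization depend on.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "DIMENSIONS",
    "DIMENSION_RANK",
    "SOURCE_CLASSES",
    "EBT_SOURCE_CLASSES",
    "ROOT_PREDICATE",
    "OntTerm",
    "PredicateDef",
    "Phenotype",
    "LogicalPhenotype",
    "PhenotypeBearer",
    "PhenotypeIndicator",
    "NeuronType",
    "TermHierarchy",
    "DisjointnessAxiom",
    "KnowledgeBase",
    "Violation",
    "KBError",
    "DuplicateIdError",
    "UnresolvedReferenceError",
    "add_neuron",
    "validate",
    "resolve_indicator",
    "canonical_bag",
]

#: Phenotypic dimensions of the data model.  The paper's Table-1 set of eight
#: plus "sex", which the Allen encodings need (it rides along in their labels
#: between taxon and anatomy).
DIMENSIONS = (
    "taxonomic",
    "sex",
    "anatomical",
    "morphological",
    "physiological",
    "molecular",
    "connection",
    "circuit-role",
    "projection-target",
)

DIMENSION_RANK = {d: i for i, d in enumerate(DIMENSIONS)}

ROOT_PREDICATE = "hasPhenotype"

#: Source classes: the two top branches plus per-project EBT subtags.
EBT_SOURCE_CLASSES = ("NeuronMarkram2015", "NeuronHuang2017", "NeuronACT")
SOURCE_CLASSES = ("NeuronCUT", "NeuronEBM") + EBT_SOURCE_CLASSES

_CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")


class KBError(Exception):
    """Base class for knowledge-base errors."""


class DuplicateIdError(KBError):
    """An id was registered twice."""


class UnresolvedReferenceError(KBError):
    """A curie or predicate id does not resolve against the registries."""

    def __init__(self, missing: Iterable[str], context: str = ""):
        self.missing = sorted(set(missing))
        msg = "unresolved references: " + ", ".join(self.missing)
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


def _check_curie(curie: str) -> None:
    if not _CURIE_RE.match(curie):
        raise ValueError(
            f"malformed curie {curie!r}: expected exactly one colon with "
            "non-empty prefix and local part"
        )


@dataclass(frozen=True)
class OntTerm:
    """A local ontology term: compact identifier plus display labels.

    ``hidden_label`` is a short display form (SKOS hidden label); when
    present it is the token used inside generated neuron names.  ``synonyms``
    carries alternate names used for query resolution (e.g. the full
    molecule name of an indicator whose label uses the short form).
    """

    curie: str
    label: str
    hidden_label: Optional[str] = None
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_curie(self.curie)
        if not self.label:
            raise ValueError(f"term {self.curie} has an empty label")

    @property
    def display(self) -> str:
        return self.hidden_label if self.hidden_label else self.label


@dataclass(frozen=True)
class PredicateDef:
    """A phenotype predicate (object property) with its dimension.

    Predicates form a tree rooted at ``hasPhenotype``; e.g.
    hasExpressionPhenotype < hasMolecularPhenotype < hasPhenotype.  Only
    the root is dimension-less; every other predicate names one dimension.
    """

    id: str
    dimension: Optional[str]
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dimension is None:
            if self.id != ROOT_PREDICATE:
                raise ValueError(f"predicate {self.id} must name a dimension")
        elif self.dimension not in DIMENSION_RANK:
            raise ValueError(
                f"predicate {self.id}: unknown dimension {self.dimension!r}"
            )


@dataclass(frozen=True)
class Phenotype:
    """One signed (predicate, value) restriction."""

    predicate: str
    value: str
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")

    @property
    def negative(self) -> bool:
        return self.polarity == "negative"


@dataclass(frozen=True)
class LogicalPhenotype:
    """A grouped restriction: intersectionOf / unionOf over several values.

    Used e.g. for Petilla e-types ("(intersectionOf AC b)") and for the
    Martinotti soma-layer disjunction ("(unionOf EGL L3 L5)").  Member order
    is preserved for display.  Logical phenotypes are always positive.
    """

    operator: str
    predicate: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.operator not in ("intersectionOf", "unionOf"):
            raise ValueError(f"bad operator {self.operator!r}")
        if len(set(self.members)) < 2:
            raise ValueError("logical phenotype needs >=2 distinct members")

    @property
    def negative(self) -> bool:
        return False


PhenotypeBearer = Union[Phenotype, LogicalPhenotype]


@dataclass(frozen=True)
class PhenotypeIndicator:
    """Groups molecular terms (gene/protein/transgene/peptide) under one
    normalized indicator with a short display name.

    ``name`` is the full molecule name ("parvalbumin"); the class's own
    label is ``short_name + " (indicator)"`` but queries may refer to the
    indicator by either form.
    """

    id: str
    short_name: str
    members: frozenset[str]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        _check_curie(self.id)
        if not self.short_name:
            raise ValueError(f"indicator {self.id} has empty short_name")

    @property
    def class_label(self) -> str:
        return self.short_name + " (indicator)"

    def known_names(self) -> tuple[str, ...]:
        out = [self.class_label, self.short_name]
        if self.name:
            out += [self.name + " (indicator)", self.name]
        return tuple(out)


@dataclass(frozen=True)
class NeuronType:
    """A neuron class.

    ``equivalence_bag`` holds the necessary-and-sufficient restrictions;
    ``subclass_phenotypes`` are necessary-only; ``entailed_negatives`` are
    distinguishing negatives recorded outside the OWL restrictions (the only
    way CUTs may carry negatives).
    """

    id: str
    equivalence_bag: frozenset[PhenotypeBearer]
    source_class: Optional[str] = None
    subclass_phenotypes: frozenset[PhenotypeBearer] = frozenset()
    entailed_negatives: frozenset[Phenotype] = frozenset()
    orig_label: Optional[str] = None
    source_tag: Optional[str] = None

    def __post_init__(self) -> None:
        _check_curie(self.id)

    @property
    def is_cut(self) -> bool:
        return self.source_class == "NeuronCUT"

    def all_phenotypes(self) -> Iterator[PhenotypeBearer]:
        yield from self.equivalence_bag
        yield from self.subclass_phenotypes
        yield from self.entailed_negatives

    def asserted_negatives(self) -> set[Phenotype]:
        return {
            p
            for p in self.all_phenotypes()
            if isinstance(p, Phenotype) and p.negative
        }


def neuron(
    id: str,
    equivalent: Iterable[PhenotypeBearer],
    source: Optional[str] = None,
    subclass: Iterable[PhenotypeBearer] = (),
    entailed_negative: Iterable[Phenotype] = (),
    orig_label: Optional[str] = None,
    source_tag: Optional[str] = None,
) -> NeuronType:
    """Convenience constructor taking any iterables."""
    return NeuronType(
        id=id,
        equivalence_bag=frozenset(equivalent),
        source_class=source,
        subclass_phenotypes=frozenset(subclass),
        entailed_negatives=frozenset(entailed_negative),
        orig_label=orig_label,
        source_tag=source_tag,
    )


class TermHierarchy:
    """Partonomy (part_of) and subtype edges over terms.

    ``part_of_edges``: child -> parent over anatomical terms; soma location
    in a part entails location in the whole.  ``subtype_edges``: subtype ->
    supertype over phenotype value terms (nest basket -> basket phenotype,
    Rattus norvegicus -> Mammalia).  Both must be acyclic.
    """

    def __init__(
        self,
        part_of_edges: Iterable[tuple[str, str]] = (),
        subtype_edges: Iterable[tuple[str, str]] = (),
    ):
        self.part_of_edges: set[tuple[str, str]] = set(part_of_edges)
        self.subtype_edges: set[tuple[str, str]] = set(subtype_edges)
        self._po_up: Optional[dict[str, set[str]]] = None
        self._st_up: Optional[dict[str, set[str]]] = None
        self._po_down: Optional[dict[str, set[str]]] = None

    def _invalidate(self) -> None:
        self._po_up = self._st_up = self._po_down = None

    def add_part_of(self, child: str, parent: str) -> None:
        self.part_of_edges.add((child, parent))
        self._invalidate()

    def add_subtype(self, sub: str, sup: str) -> None:
        self.subtype_edges.add((sub, sup))
        self._invalidate()

    @staticmethod
    def _closure(edges: set[tuple[str, str]]) -> dict[str, set[str]]:
        # transitive closure child -> all ancestors, with cycle detection
        up: dict[str, set[str]] = {}
        for c, p in edges:
            up.setdefault(c, set()).add(p)
        out: dict[str, set[str]] = {}

        def visit(node: str, stack: tuple[str, ...]) -> set[str]:
            if node in stack:
                cyc = " -> ".join(stack + (node,))
                raise KBError(f"cycle in hierarchy: {cyc}")
            if node in out:
                return out[node]
            anc: set[str] = set()
            for p in up.get(node, ()):
                anc.add(p)
                anc |= visit(p, stack + (node,))
            out[node] = anc
            return anc

        for node in list(up):
            visit(node, ())
        return out

    def part_ancestors(self, term: str) -> set[str]:
        if self._po_up is None:
            self._po_up = self._closure(self.part_of_edges)
        return self._po_up.get(term, set())

    def part_descendants(self, term: str) -> set[str]:
        if self._po_down is None:
            down: dict[str, set[str]] = {}
            if self._po_up is None:
                self._po_up = self._closure(self.part_of_edges)
            for child, ancs in self._po_up.items():
                for a in ancs:
                    down.setdefault(a, set()).add(child)
            self._po_down = down
        return self._po_down.get(term, set())

    def supertypes(self, term: str) -> set[str]:
        if self._st_up is None:
            self._st_up = self._closure(self.subtype_edges)
        return self._st_up.get(term, set())

    def part_depth(self, term: str) -> int:
        """Number of part_of ancestors; used to order region chains
        coarse-to-fine in labels."""
        return len(self.part_ancestors(term))

    def check(self) -> list[str]:
        """Return cycle error messages (empty when acyclic)."""
        errs = []
        for name, edges in (
            ("part_of", self.part_of_edges),
            ("subtype", self.subtype_edges),
        ):
            try:
                self._closure(edges)
            except KBError as e:
                errs.append(f"{name}: {e}")
        return errs


@dataclass(frozen=True)
class DisjointnessAxiom:
    """>=2 classes (neuron classes or phenotype values) declared pairwise
    disjoint.  Disjointness is checked, never used to infer negatives."""

    terms: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.terms) < 2:
            raise ValueError("disjointness axiom needs >=2 distinct members")


@dataclass(frozen=True)
class Violation:
    """One validation finding: which object, which invariant, and why."""

    code: str
    subject: str
    message: str


class KnowledgeBase:
    """Terms + predicates + indicators + neurons + hierarchies + axioms."""

    def __init__(self) -> None:
        self.terms: dict[str, OntTerm] = {}
        self.predicates: dict[str, PredicateDef] = {}
        self.indicators: dict[str, PhenotypeIndicator] = {}
        self.neurons: dict[str, NeuronType] = {}
        self.hierarchy = TermHierarchy()
        self.disjointness: list[DisjointnessAxiom] = []
        self.metadata: dict[str, str] = {}
        self._indicator_of: Optional[dict[str, str]] = None

    # -- registry management -------------------------------------------------

    def add_term(self, term: OntTerm) -> OntTerm:
        if term.curie in self.terms:
            raise DuplicateIdError(f"term {term.curie} already registered")
        self.terms[term.curie] = term
        return term

    def term(
        self,
        curie: str,
        label: Optional[str] = None,
        hidden_label: Optional[str] = None,
        synonyms: tuple[str, ...] = (),
    ) -> OntTerm:
        """Register (or fetch, when only a curie is given) a term."""
        if label is None:
            try:
                return self.terms[curie]
            except KeyError:
                raise UnresolvedReferenceError([curie]) from None
        return self.add_term(OntTerm(curie, label, hidden_label, synonyms))

    def add_predicate(self, pred: PredicateDef) -> PredicateDef:
        if pred.id in self.predicates:
            raise DuplicateIdError(f"predicate {pred.id} already registered")
        self.predicates[pred.id] = pred
        return pred

    def add_indicator(self, ind: PhenotypeIndicator) -> PhenotypeIndicator:
        if ind.id in self.indicators:
            raise DuplicateIdError(f"indicator {ind.id} already registered")
        for other in self.indicators.values():
            shared = other.members & ind.members
            if shared:
                raise KBError(
                    f"indicator {ind.id}: terms {sorted(shared)} already "
                    f"belong to {other.id} (one indicator per term)"
                )
        self.indicators[ind.id] = ind
        self._indicator_of = None
        return ind

    # -- phenotype reference checking ----------------------------------------

    def _phenotype_refs(self, p: PhenotypeBearer) -> Iterator[str]:
        if isinstance(p, Phenotype):
            yield p.value
        else:
            yield from p.members

    def missing_refs(self, n: NeuronType) -> list[str]:
        missing = []
        for p in n.all_phenotypes():
            if p.predicate not in self.predicates:
                missing.append(p.predicate)
            for v in self._phenotype_refs(p):
                if v not in self.terms and v not in self.indicators:
                    missing.append(v)
        return sorted(set(missing))

    # -- predicate hierarchy -------------------------------------------------

    def predicate_ancestors(self, pred_id: str) -> set[str]:
        out: set[str] = set()
        seen = {pred_id}
        cur = self.predicates.get(pred_id)
        while cur is not None and cur.parent:
            if cur.parent in seen:
                raise KBError(f"cycle in predicate parents at {cur.parent}")
            out.add(cur.parent)
            seen.add(cur.parent)
            cur = self.predicates.get(cur.parent)
        return out

    def predicate_dimension(self, pred_id: str) -> str:
        pred = self.predicates.get(pred_id)
        if pred is None:
            raise UnresolvedReferenceError([pred_id])
        return pred.dimension

    # -- misc ----------------------------------------------------------------

    def display(self, curie: str) -> str:
        """Display token for a term or indicator curie (used in labels)."""
        if curie in self.terms:
            return self.terms[curie].display
        if curie in self.indicators:
            return self.indicators[curie].short_name
        raise UnresolvedReferenceError([curie])

    def content_hash(self) -> str:
        """SHA-256 over the canonical text rendering of the KB content.

        Serves as the provenance fingerprint recorded in the ontology
        header (in place of a repository path + commit hash).
        """
        h = hashlib.sha256()
        for part in _canonical_dump(self):
            h.update(part.encode("utf-8"))
        return h.hexdigest()

    def copy(self) -> "KnowledgeBase":
        kb = KnowledgeBase()
        kb.terms = dict(self.terms)
        kb.predicates = dict(self.predicates)
        kb.indicators = dict(self.indicators)
        kb.neurons = dict(self.neurons)
        kb.hierarchy = TermHierarchy(
            self.hierarchy.part_of_edges, self.hierarchy.subtype_edges
        )
        kb.disjointness = list(self.disjointness)
        kb.metadata = dict(self.metadata)
        return kb


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def add_neuron(kb: KnowledgeBase, n: NeuronType) -> KnowledgeBase:
    """Add a neuron type to the KB (in place; the KB is also returned).

    Raises ``DuplicateIdError`` for a reused id and
    ``UnresolvedReferenceError`` listing every missing curie/predicate.
    """
    if n.id in kb.neurons:
        raise DuplicateIdError(f"neuron {n.id} already present")
    if not n.equivalence_bag:
        raise ValueError(f"neuron {n.id}: equivalence bag must be non-empty")
    missing = kb.missing_refs(n)
    if missing:
        raise UnresolvedReferenceError(missing, context=f"neuron {n.id}")
    kb.neurons[n.id] = n
    return kb


def resolve_indicator(kb: KnowledgeBase, term: str) -> Optional[str]:
    """The unique indicator whose members contain ``term``, else None.

    An indicator curie resolves to itself, so callers can normalize a
    value without caring whether it is already normalized.
    """
    if term in kb.indicators:
        return term
    if kb._indicator_of is None:
        kb._indicator_of = {
            m: ind.id for ind in kb.indicators.values() for m in ind.members
        }
    return kb._indicator_of.get(term)


def validate(kb: KnowledgeBase) -> list[Violation]:
    """Check every type invariant; violations are data, not exceptions."""
    out: list[Violation] = []

    for curie in list(kb.terms) + list(kb.indicators):
        if not _CURIE_RE.match(curie):
            out.append(Violation("malformed-curie", curie, "bad curie shape"))

    # predicate registry: dimensions checked on construction; parent chains
    for pid in kb.predicates:
        try:
            anc = kb.predicate_ancestors(pid)
        except KBError as e:
            out.append(Violation("predicate-cycle", pid, str(e)))
            continue
        if pid != ROOT_PREDICATE and ROOT_PREDICATE not in anc:
            out.append(
                Violation(
                    "predicate-root",
                    pid,
                    f"parent chain does not reach {ROOT_PREDICATE}",
                )
            )
        parent = kb.predicates[pid].parent
        if parent and parent not in kb.predicates:
            out.append(
                Violation("predicate-parent", pid, f"unknown parent {parent}")
            )

    # indicators: uniqueness of membership is enforced on add; re-check here
    seen_member: dict[str, str] = {}
    for ind in kb.indicators.values():
        for m in ind.members:
            if m in seen_member:
                out.append(
                    Violation(
                        "indicator-overlap",
                        m,
                        f"member of both {seen_member[m]} and {ind.id}",
                    )
                )
            seen_member[m] = ind.id
            if m not in kb.terms:
                out.append(
                    Violation(
                        "unresolved-reference",
                        ind.id,
                        f"indicator member {m} not registered",
                    )
                )

    for err in kb.hierarchy.check():
        out.append(Violation("hierarchy-cycle", "hierarchy", err))
    for child, parent in kb.hierarchy.part_of_edges | kb.hierarchy.subtype_edges:
        for t in (child, parent):
            if t not in kb.terms and t not in kb.indicators:
                out.append(
                    Violation(
                        "unresolved-reference",
                        "hierarchy",
                        f"edge endpoint {t} not registered",
                    )
                )

    for ax in kb.disjointness:
        for t in ax.terms:
            if (
                t not in kb.terms
                and t not in kb.indicators
                and t not in kb.neurons
                and t not in SOURCE_CLASSES
            ):
                out.append(
                    Violation(
                        "unresolved-reference",
                        "disjointness",
                        f"axiom member {t} not registered",
                    )
                )

    for n in kb.neurons.values():
        if not n.equivalence_bag:
            out.append(
                Violation("empty-equivalence", n.id, "equivalence bag is empty")
            )
        if n.source_class is not None and n.source_class not in SOURCE_CLASSES:
            out.append(
                Violation(
                    "bad-source-class",
                    n.id,
                    f"unknown source class {n.source_class}",
                )
            )
        missing = kb.missing_refs(n)
        if missing:
            out.append(
                Violation(
                    "unresolved-reference",
                    n.id,
                    "missing " + ", ".join(missing),
                )
            )
        # polarity conflicts over atomic (predicate, value) pairs
        pols: dict[tuple[str, str], set[str]] = {}
        for p in n.all_phenotypes():
            if isinstance(p, Phenotype):
                pols.setdefault((p.predicate, p.value), set()).add(p.polarity)
        for (pred, val), ps in sorted(pols.items()):
            if len(ps) > 1:
                out.append(
                    Violation(
                        "contradictory-polarity",
                        n.id,
                        f"({pred}, {val}) asserted both positive and negative",
                    )
                )
        if n.is_cut:
            for p in n.equivalence_bag:
                if p.negative:
                    out.append(
                        Violation(
                            "cut-negative-equivalence",
                            n.id,
                            f"CUT equivalence bag contains negative "
                            f"({p.predicate}, {p.value})",
                        )
                    )
        for p in n.entailed_negatives:
            if not p.negative:
                out.append(
                    Violation(
                        "entailed-positive",
                        n.id,
                        f"entailed_negatives contains positive "
                        f"({p.predicate}, {p.value})",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Canonical ordering
# ---------------------------------------------------------------------------

# Sub-ranks inside the molecular dimension, reflecting the printed label
# convention: indicator-valued phenotypes first, then other molecular terms
# (receptors etc.), then the neurotransmitter, then expression evidence.
_MOLECULAR_PRED_RANK = {
    "hasNeurotransmitterPhenotype": 2,
    "hasExpressionPhenotype": 3,
    "hasEpigeneticPhenotype": 3,
}


def _molecular_subrank(kb: KnowledgeBase, p: PhenotypeBearer) -> int:
    if p.predicate in _MOLECULAR_PRED_RANK:
        return _MOLECULAR_PRED_RANK[p.predicate]
    if isinstance(p, Phenotype) and p.value in kb.indicators:
        return 0
    return 1


def _display_key(kb: KnowledgeBase, curie: str) -> tuple[str, str]:
    try:
        d = kb.display(curie)
    except UnresolvedReferenceError:
        d = curie
    return (d.lower(), curie)


def sort_key(kb: KnowledgeBase, p: PhenotypeBearer):
    """Content-derived total-order key for one phenotype.

    Dimension rank first (taxon < sex < anatomy < morphology < physiology <
    molecular < connection < circuit role < projection target), then a
    dimension-specific arrangement matching the label conventions:

    * anatomical — soma regions coarse-to-fine (partonomy depth), then
      soma disjunction groups, then axon-location restrictions;
    * morphological — positive atoms, negatives, then logical groups;
    * physiological — logical groups (e-types) before plain terms;
    * molecular — positives before negatives, each ordered
      indicator < other molecular < neurotransmitter < expression and
      alphabetically (case-insensitive) within a group.
    """
    dim = kb.predicate_dimension(p.predicate)
    rank = DIMENSION_RANK[dim]
    is_logical = isinstance(p, LogicalPhenotype)
    neg = 1 if p.negative else 0
    if is_logical:
        vkey = tuple(_display_key(kb, m) for m in p.members)
    else:
        vkey = (_display_key(kb, p.value),)

    if dim == "anatomical":
        axon = 1 if p.predicate == "hasAxonLocatedIn" else 0
        depth = (
            kb.hierarchy.part_depth(p.value) if not is_logical else 0
        )
        within = (axon, int(is_logical), neg, depth)
    elif dim == "morphological":
        within = (2 if is_logical else neg, 0, 0, 0)
    elif dim == "physiological":
        within = (neg, 1 - int(is_logical), 0, 0)
    elif dim == "molecular":
        within = (neg, _molecular_subrank(kb, p), int(is_logical), 0)
    else:
        within = (neg, int(is_logical), 0, 0)
    return (rank, within, p.predicate, vkey)


def canonical_bag(
    n: NeuronType,
    kb: KnowledgeBase,
    include_subclass: bool = True,
    include_entailed: bool = True,
) -> list[PhenotypeBearer]:
    """Stable, insertion-order-independent ordering of a neuron's bag.

    Idempotent by construction: the order is a pure function of phenotype
    content.  Naming and Turtle serialization both project from this order,
    which is what makes their outputs deterministic.
    """
    items: list[PhenotypeBearer] = list(n.equivalence_bag)
    if include_subclass:
        items += list(n.subclass_phenotypes)
    if include_entailed:
        items += list(n.entailed_negatives)
    return sorted(items, key=lambda p: sort_key(kb, p))


def _canonical_phenotype_str(p: PhenotypeBearer) -> str:
    if isinstance(p, Phenotype):
        return f"({p.predicate} {p.value} {p.polarity})"
    return f"({p.operator} {p.predicate} {' '.join(p.members)})"


def _canonical_dump(kb: KnowledgeBase) -> Iterator[str]:
    """Stable text rendering of KB content (feeds the content hash)."""
    for c in sorted(kb.terms):
        t = kb.terms[c]
        yield f"term {c} {t.label!r} {t.hidden_label!r} {sorted(t.synonyms)}\n"
    for pid in sorted(kb.predicates):
        pr = kb.predicates[pid]
        yield f"pred {pid} {pr.parent} {pr.dimension}\n"
    for iid in sorted(kb.indicators):
        ind = kb.indicators[iid]
        yield f"ind {iid} {ind.short_name} {ind.name!r} {sorted(ind.members)}\n"
    for nid in sorted(kb.neurons):
        n = kb.neurons[nid]
        eq = sorted(_canonical_phenotype_str(p) for p in n.equivalence_bag)
        sc = sorted(_canonical_phenotype_str(p) for p in n.subclass_phenotypes)
        en = sorted(_canonical_phenotype_str(p) for p in n.entailed_negatives)
        yield (
            f"neuron {nid} {n.source_class} {n.orig_label!r} "
            f"{n.source_tag!r} eq={eq} sub={sc} neg={en}\n"
        )
    for e in sorted(kb.hierarchy.part_of_edges):
        yield f"part_of {e[0]} {e[1]}\n"
    for e in sorted(kb.hierarchy.subtype_edges):
        yield f"subtype {e[0]} {e[1]}\n"
    for ax in sorted(kb.disjointness, key=lambda a: sorted(a.terms)):
        yield f"disjoint {sorted(ax.terms)} {ax.provenance!r}\n"


def canonical_equal(a: KnowledgeBase, b: KnowledgeBase) -> bool:
    """Content equality after canonicalization (order-insensitive)."""
    return list(_canonical_dump(a)) == list(_canonical_dump(b))
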