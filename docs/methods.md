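# Methods

## The bag-of-phenotypes model

A neuron type is a set ("bag") of signed phenotype restrictions.  Each
atomic phenotype is a triple *(predicate, value, polarity)*: the predicate
names a phenotypic dimension (one of taxonomic, sex, anatomical,
morphological, physiological, molecular, connection, circuit-role,
projection-target), the value is a term curie, and the polarity is
positive ("has some") or negative ("has no").  Logical phenotypes group
several values under one predicate with `intersectionOf` (all hold — used
for electrophysiological profiles like *(intersectionOf AC b)* and for
multi-gene expression signatures) or `unionOf` (at least one holds — used
for disjunctive soma layers).  Predicates form a tree rooted at
`hasPhenotype` (e.g. `hasExpressionPhenotype` < `hasMolecularPhenotype` <
`hasPhenotype`); the `sex` dimension is an addition to the classical
eight, needed because cell-type records from transgenic-line databases
interleave sex between taxon and anatomy.

Two kinds of type share the representation:

* **CUTs** (common usage types) carry *positive-only* equivalence bags —
  the minimal necessary-and-sufficient conditions — so that sparsely
  measured types can still classify under them.  Additional phenotypes go
  in a subclass-only set (necessary, not sufficient), and distinguishing
  negatives are recorded as *entailed negatives* outside the defining
  restrictions.  A CUT with a negative inside its equivalence bag is a
  validation error.
* **EBTs** (evidence-based types) are encoded exactly as measured,
  including negatives and censored dimensions, and carry a source class
  (`NeuronMarkram2015`, `NeuronHuang2017`, `NeuronACT`), all of which are
  axiomatic subclasses of `NeuronEBM`.

Molecular evidence is normalized through **phenotype indicators**: an
indicator groups the gene, protein, peptide, and transgenic-line forms of
one marker under a single class with a short display name (parvalbumin →
"PV").  Membership is a partial function — a molecular term belongs to at
most one indicator; this is enforced at registration.  A double-reporter
construct that should indicate two markers is therefore rejected rather
than silently accepted; relaxing this would require changing
`resolve_indicator` from a function to a relation, and nothing in the
current reasoning depends on that generality.

## Canonical ordering and naming

All deterministic outputs (names, Turtle) project from one canonical
ordering of a bag, a pure function of phenotype content: dimension rank
first (taxon < sex < anatomy < morphology < physiology < molecular <
connection < circuit-role < projection-target), then a dimension-specific
arrangement.  Anatomical atoms order coarse-to-fine by partonomy depth,
with disjunctive layer groups after the plain regions and axon-location
restrictions last.  Morphology orders positives, then negatives, then
logical groups; physiology puts the logical profile before plain terms.

Within the molecular segment positives precede negatives, and each side
orders indicator-valued phenotypes first, then other molecular terms
(receptors), then the neurotransmitter, then expression evidence,
alphabetically (case-insensitive) within each group.  This predicate-
based rule is the one that reproduces the published names of the
reference types character-for-character — a basket-cell CUT defined via
the parvalbumin indicator renders "… Basket + PV + GABA …", while an
expression-based type renders "… Basket + GABA + PV-cre …"; a rule that
always placed the neurotransmitter first could not produce both.

Four labels derive from the bag: *normalized* (molecules shown as
indicator short names), *local* (molecules in measured form), *orig*
(the investigator's name, passed through), and *pref* (= orig when
present, else normalized, so no type lacks a preferred label).  The
circuit-role suffix is one global constant per role ("intrinsic neuron",
"projection neuron", plain "neuron" when no role is asserted); sources
that print "interneuron" are normalized to "intrinsic neuron".  Negative
tokens use the ASCII hyphen; readers accept both hyphen and minus.
Indicator classes label themselves `short_name + " (indicator)"` and keep
the full molecule name as an alias so queries can use either form.

## Reasoning fragment

The reasoner implements a closed EL-like fragment: existential
restrictions, conjunction, value/predicate hierarchies, asserted
negation, and disjointness *checks*.  Unions occur only inside logical
phenotypes and query value-expressions, never as general axioms.  A bag
is expanded to fixpoint under three monotone rules:

* **R1 — indicator normalization**: a positive molecular atom also holds
  with its indicator as value.
* **R2 — partonomy**: soma/axon location propagates to every part-of
  ancestor.
* **R3 — hierarchy generalization**: value-subtype edges (nest basket →
  basket phenotype, *Rattus norvegicus* → *Mammalia*) and predicate-parent
  edges add generalized atoms.

Negative atoms are never expanded: generalizing a negation is unsound,
and under the open world a missing assertion says nothing.  A negative
condition is satisfied only by an explicit asserted negative whose value
matches after mapping both sides to indicators when possible; no subtype
expansion is applied to negatives.  An asserted disjunction entails a
condition when every disjunct does (so "soma in EGL or L3 or L5" entails
"soma in neocortex"); conversely a disjunctive condition is met by any
single matching atom or by a covered asserted disjunction.  Each
disjunct's partonomy is expanded independently.

Classification computes, for every ordered pair, whether the subject's
expanded bag entails the object's equivalence bag; neurons with mutually
entailing bags are merged into one node (the reference KB genuinely
contains one such duplicated encoding); source-class edges are added
axiomatically; and the transitive reduction is stored, with the closure
derivable on demand.  CUT entailed negatives do not participate in
blocking classification — they are surfaced only by the consistency
checker, which reports (a) neurons classifying under two classes declared
disjoint or expanding to two disjoint values and (b) collisions between a
neuron's expanded positives and its own asserted negatives after
indicator normalization.  Disjointness never injects negatives into
reasoning: a disjointness axiom between a PV-class and a VIP-class is a
statement about the classes, not about expression.

## Queries

The DL-style grammar supports identifiers, quoted labels, `some`, `and`,
`or`, `not`, parentheses, and `'part of' some X` inside value
expressions.  Parsing is a hand-written tokenizer and recursive-descent
parser (the grammar is a dozen productions).  Names resolve
case-sensitively against display labels, then hidden labels, then
synonyms/indicator aliases, then curies; ambiguity is an error, never a
silent pick.  `not` is set complement over the neuron universe — a
closed-world choice at the query level that coexists with open-world
phenotype negation; none of the four competency queries uses `not`, so
the choice affects none of them.  Results sort lexicographically by curie
for reproducible output.  The competency suite answers the Martinotti
question both ways it can be phrased — as a DL query over EBTs with a
Martinotti phenotype and as classification under the Martinotti CUT —
and reports both.

## Turtle dialect

"Deterministic Turtle" names a goal, not a format, so the exact layout is
fixed here: sorted prefix block, subjects sorted by curie within fixed
block order (ontology header, annotation properties, source classes,
predicates, terms, indicators, neurons, entailment axioms, disjointness),
2-space indentation.  Neurons serialize as `owl:equivalentClass` of an
intersection of existential restrictions over the canonical bag, with
negatives as `owl:complementOf` a restriction; subclass phenotypes as
plain `rdfs:subClassOf` restrictions; entailed negatives as *annotated*
subclass axioms (`owl:Axiom` reification tagged
`ilxtr:axiomKind "entailed-negative"`, without asserting the base triple)
— the published convention says such negatives are "modeled as
entailments" without showing the OWL shape, so this reified form is this
package's explicit choice and the reader treats it as such.  Labels ride
along as annotations (`rdfs:label` normalized, `skos:prefLabel`,
`skos:hiddenLabel` for indicator short names, custom `ilxtr:localLabel` /
`ilxtr:origLabel` in the internal namespace, since those two property
names have no published resolvable ids).  The ontology header records
provenance as a `prov:wasGeneratedBy` string containing the tool id and
the SHA-256 of the canonical KB content — a repo-agnostic replacement for
a source path + commit hash.  Two writes of the same canonical KB are
byte-identical; `read(write(kb))` equals `kb` after canonicalization.
`lax=True` maps common equivalents (alternate label properties, part-of
as a BFO existential restriction) onto the dialect for best-effort import
of external files; unknown axiom shapes become warnings, never silent
drops.

## Synthetic generator

`gen_synthetic_kb(SynthConfig(...))` emulates the structure of the real
data: a random partonomy of configurable depth, indicators partitioning
gene/protein/transgene triples, morphology subtypes, and EBT bags drawn
over those vocabularies.  Defaults (20 EBTs, 18 molecular terms, 12
regions, depth 3, 3 planted CUTs) mirror the scale of the reference KB —
large enough to exercise every rule, small enough that every property
test runs the exact reasoner against a brute-force oracle in seconds.
Each *planted* CUT generalizes exactly one host EBT (indicator-level
marker, parent morphology, ancestor region), and marker indicators are
exclusive per CUT, so the set of true EBT→CUT subsumptions is known by
construction; recovery must be 100% at any modality-relabeling rate
(relabeling within an indicator is invisible after R1) and must degrade
to exactly the uncensored fraction under morphology censoring.
`censor_dimension` removes a stated fraction of one dimension's atoms
from EBT bags (never emptying an equivalence bag, never touching CUTs).

What the generator does **not** emulate: measurement noise that crosses
indicator boundaries, continuous expression levels, conflicting
assertions between sources, or the long-tailed phenotype-count
distribution of real cell-type records.  Passing tests therefore
demonstrate the logical machinery — closure, naming, serialization,
recovery — not robustness to biologically noisy input.

## Numerical and degenerate-input choices

There are no floating-point tolerances anywhere; every comparison is
set- or string-exact.  Ties in canonical ordering break on
(case-insensitive display, curie, predicate id), making every order
total.  Degenerate inputs are defined rather than rejected where a
definition exists: an empty condition set is entailed by everything; an
empty KB serializes to a header-only document and answers every query
with the empty set; a neuron with only a taxon names itself
"*Taxon* neuron".  Hierarchy cycles, duplicate ids, unresolved
references, and contradictory polarities are hard errors or validation
findings, never silently repaired.

## Known limitations

* The reference KB encodes the printed exemplar rows of each source
  taxonomy, not the full rosters (56 Blue Brain types, ~800 Allen
  records); headline counts against the full released knowledge base are
  therefore only reproducible through the optional external-artifact
  integration path.
* Two ids for the Huang chandelier and interneuron-selective classes are
  not published; they are minted in the internal namespace (`fix:CHC`,
  `fix:ISC`) with bags following the published marker groups.
* The reasoner is not a general OWL 2 DL engine: no role chains, no
  cardinality, no nominals, no negation as a general class constructor.
* Query-level `not` is closed-world by design (documented above).
* Label generation is one-way; there is no parser from names back to
  bags.
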