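"""Core model: registries, validation, indicator resolution, canonical order."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoneuron.core_model import (
    DuplicateIdError,
    KnowledgeBase,
    LogicalPhenotype,
    OntTerm,
    Phenotype,
    PhenotypeIndicator,
    PredicateDef,
    UnresolvedReferenceError,
    add_neuron,
    canonical_bag,
    resolve_indicator,
    validate,
)
from phenoneuron.core_model import neuron as mk_neuron
from phenoneuron.fixtures import P, standard_predicates


def small_kb():
    kb = KnowledgeBase()
    standard_predicates(kb)
    kb.term("ilxtr:GABA", "GABA")
    kb.term("ilxtr:PV", "PV")
    kb.term("ilxtr:Pvalb", "Pvalb")
    kb.term("ilxtr:neocortex", "neocortex")
    kb.add_indicator(
        PhenotypeIndicator(
            "npokb:pv-ind", "PV", frozenset({"ilxtr:PV", "ilxtr:Pvalb"})
        )
    )
    return kb


class TestRegistries:
    def test_add_neuron_and_duplicate(self):
        kb = small_kb()
        n = mk_neuron("npokb:1", [P("hasExpressionPhenotype", "ilxtr:PV")])
        add_neuron(kb, n)
        assert "npokb:1" in kb.neurons
        with pytest.raises(DuplicateIdError):
            add_neuron(kb, n)

    def test_add_neuron_empty_bag_rejected(self):
        kb = small_kb()
        with pytest.raises(ValueError, match="non-empty"):
            add_neuron(kb, mk_neuron("npokb:2", []))

    def test_add_neuron_unresolved_refs_listed(self):
        kb = small_kb()
        bad = mk_neuron(
            "npokb:3",
            [P("hasExpressionPhenotype", "ilxtr:nope"),
             P("hasMadeUpPredicate", "ilxtr:PV")],
        )
        with pytest.raises(UnresolvedReferenceError) as exc:
            add_neuron(kb, bad)
        assert set(exc.value.missing) == {"ilxtr:nope", "hasMadeUpPredicate"}

    def test_malformed_curie_rejected(self):
        with pytest.raises(ValueError, match="curie"):
            OntTerm("nocolon", "x")
        with pytest.raises(ValueError, match="curie"):
            OntTerm("a:b:c", "x")

    def test_indicator_overlap_rejected(self):
        kb = small_kb()
        with pytest.raises(Exception, match="one indicator per term"):
            kb.add_indicator(
                PhenotypeIndicator("npokb:other", "X", frozenset({"ilxtr:PV"}))
            )


class TestResolveIndicator:
    def test_member_resolves(self):
        kb = small_kb()
        assert resolve_indicator(kb, "ilxtr:Pvalb") == "npokb:pv-ind"

    def test_unknown_term_is_none(self):
        kb = small_kb()
        assert resolve_indicator(kb, "ilxtr:GABA") is None

    def test_indicator_resolves_to_itself(self):
        kb = small_kb()
        assert resolve_indicator(kb, "npokb:pv-ind") == "npokb:pv-ind"

    def test_partial_function_over_registry(self, paper_kb):
        # every molecular curie maps to at most one indicator, exhaustively
        for curie in paper_kb.terms:
            hits = [
                i.id
                for i in paper_kb.indicators.values()
                if curie in i.members
            ]
            assert len(hits) <= 1
            if hits:
                assert resolve_indicator(paper_kb, curie) == hits[0]


class TestValidate:
    def test_fixture_kb_clean(self, paper_kb):
        assert validate(paper_kb) == []

    def test_contradictory_polarity_flagged(self):
        kb = small_kb()
        kb.neurons["npokb:9"] = mk_neuron(
            "npokb:9",
            [P("hasExpressionPhenotype", "ilxtr:PV"),
             P("hasExpressionPhenotype", "ilxtr:PV", neg=True)],
        )
        codes = [v.code for v in validate(kb)]
        assert codes == ["contradictory-polarity"]

    def test_cut_negative_equivalence_flagged(self):
        kb = small_kb()
        kb.neurons["npokb:9"] = mk_neuron(
            "npokb:9",
            [P("hasExpressionPhenotype", "ilxtr:PV", neg=True)],
            source="NeuronCUT",
        )
        codes = [v.code for v in validate(kb)]
        assert "cut-negative-equivalence" in codes

    def test_unresolved_reference_reported_not_raised(self):
        kb = small_kb()
        kb.neurons["npokb:9"] = mk_neuron(
            "npokb:9", [P("hasExpressionPhenotype", "ilxtr:ghost")]
        )
        vs = validate(kb)
        assert [v.code for v in vs] == ["unresolved-reference"]
        assert "ilxtr:ghost" in vs[0].message

    def test_predicate_cycle_flagged(self):
        kb = KnowledgeBase()
        kb.predicates["a"] = PredicateDef("a", "molecular", "b")
        kb.predicates["b"] = PredicateDef("b", "molecular", "a")
        assert any(v.code == "predicate-cycle" for v in validate(kb))

    def test_hierarchy_cycle_flagged(self):
        kb = small_kb()
        kb.hierarchy.add_part_of("ilxtr:GABA", "ilxtr:PV")
        kb.hierarchy.add_part_of("ilxtr:PV", "ilxtr:GABA")
        assert any(v.code == "hierarchy-cycle" for v in validate(kb))


class TestCanonicalBag:
    def pool(self, kb):
        return [
            P("hasInstanceInTaxon", "ilxtr:Mus-musculus"),
            P("hasSomaLocatedIn", "ilxtr:neocortex"),
            P("hasSomaLocatedIn", "ilxtr:S1"),
            P("hasMorphologicalPhenotype", "ilxtr:BasketPhenotype"),
            P("hasExpressionPhenotype", "ilxtr:PV"),
            P("hasExpressionPhenotype", "ilxtr:SST", neg=True),
            P("hasNeurotransmitterPhenotype", "ilxtr:GABA"),
            LogicalPhenotype(
                "intersectionOf",
                "hasElectrophysiologicalPhenotype",
                ("ilxtr:petilla-AC", "ilxtr:petilla-b"),
            ),
        ]

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_order_independent_of_insertion(self, paper_kb, data):
        pool = self.pool(paper_kb)
        subset = data.draw(
            st.lists(st.sampled_from(range(len(pool))), min_size=1,
                     max_size=6, unique=True)
        )
        perm = data.draw(st.permutations(subset))
        a = mk_neuron("fix:a", [pool[i] for i in subset])
        b = mk_neuron("fix:b", [pool[i] for i in perm])
        assert canonical_bag(a, paper_kb) == canonical_bag(b, paper_kb)

    def test_idempotent(self, paper_kb):
        n = paper_kb.neurons["npokb:112"]
        once = canonical_bag(n, paper_kb)
        again = canonical_bag(
            mk_neuron("fix:x", once), paper_kb
        )
        assert once == again

    def test_positives_before_negatives_within_molecular(self, paper_kb):
        bag = canonical_bag(paper_kb.neurons["npokb:112"], paper_kb)
        mol = [
            p for p in bag
            if paper_kb.predicate_dimension(p.predicate) == "molecular"
        ]
        negs = [p.negative for p in mol]
        assert negs == sorted(negs)  # all positives first

    def test_empty_subclass_section_allowed(self, paper_kb):
        n = paper_kb.neurons["npokb:434"]
        assert n.subclass_phenotypes == frozenset()
        assert canonical_bag(n, paper_kb, include_subclass=True) == \
            canonical_bag(n, paper_kb, include_subclass=False)
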