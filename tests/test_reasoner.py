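"""Expansion closure, entailment, classification, consistency checking."""

import itertools

import pytest

from conftest import naive_entails

from phenoneuron.core_model import (
    DisjointnessAxiom,
    LogicalPhenotype,
    Phenotype,
)
from phenoneuron.core_model import neuron as mk_neuron
from phenoneuron.fixtures import P, SynthConfig, gen_synthetic_kb
from phenoneuron.reasoner import (
    check_consistency,
    classify,
    entails,
    expand,
)


class TestExpand:
    def test_partonomy_generalizes_soma_location(self, paper_kb):
        eb = expand(paper_kb, paper_kb.neurons["npokb:112"])
        assert ("hasSomaLocatedIn", "ilxtr:neocortex", "positive") in eb.atoms
        assert (
            "hasSomaLocatedIn",
            "ilxtr:cerebral-cortex",
            "positive",
        ) in eb.atoms

    def test_indicator_and_predicate_generalization(self, paper_kb):
        eb = expand(paper_kb, paper_kb.neurons["npokb:43"])
        # transgene PV-cre -> parvalbumin indicator, up the predicate tree
        assert (
            "hasPhenotype",
            "npokb:parvalbumin-indicator",
            "positive",
        ) in eb.atoms

    def test_no_molecular_atoms_means_no_indicator_atoms(self, paper_kb):
        n = mk_neuron("fix:x", [P("hasSomaLocatedIn", "ilxtr:S1")])
        eb = expand(paper_kb, n)
        assert not any(v in paper_kb.indicators for (_p, v, _s) in eb.atoms)

    def test_negatives_are_not_expanded(self, paper_kb):
        n = mk_neuron(
            "fix:x",
            [P("hasExpressionPhenotype", "ilxtr:PV", neg=True),
             P("hasNeurotransmitterPhenotype", "ilxtr:GABA")],
        )
        eb = expand(paper_kb, n)
        negs = {(p, v) for (p, v, s) in eb.atoms if s == "negative"}
        assert negs == {("hasExpressionPhenotype", "ilxtr:PV")}

    def test_idempotent_on_random_kbs(self, synth_kb):
        for seed in range(5):
            kb = synth_kb(seed=seed, n_neurons=8)
            for nid in kb.neurons:
                eb = expand(kb, kb.neurons[nid])
                # feed the closure back in as an asserted bag
                refed = mk_neuron(
                    nid.replace(":", ":re-"),
                    [Phenotype(p, v, s) for (p, v, s) in eb.atoms]
                    + [
                        LogicalPhenotype("unionOf", p, m)
                        for (p, m) in eb.union_atoms
                    ],
                )
                assert expand(kb, refed).atoms == eb.atoms

    def test_union_common_ancestor_materialized(self, paper_kb):
        # soma in (EGL or L3 or L5) entails soma in neocortex outright
        eb = expand(paper_kb, paper_kb.neurons["nifext:55"])
        assert ("hasSomaLocatedIn", "ilxtr:neocortex", "positive") in eb.atoms


class TestEntails:
    def test_empty_conditions_always_true(self, paper_kb):
        for n in paper_kb.neurons.values():
            assert entails(paper_kb, n, [])

    def test_own_equivalence_bag_always_true(self, paper_kb):
        for n in paper_kb.neurons.values():
            assert entails(paper_kb, n, n.equivalence_bag)

    def test_allen_cell_does_not_meet_martinotti_conditions(self, paper_kb):
        # dendrite-only morphology: no Martinotti assertion, so open world
        # blocks classification under the Martinotti CUT
        cut = paper_kb.neurons["nifext:55"]
        allen = paper_kb.neurons["npokb:415"]
        assert not entails(paper_kb, allen, cut.equivalence_bag)

    def test_markram_martinotti_meets_cut_conditions(self, paper_kb):
        cut = paper_kb.neurons["nifext:55"]
        assert entails(
            paper_kb, paper_kb.neurons["npokb:89"], cut.equivalence_bag
        )

    def test_open_world_negative_never_satisfied_without_assertion(
        self, paper_kb
    ):
        neg = P("hasExpressionPhenotype", "ilxtr:PV", neg=True)
        for n in paper_kb.neurons.values():
            if not n.asserted_negatives():
                assert not entails(paper_kb, n, [neg])

    def test_negative_condition_matches_via_indicator(self, paper_kb):
        # -PV (protein) satisfies a -Pvalb (gene) condition: both normalize
        # to the parvalbumin indicator
        cond = [P("hasExpressionPhenotype", "ilxtr:Pvalb", neg=True)]
        assert entails(paper_kb, paper_kb.neurons["npokb:89"], cond)

    def test_matches_brute_force_oracle_on_fixture_pairs(self, paper_kb):
        ids = sorted(paper_kb.neurons)
        for a, b in itertools.product(ids, ids):
            got = entails(
                paper_kb,
                paper_kb.neurons[a],
                paper_kb.neurons[b].equivalence_bag,
            )
            want = naive_entails(
                paper_kb,
                paper_kb.neurons[a],
                paper_kb.neurons[b].equivalence_bag,
            )
            assert got == want, (a, b)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_synthetic_kbs(self, seed):
        kb = gen_synthetic_kb(
            SynthConfig(seed=seed, n_neurons=12, n_planted_cuts=3,
                        modality_relabel_rate=0.2)
        )
        ids = sorted(kb.neurons)
        for a, b in itertools.product(ids, ids):
            got = entails(
                kb, kb.neurons[a], kb.neurons[b].equivalence_bag
            )
            want = naive_entails(
                kb, kb.neurons[a], kb.neurons[b].equivalence_bag
            )
            assert got == want, (a, b)

    def test_monotone_under_added_positives(self, paper_kb):
        """Adding a positive phenotype never retracts a positive-only
        entailment verdict."""
        extras = [
            P("hasExpressionPhenotype", "ilxtr:NPY"),
            P("hasSomaLocatedIn", "ilxtr:L2-3"),
            P("hasMorphologicalPhenotype", "ilxtr:ChandelierPhenotype"),
        ]
        pos_conditions = [
            [P("hasMolecularPhenotype", "npokb:parvalbumin-indicator")],
            [P("hasSomaLocatedIn", "ilxtr:neocortex")],
            [P("hasNeurotransmitterPhenotype", "ilxtr:GABA")],
        ]
        for nid, n in paper_kb.neurons.items():
            before = [entails(paper_kb, n, c) for c in pos_conditions]
            for extra in extras:
                vals = {
                    (p.predicate, p.value)
                    for p in n.all_phenotypes()
                    if isinstance(p, Phenotype)
                }
                if (extra.predicate, extra.value) in vals:
                    continue
                grown = mk_neuron(
                    n.id,
                    list(n.equivalence_bag) + [extra],
                    source=n.source_class,
                    subclass=n.subclass_phenotypes,
                    entailed_negative=n.entailed_negatives,
                )
                after = [entails(paper_kb, grown, c) for c in pos_conditions]
                for x, y in zip(before, after):
                    assert y or not x


class TestClassify:
    def test_fixture_martinotti_edges(self, paper_kb):
        hier = classify(paper_kb)
        below = hier.subclasses_of("nifext:55")
        assert {"npokb:89", "npokb:111", "npokb:42"} <= below
        allen = {"npokb:434", "npokb:296", "npokb:415", "npokb:412"}
        assert below & allen == set()

    def test_single_neuron_kb_has_only_source_edges(self, synth_kb):
        kb = synth_kb(seed=1, n_neurons=1, n_planted_cuts=0)
        hier = classify(kb)
        (nid,) = kb.neurons
        src = kb.neurons[nid].source_class
        assert hier.edges == {(nid, src), (src, "NeuronEBM")}

    def test_reduction_reexpanded_equals_pairwise_entailment(self, paper_kb):
        hier = classify(paper_kb)
        closure = hier.closure()
        ids = sorted(paper_kb.neurons)
        for a, b in itertools.product(ids, ids):
            if a == b:
                continue
            want = entails(
                paper_kb,
                paper_kb.neurons[a],
                paper_kb.neurons[b].equivalence_bag,
            )
            ra, rb = hier.representative(a), hier.representative(b)
            got = (ra, rb) in closure or ra == rb
            assert got == want, (a, b)

    def test_equivalent_bags_are_merged(self, paper_kb):
        hier = classify(paper_kb)
        # the two printed nest-basket encodings carry identical content
        assert hier.members[hier.representative("npokb:65")] == (
            "npokb:112",
            "npokb:65",
        )

    @pytest.mark.parametrize("relabel", [0.0, 0.3, 1.0])
    def test_planted_edges_recovered_under_relabeling(self, relabel):
        """Swapping gene/protein/transgene within an indicator is invisible
        after indicator expansion: planted CUT edges survive any rate."""
        kb = gen_synthetic_kb(
            SynthConfig(seed=11, n_neurons=14, n_planted_cuts=4,
                        modality_relabel_rate=relabel)
        )
        hier = classify(kb)
        closure = hier.closure()
        planted = [
            tuple(e.split("->"))
            for e in kb.metadata["planted_edges"].split(";")
        ]
        assert planted
        for a, b in planted:
            ra, rb = hier.representative(a), hier.representative(b)
            assert (ra, rb) in closure or ra == rb
        # and nothing else classifies under a planted CUT
        for a, b in closure:
            if b.startswith("fix:cut-") and not a.startswith("fix:cut-"):
                assert (a, b) in planted


class TestCheckConsistency:
    def test_fixture_is_consistent(self, paper_kb):
        assert check_consistency(paper_kb) == []

    def test_indicator_collision_detected(self, paper_kb):
        kb = paper_kb.copy()
        kb.neurons["fix:bad"] = mk_neuron(
            "fix:bad",
            [P("hasExpressionPhenotype", "ilxtr:Pvalb"),
             P("hasMolecularPhenotype", "npokb:parvalbumin-indicator",
               neg=True)],
        )
        vs = check_consistency(kb)
        assert [v.code for v in vs] == ["polarity-collision"]
        assert vs[0].subject == "fix:bad"

    def test_disjoint_class_membership_detected(self, paper_kb):
        kb = paper_kb.copy()
        # a cell satisfying both the PVBC and CCKC equivalence conditions
        kb.neurons["fix:both"] = mk_neuron(
            "fix:both",
            [P("hasInstanceInTaxon", "ilxtr:Mus-musculus"),
             P("hasSomaLocatedIn", "ilxtr:neocortex"),
             P("hasMorphologicalPhenotype", "ilxtr:BasketPhenotype"),
             P("hasNeurotransmitterPhenotype", "ilxtr:GABA"),
             P("hasCircuitRolePhenotype", "ilxtr:IntrinsicRole"),
             P("hasExpressionPhenotype", "fix:PV-cre"),
             P("hasExpressionPhenotype", "ilxtr:Cck"),
             P("hasExpressionPhenotype", "ilxtr:VIP")],
        )
        vs = check_consistency(kb)
        assert any(
            v.code == "disjoint-classification" and v.subject == "fix:both"
            for v in vs
        )

    def test_disjoint_values_detected(self, paper_kb):
        kb = paper_kb.copy()
        kb.disjointness.append(
            DisjointnessAxiom(
                frozenset({"ilxtr:PV", "ilxtr:VIP"}), "made-up for test"
            )
        )
        vs = check_consistency(kb)
        # npokb:112 and friends assert both PV and VIP
        assert any(
            v.code == "disjoint-values" and v.subject == "npokb:112"
            for v in vs
        )
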