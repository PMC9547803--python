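"""Query grammar, evaluation semantics, and the competency suite."""

import itertools

import pytest

from conftest import naive_entails, naive_matches_positive

from phenoneuron.core_model import KnowledgeBase
from phenoneuron.fixtures import SynthConfig, gen_synthetic_kb
from phenoneuron.query import (
    And,
    Named,
    Not,
    Or,
    QuerySyntaxError,
    Some,
    UnresolvedNameError,
    VOr,
    VPartOf,
    VTerm,
    evaluate,
    parse_query,
    run_competency_suite,
)


class TestParse:
    def test_simple_some(self):
        q = parse_query("hasPhenotype some 'parvalbumin (indicator)'")
        assert q == Some("hasPhenotype", VTerm("parvalbumin (indicator)"))

    def test_nested_and_or(self):
        q = parse_query(
            "(NeuronHuang2017 or NeuronMarkram2015) and "
            "hasPhenotype some 'Basket phenotype'"
        )
        assert q == And((
            Or((Named("NeuronHuang2017"), Named("NeuronMarkram2015"))),
            Some("hasPhenotype", VTerm("Basket phenotype")),
        ))

    def test_part_of_value_expression(self):
        q = parse_query(
            "hasSomaLocatedIn some (neocortex or 'part of' some neocortex)"
        )
        assert q == Some(
            "hasSomaLocatedIn",
            VOr((VTerm("neocortex"), VPartOf("neocortex"))),
        )

    def test_not(self):
        q = parse_query("not hasPhenotype some GABA")
        assert q == Not(Some("hasPhenotype", VTerm("GABA")))

    @pytest.mark.parametrize("bad", [
        "hasPhenotype some",
        "and hasPhenotype some X",
        "(hasPhenotype some X",
        "hasPhenotype some X )",
        "hasPhenotype some 'unterminated",
    ])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(QuerySyntaxError) as exc:
            parse_query(bad)
        assert "position" in str(exc.value)

    def test_whitespace_insensitive(self):
        a = parse_query("hasPhenotype   some    GABA")
        b = parse_query("hasPhenotype some GABA")
        assert a == b


class TestEvaluate:
    def test_cq1_membership(self, paper_kb):
        got = evaluate(paper_kb, "hasPhenotype some 'parvalbumin (indicator)'")
        assert {"nifext:56", "npokb:43", "npokb:112", "npokb:434",
                "npokb:59", "npokb:65"} <= set(got)
        assert "npokb:73" not in got  # explicitly PV-negative
        assert "npokb:75" not in got

    def test_results_sorted_by_curie(self, paper_kb):
        got = evaluate(paper_kb, "hasPhenotype some 'parvalbumin (indicator)'")
        assert got == sorted(got)

    def test_indicator_with_no_members_matches_nothing(self, paper_kb):
        from phenoneuron.core_model import PhenotypeIndicator

        kb = paper_kb.copy()
        kb.indicators = dict(kb.indicators)
        kb._indicator_of = None
        kb.add_indicator(PhenotypeIndicator(
            "npokb:vacant-indicator", "VAC", frozenset(), name="vacant"
        ))
        assert evaluate(kb, "hasPhenotype some 'vacant (indicator)'") == []

    def test_cq2_every_result_is_cortical(self, paper_kb):
        got = evaluate(
            paper_kb,
            "hasPhenotype some 'somatostatin (indicator)' and "
            "hasSomaLocatedIn some (neocortex or 'part of' some neocortex)",
        )
        assert got
        inside = {"ilxtr:neocortex"} | paper_kb.hierarchy.part_descendants(
            "ilxtr:neocortex"
        )
        for nid in got:
            somas = {
                p.value
                for p in paper_kb.neurons[nid].all_phenotypes()
                if getattr(p, "predicate", None) == "hasSomaLocatedIn"
                and hasattr(p, "value")
            }
            assert somas & inside or any(
                set(lp.members) <= inside
                for lp in paper_kb.neurons[nid].all_phenotypes()
                if getattr(lp, "operator", None)
            )

    def test_cq3_exact_basket_set(self, paper_kb):
        got = evaluate(
            paper_kb,
            "(NeuronHuang2017 or NeuronMarkram2015) and "
            "hasPhenotype some 'Basket phenotype'",
        )
        assert got == ["npokb:112", "npokb:114", "npokb:40", "npokb:43",
                       "npokb:59", "npokb:65", "npokb:73", "npokb:75"]

    def test_basket_subtype_soundness_exhaustive(self, paper_kb):
        """Any fixture neuron with a basket-family morphology matches the
        basket-phenotype query."""
        basket_family = {
            "ilxtr:BasketPhenotype", "ilxtr:NestBasketPhenotype",
            "ilxtr:LargeBasketPhenotype", "ilxtr:SmallBasketPhenotype",
        }
        got = set(evaluate(paper_kb, "hasPhenotype some 'Basket phenotype'"))
        for nid, n in paper_kb.neurons.items():
            has_basket = any(
                getattr(p, "value", None) in basket_family
                and not p.negative
                for p in n.all_phenotypes()
            )
            if has_basket:
                assert nid in got

    def test_unresolved_name_errors(self, paper_kb):
        with pytest.raises(UnresolvedNameError):
            evaluate(paper_kb, "hasPhenotype some 'no such thing'")
        with pytest.raises(UnresolvedNameError):
            evaluate(paper_kb, "hasNoSuchPredicate some GABA")

    def test_named_neuron_class_includes_subsumees(self, paper_kb):
        got = evaluate(paper_kb, "nifext:55")
        assert set(got) == {"nifext:55", "npokb:111", "npokb:42", "npokb:89"}


class TestSetAlgebra:
    ATOMS = [
        "hasPhenotype some 'parvalbumin (indicator)'",
        "hasPhenotype some 'Basket phenotype'",
        "NeuronMarkram2015",
        "hasSomaLocatedIn some ('part of' some neocortex)",
    ]

    @pytest.mark.parametrize("a,b", list(itertools.combinations(ATOMS, 2)))
    def test_and_or_not_laws(self, paper_kb, a, b):
        universe = set(paper_kb.neurons)
        ea = set(evaluate(paper_kb, a))
        eb = set(evaluate(paper_kb, b))
        assert set(evaluate(paper_kb, f"({a}) and ({b})")) == ea & eb
        assert set(evaluate(paper_kb, f"({a}) or ({b})")) == ea | eb
        assert set(evaluate(paper_kb, f"not ({a})")) == universe - ea

    def test_query_monotone_under_kb_growth(self, paper_kb):
        """Enlarging the KB never shrinks a not-free query's result."""
        from phenoneuron.core_model import neuron as mk_neuron
        from phenoneuron.fixtures import P

        grown = paper_kb.copy()
        grown.neurons = dict(grown.neurons)
        grown.neurons["fix:extra"] = mk_neuron(
            "fix:extra",
            [P("hasExpressionPhenotype", "ilxtr:PV"),
             P("hasSomaLocatedIn", "ilxtr:S1")],
        )
        for text in self.ATOMS:
            assert set(evaluate(paper_kb, text)) <= set(evaluate(grown, text))


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_some_query_equals_naive_scan(self, seed):
        kb = gen_synthetic_kb(
            SynthConfig(seed=seed, n_neurons=10, n_planted_cuts=2,
                        modality_relabel_rate=0.25)
        )
        ind = sorted(kb.indicators)[0]
        region = "fix:region-0"
        queries = [
            ("hasPhenotype", kb.indicators[ind].class_label),
            ("hasSomaLocatedIn", kb.terms[region].label),
        ]
        for pred, label in queries:
            got = set(evaluate(kb, f"{pred} some '{label}'"))
            want = set()
            for nid, n in kb.neurons.items():
                curie = (
                    ind if label.endswith(" (indicator)") else region
                )
                if naive_matches_positive(kb, n, pred, curie):
                    want.add(nid)
            assert got == want


class TestCompetencySuite:
    def test_fixture_counts(self, paper_kb):
        rep = run_competency_suite(paper_kb)
        assert rep.counts == {"CQ1": 7, "CQ2": 11, "CQ3": 8, "CQ4": 3}
        assert rep.martinotti_cut == "nifext:55"
        assert rep.cq4_classified == ["npokb:111", "npokb:42", "npokb:89"]

    def test_empty_kb_gives_empty_results(self):
        rep = run_competency_suite(KnowledgeBase())
        assert all(v == [] for v in rep.results.values())
        assert rep.cq4_classified == []

    def test_summary_is_tabular(self, paper_kb):
        text = run_competency_suite(paper_kb).summary()
        lines = text.splitlines()
        assert len(lines) == 5
        assert all(len(line.split("\t")) == 3 for line in lines)
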