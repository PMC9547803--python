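import pytest
from hypothesis import settings

from phenoneuron.fixtures import SynthConfig, build_paper_kb, gen_synthetic_kb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def paper_kb():
    return build_paper_kb()


@pytest.fixture
def synth_kb():
    def make(seed=0, **kw):
        return gen_synthetic_kb(SynthConfig(seed=seed, **kw))

    return make


# ---------------------------------------------------------------------------
# Independent brute-force reasoner oracle.
#
# Deliberately written as plain edge-scanning fixpoint loops over the raw
# KB structures, sharing no closure code with phenoneuron.reasoner, so the
# two can disagree.
# ---------------------------------------------------------------------------

from phenoneuron.core_model import LogicalPhenotype, Phenotype  # noqa: E402

_LOCATION = ("hasSomaLocatedIn", "hasAxonLocatedIn")


def naive_value_closure(kb, pred, value):
    vals = {value}
    while True:
        new = set(vals)
        for v in list(vals):
            for ind in kb.indicators.values():
                if v in ind.members:
                    new.add(ind.id)
            if pred in _LOCATION:
                for child, parent in kb.hierarchy.part_of_edges:
                    if child == v:
                        new.add(parent)
            for sub, sup in kb.hierarchy.subtype_edges:
                if sub == v:
                    new.add(sup)
        if new == vals:
            return vals
        vals = new


def naive_pred_closure(kb, pred):
    preds = {pred}
    while True:
        new = set(preds)
        for p in list(preds):
            d = kb.predicates.get(p)
            if d is not None and d.parent:
                new.add(d.parent)
        if new == preds:
            return preds
        preds = new


def naive_atoms(kb, n):
    """(positives, negatives, unions) asserted by a neuron, un-expanded."""
    pos, neg, unions = set(), set(), []
    for ph in n.all_phenotypes():
        if isinstance(ph, LogicalPhenotype):
            if ph.operator == "intersectionOf":
                for m in ph.members:
                    pos.add((ph.predicate, m))
            else:
                unions.append((ph.predicate, ph.members))
        elif ph.negative:
            neg.add((ph.predicate, ph.value))
        else:
            pos.add((ph.predicate, ph.value))
    return pos, neg, unions


def naive_matches_positive(kb, n, pred, value):
    pos, _neg, unions = naive_atoms(kb, n)
    for p, v in pos:
        if pred in naive_pred_closure(kb, p) and value in naive_value_closure(
            kb, p, v
        ):
            return True
    for p, members in unions:
        if pred in naive_pred_closure(kb, p) and all(
            value in naive_value_closure(kb, p, m) for m in members
        ):
            return True
    return False


def naive_indicator(kb, value):
    for ind in kb.indicators.values():
        if value == ind.id or value in ind.members:
            return ind.id
    return None


def naive_entails(kb, sub, conditions):
    _pos, _neg, unions = naive_atoms(kb, sub)
    for c in conditions:
        if isinstance(c, LogicalPhenotype):
            if c.operator == "intersectionOf":
                if not all(
                    naive_matches_positive(kb, sub, c.predicate, m)
                    for m in c.members
                ):
                    return False
            else:
                if not any(
                    naive_matches_positive(kb, sub, c.predicate, m)
                    for m in c.members
                ):
                    covered = False
                    for p, members in unions:
                        if c.predicate in naive_pred_closure(kb, p) and all(
                            any(
                                m in naive_value_closure(kb, p, am)
                                for m in c.members
                            )
                            for am in members
                        ):
                            covered = True
                    if not covered:
                        return False
        elif c.negative:
            want = naive_indicator(kb, c.value) or c.value
            ok = False
            for a in sub.asserted_negatives():
                have = naive_indicator(kb, a.value) or a.value
                if have == want and c.predicate in naive_pred_closure(
                    kb, a.predicate
                ):
                    ok = True
            if not ok:
                return False
        else:
            if not naive_matches_positive(kb, sub, c.predicate, c.value):
                return False
    return True
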