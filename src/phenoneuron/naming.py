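"""Deterministic generation of human-readable neuron names.

Every neuron class carries several labels, all derived mechanically from its
phenotype bag so that equal bags always yield equal names:

* ``normalized`` (the rdfs:label analogue) — molecular tokens are indicator
  short names, regardless of how the molecule was measured;
* ``local`` — molecular tokens keep the measured form (gene symbol, protein
  name, transgenic line), preserving each source's own nomenclature;
* ``orig`` — the investigator's/common name, passed through when provided;
* ``pref`` (skos:prefLabel analogue) — ``orig`` when present, otherwise the
  normalized label, so no neuron lacks a preferred label.

Name assembly follows the ordered-taxonomy convention: species first, then
anatomy coarse-to-fine, then morphology, physiology, molecules, and a
circuit-role suffix ("intrinsic neuron" / "projection neuron" / "neuron"),
with an optional provenance tag like "(Markram2015)" at the end.  Positive
molecular tokens are prefixed "+", negatives "-" (ASCII hyphen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_model import (
    KnowledgeBase,
    LogicalPhenotype,
    NeuronType,
    Phenotype,
    PhenotypeBearer,
    UnresolvedReferenceError,
    canonical_bag,
    resolve_indicator,
)

__all__ = ["LabelSet", "gen_label", "label_set", "indicator_display"]

#: Circuit-role value display -> suffix words.  One global constant; the
#: printed tables waver between "intrinsic neuron" and "interneuron" and we
#: standardize on the former.
CIRCUIT_ROLE_SUFFIX = {
    "intrinsic": "intrinsic neuron",
    "projection": "projection neuron",
    "sensory": "sensory neuron",
}
DEFAULT_SUFFIX = "neuron"


@dataclass(frozen=True)
class LabelSet:
    normalized: str
    local: str
    orig: Optional[str]
    pref: str


def _token(kb: KnowledgeBase, value: str, mode: str) -> str:
    """Display token for one phenotype value curie.

    In normalized mode any molecular term that belongs to an indicator is
    replaced by the indicator's short name; local mode keeps the measured
    term's own display form.  An indicator curie itself always renders as
    its short name.
    """
    if value in kb.indicators:
        return kb.indicators[value].short_name
    if mode == "normalized":
        ind = resolve_indicator(kb, value)
        if ind is not None:
            return kb.indicators[ind].short_name
    if value not in kb.terms:
        raise UnresolvedReferenceError([value], context="label generation")
    return kb.terms[value].display


def gen_label(kb: KnowledgeBase, n: NeuronType, mode: str = "local") -> str:
    """Assemble the deterministic name for a neuron from its canonical bag.

    ``mode`` is "normalized" or "local" and only affects molecular tokens.
    The bag order comes from :func:`canonical_bag`, so the result is
    invariant under phenotype insertion order.
    """
    if mode not in ("normalized", "local"):
        raise ValueError(f"unknown label mode {mode!r}")
    tokens: list[str] = []
    suffix = DEFAULT_SUFFIX
    for p in canonical_bag(n, kb):
        dim = kb.predicate_dimension(p.predicate)
        if dim == "circuit-role":
            if isinstance(p, Phenotype) and not p.negative:
                word = _token(kb, p.value, mode)
                suffix = CIRCUIT_ROLE_SUFFIX.get(word, word + " neuron")
            continue
        tok = _render(kb, p, dim, mode)
        if tok:
            tokens.append(tok)
    tokens.append(suffix)
    if n.source_tag:
        tokens.append(f"({n.source_tag})")
    return " ".join(tokens)


def _render(
    kb: KnowledgeBase, p: PhenotypeBearer, dim: str, mode: str
) -> str:
    if isinstance(p, LogicalPhenotype):
        members = [_token(kb, m, mode) for m in p.members]
        if dim == "molecular":
            inner = " ".join("+ " + m for m in members)
        else:
            inner = " ".join(members)
        return f"({p.operator} {inner})"
    tok = _token(kb, p.value, mode)
    if p.predicate == "hasAxonLocatedIn":
        return f"(with-axon-in {tok})"
    if dim == "molecular":
        return ("-" if p.negative else "+ ") + tok
    if p.negative:
        return "-" + tok
    return tok


def label_set(kb: KnowledgeBase, n: NeuronType) -> LabelSet:
    normalized = gen_label(kb, n, "normalized")
    local = gen_label(kb, n, "local")
    pref = n.orig_label if n.orig_label else normalized
    return LabelSet(normalized=normalized, local=local, orig=n.orig_label, pref=pref)


def indicator_display(
    kb: KnowledgeBase, ind: str, context: str = "label"
) -> str:
    """Display form of an indicator: short name inside neuron labels,
    short name + " (indicator)" as the indicator class's own label."""
    if ind not in kb.indicators:
        raise UnresolvedReferenceError([ind], context="unknown indicator")
    indicator = kb.indicators[ind]
    if context == "class":
        return indicator.class_label
    if context == "label":
        return indicator.short_name
    raise ValueError(f"unknown context {context!r}")
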