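"""Reference knowledge base and synthetic KB generator.

``build_paper_kb`` encodes a compact cortical-interneuron knowledge base:
two common-usage types (neocortex basket cell, neocortex Martinotti cell),
rat interneuron types from the Blue Brain somatosensory-cortex taxonomy,
the six mouse GABAergic classes of the Huang-lab expression taxonomy
(PVBC, CHC, CCKC, MNC, ISC, LPC), and mouse cell-type records in the style
of the Allen Cell Types database (transgenic-line evidence, dendrite-only
morphology).  Bags are transcribed from the published display names; the
token -> (predicate, value) transcription is tabulated below so the mapping
is auditable.

``gen_synthetic_kb`` emulates the same shape of data with controlled
structure: a random anatomical partonomy, indicators partitioning gene/
protein/transgene variants of each marker, evidence-based bags, *planted*
CUT subsumptions (each CUT's bag is a generalized subset of one EBT's bag,
so the true inferred edges are known by construction), modality relabeling
noise (swapping a measured molecule for a sibling of the same indicator),
and morphology censoring (emulating records that describe dendrites but
assert no whole-cell morphology).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core_model import (
    DIMENSIONS,
    DisjointnessAxiom,
    KnowledgeBase,
    LogicalPhenotype,
    NeuronType,
    Phenotype,
    PhenotypeIndicator,
    PredicateDef,
    add_neuron,
    neuron,
)

__all__ = [
    "SynthConfig",
    "standard_predicates",
    "build_paper_kb",
    "gen_synthetic_kb",
    "censor_dimension",
]


def P(pred: str, value: str, neg: bool = False) -> Phenotype:
    return Phenotype(pred, value, "negative" if neg else "positive")


def standard_predicates(kb: KnowledgeBase) -> None:
    """Install the standard predicate tree (all rooted at hasPhenotype)."""
    rows = [
        ("hasPhenotype", None, None),
        ("hasInstanceInTaxon", "hasPhenotype", "taxonomic"),
        ("hasBiologicalSex", "hasPhenotype", "sex"),
        ("hasSomaLocatedIn", "hasPhenotype", "anatomical"),
        ("hasAxonLocatedIn", "hasPhenotype", "anatomical"),
        ("hasMorphologicalPhenotype", "hasPhenotype", "morphological"),
        ("hasElectrophysiologicalPhenotype", "hasPhenotype", "physiological"),
        ("hasMolecularPhenotype", "hasPhenotype", "molecular"),
        ("hasNeurotransmitterPhenotype", "hasMolecularPhenotype", "molecular"),
        ("hasExpressionPhenotype", "hasMolecularPhenotype", "molecular"),
        ("hasEpigeneticPhenotype", "hasMolecularPhenotype", "molecular"),
        ("hasCircuitRolePhenotype", "hasPhenotype", "circuit-role"),
        ("hasConnectionPhenotype", "hasPhenotype", "connection"),
        ("hasProjectionPhenotype", "hasPhenotype", "projection-target"),
    ]
    for pid, parent, dim in rows:
        kb.add_predicate(PredicateDef(pid, dim, parent))


# Transcription table, label token -> (predicate, value curie).  Kept as a
# module constant so the label-to-bag mapping used below is auditable.
TOKEN_MAP = {
    "Mammalia": ("hasInstanceInTaxon", "ilxtr:Mammalia"),
    "Rattus norvegicus": ("hasInstanceInTaxon", "ilxtr:Rattus-norvegicus"),
    "Mus musculus": ("hasInstanceInTaxon", "ilxtr:Mus-musculus"),
    "female": ("hasBiologicalSex", "ilxtr:female"),
    "neocortex": ("hasSomaLocatedIn", "ilxtr:neocortex"),
    "S1": ("hasSomaLocatedIn", "ilxtr:S1"),
    "L2/3": ("hasSomaLocatedIn", "ilxtr:L2-3"),
    "VISrl2_3": ("hasSomaLocatedIn", "ilxtr:VISrl2_3"),
    "VISl5": ("hasSomaLocatedIn", "ilxtr:VISl5"),
    "VISp6a": ("hasSomaLocatedIn", "ilxtr:VISp6a"),
    "RSPd2_3": ("hasSomaLocatedIn", "ilxtr:RSPd2_3"),
    "left cerebral hemisphere": ("hasSomaLocatedIn", "ilxtr:left-hemisphere"),
    "right cerebral hemisphere": ("hasSomaLocatedIn", "ilxtr:right-hemisphere"),
    "cortical layer I": ("hasAxonLocatedIn", "ilxtr:L1"),
    "Basket": ("hasMorphologicalPhenotype", "ilxtr:BasketPhenotype"),
    "Nest basket": ("hasMorphologicalPhenotype", "ilxtr:NestBasketPhenotype"),
    "Large basket": ("hasMorphologicalPhenotype", "ilxtr:LargeBasketPhenotype"),
    "Small basket": ("hasMorphologicalPhenotype", "ilxtr:SmallBasketPhenotype"),
    "Martinotti": ("hasMorphologicalPhenotype", "ilxtr:MartinottiPhenotype"),
    "Double bouquet": ("hasMorphologicalPhenotype", "ilxtr:DoubleBouquetPhenotype"),
    "Chandelier": ("hasMorphologicalPhenotype", "ilxtr:ChandelierPhenotype"),
    "Apical Dendrite": ("hasMorphologicalPhenotype", "ilxtr:ApicalDendrite"),
    "Spiny": ("hasMorphologicalPhenotype", "ilxtr:SpinyDendrite"),
    "Fast spiking": ("hasElectrophysiologicalPhenotype", "ilxtr:FastSpiking"),
    "Regular spiking non pyramidal": (
        "hasElectrophysiologicalPhenotype",
        "ilxtr:RSNP",
    ),
    "GABA": ("hasNeurotransmitterPhenotype", "ilxtr:GABA"),
    "PV": ("hasExpressionPhenotype", "ilxtr:PV"),
    "SST": ("hasExpressionPhenotype", "ilxtr:SST"),
    "calbindin": ("hasExpressionPhenotype", "ilxtr:calbindin"),
    "CR": ("hasExpressionPhenotype", "ilxtr:CR"),
    "NPY": ("hasExpressionPhenotype", "ilxtr:NPY"),
    "VIP": ("hasExpressionPhenotype", "ilxtr:VIP"),
    "intrinsic": ("hasCircuitRolePhenotype", "ilxtr:IntrinsicRole"),
    "projection": ("hasCircuitRolePhenotype", "ilxtr:ProjectionRole"),
}


def build_paper_kb() -> KnowledgeBase:
    kb = KnowledgeBase()
    kb.metadata["id"] = "phenoneuron-reference-kb"
    standard_predicates(kb)
    T = kb.term

    # taxa and sex
    T("ilxtr:Mammalia", "Mammalia")
    T("ilxtr:Rattus-norvegicus", "Rattus norvegicus")
    T("ilxtr:Mus-musculus", "Mus musculus")
    T("ilxtr:female", "female")
    kb.hierarchy.add_subtype("ilxtr:Rattus-norvegicus", "ilxtr:Mammalia")
    kb.hierarchy.add_subtype("ilxtr:Mus-musculus", "ilxtr:Mammalia")

    # anatomy: atlas regions and layers under neocortex under cerebral cortex
    T("ilxtr:cerebral-cortex", "cerebral cortex")
    T("ilxtr:neocortex", "neocortex")
    for curie, label in [
        ("ilxtr:S1", "S1"),
        ("ilxtr:VISrl2_3", "VISrl2_3"),
        ("ilxtr:VISl5", "VISl5"),
        ("ilxtr:VISp6a", "VISp6a"),
        ("ilxtr:RSPd2_3", "RSPd2_3"),
        ("ilxtr:L2-3", "L2/3"),
        ("ilxtr:L1", "cortical layer I"),
        ("ilxtr:EGL", "EGL"),
        ("ilxtr:L3", "L3"),
        ("ilxtr:L5", "L5"),
    ]:
        T(curie, label)
        kb.hierarchy.add_part_of(curie, "ilxtr:neocortex")
    kb.hierarchy.add_part_of("ilxtr:neocortex", "ilxtr:cerebral-cortex")
    T("ilxtr:left-hemisphere", "left cerebral hemisphere")
    T("ilxtr:right-hemisphere", "right cerebral hemisphere")

    # morphology, with the basket family as subtypes of the basket phenotype
    T("ilxtr:BasketPhenotype", "Basket phenotype", "Basket")
    T("ilxtr:NestBasketPhenotype", "Nest basket phenotype", "Nest basket")
    T("ilxtr:LargeBasketPhenotype", "Large basket phenotype", "Large basket")
    T("ilxtr:SmallBasketPhenotype", "Small basket phenotype", "Small basket")
    for sub in ("Nest", "Large", "Small"):
        kb.hierarchy.add_subtype(
            f"ilxtr:{sub}BasketPhenotype", "ilxtr:BasketPhenotype"
        )
    T("ilxtr:MartinottiPhenotype", "Martinotti phenotype", "Martinotti")
    T("ilxtr:DoubleBouquetPhenotype", "Double bouquet phenotype", "Double bouquet")
    T("ilxtr:ChandelierPhenotype", "Chandelier phenotype", "Chandelier")
    T("ilxtr:ApicalDendrite", "Apical Dendrite")
    T("ilxtr:SpinyDendrite", "Spiny")
    T("ilxtr:SparseDendrite", "sparse")

    # Petilla electrophysiology
    T("ilxtr:FastSpiking", "Fast spiking")
    T("ilxtr:RSNP", "Regular spiking non pyramidal")
    for c, l in [("AC", "AC"), ("NAC", "NAC"), ("IR", "IR"),
                 ("b", "b"), ("c", "c"), ("d", "d")]:
        T(f"ilxtr:petilla-{c}", l)

    # molecules: neurotransmitter, proteins, genes, transgenic lines
    T("ilxtr:GABA", "GABA")
    T("ilxtr:GABAR", "GABAR")
    T("ilxtr:GluR", "GluR")
    T("ilxtr:PV", "PV")
    T("ilxtr:Pvalb", "Pvalb")
    T("fix:PV-cre", "PV-cre")
    T("fix:Pvalb-T2A-FlpO", "Pvalb-T2A-FlpO")
    T("ilxtr:SST", "SST")
    T("ilxtr:Sst-gene", "Sst")
    T("ilxtr:SOM", "SOM")
    T("fix:Sst-IRES-Cre", "Sst-IRES-Cre")
    T("fix:Sst-IRES-FlpO", "Sst-IRES-FlpO")
    T("ilxtr:calbindin", "calbindin")
    T("ilxtr:CR", "CR")
    T("ilxtr:NPY", "NPY")
    T("ilxtr:VIP", "VIP")
    T("ilxtr:NOS1", "NOS1")
    T("ilxtr:Cck", "Cck")
    # reporter/driver lines that belong to no indicator
    T("fix:Vipr2-IRES2-Cre", "Vipr2-IRES2-Cre")
    T("fix:Nos1-CreERT2", "Nos1-CreERT2")
    T("fix:Ai65", "Ai65(RCFL-tdT)")
    T("fix:Ai14", "Ai14(RCL-tdT)")

    kb.add_indicator(
        PhenotypeIndicator(
            "npokb:parvalbumin-indicator",
            "PV",
            frozenset(
                {"ilxtr:PV", "ilxtr:Pvalb", "fix:PV-cre", "fix:Pvalb-T2A-FlpO"}
            ),
            name="parvalbumin",
        )
    )
    kb.add_indicator(
        PhenotypeIndicator(
            "npokb:somatostatin-indicator",
            "Sst",
            frozenset(
                {
                    "ilxtr:SST",
                    "ilxtr:Sst-gene",
                    "ilxtr:SOM",
                    "fix:Sst-IRES-Cre",
                    "fix:Sst-IRES-FlpO",
                }
            ),
            name="somatostatin",
        )
    )

    T("ilxtr:IntrinsicRole", "intrinsic")
    T("ilxtr:ProjectionRole", "projection")

    soma, morph, ephys, nt, expr, mol, role, taxon, sex = (
        "hasSomaLocatedIn",
        "hasMorphologicalPhenotype",
        "hasElectrophysiologicalPhenotype",
        "hasNeurotransmitterPhenotype",
        "hasExpressionPhenotype",
        "hasMolecularPhenotype",
        "hasCircuitRolePhenotype",
        "hasInstanceInTaxon",
        "hasBiologicalSex",
    )

    # -- common usage types (positive-only equivalence) ----------------------

    add_neuron(kb, neuron(
        "nifext:56",
        equivalent=[
            P(taxon, "ilxtr:Mammalia"),
            P(soma, "ilxtr:neocortex"),
            P(morph, "ilxtr:BasketPhenotype"),
            P(mol, "npokb:parvalbumin-indicator"),
            P(nt, "ilxtr:GABA"),
            P(role, "ilxtr:IntrinsicRole"),
        ],
        subclass=[P(soma, "ilxtr:L2-3")],
        source="NeuronCUT",
        orig_label="Neocortex basket cell",
    ))

    add_neuron(kb, neuron(
        "nifext:55",
        equivalent=[
            P(taxon, "ilxtr:Mammalia"),
            P(soma, "ilxtr:neocortex"),
            P(morph, "ilxtr:MartinottiPhenotype"),
            P(mol, "npokb:somatostatin-indicator"),
            P(nt, "ilxtr:GABA"),
            P(role, "ilxtr:IntrinsicRole"),
        ],
        subclass=[
            LogicalPhenotype(
                "unionOf", soma, ("ilxtr:EGL", "ilxtr:L3", "ilxtr:L5")
            ),
            P("hasAxonLocatedIn", "ilxtr:L1"),
            P(mol, "ilxtr:GABAR"),
            P(mol, "ilxtr:GluR"),
        ],
        source="NeuronCUT",
        orig_label="Neocortex Martinotti cell",
    ))

    # -- Blue Brain (rat S1) evidence-based types ----------------------------

    def markram(nid, morph_curie, etype, fs, pos, negs, orig):
        eq = [
            P(taxon, "ilxtr:Rattus-norvegicus"),
            P(soma, "ilxtr:S1"),
            P(nt, "ilxtr:GABA"),
            P(role, "ilxtr:IntrinsicRole"),
        ]
        if morph_curie:
            eq.append(P(morph, morph_curie))
        if etype:
            eq.append(LogicalPhenotype(
                "intersectionOf",
                ephys,
                tuple(f"ilxtr:petilla-{m}" for m in etype),
            ))
        if fs:
            eq.append(P(ephys, fs))
        eq += [P(expr, v) for v in pos]
        eq += [P(expr, v, neg=True) for v in negs]
        add_neuron(kb, neuron(
            nid, eq, source="NeuronMarkram2015",
            orig_label=orig, source_tag="Markram2015",
        ))

    CALB, CRi, NPYi, PVi, SSTi, VIPi = (
        "ilxtr:calbindin", "ilxtr:CR", "ilxtr:NPY",
        "ilxtr:PV", "ilxtr:SST", "ilxtr:VIP",
    )
    markram("npokb:112", "ilxtr:NestBasketPhenotype", ("AC", "b"),
            "ilxtr:FastSpiking",
            [CALB, CRi, NPYi, PVi, VIPi], [SSTi], "Nest basket cell")
    markram("npokb:65", "ilxtr:NestBasketPhenotype", ("AC", "b"),
            "ilxtr:FastSpiking",
            [CALB, CRi, NPYi, PVi, VIPi], [SSTi], "Nest basket cell")
    markram("npokb:59", "ilxtr:LargeBasketPhenotype", ("AC", "b"),
            "ilxtr:FastSpiking",
            [CALB, CRi, NPYi, PVi, VIPi], [SSTi], "Large basket cell")
    markram("npokb:73", "ilxtr:SmallBasketPhenotype", ("AC", "c"),
            "ilxtr:FastSpiking",
            [CALB, NPYi, SSTi, VIPi], [CRi, PVi], "Small basket cell")
    markram("npokb:75", "ilxtr:SmallBasketPhenotype", ("NAC", "d"),
            "ilxtr:FastSpiking",
            [CALB, NPYi, SSTi, VIPi], [CRi, PVi], "Small basket cell")
    markram("npokb:89", "ilxtr:MartinottiPhenotype", ("AC", "b"),
            "ilxtr:RSNP",
            [CALB, NPYi, SSTi], [CRi, PVi, VIPi], "Martinotti cell")
    markram("npokb:87", "ilxtr:DoubleBouquetPhenotype", ("IR", "c"),
            "ilxtr:RSNP",
            [CALB, CRi, SSTi, VIPi], [NPYi, PVi], "Double bouquet cell")
    # morphological supertypes (no physiology/molecular profile of their own,
    # except the somatostatin that defines the Martinotti group)
    markram("npokb:114", "ilxtr:SmallBasketPhenotype", None, None,
            [], [], "Small basket neuron")
    markram("npokb:111", "ilxtr:MartinottiPhenotype", None, None,
            [SSTi], [], "Martinotti neuron")
    markram("npokb:109", "ilxtr:DoubleBouquetPhenotype", None, None,
            [], [], "Double bouquet neuron")

    # -- Huang-lab (mouse neocortex) expression types ------------------------

    def huang(nid, morph_curie, pos, role_curie, orig):
        eq = [
            P(taxon, "ilxtr:Mus-musculus"),
            P(soma, "ilxtr:neocortex"),
            P(nt, "ilxtr:GABA"),
            P(role, role_curie),
        ]
        if morph_curie:
            eq.append(P(morph, morph_curie))
        eq += [P(expr, v) for v in pos]
        add_neuron(kb, neuron(
            nid, eq, source="NeuronHuang2017",
            orig_label=orig, source_tag="Huang2017",
        ))

    huang("npokb:43", "ilxtr:BasketPhenotype", ["fix:PV-cre"],
          "ilxtr:IntrinsicRole", "PVBC cortical neuron")
    huang("npokb:40", "ilxtr:BasketPhenotype", ["ilxtr:Cck", "ilxtr:VIP"],
          "ilxtr:IntrinsicRole", "CCKC neuron")
    huang("npokb:42", "ilxtr:MartinottiPhenotype", ["ilxtr:CR", "ilxtr:SST"],
          "ilxtr:IntrinsicRole", "MNC neuron")
    huang("npokb:45", None, ["ilxtr:NOS1", "ilxtr:SST"],
          "ilxtr:ProjectionRole", "LPC neuron")
    huang("fix:CHC", "ilxtr:ChandelierPhenotype", ["ilxtr:Pvalb"],
          "ilxtr:IntrinsicRole", "CHC neuron")
    huang("fix:ISC", None, ["ilxtr:CR", "ilxtr:VIP"],
          "ilxtr:IntrinsicRole", "ISC neuron")

    # marker-group disjointness (PV-type vs VIP-type classes)
    for a in ("npokb:43", "fix:CHC"):
        for b in ("npokb:40", "fix:ISC"):
            kb.disjointness.append(DisjointnessAxiom(
                frozenset({a, b}),
                provenance="Paul et al. 2017, Fig 1b marker groups",
            ))

    # -- Allen-style (mouse) cell-type records -------------------------------

    def allen(nid, hemi, region, spiny_logical, negs, lines):
        eq = [
            P(taxon, "ilxtr:Mus-musculus"),
            P(sex, "ilxtr:female"),
            P(soma, hemi),
            P(soma, region),
        ]
        eq += [P(morph, v, neg=True) for v in negs]
        if spiny_logical:
            eq.append(LogicalPhenotype(
                "intersectionOf", morph,
                ("ilxtr:SpinyDendrite", "ilxtr:SparseDendrite"),
            ))
        eq += [P(expr, v) for v in lines]
        add_neuron(kb, neuron(
            nid, eq, source="NeuronACT", source_tag="AllenCT",
        ))

    allen("npokb:434", "ilxtr:left-hemisphere", "ilxtr:VISrl2_3", False,
          ["ilxtr:ApicalDendrite", "ilxtr:SpinyDendrite"],
          ["fix:Pvalb-T2A-FlpO", "fix:Vipr2-IRES2-Cre", "fix:Ai65"])
    allen("npokb:296", "ilxtr:right-hemisphere", "ilxtr:RSPd2_3", True,
          ["ilxtr:ApicalDendrite"],
          ["fix:Sst-IRES-FlpO", "fix:Nos1-CreERT2", "fix:Ai65"])
    allen("npokb:415", "ilxtr:left-hemisphere", "ilxtr:VISl5", False,
          ["ilxtr:ApicalDendrite", "ilxtr:SpinyDendrite"],
          ["fix:Sst-IRES-Cre", "fix:Ai14"])
    allen("npokb:412", "ilxtr:right-hemisphere", "ilxtr:VISp6a", True,
          ["ilxtr:ApicalDendrite"],
          ["fix:Sst-IRES-Cre", "fix:Ai14"])

    return kb


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic KB generator; same seed, same KB."""

    seed: int = 0
    n_neurons: int = 20
    n_molecular_terms: int = 18
    n_regions: int = 12
    partonomy_depth: int = 3
    modality_relabel_rate: float = 0.0
    censor_morphology_rate: float = 0.0
    n_planted_cuts: int = 3

    def __post_init__(self) -> None:
        for name in ("modality_relabel_rate", "censor_morphology_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_neurons",
            "n_molecular_terms",
            "n_regions",
            "partonomy_depth",
            "n_planted_cuts",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_MODALITIES = ("gene", "protein", "transgene")


def gen_synthetic_kb(cfg: SynthConfig) -> KnowledgeBase:
    """Generate a valid KB with known (planted) subsumption structure.

    Each planted CUT generalizes exactly one host EBT: its bag maps the
    host's region to a partonomy ancestor, the host's morphology to the
    parent morphology, and the host's marker molecule to its indicator.
    Marker indicators are unique per CUT and unused by other neurons, so
    the planted edges are the only EBT->CUT subsumptions by construction.
    """
    rng = random.Random(cfg.seed)
    kb = KnowledgeBase()
    kb.metadata["id"] = f"phenoneuron-synthetic-seed{cfg.seed}"
    standard_predicates(kb)
    T = kb.term

    T("fix:taxon", "Synthetus typicus")
    T("ilxtr:IntrinsicRole", "intrinsic")
    T("ilxtr:GABA", "GABA")

    # partonomy: a forest of given depth under one root region
    regions: list[str] = []
    depth_of: dict[str, int] = {}
    T("fix:region-0", "region 0")
    regions.append("fix:region-0")
    depth_of["fix:region-0"] = 0
    for i in range(1, max(1, cfg.n_regions)):
        curie = f"fix:region-{i}"
        T(curie, f"region {i}")
        candidates = [
            r for r in regions if depth_of[r] < max(1, cfg.partonomy_depth)
        ]
        parent = rng.choice(candidates) if candidates else regions[0]
        kb.hierarchy.add_part_of(curie, parent)
        depth_of[curie] = depth_of[parent] + 1
        regions.append(curie)

    # morphology: base types, each with two subtypes
    morphs: list[tuple[str, str]] = []  # (subtype, base)
    for b in range(3):
        base = f"fix:morph-{b}"
        T(base, f"morphology {b}")
        for s in range(2):
            sub = f"fix:morph-{b}-{s}"
            T(sub, f"morphology {b}.{s}")
            kb.hierarchy.add_subtype(sub, base)
            morphs.append((sub, base))

    # indicators partition molecular terms into modality triples; at least
    # one more than the planted CUTs so marker indicators stay exclusive
    n_ind = max(1, cfg.n_planted_cuts + 1,
                cfg.n_molecular_terms // len(_MODALITIES))
    indicators: list[PhenotypeIndicator] = []
    for k in range(n_ind):
        members = []
        for mod in _MODALITIES:
            curie = f"fix:mol-{k}-{mod}"
            T(curie, f"marker{k} {mod}")
            members.append(curie)
        ind = PhenotypeIndicator(
            f"fix:indicator-{k}", f"M{k}", frozenset(members), name=f"marker{k}"
        )
        kb.add_indicator(ind)
        indicators.append(ind)

    marker_inds = indicators[: cfg.n_planted_cuts]
    free_inds = indicators[cfg.n_planted_cuts :]

    def members_sorted(ind: PhenotypeIndicator) -> list[str]:
        return sorted(ind.members)

    hosts: list[tuple[str, str]] = []  # (ebt id, cut id)
    n_hosts = min(cfg.n_planted_cuts, cfg.n_neurons)
    for i in range(cfg.n_neurons):
        eq: list = [
            P("hasInstanceInTaxon", "fix:taxon"),
            P("hasCircuitRolePhenotype", "ilxtr:IntrinsicRole"),
            P("hasNeurotransmitterPhenotype", "ilxtr:GABA"),
        ]
        region = rng.choice(regions[1:] or regions)
        eq.append(P("hasSomaLocatedIn", region))
        sub, base = rng.choice(morphs)
        eq.append(P("hasMorphologicalPhenotype", sub))
        if i < n_hosts:
            ind = marker_inds[i]
            marker = rng.choice(members_sorted(ind))
            eq.append(P("hasExpressionPhenotype", marker))
            # plant the CUT: indicator-level marker, parent morphology,
            # ancestor region (or the region itself at the root)
            anc = sorted(kb.hierarchy.part_ancestors(region)) or [region]
            cut_id = f"fix:cut-{i}"
            cut = neuron(
                cut_id,
                equivalent=[
                    P("hasInstanceInTaxon", "fix:taxon"),
                    P("hasSomaLocatedIn", rng.choice(anc)),
                    P("hasMorphologicalPhenotype", base),
                    P("hasMolecularPhenotype", ind.id),
                ],
                source="NeuronCUT",
                orig_label=f"planted CUT {i}",
            )
            hosts.append((f"fix:ebt-{i}", cut_id))
        else:
            ind = rng.choice(free_inds)
            eq.append(
                P("hasExpressionPhenotype", rng.choice(members_sorted(ind)))
            )
            cut = None
        src = rng.choice(("NeuronMarkram2015", "NeuronHuang2017", "NeuronACT"))
        add_neuron(kb, neuron(
            f"fix:ebt-{i}", eq, source=src, source_tag="Synth",
            orig_label=f"synthetic EBT {i}",
        ))
        if cut is not None:
            add_neuron(kb, cut)

    kb.metadata["planted_edges"] = ";".join(f"{a}->{b}" for a, b in hosts)

    # modality relabeling: swap measured molecules for indicator siblings
    if cfg.modality_relabel_rate > 0:
        for nid in sorted(kb.neurons):
            n = kb.neurons[nid]
            if n.is_cut:
                continue
            new_eq = []
            for ph in sorted(
                n.equivalence_bag, key=lambda p: repr(p)
            ):
                if (
                    isinstance(ph, Phenotype)
                    and not ph.negative
                    and ph.predicate == "hasExpressionPhenotype"
                    and rng.random() < cfg.modality_relabel_rate
                ):
                    ind_id = None
                    for ind in indicators:
                        if ph.value in ind.members:
                            ind_id = ind
                            break
                    if ind_id is not None:
                        sibs = [m for m in members_sorted(ind_id)]
                        ph = P(ph.predicate, rng.choice(sibs))
                new_eq.append(ph)
            kb.neurons[nid] = neuron(
                n.id, new_eq, source=n.source_class,
                subclass=n.subclass_phenotypes,
                entailed_negative=n.entailed_negatives,
                orig_label=n.orig_label, source_tag=n.source_tag,
            )

    if cfg.censor_morphology_rate > 0:
        censored = censor_dimension(
            kb, "morphological", cfg.censor_morphology_rate, cfg.seed + 1
        )
        censored.metadata = dict(kb.metadata)
        return censored
    return kb


def censor_dimension(
    kb: KnowledgeBase, dimension: str, rate: float, seed: int
) -> KnowledgeBase:
    """Copy of ``kb`` with the stated fraction of that dimension's
    phenotypes removed from EBT bags (CUTs are left intact).

    Emulates sources that simply do not measure a dimension: under the
    open world the censored neurons stop classifying under any CUT that
    requires it — absence blocks entailment but asserts nothing.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = random.Random(seed)
    out = kb.copy()
    for nid in sorted(out.neurons):
        n = out.neurons[nid]
        if n.is_cut:
            continue

        def keep(ph) -> bool:
            if kb.predicate_dimension(ph.predicate) != dimension:
                return True
            return rng.random() >= rate

        eq = [p for p in sorted(n.equivalence_bag, key=repr) if keep(p)]
        sc = [p for p in sorted(n.subclass_phenotypes, key=repr) if keep(p)]
        en = [p for p in sorted(n.entailed_negatives, key=repr) if keep(p)]
        if not eq:
            eq = list(n.equivalence_bag)  # never empty an equivalence bag
        out.neurons[nid] = neuron(
            n.id, eq, source=n.source_class, subclass=sc,
            entailed_negative=en, orig_label=n.orig_label,
            source_tag=n.source_tag,
        )
    return out
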