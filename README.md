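# phenoneuron

Neuron types as computable objects: a toolkit for representing neuronal
cell types as **bags of signed phenotypes**, generating deterministic
human-readable names from them, classifying data-driven types under
classical types by subsumption reasoning, answering description-logic
style queries, and round-tripping the whole knowledge base as
deterministic Turtle.

It is aimed at neuroinformaticians and curators who need to compare cell
type proposals coming from different laboratories, techniques, and
nomenclatures — e.g. a transcriptomic type defined by a transgenic driver
line against a classical morphologically-defined interneuron.

## The model

A neuron type is the intersection of signed existential restrictions

```
NeuronType ≡ ⊓ᵢ (∃ predᵢ . valueᵢ)   plus   ¬(∃ pred . value) for negatives
```

where each `(pred, value)` pair is one phenotype along a dimension:
taxon, soma/axon location, morphology, electrophysiology, molecular
evidence, circuit role. Two flavours of type coexist in one knowledge
base:

* **Common usage types (CUTs)** — classical types (e.g. *neocortex basket
  cell*) given a *minimal, positive-only* set of necessary-and-sufficient
  conditions, so that data-driven types can classify under them.
  Distinguishing negatives are recorded as entailments, outside the
  defining restrictions.
* **Evidence-based types (EBTs)** — types proposed by a single study,
  encoded exactly as measured (gene vs protein vs transgenic line,
  explicit negatives, missing dimensions), tagged with a source class
  such as `NeuronMarkram2015`.

Three ingredients make the reasoning useful across sources:

* **Phenotype indicators** group the different molecular forms of one
  marker (`Sst` gene, SST protein, SOM, `Sst-IRES-Cre` line, …) under one
  class with a short display name, so a query for "somatostatin neurons"
  matches regardless of what was measured.
* **Partonomy expansion**: a soma in S1 is a soma in neocortex.
* **Open-world negatives**: absence of an assertion is never evidence of
  absence; a negative condition is only satisfied by an explicit negative
  assertion. Disjointness axioms are checked, never used to infer
  negatives.

Classification is EL-style: neuron *n* subsumes under class *m* iff every
condition of *m* is contained in *n*'s expanded bag.

## Worked example

The package bundles a reference knowledge base of cortical interneuron
encodings (two CUTs; rat somatosensory-cortex types from the Blue Brain
taxonomy; the six Huang-lab GABAergic classes PVBC, CHC, CCKC, MNC, ISC,
LPC; Allen-style transgenic-line records):

```
$ phenoneuron build-fixture --out kb.yaml
$ phenoneuron label kb.yaml --id npokb:112
npokb:112  Nest basket cell  Rattus norvegicus S1 Nest basket (intersectionOf AC b) Fast spiking + GABA + calbindin + CR + NPY + PV + VIP -Sst intrinsic neuron (Markram2015)  Rattus norvegicus S1 Nest basket (intersectionOf AC b) Fast spiking + GABA + calbindin + CR + NPY + PV + VIP -SST intrinsic neuron (Markram2015)  Nest basket cell
```

The four columns after the id are preferred, normalized, local, and
original label. The *local* label preserves the measured molecular forms
(protein `-SST`); the *normalized* label maps each molecule to its
indicator short name (`-Sst`). Names are assembled species → region
(coarse-to-fine) → morphology → physiology → molecules → circuit-role
suffix, and are invariant under the order phenotypes were entered.

Queries use a small DL-style expression grammar:

```
$ phenoneuron query kb.yaml "hasPhenotype some 'somatostatin (indicator)' \
    and hasSomaLocatedIn some (neocortex or 'part of' some neocortex)" --count
11
$ phenoneuron cq kb.yaml
CQ1	7	fix:CHC,nifext:56,npokb:112,npokb:43,npokb:434,npokb:59,npokb:65
CQ2	11	nifext:55,npokb:111,npokb:296,npokb:412,npokb:415,npokb:42,npokb:45,npokb:73,npokb:75,npokb:87,npokb:89
CQ3	8	npokb:112,npokb:114,npokb:40,npokb:43,npokb:59,npokb:65,npokb:73,npokb:75
CQ4	3	npokb:111,npokb:42,npokb:89
CQ4-classification	3	npokb:111,npokb:42,npokb:89
```

Reading the report: the parvalbumin query (CQ1) finds seven types across
all three sources even though they measured PV protein, the `Pvalb` gene,
or `PV-cre`/`Pvalb-T2A-FlpO` lines — and correctly excludes `npokb:73`,
which is explicitly PV-negative. CQ4 shows that the rat Martinotti types
and the mouse MNC class classify under the *neocortex Martinotti cell*
CUT, while the Allen records do not: they describe dendrites only and
assert no Martinotti morphology, and under the open world that absence
blocks classification.

`phenoneuron classify` prints the inferred hierarchy,
`phenoneuron validate` the invariant/consistency report, and
`phenoneuron convert kb.yaml kb.ttl` writes the deterministic Turtle
serialization (byte-identical for identical content; round-trip safe).

The same API is available from Python:

```python
from phenoneuron.fixtures import build_paper_kb
from phenoneuron import evaluate, classify

kb = build_paper_kb()
evaluate(kb, "hasPhenotype some 'parvalbumin (indicator)'")
# ['fix:CHC', 'nifext:56', 'npokb:112', 'npokb:43', 'npokb:434', 'npokb:59', 'npokb:65']
```

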