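# neissdist

Structure screening for **anhydride-mediated covalent probe design**: find
protein–protein complexes in which one chain's C-terminus lies close to a
reactive amine — a lysine ε-amine (Nε) or a partner chain's α-amine — on
another chain.

## Why

A binder protein fused to a calcium-triggered self-processing module can be
converted, in situ, into a C-terminal **aspartic anhydride**. If the docked
target protein presents a nucleophilic amine near that C-terminus, the amine
attacks the anhydride and the complex is ligated covalently. Picking good
binder/target pairs is therefore a geometry problem over the whole PDB:

1. the **target** should have an α- or ε-amine proximal to the binder's
   C-terminus (Ct);
2. the **binder** should *not* have an amine near its own C-terminus
   (self-reaction would cyclise the binder instead);
3. sterics at the site and linker occlusion of the interface need manual
   inspection — the tool flags this, it does not score it.

`neissdist` implements the distance survey behind that selection, the
single-complex screen, and the intact-mass bookkeeping for the cleavage and
conjugation products.

## The measurement

For every polypeptide chain instance in every biological assembly (expanded
from deposited mmCIF operators, including cartesian products of operator
lists), the **C-terminal residue** is the last resolved standard amino acid;
**targets** are every lysine plus the first resolved standard residue. One
**primary distance** per Ct/target pair is chosen by a fixed fallback order
over backbone/side-chain atoms — a priority, not a minimum:

```
lysine:       C–Nε > CA–Nε > N–Nε > C–CA > CA–CA > N–CA > C–N > CA–N > N–N
N-terminus:   C–αN > CA–αN > N–αN > C–CA > CA–CA > N–CA
N-term lysine: as above, αN or Nε chosen by shorter distance at each rank
```

Records are categorised as intramolecular, intermolecular homomeric
(identical polymer sequences) or heteromeric (different sequences).
Distances < 1.6 Å are flagged as existing covalent linkage (e.g.
ubiquitination) and excluded from shortlists. Per-structure minima are taken
per category across assemblies and models (first 10 models only; input
files ≥ 10 MB are skipped), then binned in 1 Å intervals over [0, 50) Å.
Headline queries consider only primary distances from the Ct carbonyl
carbon (C) to lysine Nε.

## Worked example

Generate a synthetic heterodimer whose binder-Ct-C → target-lysine-Nε
distance is exactly 3.5 Å, then screen it:

```
$ neissdist fixtures --layout heterodimer --distance 3.5 --out toy.cif
$ neissdist screen toy.cif --binder A --target B
binder A Ct = E6
nearest target amine: K3 (C-NZ) 3.5 A
  K3    lysine      C-NZ  3.5
  G1    n_terminus  C-aN  10.4
binder self-reaction: G1 18.8 A
target_within(<10 A): True   self_clash(<10 A): False
```

The nearest target amine is the constructed lysine at 3.5 Å (criterion 1
satisfied below the default 10 Å cutoff); the binder's nearest own amine is
its α-amine 18.8 Å away, so there is no self-reaction flag. Scanning into a
store and querying reproduces the survey semantics:

```
$ neissdist scan toy.cif --db toy.sqlite
scanned 1 structure(s) into toy.sqlite
$ neissdist query --db toy.sqlite --category heteromeric --cutoff 10
1
```

Mass bookkeeping from intact-MS component masses (Da): a precursor of
42,024.7 releasing a 26,415.1 module leaves a hydrolyzed binder fragment of
15,627.6 (anhydride form one water lighter); conjugation to a 52,929.9
target gives 68,539.5 (one water released on amide formation):

```
$ neissdist mass --precursor 42024.7 --cfrag 26415.1 --target 52929.9
n_fragment_anhydride    15609.6
n_fragment_hydrolyzed   15627.6
conjugate               68539.5
```

Real entries work the same way by accession (network required), e.g.
`neissdist screen 4zgy --binder B --target A` for the ornithine
decarboxylase / antizyme complex.

## Layout

| module | role |
| --- | --- |
| `structure_io` | mmCIF/PDB parsing, size/model gates, assembly operator expansion |
| `terminus_target` | Ct/target definitions, primary-pair priority selection |
| `scan_classify` | full per-structure scan, categories, covalent filter, minima |
| `distdb` | SQLite store: counts, histograms, shortest-category partition, shortlist TSV |
| `screen` | single-complex assessment (amine ranking, self-reaction distance) |
| `mass_calc` | average masses from sequence, cleavage/conjugate arithmetic |
| `fixtures` | synthetic mmCIF generator with exactly known geometry |

See `docs/methods.md` for the model, conventions and limitations.
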