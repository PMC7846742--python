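# Methods

## The screening model

The tool answers a purely geometric question about deposited structures:
for each polypeptide chain, how far is its C-terminus from every reactive
amine in the same biological assembly?  The chemistry it serves — a
calcium-triggered self-processing module that leaves a C-terminal aspartic
anhydride on a binder protein, ligated by nucleophilic attack from an amine
on the docked target — enters only through the choice of end points:

- **C-terminal residue (Ct)**: the *last resolved standard* amino acid of a
  chain, not the sequence terminus.  Unresolved tails and trailing
  non-standard residues are skipped.  Backbone atoms C (carbonyl carbon),
  CA and N participate; the carbonyl carbon is where the anhydride forms,
  so C is always the preferred source atom.
- **Targets**: every lysine (side-chain Nε, PDB atom NZ) and the *first
  resolved standard* residue of each chain (its backbone N is the free
  α-amine, written `aN`).  No other nucleophiles are considered: lysine
  dominates protein surfaces and the α-amine is the demonstrated secondary
  reaction channel.

### Primary distance

One distance per Ct/target pair is selected by a fixed fallback order
(lysine: C–Nε > CA–Nε > N–Nε > C–CA > CA–CA > N–CA > C–N > CA–N > N–N;
N-terminus: C–αN > CA–αN > N–αN > C–CA > CA–CA > N–CA).  The order encodes
chemical relevance first (the reacting atoms), then proxies for partially
resolved residues.  It is a **priority, not a minimum**: when C and Nε are
resolved, C–Nε is the primary distance even if some other available pair is
shorter.  For an N-terminal lysine both amines compete at each of the first
three ranks and the shorter available one wins; an exact tie goes to αN
(the α-amine is listed first in the rule and the tie is measure-zero in
real data — the convention only matters for constructed inputs).  A
residue's αN and its backbone N are one physical atom and are exposed as
αN only, so the N-terminal fallback list has six entries, not eight.

### Categories and aggregation

Every record is intramolecular (same chain instance), intermolecular
homomeric (different instances, byte-identical polymer sequences) or
heteromeric (different sequences).  Sequence identity is taken from the
polymer entity definition when present, else derived from the resolved
standard residues; symmetry copies of one deposited chain are therefore
homomeric by construction.  Ordered chain pairs are scanned, including a
chain against itself; when the Ct residue is itself the target residue
(a C-terminal lysine) the record is flagged `same_residue` and excluded
from shortlists and default query minima, where it would otherwise
dominate every intramolecular minimum.

Per-structure minima are taken per category across *all* assemblies and
all analysed models; the single overall shortest distance per structure is
the minimum of those.  Multi-model reduction (minimisation across models)
is our choice — consistent with wanting the shortest observable geometry —
since NMR-style ensembles have no privileged model.  Ties break on the
deterministic record ordering (assembly, model, source chain, target
chain, target residue), so repeated scans and shuffled inputs aggregate
byte-identically.

### Filters and conventions

| parameter | default | why |
| --- | --- | --- |
| input size gate | < 10 MB (strict) | skips viral capsids and similar mega-assemblies; applied to the input file as a proxy for assembly size, with a 500,000-atom post-expansion cap guarding pathological operator products |
| model cap | first 10 models | bounds ensemble entries; kept in file order |
| covalent cutoff | < 1.6 Å (strict) | distances below a bond length mean an *existing* covalent link (e.g. ubiquitin conjugates), not candidate geometry; such records are flagged and excluded from shortlists |
| histogram | [0, 50) Å, 0.1 Å interrogation, 1 Å bins | minima are interrogated cumulatively in 0.1 Å steps and the increments summed into 1 Å half-open bins [k, k+1); a minimum of exactly 50.0 Å falls outside the range |
| headline pair filter | primary pair = (C, Nε) | survey counts consider only Ct-carbonyl-to-lysine-ε records; for N-terminal lysines this means Nε beat αN in the primary selection; pass `pair_filter=None` to lift |
| screen cutoffs | 10 Å target, 10 Å self | the survey's headline proximity query uses < 10 Å; "close" for self-reaction is not quantified anywhere authoritative, so the same value is used symmetrically and both are configurable |
| altlocs | highest occupancy, tie → first altloc id | standard convention |
| MSE → MET | off | strict reading of "standard amino acid"; `ScanConfig(map_mse=True)` relaxes it |
| residue labels | author numbering | reports print labels like `E219`, `K92` as in the literature; label (entity) numbering is kept internally |
| report rounding | 0.1 Å, half away from zero | matches printed precision of published distances; integer-printed distances round the same way at 0 d.p. |

### Assemblies

Biological assemblies are expanded from `_pdbx_struct_assembly_gen` /
`_pdbx_struct_oper_list`: operator expressions support comma lists,
numeric ranges and parenthesized cartesian products, with `(A)(B)` composed
as A·B (B applied first).  The expansion is implemented here rather than
taken from gemmi's structure object, which drops assemblies with
unrecognised `details` strings and does not compose product expressions;
operator matrices themselves are read from the CIF tables via gemmi.
Chains only pair *within* one assembly; minima may compare across
assemblies.  Legacy PDB files fall back to the asymmetric unit with a
logged notice (REMARK 350 is deliberately not expanded — mmCIF is the
authoritative assembly source).  Cross-assembly duplicates generated by
identical operators are not deduplicated; per-structure minima make the
duplication harmless for every exported statistic.

## Mass bookkeeping

Average (not monoisotopic) masses, as compared against intact-protein ESI
deconvolution; a `monoisotopic` flag exists for completeness.  Sequence
masses are Σ residue masses + one water, using an embedded ExPASy-style
average residue table (cross-checked in the tests against Biopython's
independent table; they agree to < 5 mDa per residue).  Water is
18.0153 Da internally; printed values like “18.01” are treated as rounds.
The product arithmetic is pure accounting: cleavage at the Asp-Pro bond
gives `anhydride = precursor − C-fragment`, hydration adds one water, and
conjugation releases one water (`conjugate = hydrolyzed + target − water`),
so the water constant cancels from the closed loop — conjugate masses
computed from printed component masses inherit only the components'
0.1 Da print rounding.  `remove_fmet` models bacterial N-terminal
methionine excision by dropping one leading M before summation.

## The synthetic generator

`fixtures` emits valid mmCIF text with *exactly* placed key distances: a
heterodimer whose binder-Ct-C → target-lysine-Nε distance is set by
construction (the target chain is rigidly translated so its Nε lands on
the requested sphere), a homodimer realised purely as identity + rigid
operator in the assembly definition, and multi-model entries where model
k sits at (3.0 + k) Å so the cross-model minimum is known.  Optional
seeded Gaussian jitter perturbs all coordinates; exact-distance
constraints are re-imposed afterwards, so recovered key distances are
seed-independent.  Residues use an idealized template backbone with
plausible local bond lengths and a schematic extended lysine side chain —
no rotamer physics, no clash relief, no realistic secondary structure.

What passing tests on these fixtures show: parsing, operator algebra,
priority selection, categorisation, filtering, aggregation and SQL
queries are correct on inputs whose answers are known exactly.  What they
do not show: robustness to the full heterogeneity of real depositions
(microheterogeneity, exotic operator expressions, gaps, insertion codes
are covered only as far as the unit tests construct them), and none of
the archive-scale statistics — absolute hit counts depend on the archive
snapshot and cluster-scale compute and are out of scope by design.  The
one check against a real deposited entry (the ornithine decarboxylase /
antizyme complex, with its published 3.5 / 14 / 16.8 Å distances)
requires downloading that entry and therefore runs only where the PDB is
reachable.

## Numerical notes

- Distances are kept at full float precision internally; rounding happens
  only at the report boundary (0.1 Å, half away from zero).
- Strict inequalities everywhere they are specified: the size gate
  (10 MB file fails), the covalent filter (1.59 Å removed, 1.60 Å kept),
  query cutoffs (a 10.0 Å minimum is not "< 10 Å").
- Histogram problem sizes in `scripts/acceptance.py`: nine single-model
  heterodimers, one 12-model entry, one operator homodimer — chosen as
  the smallest set that exercises every query path with hand-countable
  answers.
- Degenerate inputs: chains with no standard residues are dropped with a
  log line; a Ct whose residue resolved none of C/CA/N yields no records
  for that chain; empty stores return zero counts and all-zero bins.

## Known limitations

- No solvent-accessibility, sterics or pKa modelling: criterion (iii) of
  the design rules is reported as a manual-inspection note, mirroring how
  candidate shortlists are actually triaged.
- Self-reaction risk uses the same primary-distance machinery as target
  ranking; it does not model linker flexibility.
- Legacy PDB input never yields intermolecular records beyond the
  asymmetric unit contents.
- Sequence identity for the homo/hetero split is exact string equality;
  a single engineered point mutation makes two otherwise identical chains
  heteromeric.
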