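# Methods

## Scope and model

`smitax` classifies small molecules at the top two levels of a
ChemOnt/ClassyFire-style chemical taxonomy — kingdom and superclass —
directly from the SMILES string, and derives interpretable features
from the same analysis. Deeper levels (class, subclass, …) are out of
scope by design. Classification is defined on the molecular graph *as
written*: the parser reads atoms, bonds, rings, fragments and formal
charges from the string but computes no implicit hydrogens, valences,
aromaticity (beyond the lowercase flags present in the input) or
tautomers. Two SMILES encodings of the same molecule can therefore
classify differently in principle; the package tests equality for the
aromatic and Kekulé encodings of benzene specifically and makes no
broader invariance claim.

## The SMILES digest

The parser (`smitax.smiles`) accepts the common core of SMILES:
organic-subset atoms, aromatic lowercase symbols, bracket atoms with
isotope / chirality / explicit-H / charge fields, branches, ring
closures (including `%nn`), bond symbols and dot disconnects. Stereo
markers, isotopes and atom classes are parsed and discarded — no
taxonomy rule consults them. Charges written `++`/`--` and `+2`/`-2`
are equivalent.

Adjacency follows the standard walk (previous-atom linkage, branch
stack, ring-closure digit pairing, dot severing). Bond order defaults
to single, or aromatic when both endpoints are aromatic and no symbol
was written. Each ring-closure pair yields exactly one recovered ring:
the shortest cycle through the closure bond, found by BFS with that
bond excluded. This equals the cyclomatic number of the graph, which
the tests verify independently. Malformed input (unbalanced brackets
or parentheses, unmatched ring digits, unknown symbols) raises a
`SmilesError` naming the offending position; batch interfaces record
such rows in an error report and continue.

`longest_carbon_chain` is the longest simple path in the carbon-only
subgraph, computed by exhaustive DFS. This is exponential in the worst
case but molecules in this problem domain are small; the test oracle
re-derives it by stack-based enumeration over an adjacency matrix.

## Kingdom

Organic ⇔ at least one carbon atom, except a fixed list of classically
inorganic carbon compounds: cyanide/isocyanide, thiophosgene, carbon
diselenide, carbon mono-/di-/subsulphide, carbon mon-/sub-oxide and
dicarbon monoxide. Matching is by whole-molecule graph isomorphism on
the H-stripped skeleton with exact bond orders and charges ignored:
formula matching alone would swallow methanol (`CO`) and methylamine
(`CN`), while string matching would miss `C(=S)=S` as carbon
disulphide. Carbon dioxide is not on the exception list and is
classified organic. Superclass predicates are evaluated only within
the assigned kingdom.

## Superclass rules

All 26 organic predicates are evaluated independently; every label
that fires is returned (labels are a set, serialized in a fixed
enumeration order). The structural definitions:

| label | rule |
|---|---|
| organoheterocyclic | ring with ≥ 1 C and ≥ 1 non-C member |
| organosulfur | any C–S bond |
| lipid | carboxyl group and carbon chain ≥ 4 |
| allene | C with double bonds to two distinct carbons (C=C=C) |
| benzenoid | all-carbon 6-ring, aromatic or alternating Kekulé |
| phenylpropanoid_polyketide | phenylpropane skeleton, or β-polyketone motif |
| organic_acid | carboxyl group |
| alkaloid | nitrogen present and net charge < 0 |
| organic_salt | ≥ 2 fragments, one net-positive and one net-negative, ≥ 1 organic |
| organohalogen | any C–halogen bond |
| organometallic | any C–metal bond |
| organic_nitrogen | nitrogen present |
| nucleoside_nucleotide | a nucleobase fragment and a ribose/deoxyribose fragment |
| organic_oxygen | oxygen present |
| organophosphorus | phosphorus present |
| lignan_neolignan | phenylpropane skeleton |
| organic_polymer | repeated atom-token unit (≥ 4 atoms, ≥ 3 back-to-back repeats) |
| hydrocarbon | element set ⊆ {C, H} |
| hydrocarbon_derivative | organic and not a hydrocarbon |
| organic_anion / organic_cation | net formal charge < 0 / > 0 |
| organic_zwitterion | equally many + and − atoms, net 0 |
| carbene | neutral non-aromatic bracket C with explicit valence 2 |
| dipolar_1_3 | net 0, a + atom and a − atom at graph distance exactly 2 |
| organopnictogen | any C–{N,P,As,Sb,Bi} bond |
| acetylide | C≡C with a metal bonded to either carbon |

Inorganic: homogeneous_metal (all atoms metals), homogeneous_non_metal
(all atoms non-metals), mixed_metal_non_metal (≥ 1 of each),
inorganic_salt (≥ 1 charged atom), miscellaneous_inorganic iff none of
the other four fired — so every inorganic molecule carries ≥ 1 label.

### Design decisions in the rules

* **Carboxyl** means C(=O)–O where the single-bonded O has no further
  heavy neighbor (hydroxyl or oxyanion). Esters are excluded; the
  underlying acid definitions are silent on this, and excluding esters
  keeps "organic acid" closer to titratable acids.
* **Element trichotomy.** The inorganic rules partition elements as
  metal / non-metal / neither, with carbon and the metalloids (B, Si,
  Ge, As, Sb, Te) in *neither*. Under a strict dichotomy every
  molecule would be all-metal, all-non-metal or mixed and the
  miscellaneous fallback could never fire; with the trichotomy,
  neutral cyanide and silica land in miscellaneous, as intended.
* **Metals table**: all alkali, alkaline-earth, transition and
  post-transition metals, lanthanides and actinides. Bi is both metal
  and pnictogen. Halogens include At.
* **Nucleoside matching** stores cytosine, adenine, guanine, thymine,
  uracil and (deoxy)ribose as reference fragment graphs and tests
  subgraph monomorphism on the element-labelled skeleton, ignoring
  bond orders, so aromatic, Kekulé and tautomeric writings all match.
  The sugar patterns omit the anomeric OH so glycosides match. String
  matching would fail across dialects.
* **Polymer heuristic**: a contiguous atom-token subsequence of length
  ≥ 4 repeated ≥ 3 times back-to-back in SMILES atom order. Thresholds
  chosen once so octane (8 carbons) does not fire while written
  repeat-unit encodings (e.g. an amylose fragment) do. A consequence,
  accepted: any molecule with a ≥ 12-atom identical run — a long fatty
  chain — also fires. It is a string-level heuristic, not a polymer
  perception algorithm.
* **Polyketide motif**: a carbon path k–m–k–m with k carbonyl and m
  non-carbonyl carbons (two consecutive carbonyl/methylene repeats).
* **Phenylpropane skeleton** (shared by the phenylpropanoid and lignan
  rules): a benzenoid ring with an exocyclic simple carbon path ≥ 3.
* **Carbene** cannot be detected via unpaired electrons (SMILES cannot
  encode them); the proxy is a neutral, non-aromatic bracket carbon
  whose explicit bond orders plus explicit H sum to 2, which captures
  `[C](Cl)Cl` and vinylidene-type `[C]=C`.
* **Zwitterion / salt** are charge-pattern rules: zwitterions count
  charged *atoms*, salts compare per-*fragment* net charges. The
  two-fragment encoding of an ammonium carboxylate satisfies both —
  labels overlap by design.

### Known rule-vs-illustration conflicts

Three molecules traditionally used to illustrate superclasses cannot
satisfy the rules as printed, and the packaged gallery flags them
(`rule_recovers=False`) rather than bending the rules: **morphine** is
neutral, so the alkaloid rule (nitrogen + negative net charge) misses
it; **phosphate** has no carbon, so it is inorganic and cannot be an
organic anion; **guanine** alone has no sugar, so it is not a
nucleoside (adenosine and uridine are the positive controls). The
dichlorocarbene exemplar is recovered, but only via the divalent-
carbon proxy above.

Gallery encodings are themselves documented choices: acetate is
shipped as its sodium salt (a lone anion has no counterion and cannot
satisfy the salt rule), ferrocene uses a σ-bonded iron encoding (the
ionic form has no C–Fe bond), the nitrone is written in its
charge-separated canonical form `[CH2+]N(C)[O-]` (the common
`C=[N+][O-]` form has adjacent charges and fails the printed 1,3
separation), and fucoxanthin is constitution-only (stereo omitted).

## Features

`char_count_features` counts characters over a fixed, versioned
alphabet (one-letter organic-subset symbols + H, lowercase aromatic
symbols, digits, and SMILES punctuation), case-sensitively — lowercase
carries aromaticity information. Untracked characters (e.g. the `l` of
`Cl`) accumulate under `other`, so counts always sum to the string
length. The feature table is `smiles`, `kingdom`, 39 character
columns, 31 flag columns, in a fixed order; malformed rows are skipped
and reported, never emitted as NA.

## Bulk analysis

`classify_batch` keeps duplicates, caches per distinct string, and
tallies *exact* label combinations (UpSet semantics: each molecule
contributes to exactly one combination), so combination counts plus
failures always sum to the input length. `upset_plot` renders the
combination bars over a membership-dot matrix with matplotlib, sorted
by descending count (ties broken lexicographically), drops
combinations below `min_subset_size` (default 1; raising it can only
remove bars), errors out if nothing survives, and writes the plotted
count table alongside the image for machine checking.

Name → SMILES resolution calls the public PubChem PUG-REST endpoint.
It is off by default, never substitutes silently on failure, and
caches successes per process; the offline test suite only exercises
its error contract.

## Synthetic datasets

`synthetic_batch(n, seed)` draws molecules from known families:
gallery organics (45 %), fatty-acid series C4–C17 (15 %), alcohols
(13 %), alkanes C1–C12 (12 %), five common heteroaromatics (10 %), and
gallery inorganics (5 %) — a composition chosen once to emulate a
bioassay-derived screening library: overwhelmingly organic,
heterocycle/benzenoid-rich, dominated by hydrocarbon derivatives, with
a trace of inorganic salts. An optional `malformed_rate` injects
unparseable strings to exercise failure handling. Because every drawn
string comes from a known family, batch summaries can be validated
against first-principles tallies.

What the generator does *not* emulate: real libraries' structural
diversity (novel scaffolds, stereochemistry, exotic valences,
macromolecules) and real-world SMILES dialect noise. Passing tests
therefore demonstrate the bookkeeping (conservation, exact-combination
tallies, determinism, throughput) and the rules' behaviour on known
chemistry — not classification accuracy on arbitrary external data.

## Numerics, determinism, problem sizes

There is no randomness anywhere in the core: parsing and
classification are pure functions, reruns are byte-identical, and
output ordering is fixed (enumeration order for labels, count-then-
lexicographic for plot bars). The test suite fuzzes ~600 generated
molecules of ≤ 12 atoms against rdkit (parser equivalence) and against
brute-force adjacency-matrix oracles (rings, bond-between-sets,
longest chain, charge distance); bulk checks run at 10,000 molecules,
which classify in well under a second on one CPU thanks to per-unique
caching.

## Limitations

* Classification is string-level: no canonicalization, so exotic but
  equivalent encodings may classify differently.
* Several rules are deliberately crude inheritances of the scheme:
  phenylalanine fires the lipid rule (carboxyl + a ≥ 4 carbon chain
  through the ring), any C–N bond fires organopnictogen, and the
  alkaloid rule labels carboxylates of N-heterocycles rather than
  free-base alkaloids.
* No valence or sanity checking: chemically impossible but
  syntactically valid SMILES are classified without complaint.
* The carbene and 1,3-dipole rules depend on how charges and bracket
  atoms are written, as discussed above.
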