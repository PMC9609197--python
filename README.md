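# smitax

Rule-based chemical taxonomy and explainable feature extraction for
small molecules, straight from SMILES strings.

`smitax` is for anyone who needs to characterize a compound library —
a screening collection, a bioassay hit list, a vendor catalogue —
without a black box. It assigns every molecule a **kingdom** (organic
vs inorganic) and a possibly **overlapping set of 31 superclasses**
(26 organic, 5 inorganic, following the ChemOnt / ClassyFire scheme at
kingdom + superclass depth), using explicit structural rules you can
read in the source. Because labels are sets rather than a single forced
category, a molecule like ethanol is simultaneously an *organic oxygen
compound* and a *hydrocarbon derivative* — which is what makes the
labels useful for grouping and comparing libraries.

On top of classification it provides:

* **Explainable ML features** — per-character counts of the SMILES
  string plus the 31 superclass indicator flags, in a fixed column
  order (`feature_table` → pandas DataFrame / CSV).
* **Bulk characterization** — batch classification with exact-
  combination (UpSet-style) intersection counts and plotting, with
  pruning of near-empty combinations (`classify_batch`, `upset_plot`).
* A packaged **31-molecule exemplar gallery** (one named molecule per
  superclass) and a **synthetic library generator** with known
  composition for testing and demos.
* Optional compound-name → SMILES resolution via PubChem PUG-REST
  (network feature, strictly off by default).

The classification rules are deliberately simple and structural:
organic means "contains carbon" minus a short list of classically
inorganic carbon compounds (CO, CO₂ excepted, CS₂, cyanide, ...); a
lipid is a carboxyl group plus a carbon chain of ≥ 4; an organohalogen
is any covalent C–halogen bond; an organic cation is a positive net
formal charge; and so on. Every rule is an independent predicate on a
small molecular-graph digest parsed directly from the SMILES string —
no valence model, no implicit hydrogens, no tautomer enumeration.

## Quick start

```python
>>> from smitax import classify
>>> r = classify("CCCC(=O)O")        # butyric acid
>>> r.kingdom
'organic'
>>> r.ordered_superclasses()
('lipid', 'organic_acid', 'organic_oxygen', 'hydrocarbon_derivative')
```

Butyric acid carries four labels at once: the carboxyl group makes it
an organic acid, the carboxyl plus its four-carbon chain satisfies the
lipid (fatty-acid) rule, the oxygens make it an organic oxygen
compound, and any organic molecule with non-C/H atoms is a hydrocarbon
derivative.

Feature extraction and bulk analysis:

```python
>>> from smitax import feature_table, classify_batch
>>> table, errors = feature_table(["CCO", "CCCCCCCC", "[He]"])
>>> table.shape           # 2 metadata + 38 char counts + 1 other + 31 flags
(3, 72)
>>> summary = classify_batch(["CCCCCCCC", "CCO", "[He]"])
>>> summary.intersection_counts[("hydrocarbon",)]
1
```

## Command line

```bash
smitax --input molecules.smi --output-dir results/ --min-subset-size 5
```

reads one SMILES per line (or `--format csv --column smiles` for
tables) and writes `taxonomy.csv`, `features.csv`, `membership.csv`,
`intersections.csv` and an UpSet-style intersection plot `upset.png`
(plus its machine-readable `upset_counts.csv`). A typical run logs:

```
INFO classifying 4 molecules (deterministic run, no randomness)
INFO 4 classified, 0 failed
INFO outputs written to results
```

Exit codes: 0 success, 1 usage error, 2 every row failed to parse.

## Tests

```bash
python -m pytest tests/
```

The suite cross-checks the parser against rdkit (atom order, charges,
bond sets) and every structural predicate against brute-force
adjacency-matrix oracles on a fuzzed corpus, alongside the exemplar
gallery and invariant checks.

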