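"""Packaged exemplar gallery and synthetic dataset generator.

The gallery holds one named molecule per superclass — the worked
examples of the method — encoded here as SMILES from their names.  Where
a printed classification rule cannot recover the molecule traditionally
used to illustrate its superclass (morphine is neutral, so the
negative-net-charge alkaloid rule misses it; phosphate has no carbon;
guanine alone has no sugar), the record says so via ``rule_recovers`` and
a note, and the rule is kept as printed.

Some encodings are deliberate choices: acetate is given its sodium salt
so an anion/cation pair exists; ferrocene uses a sigma-bonded iron
encoding so a C–metal bond is present in the graph; the nitrone is
written in its charge-separated canonical form (charges 1,3); starch is
an amylose trisaccharide written with a literally repeating unit.

The synthetic batch generator draws molecules from these families plus
parametric alkane / alcohol / fatty-acid series, emulating a small-
molecule screening library dominated by organic heterocycles, benzenoids
and acids with a sprinkle of inorganic salts — the composition one sees
when characterizing a bioassay-derived drug collection.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .taxonomy import INORGANIC, ORGANIC

__all__ = ["Exemplar", "EXEMPLARS", "exemplar_gallery", "synthetic_batch"]


@dataclass(frozen=True)
class Exemplar:
    name: str
    smiles: str
    kingdom: str
    superclass: str  # the headline label this molecule illustrates
    rule_recovers: bool = True  # does the printed rule recover that label?
    note: str = ""


EXEMPLARS: tuple[Exemplar, ...] = (
    Exemplar("imidazole", "c1cnc[nH]1", ORGANIC, "organoheterocyclic"),
    Exemplar("glutathione", "C(CC(=O)NC(CS)C(=O)NCC(=O)O)C(C(=O)O)N",
             ORGANIC, "organosulfur"),
    Exemplar("behenic acid", "CCCCCCCCCCCCCCCCCCCCCC(=O)O", ORGANIC, "lipid"),
    Exemplar(
        "fucoxanthin",
        "CC1(C)CC(O)CC2(C)OC12CC(=O)C(C)=CC=CC(C)=CC=CC=C(C)C=CC=C(C)"
        "C=C=C1C(C)(C)CC(OC(C)=O)CC1(C)O",
        ORGANIC, "allene",
        note="constitution-only encoding (stereodescriptors omitted)",
    ),
    Exemplar("benzene hexacarboxylic acid",
             "OC(=O)c1c(C(O)=O)c(C(O)=O)c(C(O)=O)c(C(O)=O)c1C(O)=O",
             ORGANIC, "benzenoid"),
    Exemplar("phenylalanine", "NC(Cc1ccccc1)C(=O)O", ORGANIC,
             "phenylpropanoid_polyketide"),
    Exemplar("butyric acid", "CCCC(=O)O", ORGANIC, "organic_acid"),
    Exemplar(
        "morphine", "CN1CCC23C4C1CC5=C2C(=C(C=C5)O)OC3C(C=C4)O",
        ORGANIC, "alkaloid", rule_recovers=False,
        note="neutral molecule; the alkaloid rule requires nitrogen plus a "
             "negative net charge, which morphine does not carry",
    ),
    Exemplar(
        "sodium acetate", "CC(=O)[O-].[Na+]", ORGANIC, "organic_salt",
        note="acetate encoded with its sodium counterion so an anion/cation "
             "pair exists, as the salt rule requires",
    ),
    Exemplar("acetyl chloride", "CC(=O)Cl", ORGANIC, "organohalogen"),
    Exemplar(
        "ferrocene", "C1=CC=C[CH]1[Fe][CH]1C=CC=C1", ORGANIC, "organometallic",
        note="sigma-bonded encoding; the ionic cyclopentadienide form has no "
             "C-Fe bond and would not fire the rule",
    ),
    Exemplar("pyrrole-2-carboxylate", "[O-]C(=O)c1ccc[nH]1", ORGANIC,
             "organic_nitrogen"),
    Exemplar(
        "guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1", ORGANIC, "nucleoside_nucleotide",
        rule_recovers=False,
        note="base without a sugar; the rule requires base plus ribose or "
             "deoxyribose (adenosine is the positive control)",
    ),
    Exemplar("ethanol", "CCO", ORGANIC, "organic_oxygen"),
    Exemplar("diethyl phosphonate", "CCOP(=O)OCC", ORGANIC, "organophosphorus"),
    Exemplar("matairesinol",
             "COc1cc(CC2COC(=O)C2Cc2ccc(O)c(OC)c2)ccc1O",
             ORGANIC, "lignan_neolignan"),
    Exemplar(
        "starch (amylose fragment)",
        "OC1OC(CO)C(O)C(O)C1OC1OC(CO)C(O)C(O)C1OC1OC(CO)C(O)C(O)C1O",
        ORGANIC, "organic_polymer",
        note="trisaccharide written with a literally repeating token unit",
    ),
    Exemplar("octane", "CCCCCCCC", ORGANIC, "hydrocarbon"),
    Exemplar("ethanol (as derivative)", "CCO", ORGANIC, "hydrocarbon_derivative"),
    Exemplar(
        "phosphate", "[O-]P(=O)([O-])O", INORGANIC, "organic_anion",
        rule_recovers=False,
        note="no carbon, so the kingdom rule places it inorganic and the "
             "organic-anion label cannot apply",
    ),
    Exemplar("choline", "C[N+](C)(C)CCO", ORGANIC, "organic_cation"),
    Exemplar("ammonium propionate", "CCC(=O)[O-].[NH4+]", ORGANIC,
             "organic_zwitterion"),
    Exemplar(
        "dichlorocarbene", "[C](Cl)Cl", ORGANIC, "carbene",
        note="SMILES cannot encode unpaired electrons; detected via the "
             "neutral divalent bracket carbon",
    ),
    Exemplar(
        "nitrone (N-methyl methanimine N-oxide)", "[CH2+]N(C)[O-]", ORGANIC,
        "dipolar_1_3",
        note="charge-separated canonical form; the common C=[N+][O-] form has "
             "adjacent charges and would not satisfy the 1,3 separation",
    ),
    Exemplar("N-(4-phenylamino-quinazolin-6-yl)-acrylamide",
             "C=CC(=O)Nc1ccc2ncnc(Nc3ccccc3)c2c1",
             ORGANIC, "organopnictogen"),
    Exemplar("lithium acetylide", "[Li]C#C", ORGANIC, "acetylide"),
    Exemplar("cerium-iron (mixed metals)", "[Ce].[Fe]", INORGANIC,
             "homogeneous_metal"),
    Exemplar("helium", "[He]", INORGANIC, "homogeneous_non_metal"),
    Exemplar("potassium nitrate", "[K+].[O-][N+](=O)[O-]", INORGANIC,
             "mixed_metal_non_metal"),
    Exemplar("sodium chloride", "[Na+].[Cl-]", INORGANIC, "inorganic_salt"),
    Exemplar(
        "hydrogen cyanide", "C#N", INORGANIC, "miscellaneous_inorganic",
        note="carbon is neither metal nor non-metal in the inorganic "
             "trichotomy, so neutral cyanide falls through to miscellaneous",
    ),
)
assert len(EXEMPLARS) == 31


def exemplar_gallery() -> tuple[Exemplar, ...]:
    """The packaged 31-molecule worked-example gallery."""
    return EXEMPLARS


# ---------------------------------------------------------------------------
# synthetic batches

# Sampling weights over molecule families.  Chosen once to emulate a
# drug-screening library: overwhelmingly organic, heterocycle- and
# benzenoid-rich, with small alkane/alcohol/acid series and a trace of
# inorganic salts.
_DEFAULT_WEIGHTS: dict[str, float] = {
    "exemplar_organic": 0.45,
    "alkane": 0.12,
    "alcohol": 0.13,
    "fatty_acid": 0.15,
    "heteroaromatic": 0.10,
    "exemplar_inorganic": 0.05,
}

_HETEROAROMATICS = (
    "c1ccncc1",          # pyridine
    "c1ccc2ncccc2c1",    # quinoline
    "c1cc[nH]c1",        # pyrrole
    "c1ccoc1",           # furan
    "c1ccsc1",           # thiophene
)


def synthetic_batch(
    n: int,
    seed: int,
    weights: dict[str, float] | None = None,
    malformed_rate: float = 0.0,
) -> list[str]:
    """Draw ``n`` SMILES from the known molecule families.

    Deterministic for a given seed.  ``malformed_rate`` injects that
    fraction of unparseable strings, for exercising failure handling.
    The composition is fully known to the caller (each string is either
    a gallery molecule, a parametric series member, or malformed), so
    batch summaries can be checked against first principles.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(seed)
    weights = dict(_DEFAULT_WEIGHTS if weights is None else weights)
    families = sorted(weights)
    wsum = sum(weights[f] for f in families)
    organic_pool = [e.smiles for e in EXEMPLARS if e.kingdom == ORGANIC]
    inorganic_pool = [e.smiles for e in EXEMPLARS if e.kingdom == INORGANIC]
    out: list[str] = []
    for _ in range(n):
        if malformed_rate > 0 and rng.random() < malformed_rate:
            out.append("not_a_smiles(%d" % rng.randrange(1000))
            continue
        r = rng.random() * wsum
        for fam in families:
            r -= weights[fam]
            if r <= 0:
                break
        if fam == "exemplar_organic":
            out.append(rng.choice(organic_pool))
        elif fam == "exemplar_inorganic":
            out.append(rng.choice(inorganic_pool))
        elif fam == "alkane":
            out.append("C" * rng.randint(1, 12))
        elif fam == "alcohol":
            out.append("C" * rng.randint(1, 10) + "O")
        elif fam == "fatty_acid":
            out.append("C" * rng.randint(3, 16) + "C(=O)O")
        elif fam == "heteroaromatic":
            out.append(rng.choice(_HETEROAROMATICS))
        else:  # pragma: no cover - unknown family name
            raise ValueError(f"unknown family {fam!r}")
    return out
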