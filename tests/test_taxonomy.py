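"""Taxonomy rule tests: kingdom assignment, the 31 superclass
predicates, the packaged exemplar gallery, and the structural
invariants that tie the labels together."""

from __future__ import annotations

import pytest

from smitax.datasets import EXEMPLARS
from smitax.smiles import parse
from smitax.taxonomy import (
    ALL_SUPERCLASSES,
    INORGANIC,
    INORGANIC_SUPERCLASSES,
    KINGDOMS,
    ORGANIC,
    ORGANIC_SUPERCLASSES,
    classify,
    classify_kingdom,
)


class TestEnumeration:
    def test_label_set_cardinality(self):
        assert len(KINGDOMS) == 2
        assert len(ORGANIC_SUPERCLASSES) == 26
        assert len(INORGANIC_SUPERCLASSES) == 5
        assert len(ALL_SUPERCLASSES) == 31
        assert len(set(ALL_SUPERCLASSES)) == 31


class TestKingdom:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCO", ORGANIC),
            ("[C-]#N", INORGANIC),          # cyanide
            ("C#N", INORGANIC),             # hydrogen cyanide
            ("[He]", INORGANIC),
            ("S=C=S", INORGANIC),           # carbon disulphide
            ("C(=S)=S", INORGANIC),         # same molecule, different string
            ("O=C=C=C=O", INORGANIC),       # carbon suboxide
            ("[C-]#[O+]", INORGANIC),       # carbon monoxide
            ("ClC(Cl)=S", INORGANIC),       # thiophosgene
            ("[Se]=C=[Se]", INORGANIC),     # carbon diselenide
            ("S=C=C=C=S", INORGANIC),       # carbon subsulphide
            ("[C]=C=O", INORGANIC),         # dicarbon monoxide
            # same heavy-atom formulas that must stay organic:
            ("CO", ORGANIC),                # methanol, not carbon monoxide
            ("CN", ORGANIC),                # methylamine, not cyanide
            ("CS", ORGANIC),                # methanethiol, not CS
            ("O=CCC=O", ORGANIC),           # propanedial, not carbon suboxide
            ("[Na+].[Cl-]", INORGANIC),
            ("O=C=O", ORGANIC),             # CO2 is not on the exception list
        ],
    )
    def test_kingdom_rule_and_exceptions(self, smiles, expected):
        assert classify_kingdom(parse(smiles)) == expected


class TestExemplarGallery:
    @pytest.mark.parametrize("ex", EXEMPLARS, ids=lambda e: e.superclass)
    def test_exemplar_kingdom_and_headline_label(self, ex):
        """Each gallery molecule gets its captioned superclass whenever
        the printed rule is self-consistent; the flagged conflicts fail
        exactly as documented."""
        result = classify(ex.smiles)
        assert result.kingdom == ex.kingdom
        assert (ex.superclass in result.superclasses) is ex.rule_recovers

    def test_gallery_covers_every_superclass(self):
        assert {e.superclass for e in EXEMPLARS} == set(ALL_SUPERCLASSES)


class TestOrganicPredicates:
    @pytest.mark.parametrize(
        "smiles,subset",
        [
            ("CCCC(=O)O", {"organic_acid", "lipid", "organic_oxygen",
                           "hydrocarbon_derivative"}),
            ("C[N+](C)(C)CCO", {"organic_cation", "organic_nitrogen",
                                "organic_oxygen"}),
            ("[C](Cl)Cl", {"carbene", "organohalogen"}),
            ("CCC(=O)[O-].[NH4+]", {"organic_salt", "organic_zwitterion"}),
            ("[Li]C#C", {"acetylide", "organometallic"}),
            ("CCO", {"organic_oxygen", "hydrocarbon_derivative"}),
            ("c1cnc[nH]1", {"organoheterocyclic"}),
            ("CC(=O)Cl", {"organohalogen"}),
            # adenosine and uridine: base + sugar hits the nucleoside rule
            ("Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O", {"nucleoside_nucleotide"}),
            ("OCC1OC(n2ccc(=O)[nH]c2=O)C(O)C1O", {"nucleoside_nucleotide"}),
        ],
    )
    def test_expected_labels_fire(self, smiles, subset):
        assert subset <= classify(smiles).superclasses

    def test_octane_is_pure_hydrocarbon(self):
        assert classify("CCCCCCCC").superclasses == {"hydrocarbon"}

    def test_ester_is_not_an_organic_acid(self):
        labels = classify("CC(=O)OC").superclasses
        assert "organic_acid" not in labels and "lipid" not in labels

    def test_guanine_alone_is_not_a_nucleoside(self):
        assert "nucleoside_nucleotide" not in classify(
            "Nc1nc2[nH]cnc2c(=O)[nH]1"
        ).superclasses

    def test_kekule_and_aromatic_benzene_agree(self):
        aromatic = classify("c1ccccc1").superclasses
        kekule = classify("C1=CC=CC=C1").superclasses
        assert aromatic == kekule == {"benzenoid", "hydrocarbon"}

    def test_octane_not_polymer_but_repeating_unit_is(self):
        assert "organic_polymer" not in classify("CCCCCCCC").superclasses
        assert "organic_polymer" in classify(
            "OC1OC(CO)C(O)C(O)C1OC1OC(CO)C(O)C(O)C1OC1OC(CO)C(O)C(O)C1O"
        ).superclasses


class TestInorganicPredicates:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("[Na+].[Cl-]", {"mixed_metal_non_metal", "inorganic_salt"}),
            ("[He]", {"homogeneous_non_metal"}),
            ("[Ce].[Fe]", {"homogeneous_metal"}),
            ("[K+].[O-][N+](=O)[O-]",
             {"mixed_metal_non_metal", "inorganic_salt"}),
            ("C#N", {"miscellaneous_inorganic"}),  # fails all four others
            ("O=[Si]=O", {"miscellaneous_inorganic"}),  # metalloid oxide
        ],
    )
    def test_inorganic_superclass_sets(self, smiles, expected):
        result = classify(smiles)
        assert result.kingdom == INORGANIC
        assert result.superclasses == expected


class TestInvariants:
    def test_hydrocarbon_dichotomy_and_charge_exclusions(self, smiles_corpus):
        for s in smiles_corpus:
            r = classify(s)
            labels = r.superclasses
            if r.kingdom == ORGANIC:
                assert labels <= set(ORGANIC_SUPERCLASSES), s
                assert ("hydrocarbon" in labels) != (
                    "hydrocarbon_derivative" in labels
                ), s
                assert not ({"organic_anion", "organic_cation"} <= labels), s
                assert not ({"organic_zwitterion", "organic_anion"} <= labels), s
                assert not ({"organic_zwitterion", "organic_cation"} <= labels), s
            else:
                assert labels <= set(INORGANIC_SUPERCLASSES), s
                assert len(labels) >= 1, s
                assert not (
                    {"homogeneous_metal", "homogeneous_non_metal"} <= labels
                ), s
                assert ("miscellaneous_inorganic" in labels) == (
                    labels == {"miscellaneous_inorganic"}
                ), s

    def test_label_implications(self, smiles_corpus):
        for s in smiles_corpus:
            r = classify(s)
            labels = r.superclasses
            if "alkaloid" in labels:
                assert {"organic_nitrogen", "organic_anion"} <= labels, s
            if "lipid" in labels:
                assert "organic_acid" in labels, s
            if "acetylide" in labels:
                assert "organometallic" in labels, s
            if "hydrocarbon" in labels:
                assert r.kingdom == ORGANIC, s

    def test_ordered_superclasses_follow_enumeration(self):
        r = classify("CCC(=O)[O-].[NH4+]")
        ordered = r.ordered_superclasses()
        positions = [ALL_SUPERCLASSES.index(lab) for lab in ordered]
        assert positions == sorted(positions)
        assert set(ordered) == r.superclasses

    def test_empty_string_propagates_parse_error(self):
        from smitax.smiles import SmilesError

        with pytest.raises(SmilesError):
            classify("")
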