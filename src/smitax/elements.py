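"""Element tables used by the taxonomy rules.

Three small, frozen sets drive most of the structural predicates: the
halogens (organohalogen rule), the metals (organometallic, acetylide and
the inorganic superclasses) and the pnictogens, i.e. group 15
(organopnictogen rule).  For the inorganic superclasses the elements are
partitioned three ways — metal, non-metal, or neither: carbon (whose
compounds are handled by the organic kingdom, minus a short list of
inorganic exceptions) and the metalloids sit outside the metal/non-metal
dichotomy, which is what makes the miscellaneous-inorganic fallback
reachable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Every IUPAC element symbol, Z = 1..118.
PERIODIC_TABLE: frozenset[str] = frozenset(
    """
    H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb
    Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re
    Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es
    Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og
    """.split()
)

#: Halogens.  At is included; the synthetic superheavy Ts is not.
HALOGENS: frozenset[str] = frozenset({"F", "Cl", "Br", "I", "At"})

#: Group 15 (pnictogens).  Note the overlap with METALS at Bi is intentional.
PNICTOGENS: frozenset[str] = frozenset({"N", "P", "As", "Sb", "Bi"})

#: Alkali, alkaline-earth, transition, post-transition metals, lanthanides
#: and actinides.  Metalloids (B, Si, Ge, As, Sb, Te) are excluded.
METALS: frozenset[str] = frozenset(
    """
    Li Na K Rb Cs Fr
    Be Mg Ca Sr Ba Ra
    Sc Ti V Cr Mn Fe Co Ni Cu Zn
    Y Zr Nb Mo Tc Ru Rh Pd Ag Cd
    Hf Ta W Re Os Ir Pt Au Hg
    Rf Db Sg Bh Hs Mt Ds Rg Cn
    Al Ga In Sn Tl Pb Bi Po
    La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu
    Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr
    """.split()
)

#: Elements counted as non-metals by the inorganic superclass rules.
#: Carbon and the metalloids are deliberately absent (neither metal nor
#: non-metal here), so e.g. hydrogen cyanide falls through every named
#: inorganic superclass into the miscellaneous bucket.
NONMETALS: frozenset[str] = frozenset(
    "H He N O F Ne P S Cl Ar Se Br Kr I Xe At Rn".split()
)

#: Metalloid staging area, for reference; treated as neither class above.
METALLOIDS: frozenset[str] = frozenset({"B", "Si", "Ge", "As", "Sb", "Te"})


@dataclass(frozen=True)
class ElementTables:
    """Immutable bundle of the element sets a rule evaluation needs."""

    halogens: frozenset[str] = HALOGENS
    metals: frozenset[str] = METALS
    pnictogens: frozenset[str] = PNICTOGENS
    nonmetals: frozenset[str] = NONMETALS

    def __post_init__(self) -> None:
        for name in ("halogens", "metals", "pnictogens", "nonmetals"):
            bad = getattr(self, name) - PERIODIC_TABLE
            if bad:
                raise ValueError(f"unknown element symbols in {name}: {sorted(bad)}")
        if self.halogens & self.metals:
            raise ValueError("halogens and metals must be disjoint")


#: Default tables, shared by every classification.
DEFAULT_TABLES = ElementTables()
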