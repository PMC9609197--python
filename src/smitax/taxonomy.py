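"""Kingdom and superclass assignment.

A molecule is first placed in one of two kingdoms.  Organic means "has at
least one carbon atom", minus a short list of classically inorganic
carbon compounds (carbon monoxide, cyanide, carbon disulphide, ...).
Within its kingdom every superclass predicate is evaluated
independently, so a molecule can — and usually does — carry several
labels at once: ethanol is both an organic-oxygen compound and a
hydrocarbon derivative.  There are 26 organic and 5 inorganic
superclasses, 31 in total.

Each predicate is a small structural rule on the parsed graph (rings,
bonds between element sets, net and per-atom formal charge, chain
lengths, reference fragments).  Nothing here estimates chemistry beyond
what the SMILES string states explicitly: no implicit hydrogens, no pKa,
no tautomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .elements import DEFAULT_TABLES, ElementTables
from .smiles import (
    DOUBLE,
    SINGLE,
    TRIPLE,
    ParsedMolecule,
    graph_distance,
    has_bond_between,
    longest_carbon_chain,
    parse,
)

__all__ = [
    "ORGANIC",
    "INORGANIC",
    "KINGDOMS",
    "ORGANIC_SUPERCLASSES",
    "INORGANIC_SUPERCLASSES",
    "ALL_SUPERCLASSES",
    "TaxonomyResult",
    "classify",
    "classify_kingdom",
    "classify_organic",
    "classify_inorganic",
]

ORGANIC = "organic"
INORGANIC = "inorganic"
KINGDOMS = (ORGANIC, INORGANIC)

ORGANIC_SUPERCLASSES: tuple[str, ...] = (
    "organoheterocyclic",
    "organosulfur",
    "lipid",
    "allene",
    "benzenoid",
    "phenylpropanoid_polyketide",
    "organic_acid",
    "alkaloid",
    "organic_salt",
    "organohalogen",
    "organometallic",
    "organic_nitrogen",
    "nucleoside_nucleotide",
    "organic_oxygen",
    "organophosphorus",
    "lignan_neolignan",
    "organic_polymer",
    "hydrocarbon",
    "hydrocarbon_derivative",
    "organic_anion",
    "organic_cation",
    "organic_zwitterion",
    "carbene",
    "dipolar_1_3",
    "organopnictogen",
    "acetylide",
)

INORGANIC_SUPERCLASSES: tuple[str, ...] = (
    "homogeneous_metal",
    "homogeneous_non_metal",
    "mixed_metal_non_metal",
    "inorganic_salt",
    "miscellaneous_inorganic",
)

ALL_SUPERCLASSES: tuple[str, ...] = ORGANIC_SUPERCLASSES + INORGANIC_SUPERCLASSES

_ENUM_POSITION = {label: i for i, label in enumerate(ALL_SUPERCLASSES)}


@dataclass(frozen=True)
class TaxonomyResult:
    """Kingdom plus the full (possibly overlapping) superclass set."""

    smiles: str
    kingdom: str
    superclasses: frozenset[str]

    def ordered_superclasses(self) -> tuple[str, ...]:
        """Labels in the fixed enumeration order, for stable serialization."""
        return tuple(sorted(self.superclasses, key=_ENUM_POSITION.__getitem__))


# ---------------------------------------------------------------------------
# graph helpers


def _heavy_graph(mol: ParsedMolecule) -> nx.Graph:
    """networkx view of the molecule without explicit-H atom tokens."""
    g = nx.Graph()
    for a in mol.atoms:
        if a.element != "H":
            g.add_node(a.index, element=a.element)
    for b in mol.bonds:
        if b.a in g and b.b in g:
            g.add_edge(b.a, b.b, order=b.order)
    return g


_elem_match = nxiso.categorical_node_match("element", None)
_order_match = nxiso.categorical_edge_match("order", None)


@lru_cache(maxsize=None)
def _pattern_graph(smiles: str) -> nx.Graph:
    return _heavy_graph(parse(smiles))


def _contains_fragment(mol_graph: nx.Graph, pattern_smiles: str) -> bool:
    """Subgraph (monomorphism) match on the element-labelled skeleton.

    Bond orders are deliberately ignored so tautomeric and Kekulé
    variants of the same fragment all match.
    """
    pattern = _pattern_graph(pattern_smiles)
    gm = nxiso.GraphMatcher(mol_graph, pattern, node_match=_elem_match)
    return gm.subgraph_is_monomorphic()


# ---------------------------------------------------------------------------
# kingdom

# Inorganic carbon exceptions, as reference structures.  Matching is by
# whole-molecule graph isomorphism on the H-stripped skeleton with exact
# bond orders and charges ignored, so "S=C=S" and "C(=S)=S" both read as
# carbon disulphide while methanol ("CO") stays organic.
_KINGDOM_EXCEPTIONS: tuple[tuple[str, str], ...] = (
    ("cyanide/isocyanide", "C#N"),
    ("thiophosgene", "ClC(Cl)=S"),
    ("carbon diselenide", "[Se]=C=[Se]"),
    ("carbon monosulphide", "[C]=S"),
    ("carbon monosulphide", "C#S"),
    ("carbon disulphide", "S=C=S"),
    ("carbon subsulphide", "S=C=C=C=S"),
    ("carbon monoxide", "[C]=O"),
    ("carbon monoxide", "C#O"),
    ("carbon suboxide", "O=C=C=C=O"),
    ("dicarbon monoxide", "[C]=C=O"),
)


def _exception_graphs() -> tuple[tuple[frozenset, nx.Graph], ...]:
    out = []
    for _name, smi in _KINGDOM_EXCEPTIONS:
        g = _pattern_graph(smi)
        formula = frozenset(
            (el, n)
            for el, n in _count_elements(g).items()
        )
        out.append((formula, g))
    return tuple(out)


def _count_elements(g: nx.Graph) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _n, d in g.nodes(data=True):
        counts[d["element"]] = counts.get(d["element"], 0) + 1
    return counts


_EXCEPTIONS_CACHE: tuple[tuple[frozenset, nx.Graph], ...] | None = None


def _is_inorganic_carbon_exception(mol: ParsedMolecule) -> bool:
    global _EXCEPTIONS_CACHE
    if _EXCEPTIONS_CACHE is None:
        _EXCEPTIONS_CACHE = _exception_graphs()
    g = _heavy_graph(mol)
    formula = frozenset(_count_elements(g).items())
    for ref_formula, ref in _EXCEPTIONS_CACHE:
        if formula == ref_formula and nx.is_isomorphic(
            g, ref, node_match=_elem_match, edge_match=_order_match
        ):
            return True
    return False


def classify_kingdom(mol: ParsedMolecule,
                     tables: ElementTables = DEFAULT_TABLES) -> str:
    """Organic iff a carbon atom exists and the molecule is not one of
    the listed inorganic carbon compounds."""
    if mol.element_counts.get("C", 0) >= 1 and not _is_inorganic_carbon_exception(mol):
        return ORGANIC
    return INORGANIC


# ---------------------------------------------------------------------------
# shared structural motifs


def _carboxyl_carbons(mol: ParsedMolecule) -> list[int]:
    """Carbons bearing C(=O)-O[H|-]: one double-bonded O plus one
    single-bonded O with no further heavy neighbor (esters excluded)."""
    hits = []
    for c in mol.carbons():
        dbl_o = False
        acid_o = False
        for n in mol.neighbors(c):
            if mol.atoms[n].element != "O":
                continue
            order = mol.bond_order(c, n)
            if order == DOUBLE:
                dbl_o = True
            elif order == SINGLE:
                heavy = [m for m in mol.neighbors(n) if mol.atoms[m].element != "H"]
                if len(heavy) == 1:
                    acid_o = True
        if dbl_o and acid_o:
            hits.append(c)
    return hits


def _benzene_rings(mol: ParsedMolecule) -> list[tuple[int, ...]]:
    """All-carbon six-membered rings, aromatic or alternating Kekulé."""
    out = []
    for ring in mol.rings:
        if len(ring) != 6:
            continue
        if not all(mol.atoms[i].element == "C" for i in ring.atom_indices):
            continue
        if ring.aromatic:
            out.append(ring.atom_indices)
            continue
        cyc = ring.atom_indices
        orders = [mol.bond_order(cyc[k], cyc[(k + 1) % 6]) for k in range(6)]
        if set(orders) <= {SINGLE, DOUBLE} and all(
            orders[k] != orders[(k + 1) % 6] for k in range(6)
        ):
            out.append(cyc)
    return out


def _longest_carbon_path_from(mol: ParsedMolecule, start: int,
                              banned: set[int]) -> int:
    best = 0

    def dfs(u: int, visited: set[int], length: int) -> None:
        nonlocal best
        best = max(best, length)
        for v in mol.neighbors(u):
            if v in visited or v in banned or mol.atoms[v].element != "C":
                continue
            visited.add(v)
            dfs(v, visited, length + 1)
            visited.remove(v)

    dfs(start, {start}, 1)
    return best


def _has_phenylpropane(mol: ParsedMolecule) -> bool:
    """Benzene ring with an exocyclic carbon chain of >= 3 carbons."""
    for ring in _benzene_rings(mol):
        ring_set = set(ring)
        for u in ring:
            for v in mol.neighbors(u):
                if v in ring_set or mol.atoms[v].element != "C":
                    continue
                if _longest_carbon_path_from(mol, v, ring_set) >= 3:
                    return True
    return False


def _is_carbonyl(mol: ParsedMolecule, c: int) -> bool:
    return any(
        mol.atoms[n].element == "O" and mol.bond_order(c, n) == DOUBLE
        for n in mol.neighbors(c)
    )


def _has_polyketide_motif(mol: ParsedMolecule) -> bool:
    """Two consecutive carbonyl/methylene repeats: a C path k1-m1-k2-m2
    with k carbonyl carbons and m plain carbons."""
    carbons = set(mol.carbons())
    carbonyl = {c for c in carbons if _is_carbonyl(mol, c)}
    for k1 in carbonyl:
        for m1 in mol.neighbors(k1):
            if m1 not in carbons or m1 in carbonyl:
                continue
            for k2 in mol.neighbors(m1):
                if k2 == k1 or k2 not in carbonyl:
                    continue
                for m2 in mol.neighbors(k2):
                    if m2 in (k1, m1) or m2 not in carbons or m2 in carbonyl:
                        continue
                    return True
    return False


# Nucleobase and sugar reference fragments (element skeleton only; bond
# orders ignored during matching so tautomers and aromatic forms match).
_BASE_FRAGMENTS = {
    "cytosine": "O=C1N=C(N)C=CN1",
    "adenine": "Nc1ncnc2[nH]cnc12",
    "guanine": "Nc1nc2[nH]cnc2c(=O)[nH]1",
    "thymine": "CC1=CNC(=O)NC1=O",
    "uracil": "O=C1C=CNC(=O)N1",
}
_SUGAR_FRAGMENTS = {
    # furanose ring + CH2OH arm; anomeric OH omitted so glycosides match
    "ribose": "OC1C(O)C(CO)OC1",
    "deoxyribose": "C1OC(CO)C(O)C1",
}


def _has_nucleoside(mol: ParsedMolecule) -> bool:
    # cheap gates before subgraph search
    if (
        mol.element_counts.get("N", 0) < 2
        or mol.element_counts.get("O", 0) < 3
        or len(mol.rings) < 2
    ):
        return False
    g = _heavy_graph(mol)
    has_base = any(_contains_fragment(g, s) for s in _BASE_FRAGMENTS.values())
    if not has_base:
        return False
    return any(_contains_fragment(g, s) for s in _SUGAR_FRAGMENTS.values())


# Polymer heuristic: a contiguous atom-token subsequence of length >= 4
# repeated >= 3 times back-to-back in SMILES atom order.
_POLYMER_UNIT_MIN = 4
_POLYMER_REPEATS = 3


def _has_repeating_unit(mol: ParsedMolecule) -> bool:
    seq = [(a.element, a.aromatic) for a in mol.atoms]
    n = len(seq)
    for unit in range(_POLYMER_UNIT_MIN, n // _POLYMER_REPEATS + 1):
        span = unit * _POLYMER_REPEATS
        for i in range(n - span + 1):
            first = seq[i : i + unit]
            if all(
                seq[i + k * unit : i + (k + 1) * unit] == first
                for k in range(1, _POLYMER_REPEATS)
            ):
                return True
    return False


def _fragment_charges(mol: ParsedMolecule) -> dict[int, int]:
    charges: dict[int, int] = {}
    for a in mol.atoms:
        charges[a.fragment_id] = charges.get(a.fragment_id, 0) + a.formal_charge
    return charges


def _fragment_has_carbon(mol: ParsedMolecule) -> set[int]:
    return {a.fragment_id for a in mol.atoms if a.element == "C"}


_BOND_VALENCE = {SINGLE: 1, DOUBLE: 2, TRIPLE: 3, "aromatic": 1}


def _explicit_valence(mol: ParsedMolecule, i: int) -> int:
    total = sum(_BOND_VALENCE[mol.bond_order(i, n)] for n in mol.neighbors(i))
    return total + mol.atoms[i].explicit_h


# ---------------------------------------------------------------------------
# organic predicates (one per superclass, evaluated independently)


def _p_organoheterocyclic(mol, t):
    return any(
        any(mol.atoms[i].element == "C" for i in r.atom_indices)
        and any(mol.atoms[i].element != "C" for i in r.atom_indices)
        for r in mol.rings
    )


def _p_organosulfur(mol, t):
    return has_bond_between(mol, {"C"}, {"S"})


def _p_lipid(mol, t):
    return bool(_carboxyl_carbons(mol)) and longest_carbon_chain(mol) >= 4


def _p_allene(mol, t):
    for c in mol.carbons():
        dbl = [
            n
            for n in mol.neighbors(c)
            if mol.atoms[n].element == "C" and mol.bond_order(c, n) == DOUBLE
        ]
        if len(dbl) >= 2:
            return True
    return False


def _p_benzenoid(mol, t):
    return bool(_benzene_rings(mol))


def _p_phenylpropanoid_polyketide(mol, t):
    return _has_phenylpropane(mol) or _has_polyketide_motif(mol)


def _p_organic_acid(mol, t):
    return bool(_carboxyl_carbons(mol))


def _p_alkaloid(mol, t):
    return mol.element_counts.get("N", 0) > 0 and mol.net_charge < 0


def _p_organic_salt(mol, t):
    if mol.fragments < 2:
        return False
    charges = _fragment_charges(mol)
    has_pos = any(q > 0 for q in charges.values())
    has_neg = any(q < 0 for q in charges.values())
    return has_pos and has_neg and bool(_fragment_has_carbon(mol))


def _p_organohalogen(mol, t):
    return has_bond_between(mol, {"C"}, t.halogens)


def _p_organometallic(mol, t):
    return has_bond_between(mol, {"C"}, t.metals)


def _p_organic_nitrogen(mol, t):
    return mol.element_counts.get("N", 0) > 0


def _p_nucleoside_nucleotide(mol, t):
    return _has_nucleoside(mol)


def _p_organic_oxygen(mol, t):
    return mol.element_counts.get("O", 0) > 0


def _p_organophosphorus(mol, t):
    return mol.element_counts.get("P", 0) > 0


def _p_lignan_neolignan(mol, t):
    return _has_phenylpropane(mol)


def _p_organic_polymer(mol, t):
    return _has_repeating_unit(mol)


def _p_hydrocarbon(mol, t):
    return set(mol.element_counts) <= {"C", "H"}


def _p_hydrocarbon_derivative(mol, t):
    return not _p_hydrocarbon(mol, t)


def _p_organic_anion(mol, t):
    return mol.net_charge < 0


def _p_organic_cation(mol, t):
    return mol.net_charge > 0


def _p_organic_zwitterion(mol, t):
    return (
        len(mol.positive_atoms) == len(mol.negative_atoms)
        and len(mol.positive_atoms) > 0
        and mol.net_charge == 0
    )


def _p_carbene(mol, t):
    return any(
        a.element == "C"
        and a.bracketed
        and not a.aromatic
        and a.formal_charge == 0
        and _explicit_valence(mol, a.index) == 2
        for a in mol.atoms
    )


def _p_dipolar_1_3(mol, t):
    if mol.net_charge != 0 or not mol.positive_atoms or not mol.negative_atoms:
        return False
    return any(
        graph_distance(mol, p, n) == 2
        for p in mol.positive_atoms
        for n in mol.negative_atoms
    )


def _p_organopnictogen(mol, t):
    return has_bond_between(mol, {"C"}, t.pnictogens)


def _p_acetylide(mol, t):
    for bond in mol.bonds:
        if bond.order != TRIPLE:
            continue
        if not (
            mol.atoms[bond.a].element == "C" and mol.atoms[bond.b].element == "C"
        ):
            continue
        for end in (bond.a, bond.b):
            if any(mol.atoms[n].element in t.metals for n in mol.neighbors(end)):
                return True
    return False


ORGANIC_PREDICATES = {
    "organoheterocyclic": _p_organoheterocyclic,
    "organosulfur": _p_organosulfur,
    "lipid": _p_lipid,
    "allene": _p_allene,
    "benzenoid": _p_benzenoid,
    "phenylpropanoid_polyketide": _p_phenylpropanoid_polyketide,
    "organic_acid": _p_organic_acid,
    "alkaloid": _p_alkaloid,
    "organic_salt": _p_organic_salt,
    "organohalogen": _p_organohalogen,
    "organometallic": _p_organometallic,
    "organic_nitrogen": _p_organic_nitrogen,
    "nucleoside_nucleotide": _p_nucleoside_nucleotide,
    "organic_oxygen": _p_organic_oxygen,
    "organophosphorus": _p_organophosphorus,
    "lignan_neolignan": _p_lignan_neolignan,
    "organic_polymer": _p_organic_polymer,
    "hydrocarbon": _p_hydrocarbon,
    "hydrocarbon_derivative": _p_hydrocarbon_derivative,
    "organic_anion": _p_organic_anion,
    "organic_cation": _p_organic_cation,
    "organic_zwitterion": _p_organic_zwitterion,
    "carbene": _p_carbene,
    "dipolar_1_3": _p_dipolar_1_3,
    "organopnictogen": _p_organopnictogen,
    "acetylide": _p_acetylide,
}
assert tuple(ORGANIC_PREDICATES) == ORGANIC_SUPERCLASSES


def classify_organic(mol: ParsedMolecule,
                     tables: ElementTables = DEFAULT_TABLES) -> frozenset[str]:
    """Evaluate all 26 organic predicates; return every label that fires."""
    return frozenset(
        label for label, pred in ORGANIC_PREDICATES.items() if pred(mol, tables)
    )


def classify_inorganic(mol: ParsedMolecule,
                       tables: ElementTables = DEFAULT_TABLES) -> frozenset[str]:
    """Evaluate the 5 inorganic predicates.  The first four are element
    and charge tests; miscellaneous fires iff none of them did, so the
    result is never empty."""
    elements = set(mol.element_counts)
    labels = set()
    if elements and elements <= tables.metals:
        labels.add("homogeneous_metal")
    if elements and elements <= tables.nonmetals:
        labels.add("homogeneous_non_metal")
    if (elements & tables.metals) and (elements & tables.nonmetals):
        labels.add("mixed_metal_non_metal")
    if mol.positive_atoms or mol.negative_atoms:
        labels.add("inorganic_salt")
    if not labels:
        labels.add("miscellaneous_inorganic")
    return frozenset(labels)


def classify(smiles: str, tables: ElementTables = DEFAULT_TABLES) -> TaxonomyResult:
    """Parse, assign the kingdom, and collect the matching superclasses."""
    mol = parse(smiles)
    kingdom = classify_kingdom(mol, tables)
    if kingdom == ORGANIC:
        labels = classify_organic(mol, tables)
    else:
        labels = classify_inorganic(mol, tables)
    return TaxonomyResult(smiles=mol.smiles, kingdom=kingdom, superclasses=labels)
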