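"""Shared fixtures: a seeded random-SMILES generator and independent
brute-force oracles operating on an explicit adjacency matrix.

The oracles deliberately avoid the package's own graph traversals: they
work on a numpy adjacency matrix derived from the bond list, using
scipy/networkx/itertools machinery, so agreement is a genuine
cross-check of the BFS/DFS code inside the package.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from smitax.smiles import ParsedMolecule

# ---------------------------------------------------------------------------
# random valid SMILES


_PLAIN_ATOMS = ["C", "C", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]
_BRACKET_ATOMS = [
    ("N", +1), ("O", -1), ("C", -1), ("N", -1), ("Na", +1), ("Cl", -1),
    ("Fe", 0), ("K", +1), ("Se", 0), ("As", 0), ("C", 0),
]
_ORDERS = ["", "", "", "", "=", "=", "#"]
_ORDER_CHAR = {"": "", "=": "=", "#": "#"}


def random_smiles(rng: random.Random, max_atoms: int = 12) -> str:
    """Emit one syntactically valid SMILES of <= max_atoms atoms.

    Builds a random tree (plus up to two extra ring-closure edges) and
    writes it out by depth-first traversal — an emitter, not a parser,
    so it shares no code with the package's reader.
    """
    n = rng.randint(1, max_atoms)
    atoms = []
    for _ in range(n):
        if rng.random() < 0.25:
            el, q = rng.choice(_BRACKET_ATOMS)
            if q > 0:
                tok = f"[{el}{'+' * q if rng.random() < 0.5 else '+' + str(q)}]" if q > 1 else f"[{el}+]"
            elif q < 0:
                tok = f"[{el}-]"
            else:
                tok = f"[{el}]"
            atoms.append(tok)
        else:
            atoms.append(rng.choice(_PLAIN_ATOMS))
    parent = {i: rng.randrange(i) for i in range(1, n)}
    edges = {(parent[i], i): rng.choice(_ORDERS) for i in parent}
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, p in parent.items():
        children[p].append(i)

    # extra non-tree edges become ring closures
    ring_edges = []
    candidates = [
        (a, b)
        for a, b in itertools.combinations(range(n), 2)
        if (a, b) not in edges and b not in children.get(a, [])
    ]
    candidates = [
        (a, b) for a, b in candidates if parent.get(b) != a and parent.get(a) != b
    ]
    rng.shuffle(candidates)
    for a, b in candidates[: rng.randint(0, 2)]:
        ring_edges.append((a, b, rng.choice(["", "", "="])))

    ring_digit: dict[int, list[tuple[int, str]]] = {}
    for digit, (a, b, o) in enumerate(ring_edges, start=1):
        ring_digit.setdefault(a, []).append((digit, o))
        ring_digit.setdefault(b, []).append((digit, ""))

    out: list[str] = []

    def walk(u: int) -> None:
        out.append(atoms[u])
        for digit, o in ring_digit.get(u, []):
            out.append(_ORDER_CHAR[o] + str(digit))
        kids = children[u]
        for k, v in enumerate(kids):
            bond = _ORDER_CHAR[edges[(u, v)]]
            if k < len(kids) - 1:
                out.append("(" + bond)
                walk(v)
                out.append(")")
            else:
                out.append(bond)
                walk(v)

    walk(0)
    s = "".join(out)
    if rng.random() < 0.15:  # dot-separated second fragment
        s += "." + rng.choice(["[Na+]", "[Cl-]", "O", "CC", "[K+]"])
    return s


_HANDWRITTEN = [
    "c1ccccc1",
    "C1=CC=CC=C1",
    "c1ccncc1",
    "c1cnc[nH]1",
    "c1ccc2ccccc2c1",
    "CC(=O)O",
    "CC(=O)[O-].[Na+]",
    "C[N+](C)(C)CCO",
    "[C](Cl)Cl",
    "[Li]C#C",
    "O=C=C=C=O",
    "S=C=S",
    "[Na+].[Cl-]",
    "C%10CCCCC%10",
    "N[C@@H](C)C(=O)O",
    "C/C=C/C",
    "[13CH4]",
    "CCOP(=O)OCC",
]


@pytest.fixture(scope="session")
def smiles_corpus() -> list[str]:
    """~600 valid SMILES of <= 12 atoms: fuzzed plus hand-written."""
    rng = random.Random(20260923)
    return [random_smiles(rng) for _ in range(600)] + _HANDWRITTEN


# ---------------------------------------------------------------------------
# adjacency-matrix oracles


def adjacency_matrix(mol: ParsedMolecule) -> np.ndarray:
    n = len(mol.atoms)
    a = np.zeros((n, n), dtype=int)
    for b in mol.bonds:
        a[b.a, b.b] = a[b.b, b.a] = 1
    return a


def oracle_bond_between(mol: ParsedMolecule, set_a, set_b) -> bool:
    a = adjacency_matrix(mol)
    els = [t.element for t in mol.atoms]
    n = len(els)
    return any(
        a[i, j]
        and (
            (els[i] in set_a and els[j] in set_b)
            or (els[i] in set_b and els[j] in set_a)
        )
        for i in range(n)
        for j in range(n)
    )


def oracle_longest_carbon_chain(mol: ParsedMolecule) -> int:
    """Exhaustive simple-path search on the carbon submatrix."""
    carbons = [t.index for t in mol.atoms if t.element == "C"]
    if not carbons:
        return 0
    a = adjacency_matrix(mol)
    best = 1
    # iterative stack-based enumeration of every simple path
    for start in carbons:
        stack = [(start, frozenset([start]))]
        while stack:
            u, seen = stack.pop()
            best = max(best, len(seen))
            for v in carbons:
                if a[u, v] and v not in seen:
                    stack.append((v, seen | {v}))
    return best


def oracle_distance(mol: ParsedMolecule, i: int, j: int):
    d = shortest_path(adjacency_matrix(mol).astype(float), unweighted=True)
    val = d[i, j]
    return None if np.isinf(val) else int(val)


def bond_graph(mol: ParsedMolecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(t.index for t in mol.atoms)
    g.add_edges_from((b.a, b.b) for b in mol.bonds)
    return g


def oracle_ring_count(mol: ParsedMolecule) -> int:
    """Cyclomatic number: one recovered ring per closure digit pair."""
    g = bond_graph(mol)
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
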