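"""A small SMILES reader producing a structural digest.

This is not a full chemistry toolkit: no valence model, no implicit
hydrogens, no aromaticity perception beyond the lowercase flags in the
input, no canonicalization.  It reads a SMILES string into atoms, bonds,
rings (one per ring-closure digit pair), dot-separated fragments and
formal charges — exactly the structural vocabulary the taxonomy rules
are written in.  Stereo markers (``/ \\ @ @@``) and isotope prefixes are
accepted and discarded; they affect no rule.

The grammar accepted is the common core of SMILES: organic-subset atoms
(``B C N O P S F Cl Br I`` and aromatic ``b c n o p s``), bracket atoms
``[isotope? symbol chiral? Hn? charge? :class?]``, branches, ring
closures (``1``–``9`` and ``%nn``), bond symbols ``- = # : / \\`` and the
dot disconnect.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

from .elements import PERIODIC_TABLE

__all__ = [
    "SmilesError",
    "AtomToken",
    "Bond",
    "Ring",
    "ParsedMolecule",
    "tokenize",
    "build_structure",
    "parse",
    "has_bond_between",
    "longest_carbon_chain",
    "graph_distance",
]

# bond order vocabulary
SINGLE, DOUBLE, TRIPLE, AROMATIC = "single", "double", "triple", "aromatic"

_BOND_CHARS = {"-": SINGLE, "=": DOUBLE, "#": TRIPLE, ":": AROMATIC,
               "/": SINGLE, "\\": SINGLE}
_ORGANIC_UPPER = {"B", "C", "N", "O", "P", "S", "F", "I"}      # one-letter
_ORGANIC_TWO = {"Cl", "Br"}
_AROMATIC_LOWER = {"b", "c", "n", "o", "p", "s"}
_AROMATIC_BRACKET = {"b", "c", "n", "o", "p", "s", "as", "se", "si", "te"}


class SmilesError(ValueError):
    """Malformed SMILES; ``position`` is the 0-based offending index."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


@dataclass
class AtomToken:
    element: str
    aromatic: bool = False
    formal_charge: int = 0
    explicit_h: int = 0
    bracketed: bool = False
    index: int = -1
    fragment_id: int = 0


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str

    def pair(self) -> frozenset[int]:
        return frozenset((self.a, self.b))


@dataclass(frozen=True)
class Ring:
    atom_indices: tuple[int, ...]
    aromatic: bool

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass
class ParsedMolecule:
    """Structural digest of one SMILES string."""

    smiles: str
    atoms: list[AtomToken]
    bonds: list[Bond]
    rings: list[Ring]
    fragments: int
    net_charge: int
    element_counts: dict[str, int]
    positive_atoms: frozenset[int]
    negative_atoms: frozenset[int]
    _adjacency: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _order: dict[frozenset, str] = field(default_factory=dict, repr=False)

    @property
    def adjacency(self) -> dict[int, list[int]]:
        return self._adjacency

    def bond_order(self, a: int, b: int) -> str | None:
        return self._order.get(frozenset((a, b)))

    def neighbors(self, i: int) -> list[int]:
        return self._adjacency.get(i, [])

    def carbons(self) -> list[int]:
        return [a.index for a in self.atoms if a.element == "C"]


# ---------------------------------------------------------------------------
# scanner


def _scan(smiles: str):
    """Yield (kind, payload, position) events.

    Kinds: ``atom`` (AtomToken without index/fragment), ``bond`` (order),
    ``open`` / ``close`` (branch), ``ring`` (closure number), ``dot``.
    """
    s = smiles
    i, n = 0, len(s)
    depth = 0
    while i < n:
        ch = s[i]
        if ch in _BOND_CHARS:
            yield ("bond", _BOND_CHARS[ch], i)
            i += 1
        elif ch == "(":
            depth += 1
            yield ("open", None, i)
            i += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SmilesError("unbalanced ')'", i)
            yield ("close", None, i)
            i += 1
        elif ch == ".":
            yield ("dot", None, i)
            i += 1
        elif ch.isdigit():
            yield ("ring", int(ch), i)
            i += 1
        elif ch == "%":
            if len(s[i + 1 : i + 3]) < 2 or not s[i + 1 : i + 3].isdigit():
                raise SmilesError("'%' must be followed by two digits", i)
            yield ("ring", int(s[i + 1 : i + 3]), i)
            i += 3
        elif ch == "[":
            atom, i2 = _parse_bracket(s, i)
            yield ("atom", atom, i)
            i = i2
        elif ch == "]":
            raise SmilesError("unbalanced ']'", i)
        elif ch == "*":
            yield ("atom", AtomToken(element="*"), i)
            i += 1
        elif ch.isupper():
            two = s[i : i + 2]
            if two in _ORGANIC_TWO:
                yield ("atom", AtomToken(element=two), i)
                i += 2
            elif ch in _ORGANIC_UPPER:
                yield ("atom", AtomToken(element=ch), i)
                i += 1
            else:
                raise SmilesError(f"unrecognized symbol {ch!r}", i)
        elif ch in _AROMATIC_LOWER:
            yield ("atom", AtomToken(element=ch.upper(), aromatic=True), i)
            i += 1
        elif ch.isspace():
            raise SmilesError("whitespace inside SMILES", i)
        else:
            raise SmilesError(f"unrecognized symbol {ch!r}", i)
    if depth != 0:
        raise SmilesError("unbalanced '('", n - 1)


def _parse_bracket(s: str, start: int) -> tuple[AtomToken, int]:
    i = start + 1
    n = len(s)
    # isotope prefix, ignored
    while i < n and s[i].isdigit():
        i += 1
    if i >= n:
        raise SmilesError("unterminated bracket atom", start)
    # element symbol
    aromatic = False
    ch = s[i]
    if ch == "*":
        element = "*"
        i += 1
    elif ch.isupper():
        two = s[i : i + 2]
        if len(two) == 2 and two[1].islower() and two in PERIODIC_TABLE:
            element, i = two, i + 2
        elif ch in PERIODIC_TABLE:
            element, i = ch, i + 1
        else:
            raise SmilesError(f"unknown element {ch!r}", i)
    elif ch.islower():
        two = s[i : i + 2]
        if two in _AROMATIC_BRACKET:
            element, i, aromatic = two.capitalize(), i + 2, True
        elif ch in _AROMATIC_BRACKET:
            element, i, aromatic = ch.upper(), i + 1, True
        else:
            raise SmilesError(f"unknown aromatic symbol {ch!r}", i)
    else:
        raise SmilesError(f"expected element symbol, got {ch!r}", i)

    explicit_h = 0
    charge = 0
    while i < n and s[i] != "]":
        ch = s[i]
        if ch == "@":
            i += 1
        elif ch == "H":
            i += 1
            digits = ""
            while i < n and s[i].isdigit():
                digits += s[i]
                i += 1
            explicit_h = int(digits) if digits else 1
        elif ch in "+-":
            sign = 1 if ch == "+" else -1
            i += 1
            digits = ""
            while i < n and s[i].isdigit():
                digits += s[i]
                i += 1
            if digits:
                charge += sign * int(digits)
            else:
                count = 1
                while i < n and s[i] == ch:
                    count += 1
                    i += 1
                charge += sign * count
        elif ch == ":":
            i += 1
            if i >= n or not s[i].isdigit():
                raise SmilesError("atom class ':' needs digits", i)
            while i < n and s[i].isdigit():
                i += 1
        else:
            raise SmilesError(f"unrecognized bracket content {ch!r}", i)
    if i >= n:
        raise SmilesError("unterminated bracket atom", start)
    if not -8 <= charge <= 8:
        raise SmilesError(f"formal charge {charge} out of range", start)
    return (
        AtomToken(element=element, aromatic=aromatic, formal_charge=charge,
                  explicit_h=explicit_h, bracketed=True),
        i + 1,
    )


# ---------------------------------------------------------------------------
# public operations


def tokenize(smiles: str) -> list[AtomToken]:
    """Return the ordered atom sequence of a SMILES string.

    Non-atom syntax (bonds, branches, ring closures, dots) is consumed
    but produces no token.  Raises :class:`SmilesError` on malformed
    input, naming the offending position.
    """
    if not smiles or not smiles.strip():
        raise SmilesError("empty SMILES string", 0)
    atoms: list[AtomToken] = []
    fragment = 0
    for kind, payload, _pos in _scan(smiles.strip()):
        if kind == "atom":
            payload.index = len(atoms)
            payload.fragment_id = fragment
            atoms.append(payload)
        elif kind == "dot":
            fragment += 1
    if not atoms:
        raise SmilesError("SMILES contains no atoms", 0)
    return atoms


def build_structure(atoms: list[AtomToken], smiles: str) -> ParsedMolecule:
    """Build the molecular graph by the standard SMILES walk.

    Adjacency follows previous-atom linkage with a parenthesis stack for
    branches; each ring-closure digit pair adds one bond and yields one
    recovered :class:`Ring`; a dot severs linkage.  Bond order defaults
    to single, or aromatic when both endpoints are aromatic and no bond
    symbol was written.
    """
    smiles = smiles.strip()
    bonds: list[Bond] = []
    order: dict[frozenset, str] = {}
    adjacency: dict[int, list[int]] = {a.index: [] for a in atoms}
    closure_bonds: list[tuple[int, int]] = []

    prev: int | None = None
    pending: str | None = None
    stack: list[int | None] = []
    ring_open: dict[int, tuple[int, str | None, int]] = {}
    cursor = -1  # index into atoms, advanced on each atom event

    def add_bond(a: int, b: int, o: str | None, pos: int) -> None:
        if a == b:
            raise SmilesError("ring closure bonds an atom to itself", pos)
        key = frozenset((a, b))
        if key in order:
            raise SmilesError("duplicate bond between the same atom pair", pos)
        if o is None:
            o = AROMATIC if atoms[a].aromatic and atoms[b].aromatic else SINGLE
        bonds.append(Bond(a, b, o))
        order[key] = o
        adjacency[a].append(b)
        adjacency[b].append(a)

    for kind, payload, pos in _scan(smiles):
        if kind == "atom":
            cursor += 1
            here = cursor
            if prev is not None:
                add_bond(prev, here, pending, pos)
            pending = None
            prev = here
        elif kind == "bond":
            pending = payload
        elif kind == "open":
            if prev is None:
                raise SmilesError("branch before any atom", pos)
            stack.append(prev)
        elif kind == "close":
            prev = stack.pop()
        elif kind == "dot":
            if pending is not None:
                raise SmilesError("bond symbol before dot", pos)
            prev = None
        elif kind == "ring":
            if prev is None:
                raise SmilesError("ring closure before any atom", pos)
            num = payload
            if num in ring_open:
                other, obond, _opos = ring_open.pop(num)
                add_bond(other, prev, pending or obond, pos)
                closure_bonds.append((other, prev))
            else:
                ring_open[num] = (prev, pending, pos)
            pending = None
    if ring_open:
        num, (_a, _b, pos) = next(iter(ring_open.items()))
        raise SmilesError(f"unmatched ring-closure digit {num}", pos)

    rings = [_recover_ring(a, b, adjacency, atoms) for a, b in closure_bonds]

    counts = Counter(a.element for a in atoms)
    pos_atoms = frozenset(a.index for a in atoms if a.formal_charge > 0)
    neg_atoms = frozenset(a.index for a in atoms if a.formal_charge < 0)
    return ParsedMolecule(
        smiles=smiles,
        atoms=atoms,
        bonds=bonds,
        rings=rings,
        fragments=(max(a.fragment_id for a in atoms) + 1),
        net_charge=sum(a.formal_charge for a in atoms),
        element_counts=dict(counts),
        positive_atoms=pos_atoms,
        negative_atoms=neg_atoms,
        _adjacency=adjacency,
        _order=order,
    )


def _recover_ring(a: int, b: int, adjacency: dict[int, list[int]],
                  atoms: list[AtomToken]) -> Ring:
    """Shortest cycle through the closure bond a–b: BFS a→b avoiding it."""
    parent: dict[int, int] = {a: -1}
    q = deque([a])
    while q:
        u = q.popleft()
        if u == b:
            break
        for v in adjacency[u]:
            if u == a and v == b:
                continue  # skip the closure bond itself
            if v not in parent:
                parent[v] = u
                q.append(v)
    path = [b]
    while path[-1] != a:
        path.append(parent[path[-1]])
    cycle = tuple(reversed(path))
    return Ring(cycle, aromatic=all(atoms[i].aromatic for i in cycle))


def parse(smiles: str) -> ParsedMolecule:
    """Tokenize and build in one call."""
    return build_structure(tokenize(smiles), smiles)


def has_bond_between(mol: ParsedMolecule, set_a: frozenset[str] | set[str],
                     set_b: frozenset[str] | set[str]) -> bool:
    """True iff some bond joins an element of ``set_a`` to one of ``set_b``."""
    for bond in mol.bonds:
        ea, eb = mol.atoms[bond.a].element, mol.atoms[bond.b].element
        if (ea in set_a and eb in set_b) or (ea in set_b and eb in set_a):
            return True
    return False


def longest_carbon_chain(mol: ParsedMolecule) -> int:
    """Atom count of the longest simple path in the carbon-only subgraph."""
    carbons = set(mol.carbons())
    if not carbons:
        return 0
    best = 1

    def dfs(u: int, visited: set[int], length: int) -> None:
        nonlocal best
        best = max(best, length)
        for v in mol.neighbors(u):
            if v in carbons and v not in visited:
                visited.add(v)
                dfs(v, visited, length + 1)
                visited.remove(v)

    for start in carbons:
        dfs(start, {start}, 1)
    return best


def graph_distance(mol: ParsedMolecule, i: int, j: int) -> int | None:
    """Bond-count distance between atoms i and j; None if disconnected."""
    if i == j:
        return 0
    dist = {i: 0}
    q = deque([i])
    while q:
        u = q.popleft()
        for v in mol.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                if v == j:
                    return dist[v]
                q.append(v)
    return None
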