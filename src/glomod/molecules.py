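"""Heavy-atom molecular graphs of the eight amino-acid stimuli.

Structures are the neutral (non-zwitterionic) forms, heavy atoms only, with
explicit bond orders; aromatic ring atoms are flagged so that atom-pair
typing can assign them one pi electron each (the convention of Carhart-style
descriptors). Connection tables are written by hand from the standard
structures; each molecule also records the public compound-registry number
it is scored under.

Note on registry numbers: the stimulus panel's published reference list
assigns 6106 to "I" and 6306 to "L", but in the public registry 6106 is
L-leucine and 6306 is L-isoleucine. ``BY_LETTER`` maps letters to the named
molecule; ``PUBLISHED_REFERENCE_LISTING`` maps letters to the listed registry
numbers (resolving each number to its true structure), so that similarity
scores can be reproduced either by molecule identity or by the published
listing. Only the L/I pair differs between the two mappings.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass


@dataclass(frozen=True)
class MoleculeGraph:
    """Element-labeled heavy-atom graph with bond orders and aromatic flags."""

    name: str
    letter: str
    cid: int
    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int, float], ...]   # (i, j, order)
    aromatic: frozenset[int] = frozenset()

    def __post_init__(self):
        n = len(self.elements)
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError(f"{self.name}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.name}: bond index out of range")
        if n and len(self._components()) != 1:
            raise ValueError(f"{self.name}: graph is disconnected")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def adjacency(self) -> tuple[frozenset[int], ...]:
        adj = [set() for _ in self.elements]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return tuple(frozenset(s) for s in adj)

    def _components(self) -> list[set[int]]:
        adj = self.adjacency
        seen: set[int] = set()
        comps = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            comp = {start}
            queue = deque([start])
            while queue:
                u = queue.popleft()
                for v in adj[u]:
                    if v not in comp:
                        comp.add(v)
                        queue.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    def pi_electrons(self) -> tuple[int, ...]:
        """Per-atom pi-electron count: aromatic atoms get 1, others the sum
        of (bond order - 1) over incident bonds."""
        pi = [0.0] * self.n_atoms
        for i, j, order in self.bonds:
            pi[i] += order - 1.0
            pi[j] += order - 1.0
        return tuple(1 if i in self.aromatic else int(round(p))
                     for i, p in enumerate(pi))

    def degrees(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.adjacency)

    def shortest_path_lengths(self) -> dict[tuple[int, int], int]:
        """All-pairs topological distances (bond counts) by BFS."""
        adj = self.adjacency
        dist: dict[tuple[int, int], int] = {}
        for src in range(self.n_atoms):
            d = {src: 0}
            queue = deque([src])
            while queue:
                u = queue.popleft()
                for v in adj[u]:
                    if v not in d:
                        d[v] = d[u] + 1
                        queue.append(v)
            for tgt, dd in d.items():
                if src < tgt:
                    dist[(src, tgt)] = dd
        return dist


def _backbone(atoms: list[str], bonds: list[tuple[int, int, float]], attach: int):
    """Append the alpha-amino-acid backbone CA(N)-C(=O)-OH bonded to ``attach``.

    Returns the index of CA. With ``attach < 0`` the backbone is standalone
    (glycine-like fragment)."""
    ca = len(atoms)
    atoms += ["C", "N", "C", "O", "O"]          # CA, N, carboxyl C, =O, -OH
    if attach >= 0:
        bonds.append((attach, ca, 1.0))
    bonds += [(ca, ca + 1, 1.0), (ca, ca + 2, 1.0),
              (ca + 2, ca + 3, 2.0), (ca + 2, ca + 4, 1.0)]
    return ca


def _methionine() -> MoleculeGraph:
    atoms = ["C", "S", "C", "C"]                 # CH3-S-CH2-CH2-
    bonds = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
    _backbone(atoms, bonds, attach=3)
    return MoleculeGraph("L-methionine", "M", 6137, tuple(atoms), tuple(bonds))


def _leucine() -> MoleculeGraph:
    atoms = ["C", "C", "C", "C"]                 # (CH3)2-CH-CH2-
    bonds = [(0, 1, 1.0), (2, 1, 1.0), (1, 3, 1.0)]
    _backbone(atoms, bonds, attach=3)
    return MoleculeGraph("L-leucine", "L", 6106, tuple(atoms), tuple(bonds))


def _isoleucine() -> MoleculeGraph:
    atoms = ["C", "C", "C", "C"]                 # CH3-CH2-CH(CH3)-
    bonds = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
    ca = _backbone(atoms, bonds, attach=2)
    return MoleculeGraph("L-isoleucine", "I", 6306, tuple(atoms), tuple(bonds))


def _histidine() -> MoleculeGraph:
    # imidazole ring: CG(0) ND1(1) CE1(2) NE2(3) CD2(4), Kekule orders
    atoms = ["C", "N", "C", "N", "C", "C"]       # ring + CB(5)
    bonds = [(0, 1, 1.0), (1, 2, 2.0), (2, 3, 1.0), (3, 4, 1.0), (4, 0, 2.0),
             (0, 5, 1.0)]
    _backbone(atoms, bonds, attach=5)
    return MoleculeGraph("L-histidine", "H", 6274, tuple(atoms), tuple(bonds),
                         aromatic=frozenset(range(5)))


def _lysine() -> MoleculeGraph:
    atoms = ["N", "C", "C", "C", "C"]            # NZ-CE-CD-CG-CB-
    bonds = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0)]
    _backbone(atoms, bonds, attach=4)
    return MoleculeGraph("L-lysine", "K", 5962, tuple(atoms), tuple(bonds))


def _arginine() -> MoleculeGraph:
    # guanidine: NH1(0)=CZ(2), NH2(1)-CZ, CZ-NE(3); chain NE-CD(4)-CG(5)-CB(6)
    atoms = ["N", "N", "C", "N", "C", "C", "C"]
    bonds = [(0, 2, 2.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0),
             (4, 5, 1.0), (5, 6, 1.0)]
    _backbone(atoms, bonds, attach=6)
    return MoleculeGraph("L-arginine", "R", 6322, tuple(atoms), tuple(bonds))


def _phenylalanine() -> MoleculeGraph:
    atoms = ["C"] * 6 + ["C"]                    # benzene 0-5, CB(6)
    bonds = [(i, (i + 1) % 6, 1.0) for i in range(6)] + [(0, 6, 1.0)]
    _backbone(atoms, bonds, attach=6)
    return MoleculeGraph("L-phenylalanine", "F", 6140, tuple(atoms), tuple(bonds),
                         aromatic=frozenset(range(6)))


def _tryptophan() -> MoleculeGraph:
    # indole: N1(0) C2(1) C3(2) C3a(3) C4(4) C5(5) C6(6) C7(7) C7a(8); CB(9)
    atoms = ["N", "C", "C", "C", "C", "C", "C", "C", "C", "C"]
    bonds = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0), (4, 5, 1.0),
             (5, 6, 1.0), (6, 7, 1.0), (7, 8, 1.0), (8, 0, 1.0), (3, 8, 1.0),
             (2, 9, 1.0)]
    _backbone(atoms, bonds, attach=9)
    return MoleculeGraph("L-tryptophan", "W", 6305, tuple(atoms), tuple(bonds),
                         aromatic=frozenset(range(9)))


#: Panel molecules keyed by their single-letter stimulus code.
BY_LETTER: dict[str, MoleculeGraph] = {
    m.letter: m
    for m in (_methionine(), _leucine(), _isoleucine(), _histidine(),
              _lysine(), _arginine(), _phenylalanine(), _tryptophan())
}

#: Molecules keyed by their public registry number.
BY_CID: dict[int, MoleculeGraph] = {m.cid: m for m in BY_LETTER.values()}

#: The published reference-number listing: letter -> registry number as
#: printed. Identical to ``BY_LETTER`` except that "L" resolves to 6306
#: (isoleucine's number) and "I" to 6106 (leucine's number).
PUBLISHED_REFERENCE_LISTING: dict[str, int] = {
    "H": 6274, "W": 6305, "F": 6140, "R": 6322,
    "K": 5962, "M": 6137, "I": 6106, "L": 6306,
}


def resolve(letter: str, by_reference_listing: bool = False) -> MoleculeGraph:
    """Molecule for a panel letter, either by identity or by the published
    reference-number listing."""
    if by_reference_listing:
        return BY_CID[PUBLISHED_REFERENCE_LISTING[letter]]
    return BY_LETTER[letter]


def from_molfile(text: str, name: str = "molfile", letter: str = "?") -> MoleculeGraph:
    """Parse a V2000 connection table (heavy atoms only; hydrogens dropped)."""
    lines = text.splitlines()
    counts = lines[3]
    n_atoms, n_bonds = int(counts[0:3]), int(counts[3:6])
    elements, keep = [], {}
    for i in range(n_atoms):
        parts = lines[4 + i].split()
        el = parts[3]
        if el != "H":
            keep[i] = len(elements)
            elements.append(el)
    bonds = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        a, b, order = int(line[0:3]) - 1, int(line[3:6]) - 1, float(int(line[6:9]))
        if a in keep and b in keep:
            aromatic_bond = order == 4.0
            bonds.append((keep[a], keep[b], 1.5 if aromatic_bond else order))
    aromatic = frozenset(i for a, b, o in bonds if o == 1.5 for i in (a, b))
    bonds = tuple((a, b, 1.0 if o == 1.5 else o) for a, b, o in bonds)
    return MoleculeGraph(name, letter, cid=0, elements=tuple(elements),
                         bonds=bonds, aromatic=aromatic)


def from_smiles(smiles: str, name: str = "smiles", letter: str = "?") -> MoleculeGraph:
    """Parse a SMILES string (requires the optional rdkit dependency)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SMILES input requires rdkit; supply a MoleculeGraph "
                          "or MOL connection table instead") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         1.0 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds())
    aromatic = frozenset(a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic())
    return MoleculeGraph(name, letter, cid=0, elements=elements, bonds=bonds,
                         aromatic=aromatic)
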