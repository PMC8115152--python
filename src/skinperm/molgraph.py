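"""Molecular graphs and Kier-Hall connectivity indices.

SMILES are parsed with RDKit; the hydrogen-depleted graph keeps only heavy
atoms, with the simple vertex degree ``delta`` (number of bonded heavy atoms)
and the valence vertex degree ``delta_v``.  Molecular connectivity indices of
order *k* (chi path indices) sum, over every simple path of *k* edges, the
reciprocal square root of the product of the (valence) degrees of the path's
vertices.  The third-order valence index X3v is the one used by the skin
permeability model; orders 0-5 are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Molecule",
    "HDepletedGraph",
    "SmilesParseError",
    "parse_smiles",
    "heavy_graph",
    "connectivity_index",
    "x3v",
]

MAX_PATH_ORDER = 5


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a usable molecule."""

    def __init__(self, smiles: str, reason: str):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"cannot parse SMILES {smiles!r}: {reason}")


# elements tolerated in neutral organics for this model; anything metallic is
# rejected up front ("no counterions or organometallics" in the data set)
_ORGANIC_Z = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 33, 34, 35, 53}


@dataclass(frozen=True)
class Molecule:
    """Parsed 2D structure (connectivity only; no geometry).

    ``atoms`` holds ``(element symbol, formal charge, attached-H count)`` per
    heavy atom; ``bonds`` holds ``(i, j, order)`` with order one of
    ``1, 2, 3, "aromatic"``.
    """

    atoms: tuple
    bonds: tuple
    source_smiles: str
    canonical_smiles: str
    rdmol: Chem.Mol = field(repr=False, compare=False)

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms_total(self) -> int:
        """Total atom count, hydrogens included."""
        return len(self.atoms) + sum(h for _, _, h in self.atoms)


def parse_smiles(smiles: str, *, allow_charged: bool = False) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Aromaticity is perceived and implicit hydrogens counted by RDKit.
    Charged species and organometallics are rejected unless
    ``allow_charged`` is set, mirroring the curation rule of the modeled
    data set.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty input")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(smiles, "RDKit could not perceive a valid structure")
    for atom in rdmol.GetAtoms():
        if atom.GetAtomicNum() not in _ORGANIC_Z:
            raise SmilesParseError(
                smiles,
                f"atom {atom.GetIdx()} ({atom.GetSymbol()}) is outside the "
                "neutral-organic element set (no organometallics supported)",
            )
    net_charge = sum(a.GetFormalCharge() for a in rdmol.GetAtoms())
    if not allow_charged and net_charge != 0:
        raise SmilesParseError(
            smiles,
            f"net formal charge {net_charge:+d} (no ions or counterions "
            "supported; dipolar neutral groups such as nitro are fine)",
        )
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs()) for a in rdmol.GetAtoms()
    )
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: "aromatic",
    }
    bonds = []
    for b in rdmol.GetBonds():
        if b.GetBondType() not in order_map:
            raise SmilesParseError(smiles, f"unsupported bond type {b.GetBondType()}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map[b.GetBondType()]))
    return Molecule(
        atoms=atoms,
        bonds=tuple(bonds),
        source_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(rdmol),
        rdmol=rdmol,
    )


_PT = Chem.GetPeriodicTable()


def _valence_degree(atom: Chem.Atom) -> float:
    """Kier-Hall valence vertex degree.

    delta_v = Zv - h for second-row atoms and (Zv - h)/(Z - Zv - 1) for
    heavier ones, with Zv the valence-electron count and h the number of
    attached hydrogens.
    """
    z = atom.GetAtomicNum()
    zv = _PT.GetNOuterElecs(z)
    h = atom.GetTotalNumHs()
    if z <= 10:
        return float(zv - h)
    return (zv - h) / float(z - zv - 1)


@dataclass(frozen=True)
class HDepletedGraph:
    """Hydrogen-depleted molecular graph with simple and valence degrees."""

    n_vertices: int
    edges: tuple  # undirected (i, j) with i < j
    delta: tuple
    delta_v: tuple
    adjacency: tuple  # adjacency[i] = tuple of neighbours of i

    def __post_init__(self):
        for i, d in enumerate(self.delta):
            if d != len(self.adjacency[i]):
                raise ValueError(f"delta[{i}] inconsistent with adjacency")


def heavy_graph(mol: Molecule) -> HDepletedGraph:
    """Build the H-depleted graph of a molecule.

    A single heavy atom yields a one-vertex graph with degree zero.
    """
    n = mol.n_heavy
    neighbours = [[] for _ in range(n)]
    edges = []
    for i, j, _order in mol.bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)
        edges.append((min(i, j), max(i, j)))
    delta = tuple(len(nb) for nb in neighbours)
    delta_v = tuple(_valence_degree(a) for a in mol.rdmol.GetAtoms())
    return HDepletedGraph(
        n_vertices=n,
        edges=tuple(sorted(edges)),
        delta=delta,
        delta_v=delta_v,
        adjacency=tuple(tuple(sorted(nb)) for nb in neighbours),
    )


def _simple_paths(g: HDepletedGraph, k: int):
    """Yield every simple path of k edges exactly once (undirected)."""
    if k == 0:
        for v in range(g.n_vertices):
            yield (v,)
        return

    def extend(path, seen):
        if len(path) == k + 1:
            # count each undirected path once: orient by endpoint index
            if path[0] < path[-1]:
                yield tuple(path)
            return
        for nb in g.adjacency[path[-1]]:
            if nb not in seen:
                path.append(nb)
                seen.add(nb)
                yield from extend(path, seen)
                seen.remove(nb)
                path.pop()

    for start in range(g.n_vertices):
        yield from extend([start], {start})


def connectivity_index(g: HDepletedGraph, k: int, valence: bool = False) -> float:
    """Molecular connectivity index of order ``k`` (chi path index).

    Sum over all simple paths of ``k`` edges of
    ``prod(degree of each path vertex) ** -0.5``; with ``valence`` the
    Kier-Hall valence degree replaces the simple degree.  Returns 0 when no
    path of the requested order exists.
    """
    if not 0 <= k <= MAX_PATH_ORDER:
        raise ValueError(f"path order must be in 0..{MAX_PATH_ORDER}, got {k}")
    if g.n_vertices == 0:
        raise ValueError("empty graph")
    deg = g.delta_v if valence else g.delta
    total = 0.0
    for path in _simple_paths(g, k):
        prod = 1.0
        for v in path:
            prod *= deg[v]
        if prod > 0:
            total += prod ** -0.5
    return total


def x3v(smiles_or_mol) -> float:
    """Third-order valence connectivity index straight from SMILES or Molecule."""
    mol = smiles_or_mol
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    return connectivity_index(heavy_graph(mol), 3, valence=True)
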