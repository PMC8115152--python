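"""The skin-permeability model's molecular descriptors.

Three descriptors drive the model:

* ``cos2_alogp`` — cos²[(4.31 + A log P)/8.66], a bounded, monotone-over-the-
  data transform of the atom-contribution octanol/water partition estimate
  A log P (hydrophobicity);
* ``x3v`` — third-order valence connectivity index (size/branching);
* ``neoplastic80`` — the Ghose-Viswanadhan-Wendoloski antineoplastic-likeness
  indicator at 80% coverage: 1 iff the molecule carries a qualifying
  functional group and A log P, molar refractivity, molecular weight and
  total atom count all fall inside the 80%-coverage ranges.

Atom contributions for A log P and molar refractivity come from the
Wildman-Crippen parameterization shipped with RDKit (the maintained successor
of the Ghose-Crippen-Viswanadhan scheme); custom element-keyed tables can be
substituted for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors
from rdkit.Chem import rdMolDescriptors

from .molgraph import Molecule, connectivity_index, heavy_graph, parse_smiles

__all__ = [
    "AtomContributionTable",
    "WILDMAN_CRIPPEN",
    "DescriptorVector",
    "DescriptorError",
    "NEOPLASTIC_GROUP_SMARTS",
    "alogp",
    "molar_refractivity",
    "cos2_transform",
    "neoplastic80",
    "has_neoplastic_group",
    "descriptor_vector",
]


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class AtomContributionTable:
    """Atom-type contribution constants for A log P and molar refractivity.

    With ``entries=None`` the table delegates atom typing and constants to
    RDKit's Wildman-Crippen implementation (per-atom contributions include
    the attached hydrogens).  An explicit ``entries`` mapping of element
    symbol -> (hydrophobicity constant, molar-refractivity constant) gives a
    simplified element-keyed table, mainly for tests.
    """

    provenance: str
    entries: Optional[Mapping[str, tuple]] = None

    def contributions(self, mol: Molecule) -> list:
        """Per-atom ``(logp, mr)`` contribution pairs.

        The Wildman-Crippen path types hydrogens explicitly, so the default
        table returns one entry per atom of the hydrogen-added structure;
        element-keyed tables cover the heavy atoms.
        """
        if self.entries is None:
            mol_h = Chem.AddHs(mol.rdmol)
            return [tuple(c) for c in rdMolDescriptors._CalcCrippenContribs(mol_h)]
        out = []
        for idx, (symbol, _charge, _h) in enumerate(mol.atoms):
            try:
                out.append(tuple(self.entries[symbol]))
            except KeyError:
                raise DescriptorError(
                    f"atom {idx} (element {symbol}) has no entry in "
                    f"contribution table {self.provenance!r}"
                ) from None
        return out


WILDMAN_CRIPPEN = AtomContributionTable(
    provenance="Wildman & Crippen (1999) atom contributions, RDKit implementation"
)


def alogp(mol: Molecule, table: AtomContributionTable = WILDMAN_CRIPPEN) -> float:
    """Atom-contribution log P: sum of per-atom hydrophobicity constants."""
    return float(sum(c[0] for c in table.contributions(mol)))


def molar_refractivity(mol: Molecule, table: AtomContributionTable = WILDMAN_CRIPPEN) -> float:
    """Atom-contribution molar refractivity (cm^3/mol)."""
    return float(sum(c[1] for c in table.contributions(mol)))


def cos2_transform(alogp_value: float) -> float:
    """cos²((4.31 + A log P)/8.66), argument in radians; always in [0, 1]."""
    return math.cos((4.31 + alogp_value) / 8.66) ** 2


# Qualifying functional groups for the antineoplastic-likeness indicator.
# One positive and one negative example per pattern is pinned in the tests.
NEOPLASTIC_GROUP_SMARTS: Mapping[str, str] = {
    "benzene_ring": "c1ccccc1",
    "heterocyclic_ring": "[!#6;R]",
    "aliphatic_amine": "[NX3;!$([NX3]C=[O,S,N]);!$([NX3]S(=O)=O);!a]",
    "carboxamide": "[CX3](=O)[NX3]",
    "alcoholic_hydroxyl": "[OX2H][CX4]",
    "carboxy_ester": "[CX3](=O)[OX2][#6]",
    "keto_group": "[#6][CX3](=O)[#6]",
}

_NEOPLASTIC_QUERIES = {
    name: Chem.MolFromSmarts(smarts) for name, smarts in NEOPLASTIC_GROUP_SMARTS.items()
}

# inclusive 80%-coverage gates: (A log P, molar refractivity, MW, total atoms)
NEOPLASTIC80_RANGES = {
    "alogp": (-1.5, 4.7),
    "mr": (43.0, 128.0),
    "mw": (180.0, 470.0),
    "n_atoms": (21, 63),
}


def has_neoplastic_group(mol: Molecule) -> bool:
    """True if the molecule carries at least one qualifying functional group."""
    return any(mol.rdmol.HasSubstructMatch(q) for q in _NEOPLASTIC_QUERIES.values())


def neoplastic80(
    mol: Molecule, alogp_value: float, mr: float, mw: float, n_atoms: int
) -> int:
    """Antineoplastic-likeness indicator (80% coverage): 0 or 1.

    1 iff a qualifying group is present and every property gate (closed
    intervals) is satisfied.
    """
    lo, hi = NEOPLASTIC80_RANGES["alogp"]
    if not lo <= alogp_value <= hi:
        return 0
    lo, hi = NEOPLASTIC80_RANGES["mr"]
    if not lo <= mr <= hi:
        return 0
    lo, hi = NEOPLASTIC80_RANGES["mw"]
    if not lo <= mw <= hi:
        return 0
    lo, hi = NEOPLASTIC80_RANGES["n_atoms"]
    if not lo <= n_atoms <= hi:
        return 0
    return int(has_neoplastic_group(mol))


@dataclass(frozen=True)
class DescriptorVector:
    """Model descriptors plus the supporting quantities they are gated on."""

    alogp: float
    cos2_alogp: float
    x3v: float
    neoplastic80: int
    mw: float
    molar_refractivity: float
    n_atoms_total: int

    def __post_init__(self):
        if not 0.0 <= self.cos2_alogp <= 1.0:
            raise ValueError("cos2_alogp outside [0, 1]")
        if self.neoplastic80 not in (0, 1):
            raise ValueError("neoplastic80 must be 0 or 1")

    def as_dict(self) -> dict:
        return {
            "alogp": self.alogp,
            "cos2_alogp": self.cos2_alogp,
            "x3v": self.x3v,
            "neoplastic80": self.neoplastic80,
            "mw": self.mw,
            "mr": self.molar_refractivity,
            "n_atoms": self.n_atoms_total,
        }


def descriptor_vector(
    smiles_or_mol, table: AtomContributionTable = WILDMAN_CRIPPEN
) -> DescriptorVector:
    """Compute the full descriptor vector for one compound."""
    mol = smiles_or_mol
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    lp = alogp(mol, table)
    mr = molar_refractivity(mol, table)
    mw = float(_RDDescriptors.MolWt(mol.rdmol))
    n_atoms = mol.n_atoms_total
    return DescriptorVector(
        alogp=lp,
        cos2_alogp=cos2_transform(lp),
        x3v=connectivity_index(heavy_graph(mol), 3, valence=True),
        neoplastic80=neoplastic80(mol, lp, mr, mw, n_atoms),
        mw=mw,
        molar_refractivity=mr,
        n_atoms_total=n_atoms,
    )
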