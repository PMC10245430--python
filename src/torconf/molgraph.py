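"""Molecular graphs for torsion prediction.

Molecules (SMILES or SDF) are parsed with RDKit, stripped to their heavy-atom
skeleton, renumbered into RDKit's canonical atom order and featurised with an
AttentiveFP-style atom/bond vocabulary.  Rotatable bonds — non-ring single
bonds between two heavy atoms that each carry at least one further heavy
neighbour — are enumerated as :class:`TorsionSpec` records in a deterministic,
input-order-independent sequence; that sequence is the autoregressive decoding
order of the network.

Canonical renumbering at parse time makes every downstream quantity (atom
features, adjacency rows, torsion ordering, predictions) invariant to the atom
order of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "MoleculeGraph",
    "TorsionSpec",
    "read_molecule",
    "featurize_atom",
    "featurize_bond",
    "find_rotatable_bonds",
    "ATOM_FEATURE_WIDTH",
    "BOND_FEATURE_WIDTH",
]

# AttentiveFP element vocabulary; anything else maps to the trailing "other" slot.
ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "As", "Se", "Br", "Te", "I", "At"]
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FEATURE_WIDTH = len(ELEMENTS) + 1 + 7 + 1 + len(HYBRIDIZATIONS) + 1 + 1 + 5 + 1 + 1
BOND_FEATURE_WIDTH = len(BOND_TYPES) + 1 + 1 + 1


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    vec[choices.index(value) if value in choices else len(choices)] = 1.0
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Fixed-width atom feature vector (element, degree, charge, hybridisation,
    aromaticity, attached hydrogens, ring membership, chirality)."""
    feats = (
        _one_hot(atom.GetSymbol(), ELEMENTS)
        + _one_hot(min(atom.GetDegree(), 5), [0, 1, 2, 3, 4, 5])
        + [float(atom.GetFormalCharge())]
        + _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(min(atom.GetTotalNumHs(), 4), [0, 1, 2, 3])[:5]
        + [1.0 if atom.IsInRing() else 0.0]
        + [1.0 if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED else 0.0]
    )
    return np.asarray(feats, dtype=np.float64)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    feats = (
        _one_hot(bond.GetBondType(), BOND_TYPES)[:-1]
        + [1.0]  # bias slot so even an "other" bond type has signal
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
    )
    return np.asarray(feats, dtype=np.float64)


@dataclass
class TorsionSpec:
    """One rotatable bond (i, j) with its heavy-atom terminal groups.

    ``a_group`` are the heavy neighbours of ``i`` excluding ``j``; ``b_group``
    likewise for ``j``.  Groups are sorted by canonical rank so the weighted
    normalised-torsion sum is deterministic.  ``sequence_index`` is the bond's
    position in the molecule's canonical torsion ordering.
    """

    bond: tuple[int, int]
    a_group: list[int]
    b_group: list[int]
    sequence_index: int = 0

    def __post_init__(self):
        if not self.a_group or not self.b_group:
            raise ValueError("torsion terminal groups must be non-empty")
        if self.bond[0] == self.bond[1]:
            raise ValueError("degenerate bond")


@dataclass
class MoleculeGraph:
    """Featurised heavy-atom graph of one molecule (canonical atom order)."""

    atoms: np.ndarray  # (N, F_a)
    bonds: dict[tuple[int, int], np.ndarray]  # symmetric: (i,j) and (j,i) share a vector
    adjacency: np.ndarray  # (N, N) binary, zero diagonal
    heavy_atom_count: int
    canonical_ranks: np.ndarray  # permutation-invariant total order, here 0..N-1
    smiles: str = ""
    rdmol: Chem.Mol = field(default=None, repr=False, compare=False)

    def neighbors(self, i: int) -> list[int]:
        return list(np.flatnonzero(self.adjacency[i]))

    def degree(self, i: int) -> int:
        return int(self.adjacency[i].sum())


class MoleculeParseError(ValueError):
    pass


def _mol_from_source(source) -> Chem.Mol:
    if isinstance(source, Chem.Mol):
        return Chem.Mol(source)
    text = str(source)
    if "\n" in text or text.endswith((".sdf", ".mol")):
        if text.endswith((".sdf", ".mol")):
            mol = Chem.MolFromMolFile(text, removeHs=True)
        else:
            mol = Chem.MolFromMolBlock(text, removeHs=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeParseError(f"could not parse molecule from {source!r}")
    return mol


def read_molecule(source) -> MoleculeGraph:
    """Parse a SMILES string, molblock, or .sdf/.mol path into a MoleculeGraph.

    Multi-fragment inputs are rejected: a torsion sequence is only defined for
    a connected graph.
    """
    mol = _mol_from_source(source)
    mol = Chem.RemoveHs(mol)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise MoleculeParseError("disconnected multi-fragment input is not supported")
    Chem.SanitizeMol(mol)
    order = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    # renumber so atom index == canonical rank
    perm = [0] * mol.GetNumAtoms()
    for old, rank in enumerate(order):
        perm[rank] = old
    mol = Chem.RenumberAtoms(mol, perm)
    n = mol.GetNumAtoms()
    atoms = np.stack([featurize_atom(mol.GetAtomWithIdx(i)) for i in range(n)])
    adjacency = np.zeros((n, n), dtype=np.float64)
    bonds: dict[tuple[int, int], np.ndarray] = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        vec = featurize_bond(b)
        bonds[(i, j)] = vec
        bonds[(j, i)] = vec
        adjacency[i, j] = adjacency[j, i] = 1.0
    return MoleculeGraph(
        atoms=atoms,
        bonds=bonds,
        adjacency=adjacency,
        heavy_atom_count=n,
        canonical_ranks=np.arange(n),
        smiles=Chem.MolToSmiles(mol),
        rdmol=mol,
    )


def find_rotatable_bonds(graph: MoleculeGraph, include_amide: bool = True) -> list[TorsionSpec]:
    """Enumerate rotatable bonds as TorsionSpecs in canonical torsion order.

    Rule: non-ring single bond, both ends heavy with >= 2 heavy neighbours.
    Amide C-N bonds are included by default; set ``include_amide=False`` for
    the stricter convention that freezes them.
    """
    mol = graph.rdmol
    amide = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
    amide_bonds = set()
    if not include_amide:
        for match in mol.GetSubstructMatches(amide):
            c, _, nidx = match
            amide_bonds.add(frozenset((c, nidx)))
    specs = []
    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE or b.IsInRing():
            continue
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if frozenset((i, j)) in amide_bonds:
            continue
        # orient the bond canonically: lower rank first
        if graph.canonical_ranks[i] > graph.canonical_ranks[j]:
            i, j = j, i
        a_group = sorted(k for k in graph.neighbors(i) if k != j)
        b_group = sorted(k for k in graph.neighbors(j) if k != i)
        if not a_group or not b_group:
            continue
        specs.append(TorsionSpec(bond=(i, j), a_group=a_group, b_group=b_group))
    specs.sort(key=lambda s: (min(s.bond), max(s.bond)))
    for idx, s in enumerate(specs):
        s.sequence_index = idx
    return specs
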