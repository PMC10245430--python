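"""3D torsion geometry.

The central quantity is the *normalized torsion angle* of a rotatable bond
(i, j): every terminal-atom pair (a_m, b_n) defines an ordinary signed
dihedral Δ_{a_m b_n}; each is mapped to the unit vector (cos Δ, sin Δ),
the vectors are combined in a fixed positively-weighted sum, and the angle of
the summed vector is the normalized torsion α.  Unlike a single dihedral, α
does not depend on an arbitrary choice of terminal atoms, yet it inherits the
defining equivariance: rotating the bond by γ shifts α by exactly γ.

The per-pair weights default to c_mn = 2^-(m+n) (m, n 1-based positions of
the terminal atoms in canonical-rank order).  Equal weights would let
symmetric terminal groups (e.g. the three fluorines of CF3 at 120° spacing)
cancel exactly; strictly decreasing weights make the sum non-zero for every
non-degenerate geometry.

Signed dihedrals follow the IUPAC convention (cis = 0, trans = π, sign
right-handed about i→j); the normalized angle is the two-argument arctangent
of the weighted sum, oriented so the rotation-equivariance property holds with
a positive sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .molgraph import MoleculeGraph, TorsionSpec

__all__ = [
    "Conformer",
    "wrap_angle",
    "dihedral",
    "default_pair_weights",
    "normalized_torsion",
    "bond_fragments",
    "rotate_bond",
    "set_torsion",
    "apply_torsion_sequence",
    "measure_torsion_sequence",
    "write_ensemble_sdf",
    "read_ensemble_sdf",
    "ENERGY_FIELD",
]

ENERGY_FIELD = "REL_ENERGY_KCAL"


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class Conformer:
    """One 3D arrangement: (N, 3) heavy-atom coordinates in Å plus the
    conformer's relative energy (kcal/mol; 0 marks the ensemble minimum)."""

    coords: np.ndarray
    relative_energy: float = 0.0
    source_tag: str = "reference"  # reference | initial | generated

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")

    def copy(self) -> "Conformer":
        return replace(self, coords=self.coords.copy())


def wrap_angle(theta):
    """Wrap angle(s) into (-pi, pi]."""
    wrapped = np.arctan2(np.sin(theta), np.cos(theta))
    return np.where(wrapped == -np.pi, np.pi, wrapped) if np.ndim(theta) else (
        np.pi if wrapped == -np.pi else float(wrapped)
    )


def dihedral(coords: np.ndarray, a: int, i: int, j: int, b: int) -> float:
    """Signed dihedral a-i-j-b in (-pi, pi], IUPAC sign convention."""
    p = np.asarray(coords, dtype=np.float64)
    b0 = p[a] - p[i]
    b1 = p[j] - p[i]
    b2 = p[b] - p[j]
    if np.linalg.norm(np.cross(b0, b1)) < 1e-10 or np.linalg.norm(np.cross(b1, b2)) < 1e-10:
        raise DegenerateGeometryError("collinear atoms: dihedral plane undefined")
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u  # component of a-i normal to the bond axis
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return wrap_angle(np.arctan2(y, x))


def default_pair_weights(spec: TorsionSpec) -> np.ndarray:
    """Strictly decreasing weights c_mn = 2^-(m+n) over terminal pairs
    (m, n 1-based canonical-rank positions within a_group / b_group)."""
    m = np.arange(1, len(spec.a_group) + 1)
    n = np.arange(1, len(spec.b_group) + 1)
    return np.power(2.0, -(m[:, None] + n[None, :]))


def normalized_torsion(
    coords: np.ndarray, spec: TorsionSpec, weights: np.ndarray | None = None
) -> float:
    """Normalized torsion angle α of bond (i, j) in (-pi, pi]."""
    if weights is None:
        weights = default_pair_weights(spec)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (len(spec.a_group), len(spec.b_group)):
        raise ValueError("one weight per terminal pair required")
    if np.any(weights <= 0):
        raise ValueError("pair weights must be strictly positive")
    i, j = spec.bond
    s = np.zeros(2)
    for mi, a in enumerate(spec.a_group):
        for ni, b in enumerate(spec.b_group):
            delta = dihedral(coords, a, i, j, b)
            s += weights[mi, ni] * np.array([np.cos(delta), np.sin(delta)])
    norm = np.linalg.norm(s)
    if norm < 1e-12:
        raise DegenerateGeometryError("terminal-pair vectors cancel; α undefined")
    return wrap_angle(np.arctan2(s[1], s[0]))


def bond_fragments(graph: MoleculeGraph, spec: TorsionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split atoms into the i-side and j-side components of bridge bond (i, j)."""
    i, j = spec.bond
    n = graph.heavy_atom_count
    side_i = np.zeros(n, dtype=bool)
    stack = [i]
    side_i[i] = True
    while stack:
        cur = stack.pop()
        for nb in graph.neighbors(cur):
            if (cur, nb) in ((i, j), (j, i)):
                continue
            if not side_i[nb]:
                side_i[nb] = True
                stack.append(nb)
    if side_i[j]:
        raise ValueError(f"bond {spec.bond} is not a bridge; cannot rotate")
    return np.flatnonzero(side_i), np.flatnonzero(~side_i)


def rotate_bond(
    conformer: Conformer, graph: MoleculeGraph, spec: TorsionSpec, gamma: float
) -> Conformer:
    """Rotate about bond (i, j) so the normalized torsion shifts by +gamma.

    The smaller fragment moves (tie → the j-side).  Intra-fragment geometry is
    preserved exactly: the moving block undergoes one rigid rotation about the
    bond axis.
    """
    i, j = spec.bond
    frag_i, frag_j = bond_fragments(graph, spec)
    move_j_side = len(frag_j) <= len(frag_i)
    moving = frag_j if move_j_side else frag_i
    coords = conformer.coords.copy()
    axis = coords[j] - coords[i]
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-8:
        raise DegenerateGeometryError("zero-length bond axis")
    # rotating the j-side by +gamma about i→j advances every Δ (hence α) by +gamma;
    # moving the i-side instead requires the inverse rotation for the same shift
    angle = gamma if move_j_side else -gamma
    rot = Rotation.from_rotvec(axis / axis_norm * angle)
    pivot = coords[i]
    coords[moving] = rot.apply(coords[moving] - pivot) + pivot
    return replace(conformer, coords=coords)


def set_torsion(
    conformer: Conformer,
    graph: MoleculeGraph,
    spec: TorsionSpec,
    target: float,
    weights: np.ndarray | None = None,
) -> Conformer:
    """Rotate about bond (i, j) so that the normalized torsion equals ``target``."""
    current = normalized_torsion(conformer.coords, spec, weights)
    return rotate_bond(conformer, graph, spec, wrap_angle(target - current))


def apply_torsion_sequence(
    initial: Conformer,
    graph: MoleculeGraph,
    specs: list[TorsionSpec],
    angles: np.ndarray,
) -> Conformer:
    """Reset every rotatable bond of an initial conformer to the given
    normalized torsion angles (canonical order), leaving bond lengths and
    bond angles untouched."""
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    if len(angles) != len(specs):
        raise ValueError(f"{len(specs)} torsions but {len(angles)} angles")
    conf = initial.copy()
    for spec, angle in zip(specs, angles):
        conf = set_torsion(conf, graph, spec, float(angle))
    return conf


def measure_torsion_sequence(conformer: Conformer, specs: list[TorsionSpec]) -> np.ndarray:
    return np.array([normalized_torsion(conformer.coords, s) for s in specs])


# --------------------------------------------------------------------- SDF io
def write_ensemble_sdf(path, graph: MoleculeGraph, conformers: list[Conformer]) -> None:
    """Write a conformer ensemble as a multi-record SDF (one record per
    conformer; relative energy in the REL_ENERGY_KCAL data field)."""
    mol = Chem.Mol(graph.rdmol)
    mol.RemoveAllConformers()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for idx, conf in enumerate(conformers):
            if conf.coords.shape[0] != graph.heavy_atom_count:
                raise ValueError("conformer size does not match graph")
            rec = Chem.Mol(mol)
            c = Chem.Conformer(graph.heavy_atom_count)
            for k, xyz in enumerate(conf.coords):
                c.SetAtomPosition(k, tuple(float(v) for v in xyz))
            rec.AddConformer(c, assignId=True)
            rec.SetProp("_Name", f"{graph.smiles} conformer {idx}")
            rec.SetProp(ENERGY_FIELD, f"{conf.relative_energy:.6f}")
            rec.SetProp("SOURCE_TAG", conf.source_tag)
            writer.write(rec)
    finally:
        writer.close()


def read_ensemble_sdf(path) -> tuple[MoleculeGraph, list[Conformer]]:
    """Read a multi-conformer SDF written by :func:`write_ensemble_sdf`."""
    from .molgraph import read_molecule

    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    graph = None
    conformers = []
    for mol in supplier:
        if mol is None:
            continue
        if graph is None:
            graph = read_molecule(mol)
        # map this record's atom order onto the canonical graph order
        match = mol.GetSubstructMatch(graph.rdmol, useChirality=False)
        if not match:
            raise ValueError("SDF record does not match the ensemble molecule")
        pos = mol.GetConformer().GetPositions()
        coords = pos[np.asarray(match)]
        energy = float(mol.GetProp(ENERGY_FIELD)) if mol.HasProp(ENERGY_FIELD) else 0.0
        tag = mol.GetProp("SOURCE_TAG") if mol.HasProp("SOURCE_TAG") else "reference"
        conformers.append(Conformer(coords=coords, relative_energy=energy, source_tag=tag))
    if graph is None:
        raise ValueError(f"no valid molecule records in {path}")
    return graph, conformers
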