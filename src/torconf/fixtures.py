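"""Synthetic conformer-ensemble generator.

Emulates the record structure of large conformer datasets — (molecule graph,
ensemble of 3D conformers, relative energy per conformer, 0 kcal/mol for the
lowest-energy member) — from nothing but a SMILES string, so that training
and evaluation can be exercised without any download.

An initial conformer comes from RDKit's ETKDG distance-geometry embedder.
The ensemble is a torsion grid: every rotatable bond is swept over a grid of
normalized torsion angles, each grid point is rebuilt from the initial
conformer by dihedral resetting, and scored with an independent per-bond
3-fold cosine potential

    E(θ) = Σ_l V_l · (1 + cos 3θ_l) / 2        [kcal/mol]

the textbook shape of a rotation barrier about an sp3–sp3 bond (minima at
±60°, 180°).  The lowest-energy ``n_keep`` grid points are kept and energies
are shifted so the minimum is exactly 0.

The potential is even in every θ_l, so grid points at ±θ are exactly
energy-degenerate whenever the grid step is below 180°; with a 180° grid and
distinct barrier heights the energy→angles map becomes a bijection, which is
the configuration :func:`recovery_records` uses for identifiable
energy-conditioned training experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .geometry import Conformer, apply_torsion_sequence, measure_torsion_sequence
from .molgraph import MoleculeGraph, find_rotatable_bonds, read_molecule
from .training import TrainingRecord

__all__ = [
    "FixtureSpec",
    "embed_initial",
    "torsion_grid_energy",
    "make_ensemble",
    "fixture_suite",
    "recovery_records",
    "FIXTURE_SMILES",
]

# standing test set: named, small, covering 0..3 torsions and symmetric groups
FIXTURE_SMILES = {
    "butane": "CCCC",
    "pentane": "CCCCC",
    "diphenylethane": "c1ccccc1CCc1ccccc1",
    "para_xylene": "Cc1ccc(C)cc1",
    "benzene": "c1ccccc1",
    "trifluoropropane": "CCC(F)(F)F",
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic ensemble."""

    smiles: str
    grid_degrees: int = 60
    barrier_heights: list[float] = field(default_factory=list)  # kcal/mol, per bond
    n_keep: int = 8
    seed: int = 0

    def __post_init__(self):
        if 360 % self.grid_degrees:
            raise ValueError("grid resolution must divide 360")
        if any(v < 0 for v in self.barrier_heights):
            raise ValueError("barrier heights must be >= 0")


class EmbeddingError(RuntimeError):
    pass


def embed_initial(smiles: str, seed: int = 0) -> tuple[MoleculeGraph, Conformer]:
    """One ETKDG-embedded 3D conformer (heavy atoms, canonical order)."""
    graph = read_molecule(smiles)
    mol = Chem.AddHs(Chem.Mol(graph.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"embedding failed for {smiles!r}; retry with another seed")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    mol = Chem.RemoveHs(mol)
    coords = mol.GetConformer().GetPositions()[: graph.heavy_atom_count]
    return graph, Conformer(coords=coords, relative_energy=0.0, source_tag="initial")


def torsion_grid_energy(angles_deg: np.ndarray, barriers: np.ndarray) -> float:
    """E(θ) = Σ_l V_l (1 + cos 3θ_l)/2, θ in degrees, E in kcal/mol."""
    theta = np.radians(np.asarray(angles_deg, dtype=np.float64))
    return float(np.sum(np.asarray(barriers) * (1.0 + np.cos(3.0 * theta)) / 2.0))


def make_ensemble(spec: FixtureSpec) -> list[TrainingRecord]:
    """Enumerate the torsion grid, rebuild and score each point, keep the
    ``n_keep`` lowest-energy conformers, and shift so min energy is 0."""
    graph, initial = embed_initial(spec.smiles, spec.seed)
    specs = find_rotatable_bonds(graph)
    if not specs:
        raise ValueError("rigid molecule: no torsion grid; use embed_initial alone")
    barriers = np.asarray(spec.barrier_heights or [1.0] * len(specs), dtype=np.float64)
    if len(barriers) != len(specs):
        raise ValueError("one barrier height per rotatable bond required")
    grid = np.arange(0, 360, spec.grid_degrees, dtype=np.float64)
    points = []
    for combo_idx, combo in enumerate(itertools.product(grid, repeat=len(specs))):
        angles_deg = np.array(combo)
        energy = torsion_grid_energy(angles_deg, barriers)
        points.append((energy, combo_idx, angles_deg))
    points.sort(key=lambda t: (t[0], t[1]))  # stable tie-break by grid index
    kept = points[: spec.n_keep]
    e_min = kept[0][0]
    records = []
    for energy, _, angles_deg in kept:
        conf = apply_torsion_sequence(initial, graph, specs, np.radians(angles_deg))
        measured = measure_torsion_sequence(conf, specs)
        records.append(
            TrainingRecord(
                graph=graph,
                specs=specs,
                angles=measured,
                relative_energy=energy - e_min,
                coords=conf.coords,
            )
        )
    return records


def fixture_suite() -> dict[str, MoleculeGraph]:
    """The standing named molecule set (0 to 3 rotatable bonds, aromatic
    rings, a para-symmetric molecule and a CF3-type symmetric terminal)."""
    return {name: read_molecule(smi) for name, smi in FIXTURE_SMILES.items()}


# barrier heights (kcal/mol) per bond for the identifiable training setup:
# distinct values make every subset sum unique, so relative energy determines
# the angle set
_RECOVERY_BARRIERS = [1.0, 2.3, 3.6]


def recovery_records(seed: int = 0) -> list[TrainingRecord]:
    """Training records for the parameter-recovery experiment.

    Uses a 180° grid (angles ∈ {0°, 180°} per bond) with distinct per-bond
    barrier heights, the configuration in which (graph, relative energy) →
    angle set is a bijection and teacher-forced recovery is well-posed.
    """
    names = ["butane", "pentane", "diphenylethane", "trifluoropropane"]
    records: list[TrainingRecord] = []
    for name in names:
        graph = read_molecule(FIXTURE_SMILES[name])
        n_bonds = len(find_rotatable_bonds(graph))
        spec = FixtureSpec(
            smiles=FIXTURE_SMILES[name],
            grid_degrees=180,
            barrier_heights=_RECOVERY_BARRIERS[:n_bonds],
            n_keep=8,
            seed=seed,
        )
        records.extend(make_ensemble(spec))
    return records
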