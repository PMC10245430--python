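"""Ensemble evaluation: coverage (COV) and matching (MAT) scores.

Given a generated set S_g and a reference set S_r of conformers, the
recall-side scores are

    COV-R = 100/|S_r| · |{R ∈ S_r : min_{R̂ ∈ S_g} RMSD(R, R̂) < δ}|
    MAT-R = 1/|S_r| · Σ_{R ∈ S_r} min_{R̂ ∈ S_g} RMSD(R, R̂)

and the precision-side scores COV-P / MAT-P are the same with the two sets
swapped.  COV measures diversity (how much of the reference ensemble is
recovered), MAT accuracy (how close the best matches are).  The default
threshold is δ = 1.25 Å.  RMSD is heavy-atom, after optimal superposition,
minimised over graph automorphisms (symmetry-aware) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolAlign

from .geometry import Conformer
from .molgraph import MoleculeGraph

__all__ = ["EnsembleMetrics", "rmsd", "pairwise_rmsd", "coverage_matching", "DEFAULT_DELTA"]

DEFAULT_DELTA = 1.25  # Å


@dataclass
class EnsembleMetrics:
    cov_r: float  # percent
    mat_r: float  # Å
    cov_p: float  # percent
    mat_p: float  # Å
    delta: float  # Å
    pairwise_rmsd: np.ndarray  # (|S_r|, |S_g|), Å
    symmetry_aware: bool = True

    def to_dict(self) -> dict:
        return {
            "cov_r": self.cov_r,
            "mat_r": self.mat_r,
            "cov_p": self.cov_p,
            "mat_p": self.mat_p,
            "delta": self.delta,
            "n_reference": int(self.pairwise_rmsd.shape[0]),
            "n_generated": int(self.pairwise_rmsd.shape[1]),
            "rmsd_convention": (
                "heavy-atom, best-fit superposition, "
                + ("automorphism-minimised" if self.symmetry_aware else "fixed atom order")
            ),
        }


def _mol_with_conformer(graph: MoleculeGraph, conf: Conformer) -> Chem.Mol:
    if conf.coords.shape[0] != graph.heavy_atom_count:
        raise ValueError("conformer does not match molecule atom count")
    mol = Chem.Mol(graph.rdmol)
    mol.RemoveAllConformers()
    c = Chem.Conformer(graph.heavy_atom_count)
    for k, xyz in enumerate(conf.coords):
        c.SetAtomPosition(k, tuple(float(v) for v in xyz))
    mol.AddConformer(c, assignId=True)
    return mol


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s_corrected = s.copy()
    s_corrected[-1] *= d
    msd = max((a * a).sum() + (b * b).sum() - 2.0 * s_corrected.sum(), 0.0) / len(a)
    return float(np.sqrt(msd))


def rmsd(conf_a: Conformer, conf_b: Conformer, graph: MoleculeGraph, symmetry_aware: bool = True) -> float:
    """Heavy-atom RMSD (Å) after optimal superposition.

    With ``symmetry_aware`` (default) the RMSD is additionally minimised over
    graph automorphisms, so e.g. a benzene relabelled by a ring rotation has
    RMSD 0 to itself.
    """
    if conf_a.coords.shape != conf_b.coords.shape:
        raise ValueError("conformers have different atom counts")
    if np.array_equal(conf_a.coords, conf_b.coords):
        return 0.0  # identical coordinates: exactly zero, no solver roundoff
    if not symmetry_aware:
        return _kabsch_rmsd(conf_a.coords, conf_b.coords)
    probe = _mol_with_conformer(graph, conf_a)
    ref = _mol_with_conformer(graph, conf_b)
    return float(rdMolAlign.GetBestRMS(probe, ref))


def pairwise_rmsd(
    s_r: list[Conformer], s_g: list[Conformer], graph: MoleculeGraph, symmetry_aware: bool = True
) -> np.ndarray:
    return np.array([[rmsd(r, g, graph, symmetry_aware) for g in s_g] for r in s_r])


def coverage_matching(
    s_g: list[Conformer],
    s_r: list[Conformer],
    graph: MoleculeGraph,
    delta: float = DEFAULT_DELTA,
    symmetry_aware: bool = True,
) -> EnsembleMetrics:
    """COV-R/MAT-R and COV-P/MAT-P at threshold ``delta`` (strict <)."""
    if not s_g or not s_r:
        raise ValueError("both ensembles must be non-empty")
    matrix = pairwise_rmsd(s_r, s_g, graph, symmetry_aware)
    min_over_g = matrix.min(axis=1)  # best generated match per reference
    min_over_r = matrix.min(axis=0)  # best reference match per generated
    return EnsembleMetrics(
        cov_r=float(100.0 * np.mean(min_over_g < delta)),
        mat_r=float(np.mean(min_over_g)),
        cov_p=float(100.0 * np.mean(min_over_r < delta)),
        mat_p=float(np.mean(min_over_r)),
        delta=float(delta),
        pairwise_rmsd=matrix,
        symmetry_aware=symmetry_aware,
    )
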