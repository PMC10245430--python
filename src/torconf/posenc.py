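"""Graph position encodings for atoms.

A plain transformer over atoms has no notion of where an atom sits in the
molecular graph, and conventional message passing struggles with long-range
and symmetry structure.  Each atom therefore gets a position vector

    pos = pos_wl ∥ pos_d ∥ pos_a

built from three complementary signals: a learned embedding of the atom's
Weisfeiler-Lehman colour (topological role — automorphism-equivalent atoms
share it), a learned embedding of the atom's degree, and a learned linear
projection of the atom's (zero-padded) adjacency row (explicit connectivity).
The vector is concatenated to the atom features to form h_v^0.

Three modes mirror the ablation design: ``"none"`` (no position information),
``"learnable"`` (a free embedding of the atom index), and ``"full"`` (the
three-part vector above).
"""

from __future__ import annotations

import hashlib

import numpy as np

from .molgraph import MoleculeGraph
from .nn import Embedding, Linear, Module, Tensor, concat

__all__ = ["wl_labels", "PositionEncoder", "POSITION_MODES"]

POSITION_MODES = ("none", "learnable", "full")


def _stable_hash(text: str) -> int:
    """Platform- and run-stable 64-bit hash (Python's hash() is salted)."""
    return int.from_bytes(hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


def wl_labels(graph: MoleculeGraph, iterations: int = 3) -> np.ndarray:
    """1-WL colour refinement seeded by (element slot, degree).

    Returns one integer label per atom after ``iterations`` rounds; atoms in
    the same automorphism orbit always share a label, and iterating separates
    atoms whose neighbourhoods differ within that radius.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = graph.heavy_atom_count
    element_slot = graph.atoms[:, :16].argmax(axis=1)
    colors = np.array(
        [_stable_hash(f"seed|{element_slot[i]}|{graph.degree(i)}") for i in range(n)],
        dtype=np.uint64,
    )
    for _ in range(iterations):
        new = np.empty_like(colors)
        for i in range(n):
            neigh = sorted(int(colors[k]) for k in graph.neighbors(i))
            new[i] = _stable_hash(f"{int(colors[i])}|{neigh}")
        colors = new
    return colors


class PositionEncoder(Module):
    """Emit per-atom position vectors for one of the three modes."""

    def __init__(
        self,
        mode: str,
        dim: int,
        max_atoms: int,
        rng: np.random.Generator,
        wl_iterations: int = 3,
        wl_buckets: int = 1024,
    ):
        if mode not in POSITION_MODES:
            raise ValueError(f"mode must be one of {POSITION_MODES}")
        if dim % 3:
            raise ValueError("position width must be divisible by 3 (three parts)")
        self.mode = mode
        self.dim = dim
        self.max_atoms = max_atoms
        self.wl_iterations = wl_iterations
        self.wl_buckets = wl_buckets
        part = dim // 3
        if mode == "full":
            self.wl_embed = Embedding(wl_buckets, part, rng)
            self.deg_embed = Embedding(8, part, rng)
            self.adj_proj = Linear(max_atoms, part, rng)
        elif mode == "learnable":
            self.index_embed = Embedding(max_atoms, dim, rng)

    @property
    def width(self) -> int:
        return 0 if self.mode == "none" else self.dim

    def __call__(self, graph: MoleculeGraph) -> Tensor | None:
        n = graph.heavy_atom_count
        if n > self.max_atoms:
            raise ValueError(f"molecule has {n} atoms; encoder capped at {self.max_atoms}")
        if self.mode == "none":
            return None
        if self.mode == "learnable":
            return self.index_embed(np.arange(n))
        labels = wl_labels(graph, self.wl_iterations) % np.uint64(self.wl_buckets)
        pos_wl = self.wl_embed(labels.astype(np.intp))
        degrees = np.array([min(graph.degree(i), 7) for i in range(n)], dtype=np.intp)
        pos_d = self.deg_embed(degrees)
        padded = np.zeros((n, self.max_atoms))
        padded[:, :n] = graph.adjacency
        pos_a = self.adj_proj(Tensor(padded))
        return concat([pos_wl, pos_d, pos_a], axis=-1)

    def initial_atom_representation(self, graph: MoleculeGraph) -> Tensor:
        """h_v^0 = atom features ∥ pos (width F_a + P)."""
        feats = Tensor(graph.atoms)
        pos = self(graph)
        return feats if pos is None else concat([feats, pos], axis=-1)
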