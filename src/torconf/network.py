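"""The torsion-prediction network.

The model maps a 2D molecular graph to a sequence of normalized torsion
angles in two stages.  A *torsion representation* stage embeds atoms
(features ∥ graph position vector), updates them with unmasked multi-head
self-attention so every atom sees every other atom, and reads out one vector
τ_l per rotatable bond by concatenating the bond's atom representations
(mean of a-side terminals ∥ h_i ∥ h_j ∥ mean of b-side terminals) with its
edge features (mean a-side edges ∥ e_ij ∥ mean b-side edges).  A *sequence*
stage runs a transformer encoder over the τ sequence — Gaussian noise added
to τ^0 is the sampling mechanism; no positional encoding is added because τ
already carries graph position — and an autoregressive decoder that emits one
angle at a time, conditioned on the conformer's relative energy (the start
token), the previously generated angles, and sinusoidal encodings of their
sequence positions.  Angles are emitted as normalised (sin, cos) pairs and
converted with atan2, avoiding the ±π discontinuity.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass
from io import BytesIO

import numpy as np

from .geometry import wrap_angle
from .molgraph import ATOM_FEATURE_WIDTH, BOND_FEATURE_WIDTH, MoleculeGraph, TorsionSpec
from .nn import (
    Adam,  # noqa: F401  (re-exported for training code)
    DecoderLayer,
    EncoderLayer,
    Linear,
    Module,
    Tensor,
    concat,
    sinusoidal_encoding,
    stack,
)
from .posenc import PositionEncoder

__all__ = ["ModelConfig", "TorsionSequence", "TorsionPredictor", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture and sampling hyper-parameters.

    Depths: ``t_update_layers`` rounds of atomic self-attention,
    ``n_encoder_layers`` / ``m_decoder_layers`` transformer blocks.  The
    sampling noise std (default 5.0, on the torsion-representation scale)
    drives conformer diversity at generation time.
    """

    t_update_layers: int = 2
    n_encoder_layers: int = 4
    m_decoder_layers: int = 4
    n_heads: int = 4
    hidden: int = 128
    ffn_mult: int = 2
    noise_std: float = 5.0
    max_atoms: int = 64
    position_mode: str = "full"
    position_dim: int = 48
    wl_iterations: int = 3
    energy_scale: float = 10.0  # kcal/mol mapped to O(1) inputs
    seed: int = 0

    def __post_init__(self):
        if min(self.t_update_layers, self.n_encoder_layers, self.m_decoder_layers) < 1:
            raise ValueError("all depths must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass
class TorsionSequence:
    """Ordered normalized torsion angles for one conformer of one molecule."""

    angles: np.ndarray
    role: str = "predicted"  # "true" | "predicted"
    conditioning_energy: float = 0.0

    def __post_init__(self):
        self.angles = wrap_angle(np.atleast_1d(np.asarray(self.angles, dtype=np.float64)))

    def __len__(self):
        return len(self.angles)


class TorsionPredictor(Module):
    # Fourier frequencies (1/kcal·mol⁻¹) for the relative-energy embedding:
    # nearby energy levels differ strongly in at least one sin/cos feature,
    # which a plain scalar input resolves only slowly during training
    ENERGY_FREQS = (0.5, 1.0, 2.0, 4.0)

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h, ff = config.hidden, config.n_heads, config.hidden * config.ffn_mult
        self.position_encoder = PositionEncoder(
            config.position_mode, config.position_dim, config.max_atoms, rng, config.wl_iterations
        )
        self.atom_in = Linear(ATOM_FEATURE_WIDTH + self.position_encoder.width, d, rng)
        self.atom_layers = [EncoderLayer(d, h, ff, rng) for _ in range(config.t_update_layers)]
        self.torsion_proj = Linear(4 * d + 3 * BOND_FEATURE_WIDTH, d, rng)
        self.encoder_layers = [EncoderLayer(d, h, ff, rng) for _ in range(config.n_encoder_layers)]
        self.decoder_layers = [DecoderLayer(d, h, ff, rng) for _ in range(config.m_decoder_layers)]
        self.energy_fc1 = Linear(1 + 2 * len(self.ENERGY_FREQS), d, rng)
        self.energy_fc2 = Linear(d, d, rng)
        self.angle_embed = Linear(2, d, rng)
        self.out_head = Linear(d, 2, rng)

    # ------------------------------------------------------------ atom stage
    def update_atoms(self, graph: MoleculeGraph) -> Tensor:
        """h^0 → h^T: all-pairs self-attention over atoms (no graph masking)."""
        if graph.heavy_atom_count == 0:
            raise ValueError("empty molecule")
        h = self.atom_in(self.position_encoder.initial_atom_representation(graph))
        for layer in self.atom_layers:
            h = layer(h)
        return h

    def readout_torsions(self, h: Tensor, graph: MoleculeGraph, specs: list[TorsionSpec]) -> Tensor:
        """τ^0_l per rotatable bond from atom representations + edge features."""
        if not specs:
            raise ValueError("no rotatable bonds to read out")
        taus = []
        for spec in specs:
            i, j = spec.bond
            h_a = stack([h[a] for a in spec.a_group], axis=0).mean(axis=0)
            h_b = stack([h[b] for b in spec.b_group], axis=0).mean(axis=0)
            h_atoms = concat([h_a, h[i], h[j], h_b], axis=-1)
            e_ai = np.mean([graph.bonds[(a, i)] for a in spec.a_group], axis=0)
            e_bj = np.mean([graph.bonds[(b, j)] for b in spec.b_group], axis=0)
            e_edges = np.concatenate([e_ai, graph.bonds[(i, j)], e_bj])
            taus.append(self.torsion_proj(concat([h_atoms, Tensor(e_edges)], axis=-1)))
        return stack(taus, axis=0)

    def torsion_representations(self, graph: MoleculeGraph, specs: list[TorsionSpec]) -> Tensor:
        return self.readout_torsions(self.update_atoms(graph), graph, specs)

    # -------------------------------------------------------- sequence stage
    def encode(self, tau0: Tensor, noise_std: float = 0.0, rng: np.random.Generator | None = None) -> Tensor:
        """Transformer encoder over the τ sequence; additive Gaussian noise on
        τ^0 is the only stochastic element (noise_std=0 → deterministic)."""
        if noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        x = tau0
        if noise_std > 0:
            if rng is None:
                raise ValueError("rng required when noise_std > 0")
            x = x + Tensor(rng.normal(0.0, noise_std, size=tau0.shape))
        for layer in self.encoder_layers:
            x = layer(x)
        return x

    def _decoder_inputs(self, prev_angles: np.ndarray, energy: float) -> Tensor:
        """Token sequence: energy start token, then embedded previous angles
        plus sinusoidal encodings of their sequence positions."""
        freqs = np.asarray(self.ENERGY_FREQS)
        feats = np.concatenate(
            [[energy / self.config.energy_scale], np.sin(freqs * energy), np.cos(freqs * energy)]
        )
        tokens = [self.energy_fc2(self.energy_fc1(Tensor(feats[None, :])).tanh())]
        if len(prev_angles):
            sc = np.stack([np.sin(prev_angles), np.cos(prev_angles)], axis=-1)
            pos = sinusoidal_encoding(np.arange(len(prev_angles)), self.config.hidden)
            tokens.append(self.angle_embed(Tensor(sc)) + Tensor(pos))
        return concat(tokens, axis=0)

    def _decode_tokens(self, tokens: Tensor, memory: Tensor) -> Tensor:
        L = tokens.shape[0]
        causal = np.tril(np.ones((L, L), dtype=bool))
        x = tokens
        for layer in self.decoder_layers:
            x = layer(x, memory, causal)
        return x

    def head_unit_vectors(self, decoded: Tensor) -> Tensor:
        """Map decoder outputs to unit-norm (sin, cos) pairs."""
        raw = self.out_head(decoded)
        norm = ((raw * raw).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        return raw / norm

    def decode_teacher_forced(
        self, memory: Tensor, energy: float, teacher_angles: np.ndarray, normalize: bool = True
    ) -> Tensor:
        """One parallel decoder pass consuming the true previous angles;
        returns (sin, cos) rows for all steps (training path).  With
        ``normalize`` the rows are unit vectors; the raw rows are exposed for
        vector-regression losses, whose gradient does not vanish when a
        prediction sits at the exact antipode of its target."""
        teacher_angles = np.atleast_1d(np.asarray(teacher_angles, dtype=np.float64))
        if len(teacher_angles) != memory.shape[0]:
            raise ValueError("teacher_angles length must match torsion count")
        tokens = self._decoder_inputs(teacher_angles[:-1], energy)
        decoded = self._decode_tokens(tokens, memory)
        return self.head_unit_vectors(decoded) if normalize else self.out_head(decoded)

    def decode_autoregressive(
        self, memory: Tensor, energy: float, teacher_angles: np.ndarray | None = None
    ) -> TorsionSequence:
        """Emit angles one at a time, feeding each prediction (or the teacher
        angle, when provided) back as the next step's input."""
        L = memory.shape[0]
        if teacher_angles is not None:
            sc = self.decode_teacher_forced(memory, energy, teacher_angles)
            angles = np.arctan2(sc.data[:, 0], sc.data[:, 1])
        else:
            prev: list[float] = []
            for _ in range(L):
                tokens = self._decoder_inputs(np.array(prev), energy)
                sc = self.head_unit_vectors(self._decode_tokens(tokens, memory))
                s, c = sc.data[-1]
                prev.append(float(np.arctan2(s, c)))
            angles = np.array(prev)
        return TorsionSequence(angles=angles, role="predicted", conditioning_energy=energy)

    # -------------------------------------------------------------- sampling
    def predict(
        self,
        graph: MoleculeGraph,
        specs: list[TorsionSpec],
        energy: float = 0.0,
        n_samples: int = 1,
        seed: int = 0,
        noise_std: float | None = None,
    ) -> list[TorsionSequence]:
        """Sample torsion-angle sequences for one molecule.

        Draws differ only through the encoder noise; each (seed, sample index)
        pair is deterministic.  A rigid molecule yields empty sequences.
        """
        if not specs:
            return [TorsionSequence(np.empty(0), conditioning_energy=energy) for _ in range(n_samples)]
        std = self.config.noise_std if noise_std is None else noise_std
        tau0 = self.torsion_representations(graph, specs)
        out = []
        for k in range(n_samples):
            rng = np.random.default_rng([seed % (2**31), k])
            memory = self.encode(tau0, noise_std=std, rng=rng)
            out.append(self.decode_autoregressive(memory, energy))
        return out


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: TorsionPredictor) -> None:
    """Single-archive checkpoint: weights (npz) + config (json)."""
    buf = BytesIO()
    np.savez(buf, **model.state_dict())
    entries = {
        "config.json": json.dumps(asdict(model.config), indent=1).encode(),
        "weights.npz": buf.getvalue(),
        "feature_vocab.json": json.dumps(
            {"atom_width": ATOM_FEATURE_WIDTH, "bond_width": BOND_FEATURE_WIDTH, "version": 1}
        ).encode(),
    }
    with zipfile.ZipFile(str(path), "w") as zf:
        for name, payload in entries.items():
            # fixed timestamp so identical models give byte-identical archives
            zf.writestr(zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0)), payload)


def load_checkpoint(path) -> TorsionPredictor:
    with zipfile.ZipFile(str(path)) as zf:
        config = ModelConfig(**json.loads(zf.read("config.json")))
        vocab = json.loads(zf.read("feature_vocab.json"))
        if vocab["atom_width"] != ATOM_FEATURE_WIDTH or vocab["bond_width"] != BOND_FEATURE_WIDTH:
            raise ValueError("checkpoint was trained with an incompatible feature vocabulary")
        weights = dict(np.load(BytesIO(zf.read("weights.npz"))))
    model = TorsionPredictor(config)
    model.load_state_dict(weights)
    return model
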