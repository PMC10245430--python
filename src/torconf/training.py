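"""Teacher-forced training of the torsion predictor.

One training example is one (molecule, conformer, relative energy) triple:
the decoder is conditioned on that conformer's relative energy, which is what
makes generation energy-guided later.

Two periodic losses are available.  The default regresses the *raw* (sin,
cos) head vector onto the target unit vector by squared error: it is zero iff
the wrapped angular difference is zero and its gradient never vanishes at a
wrong angle.  The pure cosine angular loss mean(1 - cos(â - a)) is
selectable, but note it has an exact zero-gradient saddle when a prediction
sits at the antipode of its target — with targets on a coarse torsion grid
that saddle is reachable, which is why it is not the default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .geometry import wrap_angle
from .molgraph import MoleculeGraph, TorsionSpec
from .network import ModelConfig, TorsionPredictor
from .nn import Adam, Tensor, stack

__all__ = ["TrainingRecord", "TrainConfig", "angle_loss", "train", "mean_angular_error"]


@dataclass
class TrainingRecord:
    """One supervised example: a molecule, one reference conformer's measured
    normalized torsion angles, and that conformer's relative energy."""

    graph: MoleculeGraph
    specs: list[TorsionSpec]
    angles: np.ndarray  # true normalized torsions, canonical order
    relative_energy: float
    coords: np.ndarray | None = None  # reference coordinates (optional, Å)

    def __post_init__(self):
        self.angles = wrap_angle(np.atleast_1d(np.asarray(self.angles, dtype=np.float64)))
        if len(self.angles) != len(self.specs):
            raise ValueError("one angle per torsion spec required")


@dataclass
class TrainConfig:
    epochs: int = 400
    lr: float = 3e-3
    seed: int = 0
    loss: str = "sincos_mse"  # "sincos_mse" | "cosine"
    train_noise_std: float = 0.0  # encoder noise during training
    log_every: int = 25
    plateau_patience: int = 0  # 0 disables early stopping
    plateau_tol: float = 1e-6
    model: ModelConfig = field(default_factory=ModelConfig)


def angle_loss(pred_sincos: Tensor, true_angles: np.ndarray, kind: str = "cosine") -> Tensor:
    """Loss between predicted unit (sin, cos) rows and true angles.

    cosine: mean(1 - cos(â - a)) via the identity
    cos(â - a) = sin â sin a + cos â cos a (no explicit atan2, so the loss is
    smooth in the network outputs).  Empty sequences give 0.
    """
    true_angles = np.atleast_1d(np.asarray(true_angles, dtype=np.float64))
    if true_angles.size == 0:
        return Tensor(np.zeros(()))
    target = np.stack([np.sin(true_angles), np.cos(true_angles)], axis=-1)
    if kind == "cosine":
        cos_diff = (pred_sincos * Tensor(target)).sum(axis=-1)
        return (1.0 - cos_diff).mean()
    if kind == "sincos_mse":
        diff = pred_sincos - Tensor(target)
        return (diff * diff).sum(axis=-1).mean()
    raise ValueError(f"unknown loss kind {kind!r}")


def _group_by_molecule(records: list[TrainingRecord]) -> list[list[TrainingRecord]]:
    groups: dict[str, list[TrainingRecord]] = {}
    for rec in records:
        groups.setdefault(rec.graph.smiles, []).append(rec)
    return [groups[k] for k in sorted(groups)]


def train(
    records: list[TrainingRecord],
    config: TrainConfig,
    model: TorsionPredictor | None = None,
    loss_trace_path=None,
) -> tuple[TorsionPredictor, list[float]]:
    """Full-batch teacher-forced training; returns the model and per-epoch
    mean loss.  The graph-side forward pass is shared across the conformers of
    one molecule within an epoch (they only differ in the decoder pass)."""
    if not records:
        raise ValueError("no training records")
    if model is None:
        cfg = ModelConfig(**{**vars(config.model), "seed": config.seed})
        model = TorsionPredictor(cfg)
    groups = _group_by_molecule(records)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    trace: list[float] = []
    best, stale = np.inf, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        losses = []
        for group in groups:
            rec0 = group[0]
            tau0 = model.torsion_representations(rec0.graph, rec0.specs)
            for rec in group:
                memory = model.encode(tau0, noise_std=config.train_noise_std, rng=rng)
                sc = model.decode_teacher_forced(
                    memory, rec.relative_energy, rec.angles, normalize=(config.loss == "cosine")
                )
                losses.append(angle_loss(sc, rec.angles, kind=config.loss))
        total = stack(losses, axis=0).mean()
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        total.backward()
        opt.step()
        trace.append(float(total.data))
        if config.plateau_patience:
            if total.data < best - config.plateau_tol:
                best, stale = float(total.data), 0
            else:
                stale += 1
                if stale >= config.plateau_patience:
                    break
    if loss_trace_path is not None:
        with open(loss_trace_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss"])
            for i, v in enumerate(trace):
                writer.writerow([i, f"{v:.10f}"])
    return model, trace


def mean_angular_error(model: TorsionPredictor, records: list[TrainingRecord]) -> float:
    """Mean wrapped absolute angular error (degrees) of teacher-forced
    predictions over all torsions of all records."""
    errors = []
    for group in _group_by_molecule(records):
        tau0 = model.torsion_representations(group[0].graph, group[0].specs)
        for rec in group:
            memory = model.encode(tau0, noise_std=0.0)
            pred = model.decode_autoregressive(memory, rec.relative_energy, teacher_angles=rec.angles)
            errors.extend(np.abs(wrap_angle(pred.angles - rec.angles)))
    return float(np.degrees(np.mean(errors))) if errors else 0.0
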