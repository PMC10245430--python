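# Methods

## Scope and model

torconf predicts, for one molecule, sequences of normalized torsion angles —
one angle per rotatable bond — conditioned on a conformer-level relative
energy, and rebuilds 3D conformers by resetting those torsions on an
embedded initial structure. Bond lengths and bond angles are never changed;
ring conformations and inversions are outside the model's degrees of
freedom. The model consumes only the 2D graph (plus energy and noise), so
its predictions are exactly invariant to any rigid motion of input
coordinates, and — because molecules are canonically renumbered at parse
time — to the atom order of the input file.

## Conventions that matter

- **Dihedral sign**: IUPAC (cis = 0, trans = π, right-handed about i→j),
  cross-checked against RDKit's implementation in the tests.
- **Normalized torsion**: α = atan2(Σ c·sinΔ, Σ c·cosΔ) over all terminal
  pairs. The angle is defined so that rotating the bond by γ shifts α by
  exactly +γ; that equivariance, not an absolute sign, is the contract the
  tests enforce.
- **Pair weights**: c_mn = 2^-(m+n), m/n the 1-based canonical-rank position
  of each terminal atom. A single shared constant cannot prevent exact
  cancellation for symmetric terminal groups (three CF3 fluorines at 120°
  spacing sum to zero); strictly decreasing positive weights make the sum
  non-zero for every non-degenerate geometry. The tests construct the exact
  symmetric geometry and verify equal weights fail where the default
  succeeds.
- **Angles** live in (−π, π]; every comparison uses the wrapped difference.
- **Rotatable bond**: non-ring single bond between heavy atoms, each end
  with ≥ 1 further heavy neighbour. Amide C–N bonds count as rotatable by
  default (`include_amide=False` for the stricter convention). Torsions are
  ordered by (min, max) canonical rank of the bond atoms; this deterministic
  order is also the decoder's autoregressive order.
- **Hydrogens** are implicit: graph nodes are heavy atoms, H counts are atom
  features, and RMSD is heavy-atom.

## Architecture and defaults

Atom features (38) and bond features (7) follow the AttentiveFP vocabulary
(16-element one-hot + other, degree, formal charge, hybridisation,
aromaticity, H count, ring, chirality flag). The position vector has three
equal parts (default 16 each): a WL-label embedding (3 refinement
iterations, seeded by element+degree, hashed into 1024 buckets with a
platform-stable hash), a degree embedding, and a linear map of the
zero-padded adjacency row (capped at `max_atoms`, default 64). Ablation
modes `none` and `learnable` (free per-index embedding) mirror the full
variant for controlled comparisons.

Default depths are 2 atom-attention rounds, 4 encoder and 4 decoder layers,
4 heads, width 128. The tests and the acceptance script use a lighter
configuration (1/2/2, width 64) — ample for the synthetic task sizes and
chosen so a full training run takes tens of seconds on one CPU. Sampling
noise is Gaussian on T0 with std 5.0 by default at generation time; training
runs with noise 0 (`train_noise_std`) so the deterministic recovery
experiments are well-posed.

The relative energy enters as the decoder start token through a small MLP
over Fourier features of the energy (frequencies 0.5/1/2/4 per kcal/mol plus
the scaled raw value). A raw scalar input also works but separates nearby
energy levels far more slowly during training.

## Training objective

The default loss is the squared error of the raw (sin, cos) head output
against the target unit vector. The pure cosine angular loss
mean(1 − cos(â − a)) is selectable (`loss: cosine`) and is the form used for
reporting, but it is not the training default for a concrete reason: its
gradient vanishes exactly when a prediction sits at the antipode of its
target, and with grid-valued targets ({0°, 180°}) training demonstrably
freezes in that saddle. The raw-vector loss is zero iff the wrapped error is
zero and has no such stationary point.

Optimisation is full-batch Adam (default lr 3e-3 in the library, 5e-3 in
the experiments), teacher-forced, with optional plateau early stopping.
Within an epoch the graph-side forward pass is shared across conformers of
the same molecule.

## Synthetic data: what it does and does not emulate

`make_ensemble` sweeps every rotatable bond over a torsion grid (default
60°), rebuilds each grid point from one ETKDG-embedded conformer, scores it
with independent per-bond 3-fold cosine barriers
E(θ) = Σ V_l(1 + cos 3θ_l)/2, keeps the `n_keep` (default 8) lowest-energy
points and shifts energies so the minimum is exactly 0 — the record shape of
the large experimental conformer collections (graph, conformers, relative
energies with 0 marking the minimum).

This emulates the *structure* of real data, not its physics: real torsion
profiles couple across bonds, have non-3-fold terms, and real ensembles
contain ring puckers and correlated relaxation. Passing tests therefore
demonstrate that the architecture, geometry engine and metrics behave
correctly — not that the model generalises to experimental chemical space.

**Identifiability of the recovery experiment.** The 3-fold potential is even
in each θ, so ±θ grid points are exactly energy-degenerate for any grid step
below 180°; (graph, energy) → angle-set is then one-to-many and no
deterministic decoder can fit it — for three equally spaced degenerate
targets the angular loss is exactly flat. The parameter-recovery experiment
(`recovery_records`) therefore uses a 180° grid (angles ∈ {0°, 180°}) with
distinct per-bond barriers (1.0/2.3/3.6 kcal/mol), making energy a unique
key for the angle set within each molecule: 2 records for butane and
1,1,1-trifluoropropane, 4 for pentane, 8 for 1,2-diphenylethane. This is a
mathematical requirement of a well-posed recovery target, fixed at design
time; the generator's own defaults (60° grid, n_keep 8) are unchanged and
used for the ensemble-level demonstrations.

## Generation and evaluation

Conformers are rebuilt by rotating the smaller fragment (tie → the j-side)
about each bond in canonical order; intra-fragment geometry is preserved to
1e-9 Å. Sampling draws differ only through encoder noise; each
(seed, sample index) is deterministic, and the `--n 2k` convention generates
twice the reference count, conditioning on each reference energy twice.

RMSD is heavy-atom, best-fit, minimised over graph automorphisms (RDKit
GetBestRMS); a fixed-order variant is flag-selectable since published
benchmarks do not always state which convention they used. COV uses strict
`< δ`, δ = 1.25 Å by default. Identical coordinate arrays short-circuit to
RMSD exactly 0 so that S_g = S_r yields MAT = 0 exactly rather than solver
roundoff. The COV/MAT aggregation is cross-checked against an independently
coded brute-force double loop to 1e-9.

## Known limitations

- No stereochemistry enumeration, tautomers, or macrocycle-specific torsion
  handling; multi-fragment inputs are rejected.
- The WL hash vocabulary (1024 buckets) can collide on large diverse
  datasets; at the package's problem sizes collisions are negligible.
- `pos_a` requires a fixed `max_atoms` cap; larger molecules are rejected
  rather than truncated.
- Trained checkpoints here are desk-scale demonstrations; no claim is made
  about benchmark performance on large experimental datasets, which would
  require training at a scale this package does not attempt.
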