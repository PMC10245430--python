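"""Dihedral math, the normalized torsion angle, and conformer reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from torconf import (
    apply_torsion_sequence,
    find_rotatable_bonds,
    normalized_torsion,
    read_molecule,
    set_torsion,
    wrap_angle,
)
from torconf.fixtures import embed_initial
from torconf.geometry import (
    Conformer,
    DegenerateGeometryError,
    bond_fragments,
    default_pair_weights,
    dihedral,
    measure_torsion_sequence,
    read_ensemble_sdf,
    rotate_bond,
    write_ensemble_sdf,
)


def chain_coords(dihedral_deg: float, bond_angle_deg: float = 111.0, r: float = 1.53) -> np.ndarray:
    """Analytic 4-atom chain a-i-j-b with a prescribed dihedral a-i-j-b.

    Placement in internal coordinates: i at origin, j on +x, a in the xy
    plane, b rotated out of plane by the dihedral.
    """
    theta = np.radians(180.0 - bond_angle_deg)
    phi = np.radians(dihedral_deg)
    i = np.zeros(3)
    j = np.array([r, 0.0, 0.0])
    a = np.array([-r * np.cos(theta), r * np.sin(theta), 0.0])
    # b placed relative to j, then rotated about the i->j axis by the dihedral
    b0 = j + np.array([r * np.cos(theta), r * np.sin(theta), 0.0])
    b = j + Rotation.from_rotvec([phi, 0.0, 0.0]).apply(b0 - j)
    return np.stack([a, i, j, b])


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert abs(dihedral(chain_coords(0.0), 0, 1, 2, 3)) < 1e-12

    def test_planar_trans_is_pi(self):
        assert abs(abs(dihedral(chain_coords(180.0), 0, 1, 2, 3)) - np.pi) < 1e-12

    @pytest.mark.parametrize("deg", [60.0, -60.0, 35.0, -150.0, 90.0])
    def test_analytic_chain_reproduces_signed_angle(self, deg):
        assert abs(wrap_angle(dihedral(chain_coords(deg), 0, 1, 2, 3) - np.radians(deg))) < 1e-9

    def test_rigid_motion_invariance(self):
        coords = chain_coords(47.0)
        rng = np.random.default_rng(0)
        rot = Rotation.random(random_state=42)
        moved = rot.apply(coords) + rng.normal(size=3)
        assert abs(dihedral(moved, 0, 1, 2, 3) - dihedral(coords, 0, 1, 2, 3)) < 1e-9

    def test_collinear_geometry_raises(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(DegenerateGeometryError):
            dihedral(coords, 0, 1, 2, 3)


class TestNormalizedTorsion:
    def test_single_pair_equals_plain_dihedral(self, suite_embedded):
        graph, conf, specs = suite_embedded["butane"]
        (spec,) = specs
        assert len(spec.a_group) == len(spec.b_group) == 1
        d = dihedral(conf.coords, spec.a_group[0], spec.bond[0], spec.bond[1], spec.b_group[0])
        assert abs(wrap_angle(normalized_torsion(conf.coords, spec) - d)) < 1e-12

    def test_rotation_equivariance(self, suite_embedded):
        graph, conf, specs = suite_embedded["pentane"]
        rng = np.random.default_rng(1)
        for spec in specs:
            base = normalized_torsion(conf.coords, spec)
            for gamma in rng.uniform(-np.pi, np.pi, 10):
                rotated = rotate_bond(conf, graph, spec, gamma)
                shifted = normalized_torsion(rotated.coords, spec)
                assert abs(wrap_angle(shifted - base - gamma)) < 1e-6

    def test_se3_invariance_and_reflection_sign_flip(self, suite_embedded):
        graph, conf, specs = suite_embedded["trifluoropropane"]
        (spec,) = specs
        base = normalized_torsion(conf.coords, spec)
        rng = np.random.default_rng(2)
        for k in range(5):
            rot = Rotation.random(random_state=k)
            moved = rot.apply(conf.coords) + rng.normal(size=3)
            assert abs(normalized_torsion(moved, spec) - base) < 1e-6
        mirrored = conf.coords * np.array([1.0, 1.0, -1.0])
        assert abs(wrap_angle(normalized_torsion(mirrored, spec) + base)) < 1e-6

    def test_cf3_symmetric_group_cancels_under_equal_weights_only(self):
        """Three terminal atoms at exactly 120° spacing cancel under equal
        pair weights; the strictly decreasing default weights keep α defined."""
        from torconf.molgraph import TorsionSpec

        r, theta = 1.35, np.radians(180.0 - 109.5)
        i, j = np.zeros(3), np.array([1.53, 0.0, 0.0])
        b = j + np.array([r * np.cos(theta), r * np.sin(theta), 0.0])
        a_atoms = [
            i + Rotation.from_rotvec([phi, 0.0, 0.0]).apply(
                np.array([-r * np.cos(theta), r * np.sin(theta), 0.0])
            )
            for phi in np.radians([0.0, 120.0, 240.0])
        ]
        coords = np.stack([i, j, b, *a_atoms])
        spec = TorsionSpec(bond=(0, 1), a_group=[3, 4, 5], b_group=[2])
        with pytest.raises(DegenerateGeometryError):
            normalized_torsion(coords, spec, weights=np.ones((3, 1)))
        alpha = normalized_torsion(coords, spec)  # default weights: defined
        assert np.isfinite(alpha)

    def test_weights_shape_and_positivity_enforced(self, suite_embedded):
        graph, conf, specs = suite_embedded["butane"]
        with pytest.raises(ValueError):
            normalized_torsion(conf.coords, specs[0], weights=np.ones((2, 2)))


class TestSetTorsion:
    def test_identity_target_leaves_coordinates(self, suite_embedded):
        graph, conf, specs = suite_embedded["pentane"]
        spec = specs[0]
        current = normalized_torsion(conf.coords, spec)
        out = set_torsion(conf, graph, spec, current)
        np.testing.assert_allclose(out.coords, conf.coords, atol=1e-9)

    def test_round_trip_on_random_targets(self, suite_embedded):
        graph, conf, specs = suite_embedded["butane"]
        rng = np.random.default_rng(3)
        for target in rng.uniform(-np.pi, np.pi, 100):
            out = set_torsion(conf, graph, specs[0], float(target))
            assert abs(wrap_angle(normalized_torsion(out.coords, specs[0]) - target)) < 1e-6

    def test_fragment_internal_distances_preserved(self, suite_embedded):
        graph, conf, specs = suite_embedded["diphenylethane"]
        spec = specs[1]
        frag_i, frag_j = bond_fragments(graph, spec)
        out = set_torsion(conf, graph, spec, 2.0)
        for frag in (frag_i, frag_j):
            d_before = np.linalg.norm(conf.coords[frag][:, None] - conf.coords[frag][None], axis=-1)
            d_after = np.linalg.norm(out.coords[frag][:, None] - out.coords[frag][None], axis=-1)
            np.testing.assert_allclose(d_after, d_before, atol=1e-9)

    def test_sequential_sets_on_distinct_bonds_commute(self, suite_embedded):
        graph, conf, specs = suite_embedded["pentane"]
        t0, t1 = np.radians(60.0), np.radians(180.0)
        out = set_torsion(set_torsion(conf, graph, specs[0], t0), graph, specs[1], t1)
        assert abs(wrap_angle(normalized_torsion(out.coords, specs[0]) - t0)) < 1e-6
        assert abs(wrap_angle(normalized_torsion(out.coords, specs[1]) - t1)) < 1e-6

    def test_non_bridge_bond_rejected(self, suite_embedded):
        graph, conf, specs = suite_embedded["butane"]
        from torconf.molgraph import TorsionSpec

        ring_graph = read_molecule("C1CCCCC1")
        ring_spec = TorsionSpec(bond=(0, 3), a_group=[1], b_group=[2])
        with pytest.raises(ValueError, match="bridge"):
            bond_fragments(ring_graph, ring_spec)


class TestApplySequence:
    def test_empty_sequence_returns_initial(self, suite_embedded):
        graph, conf, _ = suite_embedded["benzene"]
        out = apply_torsion_sequence(conf, graph, [], np.empty(0))
        np.testing.assert_array_equal(out.coords, conf.coords)

    def test_all_angles_hit_targets(self, suite_embedded):
        graph, conf, specs = suite_embedded["diphenylethane"]
        targets = np.radians([60.0, 180.0, -75.0])
        out = apply_torsion_sequence(conf, graph, specs, targets)
        measured = measure_torsion_sequence(out, specs)
        assert np.max(np.abs(wrap_angle(measured - targets))) < 1e-5

    def test_idempotent(self, suite_embedded):
        graph, conf, specs = suite_embedded["pentane"]
        targets = np.radians([45.0, -120.0])
        once = apply_torsion_sequence(conf, graph, specs, targets)
        twice = apply_torsion_sequence(once, graph, specs, targets)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-6)

    def test_length_mismatch_rejected(self, suite_embedded):
        graph, conf, specs = suite_embedded["pentane"]
        with pytest.raises(ValueError, match="angles"):
            apply_torsion_sequence(conf, graph, specs, np.array([0.1]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=-50.0, max_value=50.0))
def test_wrap_angle_is_periodic_and_in_range(theta):
    w = wrap_angle(theta)
    assert -np.pi < w <= np.pi
    assert abs(wrap_angle(theta + 2 * np.pi) - w) < 1e-9


def test_sdf_round_trip(tmp_path, suite_embedded):
    graph, conf, specs = suite_embedded["pentane"]
    variants = [
        apply_torsion_sequence(conf, graph, specs, np.radians(a)).coords for a in ([60, 60], [180, -60])
    ]
    conformers = [
        Conformer(coords=variants[0], relative_energy=0.0),
        Conformer(coords=variants[1], relative_energy=1.25),
    ]
    path = tmp_path / "ens.sdf"
    write_ensemble_sdf(path, graph, conformers)
    graph2, back = read_ensemble_sdf(path)
    assert graph2.smiles == graph.smiles
    assert [round(c.relative_energy, 6) for c in back] == [0.0, 1.25]
    from torconf.evaluation import rmsd

    for orig, rt in zip(conformers, back):
        assert rmsd(orig, rt, graph) < 1e-4
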