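"""R2 family, internal coordinates, and Cremer–Pople puckering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from namdclust.datasets import Geometry
from namdclust.descriptors import (
    bond_angle,
    cremer_pople,
    default_connectivity,
    delta_zmatrix,
    descriptor_dataset,
    dihedral_angle,
    pairwise_distance_names,
    pairwise_distance_vector,
    r2_variant,
    wrap_angle,
    zmatrix,
    zmatrix_names,
    zmatrix_to_cartesian,
)
from namdclust.exceptions import ConfigError, DataError
from namdclust.synthetic import make_template

from conftest import apply_rigid, random_rigid_motion


def _random_geometry(rng, n=8, spread=2.0):
    """Random geometry with a minimum interatomic distance (no collinearity traps)."""
    while True:
        coords = rng.uniform(-spread, spread, size=(n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.5:
            return Geometry(("C",) * n, coords)


class TestR2:
    def test_right_triangle_example(self):
        g = Geometry(("C",) * 3, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_allclose(
            pairwise_distance_vector(g), [1.0, 1.0, math.sqrt(2)], atol=1e-12
        )

    def test_twelve_atoms_give_66_features(self):
        g = make_template("fulvene_like")
        v = pairwise_distance_vector(g)
        assert len(v) == 66
        names = pairwise_distance_names(12)
        assert len(names) == 66 and names[0] == "R_1_0" and names[2] == "R_2_1"

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        g = _random_geometry(rng)
        rot, shift = random_rigid_motion(rng)
        v1 = pairwise_distance_vector(g)
        v2 = pairwise_distance_vector(apply_rigid(g, rot, shift))
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    @pytest.mark.parametrize(
        "variant,expected",
        [("delta", 0.0), ("re", 1.0)],
    )
    def test_identity_reference_compositions(self, variant, expected):
        v = np.array([1.0, 2.0, 3.5])
        np.testing.assert_allclose(r2_variant(v, v, variant), expected)

    def test_inverse(self):
        np.testing.assert_allclose(r2_variant(np.array([2.0]), None, "inverse"), [0.5])

    def test_zero_distance_inverse_rejected(self):
        with pytest.raises(DataError):
            r2_variant(np.array([0.0, 1.0]), None, "inverse")

    def test_single_atom_rejected(self):
        with pytest.raises(DataError):
            pairwise_distance_vector(Geometry(("C",), [[0, 0, 0]]))


class TestAnglesAndDihedrals:
    def test_right_angle(self):
        g = Geometry(("C",) * 3, [[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        assert bond_angle(g, 0, 1, 2) == pytest.approx(90.0)

    def test_collinear_angle_is_180(self):
        g = Geometry(("C",) * 3, [[-1, 0, 0], [0, 0, 0], [1, 0, 0]])
        assert bond_angle(g, 0, 1, 2) == pytest.approx(180.0)

    @pytest.mark.parametrize(
        "d_coords,expected",
        [([0, 1, 0], 0.0), ([2, 1, 0], 180.0), ([1, 1, 1], 90.0)],
    )
    def test_reference_torsions(self, d_coords, expected):
        g = Geometry(
            ("C",) * 4, [[0, 0, 0], [1, 0, 0], [1, 1, 0], d_coords]
        )
        assert dihedral_angle(g, 0, 1, 2, 3) == pytest.approx(expected)

    def test_against_vector_algebra_oracle(self):
        """1000 random quadruples vs. an independently coded atan2 formula."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            g = _random_geometry(rng, n=4)
            # independent oracle: the signed angle between the two bond planes,
            # sign from the determinant (scalar triple product) det[n1, n2, b2]
            p0, p1, p2, p3 = g.coords
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            y = np.linalg.det(np.stack([n1, n2, b2 / np.linalg.norm(b2)]))
            expected_dih = math.degrees(math.atan2(y, n1 @ n2))
            u, v = p0 - p1, p2 - p1
            expected_ang = math.degrees(
                math.acos(np.clip(u @ v / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))
            )
            assert dihedral_angle(g, 0, 1, 2, 3) == pytest.approx(
                expected_dih, abs=1e-9
            )
            assert bond_angle(g, 0, 1, 2) == pytest.approx(expected_ang, abs=1e-9)

    def test_collinear_backbone_rejected(self):
        g = Geometry(("C",) * 4, [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(DataError):
            dihedral_angle(g, 0, 1, 2, 3)


class TestZMatrix:
    def test_square_path_counts(self):
        g = Geometry(("C",) * 4, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        z = zmatrix(g)
        assert len(z.bonds) == 3 and len(z.angles) == 2 and len(z.dihedrals) == 1
        assert z.dihedrals[0] == pytest.approx(0.0, abs=1e-9)

    def test_feature_count_3n_minus_6(self):
        g = make_template("fulvene_like")
        assert len(zmatrix(g).vector()) == 30
        assert len(zmatrix_names(12)) == 30

    def test_cartesian_roundtrip(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = _random_geometry(rng, n=7)
            z = zmatrix(g)
            rebuilt = Geometry(g.labels, zmatrix_to_cartesian(z))
            z2 = zmatrix(rebuilt)
            np.testing.assert_allclose(z.vector(), z2.vector(), atol=1e-8)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        g = _random_geometry(rng)
        rot, shift = random_rigid_motion(rng)
        np.testing.assert_allclose(
            zmatrix(g).vector(),
            zmatrix(apply_rigid(g, rot, shift)).vector(),
            atol=1e-9,
        )

    def test_forward_reference_connectivity_rejected(self):
        g = _random_geometry(np.random.default_rng(0), n=4)
        conn = [(1, -1, -1), (0, 3, -1), (1, 0, 3)]  # atom 1 references atom 3
        with pytest.raises(DataError):
            zmatrix(g, conn)


class TestDeltaZMatrix:
    def test_identity_reference(self):
        g = _random_geometry(np.random.default_rng(1))
        z = zmatrix(g)
        np.testing.assert_allclose(delta_zmatrix(z, z, "none"), 0.0, atol=1e-12)
        np.testing.assert_allclose(delta_zmatrix(z, z, "sig"), 0.5, atol=1e-12)

    def test_dihedral_wrap_rule(self):
        assert wrap_angle(np.array([179.0 - (-179.0)]))[0] == pytest.approx(-2.0)
        assert wrap_angle(np.array([180.0]))[0] == pytest.approx(180.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-720, 720))
    def test_wrap_range_property(self, delta):
        w = float(wrap_angle(np.array([delta]))[0])
        assert -180.0 < w <= 180.0
        # wrapped value is congruent mod 360
        assert math.isclose((delta - w) % 360.0, 0.0, abs_tol=1e-6) or math.isclose(
            (delta - w) % 360.0, 360.0, abs_tol=1e-6
        )

    def test_tanh_bounds_large_stretch(self):
        g = _random_geometry(np.random.default_rng(3), n=4)
        z_ref = zmatrix(g)
        stretched = g.coords.copy()
        bond_dir = (g.coords[1] - g.coords[0]) / np.linalg.norm(g.coords[1] - g.coords[0])
        stretched[1:] += 5.0 * bond_dir  # stretch first bond by 5 Å
        z = zmatrix(Geometry(g.labels, stretched))
        out = delta_zmatrix(z, z_ref, "tanh")
        assert out[0] == pytest.approx(math.tanh(5.0), abs=1e-6)

    def test_connectivity_mismatch_rejected(self):
        g = _random_geometry(np.random.default_rng(4), n=5)
        z1 = zmatrix(g)
        conn = [list(c) for c in default_connectivity(5)]
        conn[3] = (2, 1, 0)
        z2 = zmatrix(g, conn)
        with pytest.raises(DataError):
            delta_zmatrix(z1, z2)


class TestCremerPople:
    def test_planar_hexagon_is_flat(self):
        p = cremer_pople(make_template("ring6_planar"), range(6))
        assert p.Q == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(p.z, 0.0, atol=1e-10)

    def test_chair_pure_q3_mode(self):
        """Alternating ±0.25 Å displacements: the Fourier sums give a pure
        m=3 mode with Q = sqrt(6)*0.25 and a polar angle at a pole."""
        ring = make_template("ring6_planar")
        coords = ring.coords.copy()
        coords[:, 2] = (-1.0) ** np.arange(6) * 0.25
        p = cremer_pople(Geometry(ring.labels, coords), range(6))
        assert p.Q == pytest.approx(math.sqrt(6) * 0.25, abs=1e-10)
        assert p.q[2] == pytest.approx(0.0, abs=1e-10)
        assert p.theta in (pytest.approx(0.0, abs=1e-8), pytest.approx(180.0, abs=1e-8))

    def test_six_ring_reports_three_parameters(self):
        ring = make_template("ring6_planar")
        coords = ring.coords + np.random.default_rng(0).normal(0, 0.05, (6, 3))
        p = cremer_pople(Geometry(ring.labels, coords), range(6))
        # N - 3 = 3 independent coordinates: (Q, theta, phi)
        assert p.theta is not None and p.phi_angle is not None
        assert set(p.q) == {2, 3}

    def test_invariants_sum_and_norm(self):
        rng = np.random.default_rng(9)
        ring = make_template("ring6_planar")
        for _ in range(10):
            g = Geometry(ring.labels, ring.coords + rng.normal(0, 0.15, (6, 3)))
            p = cremer_pople(g, range(6))
            assert abs(p.z.sum()) < 1e-10
            assert p.Q**2 == pytest.approx(float((p.z**2).sum()), abs=1e-10)

    def test_fourier_sum_oracle(self):
        """Amplitudes match a from-scratch evaluation of the discrete sums."""
        rng = np.random.default_rng(4)
        ring = make_template("ring6_planar")
        g = Geometry(ring.labels, ring.coords + rng.normal(0, 0.1, (6, 3)))
        p = cremer_pople(g, range(6))
        z, N, j = p.z, 6, np.arange(6)
        for m in (2,):
            qc = math.sqrt(2 / N) * sum(z[i] * math.cos(2 * math.pi * m * i / N) for i in j)
            qs = -math.sqrt(2 / N) * sum(z[i] * math.sin(2 * math.pi * m * i / N) for i in j)
            assert p.q[m] == pytest.approx(math.hypot(qc, qs), abs=1e-12)
        q3 = math.sqrt(1 / N) * sum(z[i] * (-1) ** i for i in j)
        assert p.q[3] == pytest.approx(q3, abs=1e-12)

    def test_degenerate_ring_rejected(self):
        g = Geometry(("C",) * 4, [[i, 0, 0] for i in range(4)])
        with pytest.raises(DataError):
            cremer_pople(g, range(4))


class TestDescriptorDataset:
    def test_r2_table_width_and_per_frame_oracle(self, small_ensemble):
        table = descriptor_dataset(small_ensemble, "r2")
        assert table.shape[1] == 66
        traj, time = table.index[10]
        row = table.iloc[10].to_numpy()
        np.testing.assert_array_equal(
            row, pairwise_distance_vector(small_ensemble.select_frame(traj, time))
        )

    def test_delta_r2_with_self_reference_is_zero(self, small_ensemble):
        key = small_ensemble.keys[0]
        ref = small_ensemble.geometries[key]
        table = descriptor_dataset(small_ensemble, "delta_r2", reference=ref)
        np.testing.assert_allclose(table.loc[key].to_numpy(), 0.0, atol=1e-12)

    def test_missing_reference_rejected(self, small_ensemble):
        ens = small_ensemble
        saved, ens.reference = ens.reference, None
        try:
            with pytest.raises(ConfigError):
                descriptor_dataset(ens, "delta_zmat")
        finally:
            ens.reference = saved

    def test_cremer_pople_table_for_ring(self, small_ensemble):
        table = descriptor_dataset(small_ensemble, "cremer_pople", ring_atoms=range(5))
        assert table.shape[0] == small_ensemble.n_frames
        assert np.isfinite(table.to_numpy()).all()
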