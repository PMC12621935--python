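"""Dimer order parameters: distance maps, Crick angles, twist dihedral."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from micellekit.dimer_geometry import (GeometryError, analyze_dimer_frame,
                                       crick_angle, dihedral, dimer_dihedral,
                                       helix_axis, histogram2d,
                                       lysine_pair_distances,
                                       residue_distance_matrix)
from micellekit.synthetic_data import HelixSpec, make_dimer, make_helix


def _spec(chain):
    return HelixSpec(chain=chain)


class TestDistanceMatrix:
    def test_parallel_helices_diagonal(self, parallel_dimer):
        """Identical parallel helices, axes 10 Å apart: like-residue pair
        distances for mid-helix residues sit near the axis separation."""
        topo, pos = parallel_dimer
        resids, mat = residue_distance_matrix(topo, pos)
        mid = slice(10, 30)
        diag = np.diag(mat)[mid]
        assert np.all(np.abs(diag - 10.0) < 2.0 * 2.3)

    def test_chain_swap_invariance(self, parallel_dimer):
        topo, pos = parallel_dimer
        _, mat = residue_distance_matrix(topo, pos, "A", "B")
        _, swapped = residue_distance_matrix(topo, pos, "B", "A")
        assert np.allclose(mat, swapped, equal_nan=True)

    def test_symmetric(self, parallel_dimer):
        topo, pos = parallel_dimer
        _, mat = residue_distance_matrix(topo, pos)
        assert np.allclose(mat, mat.T, equal_nan=True)

    def test_constructed_k28_distance(self):
        """Parallel helices at separation 13 with identical rolls put every
        like-residue pair, K28 included, exactly 13 Å apart."""
        a, pa = make_helix(HelixSpec(chain="A"))
        b, pb = make_helix(HelixSpec(chain="B"))
        topo = a.concat(b)
        pos = np.vstack([pa, pb + np.array([13.0, 0.0, 0.0])])
        d28, d54 = lysine_pair_distances(topo, pos)
        assert d28 == pytest.approx(13.0, abs=1e-9)
        assert d54 == pytest.approx(13.0, abs=1e-9)
        resids, mat = residue_distance_matrix(topo, pos)
        i28 = int(np.flatnonzero(resids == 28)[0])
        assert mat[i28, i28] == pytest.approx(13.0, abs=1e-9)

    def test_crossed_at_c_terminus_flips_ordering(self):
        """A crossing that splays the C-termini makes d_K54 exceed d_K28."""
        topo, pos = make_dimer(_spec("A"), _spec("B"), crossing_angle=40.0,
                               separation=10.0, g33_phase=90.0)
        d28, d54 = lysine_pair_distances(topo, pos)
        topo0, pos0 = make_dimer(_spec("A"), _spec("B"), crossing_angle=0.0,
                                 separation=10.0, g33_phase=90.0)
        d28_0, d54_0 = lysine_pair_distances(topo0, pos0)
        assert abs(d54 - d28) > abs(d54_0 - d28_0)


class TestHelixAxis:
    def test_ideal_helix_axis_along_z(self):
        # 37 residues = 36 rises x 100 deg = 10 full turns: the Ca set is
        # rotationally balanced and the principal axis is exact
        topo, pos = make_helix(HelixSpec(n_residues=37))
        ca = pos[topo.select(name="CA")]
        axis, point = helix_axis(ca)
        assert np.allclose(axis, [0, 0, 1], atol=1e-6)
        assert np.linalg.norm(point[:2]) < 0.01  # fitted centre on axis
        # a non-integer number of turns tilts the PCA axis only slightly
        topo40, pos40 = make_helix(HelixSpec())
        axis40, _ = helix_axis(pos40[topo40.select(name="CA")])
        assert np.degrees(np.arccos(abs(axis40[2]))) < 1.0

    def test_reversed_order_flips_orientation(self):
        topo, pos = make_helix(HelixSpec())
        ca = pos[topo.select(name="CA")]
        axis_fwd, _ = helix_axis(ca)
        axis_rev, _ = helix_axis(ca[::-1])
        assert np.allclose(axis_rev, -axis_fwd, atol=1e-6)

    def test_noisy_helix_axis_within_2_degrees(self):
        topo, pos = make_helix(HelixSpec())
        ca = pos[topo.select(name="CA")]
        angles = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = ca + rng.normal(0, 0.3, ca.shape)
            axis, _ = helix_axis(noisy)
            angles.append(np.degrees(np.arccos(abs(axis[2]))))
        assert max(angles) < 2.0

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            helix_axis(np.zeros((3, 3)))


class TestCrickAngle:
    @pytest.mark.parametrize("phase", [0.0, 90.0, 180.0])
    def test_fixture_endpoints(self, phase):
        topo, pos = make_dimer(_spec("A"), _spec("B"), 0.0, 10.0, phase)
        for chain in ("A", "B"):
            assert crick_angle(topo, pos, chain) == pytest.approx(
                phase, abs=2.0)

    def test_swap_symmetry(self):
        """Relabeling chains swaps (ψ_A, ψ_B)."""
        topo, pos = make_dimer(_spec("A"), _spec("B"), 0.0, 10.0, 60.0)
        psi_a = crick_angle(topo, pos, "A")
        psi_b = crick_angle(topo, pos, "B")
        relabeled = topo.subset(np.arange(topo.n_atoms))
        relabeled.chain = np.where(relabeled.chain == "A", "B",
                                   np.where(relabeled.chain == "B", "A",
                                            relabeled.chain))
        assert crick_angle(relabeled, pos, "A") == pytest.approx(psi_b,
                                                                 abs=1e-6)
        assert crick_angle(relabeled, pos, "B") == pytest.approx(psi_a,
                                                                 abs=1e-6)


class TestDihedral:
    def test_cis_is_zero(self):
        pts = [(1, 1, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0)]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-9)

    def test_iupac_plus_90(self):
        """The worked four-point example is +90° under the convention."""
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1),
                        (0, 1, 1)) == pytest.approx(90.0)

    def test_collinear_undefined(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0))

    def test_handedness_on_randomized_crossed_dimers(self):
        """Dihedral sign equals constructed crossing handedness for 50
        randomized crossed dimers (symmetric marker phase)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            ang = rng.uniform(8.0, 60.0) * rng.choice([-1.0, 1.0])
            sep = rng.uniform(8.0, 14.0)
            topo, pos = make_dimer(_spec("A"), _spec("B"), ang, sep, 90.0)
            assert np.sign(dimer_dihedral(topo, pos)) == np.sign(ang)

    def test_right_handed_fixture_negative(self):
        topo, pos = make_dimer(_spec("A"), _spec("B"), -25.0, 10.0, 90.0)
        assert dimer_dihedral(topo, pos) < 0


class TestRigidMotionInvariance:
    def test_all_order_parameters(self):
        topo, pos = make_dimer(_spec("A"), _spec("B"), -20.0, 11.0, 45.0)
        base = analyze_dimer_frame(topo, pos)
        rot = Rotation.random(random_state=9).as_matrix()
        moved = pos @ rot.T + np.array([120.0, -40.0, 7.0])
        other = analyze_dimer_frame(topo, moved)
        assert other.d_k28 == pytest.approx(base.d_k28, abs=1e-9)
        assert other.d_k54 == pytest.approx(base.d_k54, abs=1e-9)
        assert other.psi_a == pytest.approx(base.psi_a, abs=1e-6)
        assert other.psi_b == pytest.approx(base.psi_b, abs=1e-6)
        assert other.phi == pytest.approx(base.phi, abs=1e-6)
        assert np.allclose(other.distance_matrix, base.distance_matrix,
                           equal_nan=True, atol=1e-9)


class TestHistogram2D:
    def test_single_bin_carries_all_mass(self):
        h = histogram2d([1.0] * 10, [2.0] * 10, bins=5,
                        ranges=[[0, 5], [0, 5]])
        assert h.integral() == pytest.approx(1.0)
        assert np.count_nonzero(h.density) == 1

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        h = histogram2d(rng.normal(0, 1, 500), rng.normal(0, 2, 500), 30)
        assert h.integral() == pytest.approx(1.0)

    def test_uniform_approximately_flat(self):
        rng = np.random.default_rng(1)
        h = histogram2d(rng.uniform(0, 1, 40_000), rng.uniform(0, 1, 40_000),
                        bins=4, ranges=[[0, 1], [0, 1]])
        assert np.all(np.abs(h.density - 1.0) < 0.15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram2d([], [], 10)
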