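"""Hydrogen bonds and helicity: criteria, maps, marginals, profiles."""

import numpy as np
import pytest

from conftest import naive_hbonds
from micellekit.hbond_helicity import (ALIPHATIC_CAH, BACKBONE_NH, HBondMap,
                                       HBondCriterion, detect_hbonds,
                                       fractional_helicity, marginal_profile,
                                       propensity_map)
from micellekit.io_model import Frame, Topology, Trajectory
from micellekit.synthetic_data import HelixSpec, make_dimer, make_helix
from micellekit.workflows import single_frame_trajectory


def _toy_nh_o(d_ho: float, angle: float = 180.0):
    """Two residues: an N-H donor and a carbonyl O acceptor, with the
    H···O distance and N-H···O angle set explicitly."""
    # N at origin, H at (1.01, 0, 0); acceptor O placed so that the
    # N-H...O angle is `angle` and |H-O| = d_ho
    theta = np.deg2rad(180.0 - angle)
    o = np.array([1.01 + d_ho * np.cos(theta), d_ho * np.sin(theta), 0.0])
    topo = Topology(
        molecule_id=[0, 0, 0], mol_class=["protein"] * 3,
        chain=["A"] * 3, resname=["ALA", "ALA", "ALA"],
        resid=[1, 1, 5], name=["N", "H", "O"], mass=[1.0] * 3)
    pos = np.array([[0.0, 0, 0], [1.01, 0, 0], o])
    return topo, pos


class TestDetection:
    def test_collinear_inside_cutoffs_detected(self):
        topo, pos = _toy_nh_o(2.0, 180.0)
        bonds = detect_hbonds(topo, pos, BACKBONE_NH, scope="intra")
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.0)
        assert bonds[0].angle == pytest.approx(180.0)

    def test_distance_boundary_excludes(self):
        topo, pos = _toy_nh_o(2.6, 180.0)
        assert detect_hbonds(topo, pos, BACKBONE_NH, scope="intra") == []

    def test_angle_boundary(self):
        topo, pos = _toy_nh_o(2.0, 149.0)
        assert detect_hbonds(topo, pos, BACKBONE_NH, scope="intra") == []
        topo, pos = _toy_nh_o(2.0, 150.5)
        assert len(detect_hbonds(topo, pos, BACKBONE_NH, scope="intra")) == 1

    def test_ideal_helix_i_to_i4_pattern(self, ideal_helix):
        """The ideal helix shows exactly the i→i+4 backbone pattern for
        interior residues, and matches the exhaustive pair scan."""
        topo, pos = ideal_helix
        bonds = detect_hbonds(topo, pos, BACKBONE_NH, scope="intra")
        offsets = {b.donor_resid - b.acceptor_resid for b in bonds}
        assert offsets == {4}          # donor i+4 -> acceptor i
        donors = sorted(b.donor_resid for b in bonds)
        assert donors == list(range(20, 56))  # every residue with an H, i>=4

    @pytest.mark.parametrize("criterion", [BACKBONE_NH, ALIPHATIC_CAH])
    @pytest.mark.parametrize("scope", ["intra", "inter"])
    def test_equals_exhaustive_scan(self, criterion, scope):
        """Detector output is identical to an O(n²) brute-force scan on a
        crossed dimer fixture."""
        topo, pos = make_dimer(HelixSpec(chain="A"), HelixSpec(chain="B"),
                               crossing_angle=-30.0, separation=7.0,
                               g33_phase=0.0)
        got = {(b.donor_chain, b.donor_resid, b.acceptor_chain,
                b.acceptor_resid)
               for b in detect_hbonds(topo, pos, criterion, scope)}
        assert got == naive_hbonds(topo, pos, criterion, scope)

    def test_missing_hydrogens_instructive_error(self):
        topo, pos = make_helix(HelixSpec(include_hydrogens=False))
        with pytest.raises(ValueError, match="explicit-hydrogen"):
            detect_hbonds(topo, pos, BACKBONE_NH)

    def test_tighter_cutoff_never_adds_bonds(self, ideal_helix):
        topo, pos = ideal_helix
        loose = {(b.donor_resid, b.acceptor_resid) for b in detect_hbonds(
            topo, pos, HBondCriterion(distance_cutoff=2.5), "intra")}
        tight = {(b.donor_resid, b.acceptor_resid) for b in detect_hbonds(
            topo, pos, HBondCriterion(distance_cutoff=2.0), "intra")}
        assert tight <= loose

    def test_invalid_criterion(self):
        with pytest.raises(ValueError):
            HBondCriterion(distance_cutoff=-1.0)
        with pytest.raises(ValueError):
            HBondCriterion(angle_cutoff=200.0)


class TestPropensity:
    def _alternating_traj(self):
        """Frames alternate between bonded and unbonded geometry."""
        topo, pos_on = _toy_nh_o(2.0, 180.0)
        _, pos_off = _toy_nh_o(4.0, 180.0)
        frames = [Frame(positions=(pos_on if i % 2 == 0 else pos_off),
                        time=float(i)) for i in range(10)]
        return Trajectory(topology=topo, frames=frames)

    def test_present_every_frame(self):
        topo, pos = _toy_nh_o(2.0, 180.0)
        traj = single_frame_trajectory(topo, Frame(positions=pos), 4)
        hmap = propensity_map(traj, BACKBONE_NH, scope="intra")
        assert hmap.p.max() == 1.0

    def test_alternating_half(self):
        hmap = propensity_map(self._alternating_traj(), BACKBONE_NH,
                              scope="intra")
        assert hmap.p.max() == pytest.approx(0.5)

    def test_counted_once_per_frame(self, ideal_helix):
        """P_ij never exceeds 1 even with several qualifying atom pairs."""
        topo, pos = ideal_helix
        traj = single_frame_trajectory(topo, Frame(positions=pos), 3)
        hmap = propensity_map(traj, ALIPHATIC_CAH, scope="intra")
        assert hmap.p.max() <= 1.0


class TestMarginal:
    def test_single_entry_arithmetic(self):
        """P_{29,33} = 1 on a 40x40 grid: residue 29 gets 1/40 (row mean),
        residue 33 gets 1/40 (column mean)."""
        resids = np.arange(16, 56)
        p = np.zeros((40, 40))
        p[29 - 16, 33 - 16] = 1.0
        hmap = HBondMap(resids=resids, p=p, n_frames=1,
                        criterion=BACKBONE_NH)
        out = marginal_profile(hmap)
        assert out[29 - 16] == pytest.approx(1 / 40)
        assert out[33 - 16] == pytest.approx(1 / 40)
        assert out.sum() == pytest.approx(2 / 40)

    def test_zero_map(self):
        hmap = HBondMap(resids=np.arange(10), p=np.zeros((10, 10)),
                        n_frames=1, criterion=BACKBONE_NH)
        assert np.all(marginal_profile(hmap) == 0.0)

    def test_uniform_map(self):
        hmap = HBondMap(resids=np.arange(8), p=np.full((8, 8), 0.3),
                        n_frames=1, criterion=BACKBONE_NH)
        assert np.allclose(marginal_profile(hmap), 0.6)


class TestHelicity:
    def test_ideal_helix_interior(self, ideal_helix_traj):
        hel = fractional_helicity(ideal_helix_traj)
        interior = hel.helicity["A"][5:-5]
        assert np.all(interior >= 0.99)

    def test_extended_chain_zero(self):
        topo, pos = make_helix(HelixSpec(rise=3.5, twist=180.0))
        traj = single_frame_trajectory(topo, Frame(positions=pos), 2)
        hel = fractional_helicity(traj)
        assert np.all(hel.helicity["A"] == 0.0)

    def test_melted_window_dips(self, ideal_helix):
        """Displacing residues 20-25 produces a dip exactly there."""
        topo, pos = ideal_helix
        melted = pos.copy()
        sel = np.isin(topo.resid, range(20, 26))
        rng = np.random.default_rng(0)
        melted[sel] += rng.normal(0, 3.0, (sel.sum(), 3)) + [8.0, 0, 0]
        traj = single_frame_trajectory(topo, Frame(positions=melted), 1)
        hel = fractional_helicity(traj)
        prof = hel.helicity["A"]
        resids = hel.resids
        perturbed = np.isin(resids, range(20, 26))
        far = np.isin(resids, range(32, 50))
        assert prof[perturbed].mean() < 0.5
        assert np.all(prof[far] >= 0.99)

    def test_short_chain_all_zero(self):
        topo, pos = _toy_nh_o(2.0)
        traj = single_frame_trajectory(topo, Frame(positions=pos), 1)
        hel = fractional_helicity(traj)
        assert all(np.all(v == 0.0) for v in hel.helicity.values())

    def test_rotation_translation_invariance(self, ideal_helix):
        from scipy.spatial.transform import Rotation
        topo, pos = ideal_helix
        rot = Rotation.random(random_state=4).as_matrix()
        moved = pos @ rot.T + np.array([30.0, -12.0, 5.0])
        a = fractional_helicity(
            single_frame_trajectory(topo, Frame(positions=pos), 1))
        b = fractional_helicity(
            single_frame_trajectory(topo, Frame(positions=moved), 1))
        assert np.allclose(a.helicity["A"], b.helicity["A"])
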