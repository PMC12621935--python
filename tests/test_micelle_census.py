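"""Census: clustering, size rule, classification, statistics, convergence."""

import numpy as np
import pandas as pd
import pytest

from micellekit.io_model import Box, Frame, ReplicateSet, Trajectory
from micellekit.micelle_census import (aggregation_series, apply_min_size,
                                       census_frame, classify_micelles,
                                       cluster_surfactants, ergodic_measure,
                                       finite_size_check, size_histogram)
from micellekit.synthetic_data import (MicelleSpec, make_assembly_box,
                                       make_micelle)
from micellekit.workflows import single_frame_trajectory


class TestClustering:
    def test_two_separated_micelles(self):
        t1, p1 = make_micelle(MicelleSpec(s=15, r_head=10.0), seed=1)
        t2, p2 = make_micelle(MicelleSpec(s=12, r_head=9.0), seed=2)
        topo = t1.concat(t2)
        pos = np.vstack([p1 + 30.0, p2 + 90.0])
        frame = Frame(positions=pos, box=Box.cubic(120.0))
        mol_ids, labels = cluster_surfactants(frame, topo, cutoff=6.0)
        assert len(np.unique(labels)) == 2
        assert set(mol_ids[labels == 0]) == set(range(15))
        assert set(mol_ids[labels == 1]) == set(range(15, 27))

    def test_overlapping_micelles_merge(self):
        t1, p1 = make_micelle(MicelleSpec(s=15, r_head=10.0), seed=1)
        t2, p2 = make_micelle(MicelleSpec(s=12, r_head=9.0), seed=2)
        topo = t1.concat(t2)
        pos = np.vstack([p1 + 30.0, p2 + 34.0])  # shells within cutoff
        frame = Frame(positions=pos, box=Box.cubic(120.0))
        _, labels = cluster_surfactants(frame, topo, cutoff=6.0)
        assert len(np.unique(labels)) == 1

    def test_isolated_monomers_are_singletons(self):
        parts = [make_micelle(MicelleSpec(s=1, r_head=5.0), seed=i)
                 for i in range(50)]
        topo = parts[0][0]
        for t, _ in parts[1:]:
            topo = topo.concat(t)
        grid = np.array([(i % 4, (i // 4) % 4, i // 16)
                         for i in range(50)]) * 40.0 + 20.0
        pos = np.vstack([p + g for (_, p), g in zip(parts, grid)])
        frame = Frame(positions=pos, box=Box.cubic(200.0))
        _, labels = cluster_surfactants(frame, topo, cutoff=6.0)
        assert len(np.unique(labels)) == 50

    def test_input_order_invariance(self, assembly_box):
        """Census membership is independent of particle ordering."""
        topo, frame, _ = assembly_box
        ids1, lab1 = cluster_surfactants(frame, topo, 6.0)
        perm = np.random.default_rng(0).permutation(topo.n_atoms)
        topo_p = topo.subset(perm)
        frame_p = Frame(positions=frame.positions[perm], box=frame.box)
        ids2, lab2 = cluster_surfactants(frame_p, topo_p, 6.0)
        groups1 = {frozenset(ids1[lab1 == k]) for k in np.unique(lab1)}
        groups2 = {frozenset(ids2[lab2 == k]) for k in np.unique(lab2)}
        assert groups1 == groups2

    def test_bad_cutoff(self, assembly_box):
        topo, frame, _ = assembly_box
        with pytest.raises(ValueError):
            cluster_surfactants(frame, topo, cutoff=0.0)


class TestMinSize:
    @pytest.mark.parametrize("size,kept", [(9, False), (10, True), (11, True)])
    def test_threshold_boundary(self, size, kept):
        mol_ids = np.arange(size)
        labels = np.zeros(size, dtype=int)
        census = apply_min_size(mol_ids, labels, min_size=10)
        if kept:
            assert len(census.micelles) == 1
            assert census.micelles[0].size == size
        else:
            assert census.micelles == []
            assert len(census.free_molecule_ids) == size

    def test_identity_when_all_large(self):
        mol_ids = np.arange(30)
        labels = np.repeat([0, 1], 15)
        census = apply_min_size(mol_ids, labels, min_size=10)
        assert [m.size for m in census.micelles] == [15, 15]
        assert census.free_molecule_ids == []


class TestGroundTruthRecovery:
    def test_exact_recovery(self, assembly_box):
        """The reference box {5 dimer s=69, 4 empty s=42, 7 free} is
        recovered exactly: labels, sizes, classes, free monomers."""
        topo, frame, truth = assembly_box
        census = census_frame(frame, topo)
        assert sorted(m.size for m in census.micelles) == \
            sorted(m["size"] for m in truth["micelles"])
        got = {frozenset(m.molecule_ids): m.mol_class
               for m in census.micelles}
        expected = {frozenset(m["surfactant_molecule_ids"]): m["class"]
                    for m in truth["micelles"]}
        assert got == expected
        assert sorted(census.free_molecule_ids) == \
            sorted(truth["free_molecule_ids"])

    @pytest.mark.parametrize("cutoff", [5.0, 6.0, 8.0])
    def test_recovery_across_safe_cutoff_band(self, assembly_box, cutoff):
        topo, frame, truth = assembly_box
        census = census_frame(frame, topo, cutoff=cutoff)
        got = {frozenset(m.molecule_ids) for m in census.micelles}
        expected = {frozenset(m["surfactant_molecule_ids"])
                    for m in truth["micelles"]}
        assert got == expected

    def test_surfactant_conservation(self, assembly_box):
        topo, frame, _ = assembly_box
        census = census_frame(frame, topo)
        total = sum(m.size for m in census.micelles) + \
            len(census.free_molecule_ids)
        assert total == len(topo.molecules("surfactant"))

    def test_tie_break_to_smaller_label(self):
        """A dimer with equal contacts to two micelles goes to the smaller
        label."""
        t1, p1 = make_micelle(MicelleSpec(s=12, r_head=10.0), seed=1)
        t2, p2 = make_micelle(MicelleSpec(s=12, r_head=10.0), seed=1)
        from micellekit.synthetic_data import make_cg_dimer
        td, pd_ = make_cg_dimer(n_residues=10)
        topo = t1.concat(t2).concat(td)
        # dimer exactly midway between mirror-image micelles
        pos = np.vstack([p1 + [30, 50, 50],
                         (p2 * [-1, 1, 1]) + [70, 50, 50],
                         pd_ + [50, 50, 50]])
        frame = Frame(positions=pos, box=Box.cubic(100.0))
        census = census_frame(frame, topo, contact_cutoff=30.0,
                              min_contacts=1)
        dimered = [m for m in census.micelles if m.mol_class == "dimer"]
        assert len(dimered) == 1
        assert dimered[0].label == 0


class TestAggregationSeries:
    def test_static_box_means(self, assembly_box):
        """10 frames of the static box: means exactly 69 / 42, counts 5 / 4,
        overall size-weighted mean (5*69 + 4*42)/9 = 57.0."""
        topo, frame, _ = assembly_box
        traj = single_frame_trajectory(topo, frame, n_frames=10)
        series = aggregation_series(traj)
        assert (series.table["n_dimer"] == 5).all()
        assert (series.table["n_empty"] == 4).all()
        assert (series.table["mean_s_dimer"] == 69.0).all()
        assert (series.table["mean_s_empty"] == 42.0).all()
        assert np.allclose(series.table["mean_s_all"], 57.0)

    def test_class_mean_consistency(self, assembly_box):
        """total size = n_dimer*mean_dimer + n_empty*mean_empty per frame."""
        topo, frame, _ = assembly_box
        traj = single_frame_trajectory(topo, frame, n_frames=2)
        series = aggregation_series(traj)
        for _, row in series.table.iterrows():
            assert row["total_s"] == pytest.approx(
                row["n_dimer"] * row["mean_s_dimer"]
                + row["n_empty"] * row["mean_s_empty"])

    def test_single_micelle_mean(self):
        topo, pos = make_micelle(MicelleSpec(s=10, r_head=9.0))
        frame = Frame(positions=pos + 30.0, box=Box.cubic(60.0))
        traj = single_frame_trajectory(topo, frame)
        series = aggregation_series(traj)
        assert series.table["mean_s_all"].iloc[0] == 10.0

    def test_size_histogram_weightings(self, assembly_box):
        topo, frame, _ = assembly_box
        censuses = [census_frame(frame, topo)] * 3
        obs = size_histogram(censuses, weighting="observation")
        per_frame = size_histogram(censuses, weighting="frame")
        assert obs["weight"].sum() == pytest.approx(27)   # 9 micelles x 3
        assert per_frame["weight"].sum() == pytest.approx(3)


class TestErgodicMeasure:
    def test_identical_replicates_zero(self):
        rs = ReplicateSet(np.arange(10.0), np.tile(np.arange(10.0), (4, 1)))
        assert np.allclose(ergodic_measure(rs).omega, 0.0)

    def test_hand_example_m2(self):
        """M=2 constant counts 3 and 5: Ω = ((3-4)² + (5-4)²)/2 = 1."""
        rs = ReplicateSet(np.arange(6.0),
                          np.array([[3.0] * 6, [5.0] * 6]))
        assert np.allclose(ergodic_measure(rs).omega, 1.0)

    def test_matches_two_pass_variance(self):
        """Ω equals an independent two-pass population variance to 1e-12."""
        rng = np.random.default_rng(5)
        series = rng.integers(0, 30, size=(9, 40)).astype(float)
        rs = ReplicateSet(np.arange(40.0), series)
        omega = ergodic_measure(rs).omega
        for t in range(40):
            vals = series[:, t]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / len(vals)
            assert abs(omega[t] - var) < 1e-12

    def test_needs_two_replicates(self):
        rs = ReplicateSet(np.arange(4.0), np.ones((1, 4)))
        with pytest.raises(ValueError):
            ergodic_measure(rs)

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError):
            ReplicateSet(np.arange(5.0), np.ones((2, 4)))


class TestFiniteSize:
    def _series(self, n_dimer, n_empty):
        table = pd.DataFrame({
            "time": np.arange(10.0),
            "n_dimer": n_dimer, "n_empty": n_empty, "n_all": 0,
            "mean_s_dimer": np.nan, "mean_s_empty": np.nan,
            "mean_s_all": np.nan, "total_s": 0, "n_free": 0})
        from micellekit.micelle_census import AggregationSeries
        return AggregationSeries(table=table)

    def test_pass_5_4(self):
        report = finite_size_check(self._series(5, 4), t_eq=4.0)
        assert report.passed
        assert report.mean_n_dimer == 5.0

    def test_fail_too_few_empty(self):
        report = finite_size_check(self._series(5, 2), t_eq=4.0)
        assert not report.passed
        assert report.reasons == ["empty micelles < 3"]

    def test_boundary_3_3_passes(self):
        assert finite_size_check(self._series(3, 3), t_eq=4.0).passed
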