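"""Shared fixtures: synthetic systems with known ground truth."""

import numpy as np
import pytest

from micellekit.io_model import Frame
from micellekit.synthetic_data import (HelixSpec, MicelleSpec,
                                       make_assembly_box, make_dimer,
                                       make_helix)
from micellekit.workflows import single_frame_trajectory


@pytest.fixture(scope="session")
def assembly_box():
    """The reference census fixture: 5 dimer micelles (s=69), 4 empty
    (s=42), 7 free monomers, solvent."""
    dimers = [MicelleSpec(s=69, r_head=21.0, jitter=0.5) for _ in range(5)]
    empties = [MicelleSpec(s=42, r_head=16.0, jitter=0.5) for _ in range(4)]
    return make_assembly_box(dimers, empties, n_free=7, n_water=100, seed=11)


@pytest.fixture(scope="session")
def ideal_helix():
    """One 40-residue ideal α-helix with explicit amide/alpha hydrogens."""
    return make_helix(HelixSpec())


@pytest.fixture(scope="session")
def ideal_helix_traj(ideal_helix):
    topo, pos = ideal_helix
    return single_frame_trajectory(topo, Frame(positions=pos), n_frames=3)


@pytest.fixture(scope="session")
def parallel_dimer():
    """Gly-in parallel dimer: crossing 0, separation 10 Å, marker phase 0."""
    return make_dimer(HelixSpec(chain="A"), HelixSpec(chain="B"),
                      crossing_angle=0.0, separation=10.0, g33_phase=0.0)


def naive_min_image(a, b, box):
    """Brute-force minimum image over the 27 neighbour cells (oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if not box.periodic:
        return float(np.linalg.norm(b - a))
    best = np.inf
    rng3 = (-3, -2, -1, 0, 1, 2, 3)
    for i in rng3:
        for j in rng3:
            for k in rng3:
                shift = (i * box.vectors[0] + j * box.vectors[1]
                         + k * box.vectors[2])
                best = min(best, float(np.linalg.norm(b - a + shift)))
    return best


def naive_rg(points):
    """Double-loop pairwise radius of gyration (oracle)."""
    pts = np.asarray(points, float)
    n = len(pts)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                acc += np.sum((pts[i] - pts[j]) ** 2)
    return np.sqrt(acc / (2 * n * n))


def naive_hbonds(topology, positions, criterion, scope):
    """Exhaustive O(n²) hydrogen-bond scan (oracle, independent loops)."""
    out = set()
    h_idx = topology.select(mol_class="protein",
                            name=criterion.donor_hydrogens)
    a_idx = topology.select(mol_class="protein", name=criterion.acceptors)
    for h in h_idx:
        d_cands = topology.select(mol_class="protein",
                                  name=criterion.donor_heavy,
                                  chain=topology.chain[h],
                                  resid=int(topology.resid[h]))
        if len(d_cands) == 0:
            continue
        d = d_cands[0]
        for a in a_idx:
            same_chain = topology.chain[h] == topology.chain[a]
            if (topology.resid[h] == topology.resid[a]) and same_chain:
                continue
            if scope == "intra" and not same_chain:
                continue
            if scope == "inter" and same_chain:
                continue
            r = np.linalg.norm(positions[a] - positions[h])
            if r > criterion.distance_cutoff:
                continue
            v1 = positions[d] - positions[h]
            v2 = positions[a] - positions[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= criterion.angle_cutoff:
                out.add((str(topology.chain[h]), int(topology.resid[h]),
                         str(topology.chain[a]), int(topology.resid[a])))
    return out
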