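"""Hydrogen-bond detection, residue-pair propensity maps, and helicity.

Two geometric criteria are built in, both taking the distance as
hydrogen-to-acceptor and the angle as donor–hydrogen–acceptor (the only
reading for which a 2.5 Å cutoff is physical):

* backbone amide NH⋯O=C: H⋯O within 2.5 Å and angle ≥ 150°;
* aliphatic CαH⋯O=C (the glycine-zipper stabilizing contact): H⋯O within
  3.5 Å and angle ≥ 120°.

Propensity maps P_ij count a (donor residue i, acceptor residue j) pair at
most once per frame regardless of how many atom pairs qualify, normalized
by the total frame count.  Fractional helicity marks residue i helical in
a frame when it participates (either role) in a backbone bond to residue
i±3, 4 or 5 on the same chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_model import Topology, Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond rule over named donor/acceptor atoms."""

    donor_heavy: tuple = ("N",)
    donor_hydrogens: tuple = ("H", "HN")
    acceptors: tuple = ("O", "OT1", "OXT")
    distance_cutoff: float = 2.5     # Å, hydrogen to acceptor
    angle_cutoff: float = 150.0      # degrees, donor-hydrogen-acceptor

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


BACKBONE_NH = HBondCriterion()
ALIPHATIC_CAH = HBondCriterion(
    donor_heavy=("CA",), donor_hydrogens=("HA", "HA1", "HA2", "HA3"),
    distance_cutoff=3.5, angle_cutoff=120.0)


@dataclass
class HBond:
    donor_chain: str
    donor_resid: int
    acceptor_chain: str
    acceptor_resid: int
    distance: float
    angle: float


def _donor_pairs(topology: Topology, criterion: HBondCriterion
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Match each donor hydrogen to its heavy atom within the same residue.

    Returns (hydrogen indices, heavy indices), aligned.
    """
    h_idx = topology.select(mol_class="protein",
                            name=criterion.donor_hydrogens)
    d_idx = topology.select(mol_class="protein", name=criterion.donor_heavy)
    if len(h_idx) == 0:
        raise ValueError(
            "no donor hydrogens found; hydrogen-bond analysis requires "
            "explicit-hydrogen input")
    heavy_of = {}
    for d in d_idx:
        heavy_of[(topology.chain[d], topology.resid[d])] = d
    hs, ds = [], []
    for h in h_idx:
        key = (topology.chain[h], topology.resid[h])
        if key in heavy_of:
            hs.append(h)
            ds.append(heavy_of[key])
    return np.array(hs, dtype=int), np.array(ds, dtype=int)


def detect_hbonds(topology: Topology, positions: np.ndarray,
                  criterion: HBondCriterion = BACKBONE_NH,
                  scope: str = "intra") -> list[HBond]:
    """All hydrogen bonds satisfying the criterion in one configuration.

    ``scope`` restricts donor/acceptor chains: "intra" (same chain),
    "inter" (different chains), or "all".  Same-residue pairs never count.
    """
    if scope not in ("intra", "inter", "all"):
        raise ValueError("scope must be 'intra', 'inter' or 'all'")
    hs, ds = _donor_pairs(topology, criterion)
    acc = topology.select(mol_class="protein", name=criterion.acceptors)
    if len(acc) == 0:
        return []
    hp, dp, ap = positions[hs], positions[ds], positions[acc]
    # (n_h, n_a) distance matrix; fixture scale keeps this dense and cheap
    dvec = ap[None, :, :] - hp[:, None, :]
    dist = np.linalg.norm(dvec, axis=2)
    near = dist <= criterion.distance_cutoff
    bonds: list[HBond] = []
    for i, j in zip(*np.nonzero(near)):
        h, d, a = hs[i], ds[i], acc[j]
        same_res = (topology.chain[h] == topology.chain[a]
                    and topology.resid[h] == topology.resid[a])
        if same_res:
            continue
        same_chain = topology.chain[h] == topology.chain[a]
        if scope == "intra" and not same_chain:
            continue
        if scope == "inter" and same_chain:
            continue
        v1 = positions[d] - positions[h]
        v2 = positions[a] - positions[h]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < 1e-12:
            continue
        ang = float(np.degrees(np.arccos(
            np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))))
        if ang >= criterion.angle_cutoff:
            bonds.append(HBond(
                donor_chain=str(topology.chain[h]),
                donor_resid=int(topology.resid[h]),
                acceptor_chain=str(topology.chain[a]),
                acceptor_resid=int(topology.resid[a]),
                distance=float(dist[i, j]), angle=ang))
    return bonds


@dataclass
class HBondMap:
    """Residue-pair bond propensity P_ij (donor i, acceptor j) in [0, 1]."""

    resids: np.ndarray
    p: np.ndarray            # (n_res, n_res)
    n_frames: int
    criterion: HBondCriterion
    scope: str = "inter"


def propensity_map(trajectory: Trajectory,
                   criterion: HBondCriterion = BACKBONE_NH,
                   scope: str = "inter") -> HBondMap:
    """P_ij = (frames in which a donor-i → acceptor-j bond exists) / frames."""
    topo = trajectory.topology
    resids = np.unique(topo.resid[topo.select(mol_class="protein")])
    index = {int(r): i for i, r in enumerate(resids)}
    counts = np.zeros((len(resids), len(resids)))
    for fr in trajectory:
        seen = set()
        for b in detect_hbonds(topo, fr.positions, criterion, scope):
            seen.add((index[b.donor_resid], index[b.acceptor_resid]))
        for i, j in seen:
            counts[i, j] += 1
    return HBondMap(resids=resids, p=counts / len(trajectory.frames),
                    n_frames=len(trajectory.frames), criterion=criterion,
                    scope=scope)


def marginal_profile(hmap: HBondMap) -> np.ndarray:
    """Per-residue participation: mean of column i plus mean of row i."""
    return hmap.p.mean(axis=0) + hmap.p.mean(axis=1)


@dataclass
class HelicityProfile:
    resids: np.ndarray
    helicity: dict[str, np.ndarray] = field(default_factory=dict)  # chain ->


def fractional_helicity(trajectory: Trajectory,
                        criterion: HBondCriterion = BACKBONE_NH,
                        offsets: tuple = (3, 4, 5)) -> HelicityProfile:
    """Per-residue fraction of frames with a backbone hydrogen bond between
    residue i and i±3, 4 or 5 on the same chain (either bonding role)."""
    topo = trajectory.topology
    prot = topo.select(mol_class="protein")
    chains = sorted({str(c) for c in topo.chain[prot]})
    resids = np.unique(topo.resid[prot])
    index = {int(r): i for i, r in enumerate(resids)}
    if len(resids) < min(offsets) + 1:
        logger.warning("chains shorter than %d residues: helicity all zero",
                       min(offsets) + 1)
        return HelicityProfile(
            resids=resids,
            helicity={c: np.zeros(len(resids)) for c in chains})
    counts = {c: np.zeros(len(resids)) for c in chains}
    for fr in trajectory:
        helical = {c: np.zeros(len(resids), dtype=bool) for c in chains}
        for b in detect_hbonds(topo, fr.positions, criterion, scope="intra"):
            if abs(b.donor_resid - b.acceptor_resid) in offsets:
                helical[b.donor_chain][index[b.donor_resid]] = True
                helical[b.acceptor_chain][index[b.acceptor_resid]] = True
        for c in chains:
            counts[c] += helical[c]
    nf = len(trajectory.frames)
    return HelicityProfile(resids=resids,
                           helicity={c: counts[c] / nf for c in chains})
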