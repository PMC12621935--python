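"""Micelle identification, classification and aggregation-number statistics.

A micelle is a single-linkage component of the contact graph on surfactant
molecules: two surfactants are linked when any inter-molecule bead pair is
within a cutoff distance under minimum-image convention (default 6 Å at
coarse-grained bead scale, 4 Å for atomistic heavy atoms).  Components
below a minimum size (default 10 monomers) are free monomers, not micelles.
Micelles are classified as dimer-encapsulating or empty by contact counting
against each protein dimer; convergence of the assembly is judged by the
ergodic measure Ω(t), the cross-replicate population variance of the
micelle count, and box adequacy by the finite-size rule requiring at least
three micelles of each class at equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io_model import Box, Frame, ReplicateSet, Topology, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_CG = 6.0        # Å, bead-bead linkage for CG systems
DEFAULT_CUTOFF_ATOMISTIC = 4.0  # Å, heavy-atom linkage for atomistic systems
DEFAULT_MIN_SIZE = 10           # monomers
DEFAULT_CONTACT_CUTOFF = 6.0    # Å, dimer-surfactant contact
DEFAULT_MIN_CONTACTS = 10       # surfactant beads in contact


@dataclass
class Micelle:
    label: int
    molecule_ids: list[int]
    mol_class: str = "empty"        # "dimer" | "empty"
    dimer_ids: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.molecule_ids)


@dataclass
class MicelleCensusFrame:
    """Census of one frame: micelle list plus free-monomer ids."""

    micelles: list[Micelle]
    free_molecule_ids: list[int]
    time: float = 0.0

    def sizes(self, mol_class: str | None = None) -> np.ndarray:
        return np.array([m.size for m in self.micelles
                         if mol_class is None or m.mol_class == mol_class])

    def count(self, mol_class: str | None = None) -> int:
        return len(self.sizes(mol_class))


@dataclass
class AggregationSeries:
    """Per-frame class-resolved micelle counts and mean aggregation numbers."""

    table: pd.DataFrame  # columns: time, n_dimer, n_empty, n_all,
    #                       mean_s_dimer, mean_s_empty, mean_s_all, total_s
    replicate: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    def equilibrium_summary(self, t_eq: float | None = None) -> pd.Series:
        """Time-averaged counts and mean sizes over t > t_eq (default: the
        second half of the series)."""
        t = self.times
        if t_eq is None:
            t_eq = t[0] + (t[-1] - t[0]) / 2.0 if len(t) > 1 else t[0] - 1.0
        sel = self.table[self.table["time"] > t_eq]
        if sel.empty:
            sel = self.table
        out = sel.drop(columns=["time"]).mean()
        out["t_eq"] = t_eq
        return out


@dataclass
class ErgodicSeries:
    times: np.ndarray
    omega: np.ndarray
    label: str = ""

    def decay_ratio(self, t_late: float) -> float:
        """Ω(0) / Ω(t_late) (mean of Ω at/after t_late), gauging convergence."""
        late = self.omega[self.times >= t_late]
        denom = float(np.mean(late)) if len(late) else np.nan
        return float(self.omega[0]) / denom if denom > 0 else np.inf


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _pairs_within(positions: np.ndarray, cutoff: float, box: Box) -> np.ndarray:
    """Index pairs (i, j) with minimum-image distance <= cutoff."""
    if box.periodic and box.is_orthorhombic:
        edges = np.diag(box.vectors)
        pos = np.mod(positions, edges)
        tree = cKDTree(pos, boxsize=edges)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs
    if not box.periodic:
        tree = cKDTree(positions)
        return tree.query_pairs(cutoff, output_type="ndarray")
    # triclinic fallback: brute force over minimum images (test-scale only)
    n = len(positions)
    ii, jj = np.triu_indices(n, k=1)
    d = box.minimum_image_displacement(positions[jj] - positions[ii])
    keep = (d ** 2).sum(axis=1) <= cutoff ** 2
    return np.column_stack([ii[keep], jj[keep]])


def cluster_surfactants(frame: Frame, topology: Topology,
                        cutoff: float = DEFAULT_CUTOFF_CG
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage components of the surfactant contact graph.

    Returns ``(molecule_ids, labels)``: the sorted surfactant molecule ids
    and one component label per molecule.  Labels are deterministic —
    components are numbered 0, 1, ... by their smallest member molecule id.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    surf_idx = topology.select(mol_class="surfactant")
    if len(surf_idx) == 0:
        raise ValueError("frame contains no surfactant particles")
    mol_of_bead = topology.molecule_id[surf_idx]
    mol_ids = np.unique(mol_of_bead)
    mol_index = {int(m): i for i, m in enumerate(mol_ids)}
    bead_mol = np.array([mol_index[int(m)] for m in mol_of_bead])

    pairs = _pairs_within(frame.positions[surf_idx], cutoff, frame.box)
    if len(pairs):
        mi, mj = bead_mol[pairs[:, 0]], bead_mol[pairs[:, 1]]
        keep = mi != mj
        mi, mj = mi[keep], mj[keep]
    else:
        mi = mj = np.array([], dtype=int)
    n = len(mol_ids)
    graph = sparse.coo_matrix((np.ones(len(mi)), (mi, mj)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    # deterministic relabeling by smallest member molecule id
    order = {}
    for c in comp[np.argsort(mol_ids)]:
        if c not in order:
            order[c] = len(order)
    labels = np.array([order[c] for c in comp])
    return mol_ids, labels


def apply_min_size(mol_ids: np.ndarray, labels: np.ndarray,
                   min_size: int = DEFAULT_MIN_SIZE,
                   time: float = 0.0) -> MicelleCensusFrame:
    """Drop components smaller than ``min_size`` (kept as free monomers)."""
    micelles: list[Micelle] = []
    free: list[int] = []
    for lab in np.unique(labels):
        members = [int(m) for m in mol_ids[labels == lab]]
        if len(members) >= min_size:
            micelles.append(Micelle(label=len(micelles),
                                    molecule_ids=members))
        else:
            free.extend(members)
    return MicelleCensusFrame(micelles=micelles, free_molecule_ids=free,
                              time=time)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def group_dimers(topology: Topology) -> list[tuple[int, ...]]:
    """Pair protein chains into dimers by ascending molecule id (A with B)."""
    prot = sorted(topology.molecules(mol_class="protein"))
    if len(prot) % 2:
        raise ValueError("odd number of protein chains; cannot pair dimers")
    return [tuple(prot[i:i + 2]) for i in range(0, len(prot), 2)]


def classify_micelles(census: MicelleCensusFrame, frame: Frame,
                      topology: Topology,
                      contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                      min_contacts: int = DEFAULT_MIN_CONTACTS
                      ) -> MicelleCensusFrame:
    """Assign each protein dimer to the micelle with the most surfactant
    beads within ``contact_cutoff`` of any dimer bead (requiring at least
    ``min_contacts``); micelles with an assigned dimer are class "dimer",
    the rest "empty".  Ties go to the smaller micelle label (logged); a
    dimer with no qualifying micelle is flagged unencapsulated (logged)."""
    for m in census.micelles:
        m.mol_class = "empty"
        m.dimer_ids = []
    surf_idx = topology.select(mol_class="surfactant")
    bead_label = np.full(len(surf_idx), -1)
    label_of_mol = {}
    for m in census.micelles:
        for mol in m.molecule_ids:
            label_of_mol[mol] = m.label
    for i, b in enumerate(surf_idx):
        bead_label[i] = label_of_mol.get(int(topology.molecule_id[b]), -1)

    box = frame.box
    if box.periodic and box.is_orthorhombic:
        edges = np.diag(box.vectors)
        tree = cKDTree(np.mod(frame.positions[surf_idx], edges),
                       boxsize=edges)
    else:
        tree = cKDTree(frame.positions[surf_idx])
        edges = None

    micelle_by_label = {m.label: m for m in census.micelles}
    for d, chains in enumerate(group_dimers(topology)):
        didx = np.flatnonzero(np.isin(topology.molecule_id, chains))
        q = frame.positions[didx]
        if edges is not None:
            q = np.mod(q, edges)
        hit_lists = tree.query_ball_point(q, contact_cutoff)
        hit_beads = sorted({h for hl in hit_lists for h in hl})
        counts: dict[int, int] = {}
        for h in hit_beads:
            lab = int(bead_label[h])
            if lab >= 0:
                counts[lab] = counts.get(lab, 0) + 1
        qualifying = {lab: c for lab, c in counts.items()
                      if c >= min_contacts}
        if not qualifying:
            logger.warning("dimer %d (chains %s) unencapsulated", d, chains)
            continue
        best = max(qualifying.values())
        winners = sorted(lab for lab, c in qualifying.items() if c == best)
        if len(winners) > 1:
            logger.warning("dimer %d contact tie between micelles %s; "
                           "assigned to %d", d, winners, winners[0])
        m = micelle_by_label[winners[0]]
        m.mol_class = "dimer"
        m.dimer_ids.append(d)
    return census


def census_frame(frame: Frame, topology: Topology,
                 cutoff: float = DEFAULT_CUTOFF_CG,
                 min_size: int = DEFAULT_MIN_SIZE,
                 contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                 min_contacts: int = DEFAULT_MIN_CONTACTS
                 ) -> MicelleCensusFrame:
    """Full census of one frame: cluster, size-filter, classify."""
    mol_ids, labels = cluster_surfactants(frame, topology, cutoff)
    census = apply_min_size(mol_ids, labels, min_size, time=frame.time)
    if len(topology.select(mol_class="protein")):
        census = classify_micelles(census, frame, topology,
                                   contact_cutoff, min_contacts)
    return census


# ---------------------------------------------------------------------------
# Aggregation statistics
# ---------------------------------------------------------------------------

def aggregation_series(trajectory: Trajectory,
                       cutoff: float = DEFAULT_CUTOFF_CG,
                       min_size: int = DEFAULT_MIN_SIZE,
                       contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       min_contacts: int = DEFAULT_MIN_CONTACTS,
                       replicate: int = 0) -> AggregationSeries:
    """Class-resolved micelle counts and mean aggregation numbers per frame."""
    rows = []
    any_micelle = False
    for fr in trajectory:
        c = census_frame(fr, trajectory.topology, cutoff, min_size,
                         contact_cutoff, min_contacts)
        s_dim, s_emp, s_all = (c.sizes("dimer"), c.sizes("empty"), c.sizes())
        any_micelle = any_micelle or len(s_all) > 0
        rows.append({
            "time": fr.time,
            "n_dimer": len(s_dim), "n_empty": len(s_emp), "n_all": len(s_all),
            "mean_s_dimer": s_dim.mean() if len(s_dim) else np.nan,
            "mean_s_empty": s_emp.mean() if len(s_emp) else np.nan,
            "mean_s_all": s_all.mean() if len(s_all) else np.nan,
            "total_s": int(s_all.sum()),
            "n_free": len(c.free_molecule_ids),
        })
    if not any_micelle:
        logger.warning("no micelles found in any frame")
    return AggregationSeries(table=pd.DataFrame(rows), replicate=replicate)


def size_histogram(censuses: list[MicelleCensusFrame],
                   mol_class: str | None = None,
                   weighting: str = "observation") -> pd.DataFrame:
    """Aggregation-number histogram over frames.

    ``weighting='observation'`` counts every micelle-frame observation;
    ``'frame'`` weights each frame equally (each frame's micelles contribute
    total weight 1).  Both are reported because a census over frames can be
    normalized either way.
    """
    sizes, weights = [], []
    for c in censuses:
        s = c.sizes(mol_class)
        if len(s) == 0:
            continue
        sizes.extend(s.tolist())
        w = 1.0 if weighting == "observation" else 1.0 / len(s)
        weights.extend([w] * len(s))
    df = pd.DataFrame({"size": sizes, "weight": weights})
    return df.groupby("size", as_index=False)["weight"].sum()


# ---------------------------------------------------------------------------
# Ergodic measure and finite-size adequacy
# ---------------------------------------------------------------------------

def ergodic_measure(replicates: ReplicateSet) -> ErgodicSeries:
    """Ω(t) = (1/M)·Σ_i [n_i(t) − N(t)]², the population variance of the
    per-replicate micelle count about the cross-replicate mean N(t)."""
    if replicates.n_replicates < 2:
        raise ValueError("ergodic measure needs at least 2 replicates")
    n = replicates.series
    mean = n.mean(axis=0)
    omega = ((n - mean) ** 2).mean(axis=0)
    return ErgodicSeries(times=replicates.times.copy(), omega=omega,
                         label=replicates.label)


@dataclass
class FiniteSizeReport:
    passed: bool
    mean_n_dimer: float
    mean_n_empty: float
    t_eq: float
    reasons: list[str]

    def to_dict(self) -> dict:
        return {"passed": bool(self.passed),
                "mean_n_dimer": float(self.mean_n_dimer),
                "mean_n_empty": float(self.mean_n_empty),
                "t_eq": float(self.t_eq),
                "reasons": list(self.reasons)}


def finite_size_check(series: AggregationSeries,
                      t_eq: float | None = None,
                      min_micelles: int = 3) -> FiniteSizeReport:
    """Box-adequacy rule: the equilibrated time-averaged counts of both
    empty and dimer micelles must reach ``min_micelles`` (boundary
    inclusive), otherwise the box is too small for an unbiased census."""
    summ = series.equilibrium_summary(t_eq)
    nd, ne = float(summ["n_dimer"]), float(summ["n_empty"])
    reasons = []
    if nd < min_micelles:
        reasons.append(f"dimer micelles < {min_micelles}")
    if ne < min_micelles:
        reasons.append(f"empty micelles < {min_micelles}")
    return FiniteSizeReport(passed=not reasons, mean_n_dimer=nd,
                            mean_n_empty=ne, t_eq=float(summ["t_eq"]),
                            reasons=reasons)
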