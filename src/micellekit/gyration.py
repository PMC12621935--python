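"""Radius of gyration in mass-weighted and equal-mass pairwise forms, with
per-class micelle statistics and coarse-grained-to-atomistic size matching.

Two algebraically related operators are provided.  The mass-weighted form
is the root of the mass-weighted mean squared distance to the mass-weighted
centroid,

    Rg² = Σ m_i |r_i − r_com|² / Σ m_i .

For equal masses this is identical to the pairwise form, which needs no
centroid at all,

    Rg² = (1/2N²) Σ_{i≠j} d_ij² ,

convenient for bead models where every bead carries the same mass.  Both
act on any point set; callers choose beads or monomer centres of mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Topology, Trajectory, unwrap_group
from .micelle_census import MicelleCensusFrame

logger = logging.getLogger(__name__)


def rg_mass_weighted(coordinates: np.ndarray,
                     masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of an (unwrapped) point set in Å."""
    pos = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(pos) == 0:
        raise ValueError("radius of gyration of an empty point set")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses, float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = (m[:, None] * pos).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_pairwise(coordinates: np.ndarray) -> float:
    """Equal-mass radius of gyration from pairwise distances alone."""
    pos = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    n = len(pos)
    if n < 2:
        raise ValueError("pairwise radius of gyration needs >= 2 points")
    # sum_{i!=j} d_ij^2 = 2N sum|r|^2 - 2|sum r|^2 (expanded form, O(N))
    sq = (pos ** 2).sum()
    tot = pos.sum(axis=0)
    ssq = 2.0 * n * sq - 2.0 * (tot ** 2).sum()
    return float(np.sqrt(ssq / (2.0 * n * n)))


@dataclass
class GyrationResult:
    """Per-micelle Rg series plus per-class ensemble statistics."""

    table: pd.DataFrame   # columns: time, micelle, mol_class, size, rg
    include_protein: bool
    formula: str          # "pairwise" | "mass-weighted"

    def class_summary(self, t_eq: float | None = None) -> pd.DataFrame:
        """Mean and SD of Rg per micelle class over the equilibrated window
        (default: second half of the time span)."""
        t = self.table["time"]
        if t_eq is None:
            t_eq = (t.min() + (t.max() - t.min()) / 2.0
                    if t.nunique() > 1 else t.min() - 1.0)
        sel = self.table[self.table["time"] > t_eq]
        if sel.empty:
            sel = self.table
        grp = sel.groupby("mol_class")["rg"]
        out = grp.agg(mean_rg="mean", sd_rg="std", n="count").reset_index()
        out["sd_rg"] = out["sd_rg"].fillna(0.0)
        out["t_eq"] = t_eq
        return out


def micelle_rg_series(trajectory: Trajectory,
                      censuses: list[MicelleCensusFrame],
                      include_protein: bool = False,
                      formula: str = "pairwise") -> GyrationResult:
    """Rg of every micelle in every frame.

    Coordinates are made whole across periodic boundaries before the
    computation.  ``formula='pairwise'`` treats every bead as equal mass
    (the coarse-grained convention); ``'mass-weighted'`` uses topology
    masses.  An Rg exceeding half the shortest box extent triggers a
    wrap-suspicion warning.
    """
    topo = trajectory.topology
    if len(censuses) != len(trajectory.frames):
        raise ValueError("need one census per frame")
    mol_atoms = topo.molecules()
    rows = []
    for fr, census in zip(trajectory, censuses):
        for m in census.micelles:
            idx = np.concatenate([mol_atoms[mid] for mid in m.molecule_ids])
            if include_protein and m.dimer_ids:
                dimers = _dimer_chain_ids(topo)
                for d in m.dimer_ids:
                    idx = np.concatenate(
                        [idx] + [mol_atoms[c] for c in dimers[d]])
            if len(idx) < 2:
                logger.warning("micelle %d has <2 particles; skipped", m.label)
                continue
            pos = unwrap_group(fr.positions[idx], fr.box,
                               warn_label=f"micelle {m.label}")
            if formula == "pairwise":
                rg = rg_pairwise(pos)
            else:
                rg = rg_mass_weighted(pos, topo.mass[idx])
            if fr.box.periodic and rg > fr.box.shortest_extent / 2.0:
                warnings.warn(
                    f"micelle {m.label} Rg {rg:.1f} Å exceeds half-box; "
                    "coordinates may not be whole", stacklevel=2)
            rows.append({"time": fr.time, "micelle": m.label,
                         "mol_class": m.mol_class, "size": m.size, "rg": rg})
    return GyrationResult(table=pd.DataFrame(
        rows, columns=["time", "micelle", "mol_class", "size", "rg"]),
        include_protein=include_protein, formula=formula)


def _dimer_chain_ids(topology: Topology) -> list[tuple[int, ...]]:
    from .micelle_census import group_dimers
    return group_dimers(topology)


@dataclass
class RgMatchResult:
    target_rg: float
    candidates: dict[int, float]    # aggregation number -> measured Rg, Å
    selected: int
    deviation: float                # |Rg(selected) − target|, Å

    def to_dict(self) -> dict:
        return {"target_rg": self.target_rg,
                "candidates": {str(k): v for k, v in self.candidates.items()},
                "selected": self.selected, "deviation": self.deviation}


def rg_matched_aggregation(target_rg: float,
                           candidates: dict[int, float]) -> RgMatchResult:
    """Pick the candidate aggregation number whose measured Rg best
    reproduces the coarse-grained target; ties go to the smaller size."""
    if not candidates:
        raise ValueError("empty candidate table")
    best = None
    for s in sorted(candidates):
        dev = abs(candidates[s] - target_rg)
        if best is None or dev < best[1] - 1e-12:
            best = (s, dev)
        elif abs(dev - best[1]) <= 1e-12:
            logger.warning("Rg-match tie between s=%d and s=%d; keeping the "
                           "smaller", best[0], s)
    return RgMatchResult(target_rg=float(target_rg),
                         candidates=dict(candidates),
                         selected=int(best[0]), deviation=float(best[1]))


def aggregation_rg_ratio(mean_s: float, mean_rg: float,
                         decimals: int = 1) -> float:
    """s*/Rg, the aggregation number per ångström of micelle radius of
    gyration (≈3.2 for dimer-encapsulating, ≈2.6 for empty micelles in the
    reference coarse-grained systems); 0 when s* = 0."""
    if mean_rg <= 0:
        raise ValueError("mean Rg must be positive")
    return round(float(mean_s) / float(mean_rg), decimals)
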