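"""Structural order parameters of a two-helix transmembrane dimer.

Quantities computed per configuration:

* residue-pair centre-of-mass distance matrix, symmetrized across the two
  chains so entry (i, j) averages d(i on A, j on B) with d(j on A, i on B);
* the K28–K28 and K54–K54 lysine anchor distances;
* the Crick angle ψ of the marker glycine (residue 33): the angle between
  the inter-helix centre-of-mass connection and the axis-to-marker radial
  vector, both projected normal to the helix axis — 0° is Gly-in (marker
  buried at the interface), 180° Gly-out;
* the four-point twist dihedral φ over the Cα atoms (G29A, G37A, G37B,
  G29B); negative φ is a right-handed coiled-coil.

All functions take a topology plus one frame's (unwrapped) coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import Topology

logger = logging.getLogger(__name__)

#: default transmembrane residue window for the helix-axis fit
DEFAULT_AXIS_WINDOW = (30, 52)
#: backbone reference atom: Cα atomistically, BB bead for coarse-grained
BACKBONE_NAMES = ("CA", "BB")


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, zero-length projection)."""


def _backbone_indices(topology: Topology, chain: str,
                      resids=None) -> np.ndarray:
    idx = topology.select(mol_class="protein", chain=chain,
                          name=BACKBONE_NAMES)
    if resids is not None:
        idx = idx[np.isin(topology.resid[idx], list(resids))]
    return idx


def residue_com(topology: Topology, positions: np.ndarray, chain: str,
                resid: int) -> np.ndarray:
    """Mass-weighted centre of mass of one residue on one chain."""
    idx = topology.select(mol_class="protein", chain=chain, resid=resid)
    if len(idx) == 0:
        raise GeometryError(f"residue {resid} missing on chain {chain}")
    m = topology.mass[idx]
    return (m[:, None] * positions[idx]).sum(axis=0) / m.sum()


def residue_distance_matrix(topology: Topology, positions: np.ndarray,
                            chain_a: str = "A", chain_b: str = "B"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Inter-chain residue-pair COM distances, chain-symmetrized.

    Returns ``(resids, matrix)`` where ``matrix[i, j]`` is the mean of
    d(res_i on A, res_j on B) and d(res_j on A, res_i on B).  A residue
    missing on either chain masks its row/column with NaN (warned).
    """
    resids = np.unique(topology.resid[topology.select(mol_class="protein")])
    coms = {}
    for ch in (chain_a, chain_b):
        for r in resids:
            try:
                coms[(ch, r)] = residue_com(topology, positions, ch, int(r))
            except GeometryError:
                warnings.warn(f"residue {r} missing on chain {ch}; masked",
                              stacklevel=2)
                coms[(ch, r)] = None
    n = len(resids)
    mat = np.full((n, n), np.nan)
    for i, ri in enumerate(resids):
        for j, rj in enumerate(resids):
            a1, b1 = coms[(chain_a, ri)], coms[(chain_b, rj)]
            a2, b2 = coms[(chain_a, rj)], coms[(chain_b, ri)]
            if any(x is None for x in (a1, b1, a2, b2)):
                continue
            mat[i, j] = 0.5 * (np.linalg.norm(a1 - b1)
                               + np.linalg.norm(a2 - b2))
    return resids, mat


def lysine_pair_distances(topology: Topology, positions: np.ndarray,
                          resid_n: int = 28, resid_c: int = 54,
                          chain_a: str = "A", chain_b: str = "B"
                          ) -> tuple[float, float]:
    """COM distances between like anchor residues across chains
    (K28A–K28B, K54A–K54B by default)."""
    out = []
    for r in (resid_n, resid_c):
        a = residue_com(topology, positions, chain_a, r)
        b = residue_com(topology, positions, chain_b, r)
        out.append(float(np.linalg.norm(a - b)))
    return out[0], out[1]


def helix_axis(ca_coordinates: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis from a Cα window: direction and a point on the axis.

    The direction is the first principal component of the window, oriented
    N→C.  The axis point is refined beyond the raw centroid by a
    least-squares circle fit in the plane normal to the axis: the centroid
    of a helical arc spanning a non-integer number of turns is biased
    off-axis by up to the Cα radius, whereas the fitted circle centre is
    unbiased.  Fewer than 4 points, or a degenerate point cloud, raises
    ``GeometryError``.
    """
    from scipy.optimize import least_squares

    pos = np.asarray(ca_coordinates, dtype=float).reshape(-1, 3)
    if len(pos) < 4:
        raise GeometryError("helix axis fit needs >= 4 backbone points")
    centroid = pos.mean(axis=0)
    rel = pos - centroid
    u, s, vt = np.linalg.svd(rel)
    if s[0] <= 0 or (len(s) > 1 and s[1] / s[0] > 0.999):
        raise GeometryError("degenerate point cloud; no principal axis")
    e0, e1, e2 = vt

    def circle_residuals(xy):
        # Kåsa algebraic circle fit, then radial residuals
        a = np.column_stack([2 * xy, np.ones(len(xy))])
        b = (xy ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        cx, cy = sol[0], sol[1]
        r = np.sqrt(max(sol[2] + cx ** 2 + cy ** 2, 0.0))
        return np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - r, (cx, cy)

    def residuals(ab):
        ax = e0 + ab[0] * e1 + ab[1] * e2
        ax = ax / np.linalg.norm(ax)
        p1 = rel - np.outer(rel @ ax, ax)
        basis1 = np.cross(ax, e1 if abs(ax @ e1) < 0.9 else e2)
        basis1 /= np.linalg.norm(basis1)
        basis2 = np.cross(ax, basis1)
        xy = np.column_stack([p1 @ basis1, p1 @ basis2])
        res, _ = circle_residuals(xy)
        return res

    fit = least_squares(residuals, x0=[0.0, 0.0], method="lm")
    axis = e0 + fit.x[0] * e1 + fit.x[1] * e2
    axis = axis / np.linalg.norm(axis)
    if np.dot(pos[-1] - pos[0], axis) < 0:
        axis = -axis
    # axis point from the circle fit in the optimal normal plane
    b1 = np.cross(axis, e1 if abs(axis @ e1) < 0.9 else e2)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    proj = rel - np.outer(rel @ axis, axis)
    _, (cx, cy) = circle_residuals(
        np.column_stack([proj @ b1, proj @ b2]))
    centre = centroid + cx * b1 + cy * b2
    return axis, centre


def crick_angle(topology: Topology, positions: np.ndarray, chain: str,
                partner_chain: str | None = None,
                marker_resid: int = 33,
                axis_window: tuple[int, int] = DEFAULT_AXIS_WINDOW) -> float:
    """Crick angle ψ of the marker residue on one chain, degrees in [0, 180].

    The marker direction is the axis-to-Cα radial vector of the marker
    residue (the natural choice for glycine, which has no side chain); the
    reference is the vector connecting the two helix centres — taken as the
    fitted axis centres of the two axis windows, which for a helical arc is
    the unbiased reading of the helix centre of mass — both projected
    normal to this chain's axis.
    """
    if partner_chain is None:
        partner_chain = "B" if chain == "A" else "A"
    window = range(axis_window[0], axis_window[1] + 1)
    self_idx = _backbone_indices(topology, chain, window)
    partner_idx = _backbone_indices(topology, partner_chain, window)
    axis, point = helix_axis(positions[self_idx])
    com_self = point
    _, com_partner = helix_axis(positions[partner_idx])

    def perp(v):
        return v - np.dot(v, axis) * axis

    conn = perp(com_partner - com_self)
    marker_idx = _backbone_indices(topology, chain, [marker_resid])
    if len(marker_idx) == 0:
        raise GeometryError(f"marker residue {marker_resid} missing on "
                            f"chain {chain}")
    marker = positions[marker_idx].mean(axis=0)
    radial = perp(marker - (point + np.dot(marker - point, axis) * axis))
    nc, nr = np.linalg.norm(conn), np.linalg.norm(radial)
    if nc < 1e-9 or nr < 1e-9:
        raise GeometryError("marker or connection vector parallel to the "
                            "helix axis; Crick angle undefined")
    cosang = np.clip(np.dot(conn, radial) / (nc * nr), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p0, p1, p2, p3) -> float:
    """Four-point dihedral in degrees, (−180, 180]; 0 is cis and the sign is
    clockwise-positive viewed along the central bond (IUPAC)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("central bond has zero length")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise GeometryError("collinear points; dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def dimer_dihedral(topology: Topology, positions: np.ndarray,
                   resid_inner: int = 37, resid_outer: int = 29,
                   chain_a: str = "A", chain_b: str = "B") -> float:
    """Twist dihedral φ over backbone atoms (29A, 37A, 37B, 29B); negative φ
    is a right-handed coiled-coil."""
    pts = []
    for ch, r in ((chain_a, resid_outer), (chain_a, resid_inner),
                  (chain_b, resid_inner), (chain_b, resid_outer)):
        idx = _backbone_indices(topology, ch, [r])
        if len(idx) == 0:
            raise GeometryError(f"backbone atom of residue {r} chain {ch} "
                                "missing")
        pts.append(positions[idx].mean(axis=0))
    return dihedral(*pts)


def marker_pair_distance(topology: Topology, positions: np.ndarray,
                         marker_resid: int = 33, chain_a: str = "A",
                         chain_b: str = "B") -> float:
    """Backbone-atom distance between the marker residues across chains."""
    a = _backbone_indices(topology, chain_a, [marker_resid])
    b = _backbone_indices(topology, chain_b, [marker_resid])
    if len(a) == 0 or len(b) == 0:
        raise GeometryError(f"marker residue {marker_resid} missing")
    return float(np.linalg.norm(positions[a].mean(axis=0)
                                - positions[b].mean(axis=0)))


@dataclass
class Histogram2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray   # integrates to 1 over the grid

    def integral(self) -> float:
        dx = np.diff(self.x_edges)
        dy = np.diff(self.y_edges)
        return float((self.density * np.outer(dx, dy)).sum())


def histogram2d(x, y, bins: int | tuple = 50,
                ranges=None) -> Histogram2D:
    """Density-normalized 2D histogram of two order-parameter series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(x) != len(y):
        raise ValueError("need equal-length, non-empty series")
    h, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges, density=True)
    return Histogram2D(x_edges=xe, y_edges=ye, density=h)


@dataclass
class DimerGeometryFrame:
    """All order parameters of one configuration."""

    resids: np.ndarray
    distance_matrix: np.ndarray
    d_k28: float
    d_k54: float
    psi_a: float
    psi_b: float
    phi: float
    d_marker: float
    time: float = 0.0


def analyze_dimer_frame(topology: Topology, positions: np.ndarray,
                        time: float = 0.0,
                        axis_window: tuple[int, int] = DEFAULT_AXIS_WINDOW,
                        ) -> DimerGeometryFrame:
    """Compute the full order-parameter set for one configuration."""
    resids, mat = residue_distance_matrix(topology, positions)
    d28, d54 = lysine_pair_distances(topology, positions)
    return DimerGeometryFrame(
        resids=resids, distance_matrix=mat, d_k28=d28, d_k54=d54,
        psi_a=crick_angle(topology, positions, "A", axis_window=axis_window),
        psi_b=crick_angle(topology, positions, "B", axis_window=axis_window),
        phi=dimer_dihedral(topology, positions),
        d_marker=marker_pair_distance(topology, positions),
        time=time)
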