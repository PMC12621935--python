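"""Synthetic configurations and time series with known ground truth.

These generators emulate the systems the analysis stack is built for —
coarse-grained boxes of surfactants assembled into micelles (with and
without an embedded two-helix transmembrane dimer, plus free monomers and
uniform solvent), replicate micelle-count series relaxing to equilibrium,
and ideal α-helix dimers with controllable crossing angle, separation and
glycine-face orientation — without running any molecular dynamics.  They
carry no energetics; their value is that every structural ground truth
(cluster membership, aggregation number, shell radius, hydrogen-bond
pattern, crossing handedness) is known by construction.

All generators are deterministic given (spec, seed); per-replicate and
per-molecule random streams are derived from the master seed by spawn keys,
so adding a replicate never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_model import Box, Frame, ReplicateSet, Topology

#: C99 residues 16-55 (transmembrane + juxtamembrane span), one-letter.
C99_SEQUENCE_16_55 = "KLVFFAEDVGSNKGAIIGLMVGGVVIATVIVITLVMLKKK"
C99_FIRST_RESID = 16

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


class PlacementError(RuntimeError):
    """Requested contents cannot be packed into the box."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicelleSpec:
    """One spherical micelle: ``s`` surfactants with head beads on a shell."""

    s: int                          # aggregation number
    r_head: float = 16.0            # head-shell radius, Å
    beads_per_surfactant: int = 12
    jitter: float = 0.0             # Gaussian sd added to every bead, Å
    center: tuple = (0.0, 0.0, 0.0)
    with_dimer: bool = False

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("aggregation number s must be >= 1")
        if self.r_head <= 0:
            raise ValueError("r_head must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass(frozen=True)
class HelixSpec:
    """Ideal α-helix: full backbone (N, H, Cα, HA, C, O) per residue."""

    n_residues: int = 40
    rise: float = 1.5               # Å per residue
    twist: float = 100.0            # degrees per residue
    radius: float = 2.3             # Cα helix radius, Å
    sequence: str = C99_SEQUENCE_16_55
    first_resid: int = C99_FIRST_RESID
    chain: str = "A"
    include_hydrogens: bool = True

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues for a helix")


@dataclass(frozen=True)
class AssemblyKineticsSpec:
    """Replicate micelle-count series relaxing exponentially to equilibrium.

    Each replicate starts from its own initial count N0 + U{−spread..+spread}
    (random initial configurations assemble different numbers of early
    aggregates) and relaxes toward the shared equilibrium count, so the
    cross-replicate variance decays from roughly the initial-count variance
    to the floor set by the frame-to-frame integer noise.
    """

    n_replicates: int = 9
    n0: int = 20                    # initial micelle count
    n_eq: int = 9                   # equilibrium micelle count
    tau: float = 500.0              # relaxation time, ns
    noise: int = 1                  # symmetric integer noise on {-a..+a}
    n0_spread: int = 5              # per-replicate initial-count spread
    times: tuple = tuple(np.arange(0.0, 4000.0 + 1, 10.0))
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")
        if self.n0 < 0 or self.n_eq < 0:
            raise ValueError("micelle counts must be non-negative")


# ---------------------------------------------------------------------------
# Micelles
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral lattice)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_micelle(spec: MicelleSpec, seed: int = 0, mol_id_start: int = 0,
                 r_core: float = 2.0) -> tuple[Topology, np.ndarray]:
    """Build one micelle: heads quasi-uniform on the r_head sphere, tail
    beads on inward radial segments reaching down to ``r_core``."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nb = spec.beads_per_surfactant
    units = fibonacci_sphere(spec.s)
    if nb > 1:
        radii = np.linspace(spec.r_head, min(r_core, spec.r_head), nb)
    else:
        radii = np.array([spec.r_head])
    pos = (units[:, None, :] * radii[None, :, None]).reshape(-1, 3)
    if spec.jitter > 0:
        pos = pos + rng.normal(0.0, spec.jitter, size=pos.shape)
    pos = pos + np.asarray(spec.center, dtype=float)

    names = ["NC3"] + [f"C{k}" for k in range(1, nb)]
    n = spec.s * nb
    topology = Topology(
        molecule_id=np.repeat(np.arange(spec.s) + mol_id_start, nb),
        mol_class=np.array(["surfactant"] * n, dtype=object),
        chain=np.array([""] * n, dtype=object),
        resname=np.array(["DPC"] * n, dtype=object),
        resid=np.repeat(np.arange(spec.s) + 1, nb),
        name=np.array(names * spec.s, dtype=object),
        mass=np.ones(n),
    )
    return topology, pos


# ---------------------------------------------------------------------------
# Ideal helices and dimers
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle, dihedral):
    """Natural-extension-reference-frame placement of the next atom."""
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(angle),
                         np.sin(angle) * np.cos(dihedral),
                         np.sin(angle) * np.sin(dihedral)])
    return c + d[0] * bc + d[1] * m + d[2] * n


@lru_cache(maxsize=1)
def _backbone_template() -> dict[str, np.ndarray]:
    """Per-residue backbone atom offsets relative to Cα in the local helix
    frame (radial, tangential, axial).

    Derived once from a canonical α-helix built by internal coordinates
    (φ = −57.8°, ψ = −47.0°, ω = 180°, standard bond lengths and angles),
    with the carbonyl O anti to the next amide N and the amide H on the
    N–Cα/N–C bisector at 1.01 Å.  Re-laying these offsets onto any
    (rise, twist, radius) helix reproduces i→i+4 N–H⋯O geometry within the
    backbone hydrogen-bond criterion at the canonical parameters.
    """
    phi, psi, omega = -57.8, -47.0, 180.0
    b_nca, b_cac, b_cn = 1.458, 1.525, 1.329
    a_ncac, a_cacn, a_cnca = 111.2, 116.2, 121.7
    nres = 24
    N = [np.array([0.0, 0.0, 0.0])]
    ang = np.deg2rad(a_ncac)
    CA = [np.array([b_nca, 0.0, 0.0])]
    C = [CA[0] + b_cac * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for _ in range(1, nres):
        N.append(_nerf(N[-1], CA[-1], C[-1], b_cn, a_cacn, psi))
        CA.append(_nerf(CA[-1], C[-1], N[-1], b_nca, a_cnca, omega))
        C.append(_nerf(C[-1], N[-1], CA[-1], b_cac, a_ncac, phi))
    O = [_nerf(N[i], CA[i], C[i], 1.231, 120.8, psi + 180.0)
         for i in range(nres)]
    H = []
    for i in range(1, nres):
        u1 = C[i - 1] - N[i]
        u2 = CA[i] - N[i]
        h = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
        H.append(N[i] + 1.01 * h / np.linalg.norm(h))
    # alpha hydrogens: the two tetrahedral directions left after N and C
    HA1, HA2 = [], []
    half = np.deg2rad(54.25)
    for i in range(nres):
        a = N[i] - CA[i]
        b = C[i] - CA[i]
        a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
        p = (a + b) / np.linalg.norm(a + b)
        q = np.cross(a, b)
        q = q / np.linalg.norm(q)
        d1 = -p * np.cos(half) + q * np.sin(half)
        d2 = -p * np.cos(half) - q * np.sin(half)
        HA1.append(CA[i] + 1.09 * d1)
        HA2.append(CA[i] + 1.09 * d2)

    ca = np.array(CA)
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    ax = vt[0]
    if np.dot(ca[-1] - ca[0], ax) < 0:
        ax = -ax
    proj = centred - np.outer(centred @ ax, ax)
    atoms = {"N": N, "H": [None] + H, "C": C, "O": O, "HA1": HA1, "HA2": HA2}
    offsets = {k: [] for k in atoms}
    for i in range(4, nres - 4):
        er = proj[i] / np.linalg.norm(proj[i])
        et = np.cross(ax, er)
        for k, arr in atoms.items():
            d = arr[i] - ca[i]
            offsets[k].append([d @ er, d @ et, d @ ax])
    return {k: np.mean(v, axis=0) for k, v in offsets.items()}


def make_helix(spec: HelixSpec) -> tuple[Topology, np.ndarray]:
    """Ideal helix along +z through the origin (axis at x = y = 0, residue 0
    Cα at z = 0).  Use :func:`make_dimer` for oriented, paired helices."""
    tmpl = _backbone_template()
    seq = (spec.sequence * ((spec.n_residues // len(spec.sequence)) + 1)
           )[: spec.n_residues]
    names_out, res_out, resid_out, pos_out = [], [], [], []
    for i, letter in enumerate(seq):
        theta = np.deg2rad(i * spec.twist)
        er = np.array([np.cos(theta), np.sin(theta), 0.0])
        ez = np.array([0.0, 0.0, 1.0])
        et = np.cross(ez, er)
        ca = spec.radius * er + np.array([0.0, 0.0, i * spec.rise])

        def put(name, offset=None, coord=None):
            names_out.append(name)
            res_out.append(_THREE[letter])
            resid_out.append(spec.first_resid + i)
            if coord is None:
                o = tmpl[offset]
                coord = ca + o[0] * er + o[1] * et + o[2] * ez
            pos_out.append(coord)

        put("N", "N")
        if spec.include_hydrogens and i > 0:
            put("H", "H")
        put("CA", coord=ca)
        if spec.include_hydrogens:
            if letter == "G":
                put("HA1", "HA1")
                put("HA2", "HA2")
            else:
                put("HA", "HA1")
        put("C", "C")
        put("O", "O")

    n = len(names_out)
    topology = Topology(
        molecule_id=np.zeros(n, dtype=int),
        mol_class=np.array(["protein"] * n, dtype=object),
        chain=np.array([spec.chain] * n, dtype=object),
        resname=np.array(res_out, dtype=object),
        resid=np.array(resid_out, dtype=int),
        name=np.array(names_out, dtype=object),
        mass=np.ones(n),
    )
    return topology, np.array(pos_out)


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(
        np.deg2rad(angle_deg) * axis / np.linalg.norm(axis)).as_matrix()


def make_dimer(spec_a: HelixSpec, spec_b: HelixSpec,
               crossing_angle: float = 0.0,
               separation: float = 10.0,
               g33_phase: float = 0.0,
               marker_resid: int = 33) -> tuple[Topology, np.ndarray]:
    """Two ideal helices crossing at a stated angle and closest approach.

    Helix A sits at x = −separation/2, B at +separation/2, both nominally
    along z and tilted by ±crossing_angle/2 about the connection (x) axis.
    A negative crossing angle yields a right-handed pairing (negative
    four-point twist dihedral).  ``g33_phase`` rolls each helix about its own
    axis so that the marker residue's Cα radial direction makes that angle
    with the direction toward the partner: 0° is marker-in (glycine face
    buried at the interface), 180° marker-out.
    """
    if abs(crossing_angle) >= 90:
        raise ValueError("|crossing angle| must be < 90 degrees")
    if separation <= 0:
        raise ValueError("separation must be positive")
    spec_b = spec_b if spec_b.chain != spec_a.chain else HelixSpec(
        **{**spec_b.__dict__, "chain": "B"})

    parts = []
    for spec, side in ((spec_a, -1.0), (spec_b, +1.0)):
        topo, pos = make_helix(spec)
        # centre the axis span at the origin
        pos = pos - np.array([0.0, 0.0, (spec.n_residues - 1) * spec.rise / 2])
        # roll: marker residue Cα radial angle -> g33_phase from partner dir
        i_marker = marker_resid - spec.first_resid
        theta_marker = i_marker * spec.twist
        # partner direction is +x for A (side -1), -x for B (side +1)
        target = g33_phase if side < 0 else 180.0 - g33_phase
        pos = pos @ _rotation([0, 0, 1], target - theta_marker).T
        # tilt about the connection axis: A by -angle/2, B by +angle/2
        pos = pos @ _rotation([1, 0, 0], side * crossing_angle / 2.0).T
        pos = pos + np.array([side * separation / 2.0, 0.0, 0.0])
        parts.append((topo, pos))

    topo = parts[0][0].concat(parts[1][0])
    return topo, np.vstack([parts[0][1], parts[1][1]])


def make_cg_dimer(n_residues: int = 40, separation: float = 10.0,
                  first_resid: int = C99_FIRST_RESID,
                  sequence: str = C99_SEQUENCE_16_55
                  ) -> tuple[Topology, np.ndarray]:
    """Bead-resolution dimer (one backbone bead per residue) for the
    coarse-grained assembly boxes: two parallel helical traces along z."""
    parts = []
    for chain, x0 in (("A", -separation / 2), ("B", +separation / 2)):
        seq = (sequence * ((n_residues // len(sequence)) + 1))[:n_residues]
        i = np.arange(n_residues)
        theta = np.deg2rad(i * 100.0)
        pos = np.column_stack([
            x0 + 2.3 * np.cos(theta),
            2.3 * np.sin(theta),
            (i - (n_residues - 1) / 2) * 1.5,
        ])
        topo = Topology(
            molecule_id=np.zeros(n_residues, dtype=int),
            mol_class=np.array(["protein"] * n_residues, dtype=object),
            chain=np.array([chain] * n_residues, dtype=object),
            resname=np.array([_THREE[c] for c in seq], dtype=object),
            resid=i + first_resid,
            name=np.array(["BB"] * n_residues, dtype=object),
            mass=np.ones(n_residues),
        )
        parts.append((topo, pos))
    return parts[0][0].concat(parts[1][0]), np.vstack([p[1] for p in parts])


# ---------------------------------------------------------------------------
# Assembly boxes
# ---------------------------------------------------------------------------

def _empty_topology() -> Topology:
    z = np.array([], dtype=int)
    s = np.array([], dtype=object)
    return Topology(molecule_id=z, mol_class=s, chain=s, resname=s,
                    resid=z, name=s, mass=np.array([]))


def _free_monomer(nb: int = 12, bond: float = 1.3) -> np.ndarray:
    """A single extended surfactant at the origin along +z."""
    return np.column_stack([np.zeros(nb), np.zeros(nb),
                            np.arange(nb) * bond])


def make_assembly_box(dimer_micelles: list[MicelleSpec],
                      empty_micelles: list[MicelleSpec],
                      n_free: int = 0,
                      n_water: int = 0,
                      box_edge: float | None = None,
                      seed: int = 0,
                      clearance: float = 12.0,
                      max_tries: int = 2000
                      ) -> tuple[Topology, Frame, dict]:
    """Assemble a periodic cubic box of micelles, free monomers and solvent.

    Micelle centres go on a shuffled cubic grid with spacing
    ``2·max(r_head) + clearance``; free monomers and waters are placed
    uniformly, monomers rejected until farther than ``clearance`` from every
    micelle surface and from each other.  Returns the topology, the frame,
    and a ground-truth dict with per-micelle member molecule ids and classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    specs = ([(sp, True) for sp in dimer_micelles]
             + [(sp, False) for sp in empty_micelles])
    n_micelles = len(specs)
    max_r = max([sp.r_head for sp, _ in specs], default=10.0)
    spacing = 2.0 * max_r + clearance
    if box_edge is None:
        per_side = int(np.ceil(n_micelles ** (1.0 / 3.0))) if n_micelles else 1
        box_edge = max(per_side * spacing, 40.0)
    per_side = int(box_edge // spacing)
    if n_micelles and per_side ** 3 < n_micelles:
        raise PlacementError(
            f"{n_micelles} micelles need more than {per_side ** 3} grid "
            f"sites at spacing {spacing:.1f} Å in a {box_edge:.1f} Å box")
    box = Box.cubic(box_edge)

    # micelle centres: shuffled grid
    cells = np.array([(i, j, k) for i in range(per_side)
                      for j in range(per_side) for k in range(per_side)],
                     dtype=float) if n_micelles else np.zeros((0, 3))
    if n_micelles:
        rng.shuffle(cells)
    centres = (cells[:n_micelles] + 0.5) * spacing

    topo = _empty_topology()
    positions = []
    ground_truth = {"micelles": [], "free_molecule_ids": [], "box_edge": box_edge}
    next_mol = 0
    for m, ((sp, with_dimer), centre) in enumerate(zip(specs, centres)):
        sp_c = MicelleSpec(s=sp.s, r_head=sp.r_head,
                           beads_per_surfactant=sp.beads_per_surfactant,
                           jitter=sp.jitter, center=tuple(centre),
                           with_dimer=with_dimer)
        mt, mp = make_micelle(sp_c, seed=seed * 1000 + m,
                              mol_id_start=0)
        surf_ids = list(range(next_mol, next_mol + sp.s))
        entry = {"surfactant_molecule_ids": surf_ids,
                 "class": "dimer" if with_dimer else "empty",
                 "size": sp.s, "center": [float(c) for c in centre]}
        topo = topo.concat(mt) if topo.n_atoms else mt
        positions.append(mp)
        next_mol += sp.s
        if with_dimer:
            dt, dp = make_cg_dimer()
            entry["protein_molecule_ids"] = [next_mol, next_mol + 1]
            topo = topo.concat(dt)
            positions.append(dp + centre)
            next_mol += 2
        ground_truth["micelles"].append(entry)

    # free monomers: uniform with clearance from micelles and each other
    mono_centres: list[np.ndarray] = []
    for k in range(n_free):
        for _ in range(max_tries):
            cand = rng.uniform(0, box_edge, size=3)
            # monomer half-extent is ~8 Å; keep beads well clear of the
            # micelle shells and of other monomers
            ok = all(np.linalg.norm(
                box.minimum_image_displacement(cand - c))
                > sp.r_head + clearance + 8.0
                for (sp, _), c in zip(specs, centres))
            ok = ok and all(np.linalg.norm(
                box.minimum_image_displacement(cand - c)) > clearance + 16.0
                for c in mono_centres)
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place free monomer {k} after {max_tries} tries")
        mono_centres.append(cand)
        nb = 12
        mono = _free_monomer(nb)
        mono = mono - mono.mean(axis=0) + cand
        n = nb
        # fragment ids are 0-based; concat shifts them to the global range
        mt = Topology(
            molecule_id=np.zeros(n, dtype=int),
            mol_class=np.array(["surfactant"] * n, dtype=object),
            chain=np.array([""] * n, dtype=object),
            resname=np.array(["DPC"] * n, dtype=object),
            resid=np.ones(n, dtype=int),
            name=np.array(["NC3"] + [f"C{j}" for j in range(1, nb)],
                          dtype=object),
            mass=np.ones(n),
        )
        topo = topo.concat(mt) if topo.n_atoms else mt
        positions.append(mono)
        ground_truth["free_molecule_ids"].append(next_mol)
        next_mol += 1

    if n_water:
        wpos = rng.uniform(0, box_edge, size=(n_water, 3))
        wt = Topology(
            molecule_id=np.arange(n_water),
            mol_class=np.array(["water"] * n_water, dtype=object),
            chain=np.array([""] * n_water, dtype=object),
            resname=np.array(["W"] * n_water, dtype=object),
            resid=np.ones(n_water, dtype=int),
            name=np.array(["W"] * n_water, dtype=object),
            mass=np.ones(n_water),
        )
        topo = topo.concat(wt) if topo.n_atoms else wt
        positions.append(wpos)
        next_mol += n_water

    pos = np.vstack(positions) if positions else np.zeros((0, 3))
    frame = Frame(positions=pos, time=0.0, box=box)
    return topo, frame, ground_truth


# ---------------------------------------------------------------------------
# Kinetics series and bulk points
# ---------------------------------------------------------------------------

def make_assembly_series(spec: AssemblyKineticsSpec) -> ReplicateSet:
    """Replicate micelle-count series
    n_i(t) = round(N_eq + (N0_i − N_eq)·e^(−t/τ)) + integer noise,
    floored at zero, with N0_i the per-replicate initial count."""
    t = np.asarray(spec.times, dtype=float)
    series = np.empty((spec.n_replicates, len(t)))
    for i in range(spec.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        n0_i = spec.n0 + (int(rng.integers(-spec.n0_spread,
                                           spec.n0_spread + 1))
                          if spec.n0_spread > 0 else 0)
        base = np.round(spec.n_eq + (n0_i - spec.n_eq) * np.exp(-t / spec.tau))
        noise = (rng.integers(-spec.noise, spec.noise + 1, size=len(t))
                 if spec.noise > 0 else np.zeros(len(t), dtype=int))
        series[i] = np.maximum(base + noise, 0)
    return ReplicateSet(times=t, series=series, label="micelle count")


def make_bulk_points(rho: float, box: Box, seed: int = 0) -> np.ndarray:
    """Poisson-uniform points at number density ``rho`` (Å⁻³) in the box."""
    if rho < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = rng.poisson(rho * box.volume)
    frac = rng.uniform(0.0, 1.0, size=(n, 3))
    return frac @ box.vectors


def points_to_frame(points: np.ndarray, box: Box, resname: str = "SOL",
                    name: str = "OW", mol_class: str = "water",
                    mol_id_start: int = 0) -> tuple[Topology, Frame]:
    """Wrap bare coordinates (one particle per molecule) as topology+frame."""
    n = len(points)
    topo = Topology(
        molecule_id=np.arange(n) + mol_id_start,
        mol_class=np.array([mol_class] * n, dtype=object),
        chain=np.array([""] * n, dtype=object),
        resname=np.array([resname] * n, dtype=object),
        resid=np.ones(n, dtype=int),
        name=np.array([name] * n, dtype=object),
        mass=np.ones(n),
    )
    return topo, Frame(positions=np.asarray(points, float), box=box)
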