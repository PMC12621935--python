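"""Core data model: particles, frames, trajectories, periodic boxes, and file I/O.

Coordinates are ångström internally; GRO nanometre values are converted on
read and write.  Particle indices are 0-based; residue numbers keep whatever
convention the input uses (the C99 fixtures number the transmembrane and
juxtamembrane span 16-55).  The box is a general 3x3 triclinic lattice;
minimum-image displacements are found by searching the 27 neighbour images,
which is exact for any cell whose particles have first been reduced to one
cell (a cubic or dodecahedral-as-triclinic cell included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: residue-name -> molecule-class defaults.  Editable: pass your own mapping
#: to ``read_structure`` or ``classify_particles``.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{aa: "protein" for aa in AMINO_ACIDS},
    "DPC": "surfactant", "FOS": "surfactant", "SDS": "surfactant",
    "LMPG": "surfactant", "DHPC": "surfactant",
    "W": "water", "WF": "water", "SOL": "water", "TIP3": "water",
    "HOH": "water", "WAT": "water", "TIP": "water",
    "NA": "ion", "CL": "ion", "NA+": "ion", "CL-": "ion", "SOD": "ion",
    "CLA": "ion", "K": "ion", "POT": "ion", "ION": "ion", "MG": "ion",
    "CA2": "ion",
}

MOLECULE_CLASSES = ("surfactant", "protein", "water", "ion")


class FormatError(ValueError):
    """Unreadable or malformed structure/trajectory file."""


class TopologyError(ValueError):
    """Topology inconsistent with coordinate data."""


# ---------------------------------------------------------------------------
# Box
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Simulation cell: rows of ``vectors`` are lattice vectors in Å."""

    vectors: np.ndarray
    periodic: bool = True

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float).reshape(3, 3)
        object.__setattr__(self, "vectors", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("box vectors must be finite")
        if self.periodic and self.volume <= 0:
            raise ValueError("periodic box must span positive volume")

    @classmethod
    def cubic(cls, edge: float, periodic: bool = True) -> "Box":
        return cls(np.eye(3) * float(edge), periodic=periodic)

    @classmethod
    def nonperiodic(cls) -> "Box":
        return cls(np.zeros((3, 3)), periodic=False)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    @property
    def shortest_extent(self) -> float:
        """Shortest distance between opposite cell faces."""
        if not self.periodic:
            return np.inf
        # face distance = volume / area of the face spanned by the other two
        v = self.vectors
        out = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            area = np.linalg.norm(np.cross(v[j], v[k]))
            out.append(self.volume / area)
        return float(min(out))

    @property
    def is_orthorhombic(self) -> bool:
        off = self.vectors - np.diag(np.diag(self.vectors))
        return bool(np.allclose(off, 0.0))

    def minimum_image_displacement(self, d: np.ndarray) -> np.ndarray:
        """Map raw displacement vectors to their shortest periodic image.

        Accepts a single vector or an (n, 3) array.  Non-periodic boxes
        return ``d`` unchanged.
        """
        d = np.asarray(d, dtype=float)
        if not self.periodic:
            return d
        single = d.ndim == 1
        d2 = np.atleast_2d(d)
        inv = np.linalg.inv(self.vectors)
        frac = d2 @ inv
        d0 = (frac - np.round(frac)) @ self.vectors
        if self.is_orthorhombic:
            return d0[0] if single else d0
        # skewed cells: rounding fractional coordinates is not always the
        # minimum image; search the 27 neighbour lattice translations
        shifts = np.array([(i, j, k)
                           for i in (-1, 0, 1)
                           for j in (-1, 0, 1)
                           for k in (-1, 0, 1)], dtype=float) @ self.vectors
        cand = d0[:, None, :] + shifts[None, :, :]
        best = np.argmin((cand ** 2).sum(axis=2), axis=1)
        out = cand[np.arange(len(d0)), best]
        return out[0] if single else out

    def to_mdanalysis_dimensions(self) -> np.ndarray | None:
        if not self.periodic:
            return None
        from MDAnalysis.lib.mdamath import triclinic_box
        v = self.vectors
        return np.asarray(triclinic_box(v[0], v[1], v[2]), dtype=np.float32)


def minimum_image_distance(a, b, box: Box) -> float:
    """Shortest distance between points ``a`` and ``b`` over periodic images."""
    d = box.minimum_image_displacement(np.asarray(b, float) - np.asarray(a, float))
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# Topology / Frame / Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-particle records stored as parallel arrays.

    ``molecule_id`` partitions particles into molecules (a surfactant, a
    water, an ion, or one protein chain).  ``chain`` is "A"/"B" for the two
    peptides of a dimer and "" elsewhere.
    """

    molecule_id: np.ndarray          # (n,) int
    mol_class: np.ndarray            # (n,) str
    chain: np.ndarray                # (n,) str
    resname: np.ndarray              # (n,) str
    resid: np.ndarray                # (n,) int
    name: np.ndarray                 # (n,) str
    mass: np.ndarray = None          # (n,) float, default 1.0

    def __post_init__(self):
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        n = len(self.molecule_id)
        self.mol_class = np.asarray(self.mol_class, dtype=object)
        self.chain = np.asarray(self.chain, dtype=object)
        self.resname = np.asarray(self.resname, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.name = np.asarray(self.name, dtype=object)
        if self.mass is None:
            self.mass = np.ones(n)
        self.mass = np.asarray(self.mass, dtype=float)
        lengths = {len(a) for a in (self.mol_class, self.chain, self.resname,
                                    self.resid, self.name, self.mass)}
        if lengths != {n}:
            raise TopologyError("topology arrays have mismatched lengths")
        bad = set(np.unique(self.mol_class)) - set(MOLECULE_CLASSES)
        if bad:
            raise TopologyError(f"unknown molecule classes: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.molecule_id)

    def select(self, mol_class=None, name=None, resid=None, chain=None,
               resname=None) -> np.ndarray:
        """Particle indices matching all given criteria (each scalar or set)."""
        mask = np.ones(self.n_atoms, dtype=bool)

        def _match(arr, crit):
            vals = {crit} if np.isscalar(crit) or isinstance(crit, str) else set(crit)
            return np.isin(arr, list(vals))

        if mol_class is not None:
            mask &= _match(self.mol_class, mol_class)
        if name is not None:
            mask &= _match(self.name, name)
        if resid is not None:
            mask &= _match(self.resid, resid)
        if chain is not None:
            mask &= _match(self.chain, chain)
        if resname is not None:
            mask &= _match(self.resname, resname)
        return np.flatnonzero(mask)

    def molecules(self, mol_class=None) -> dict[int, np.ndarray]:
        """Map molecule id -> particle indices, optionally filtered by class."""
        idx = (np.arange(self.n_atoms) if mol_class is None
               else self.select(mol_class=mol_class))
        out: dict[int, np.ndarray] = {}
        for mid in np.unique(self.molecule_id[idx]):
            out[int(mid)] = idx[self.molecule_id[idx] == mid]
        return out

    def subset(self, indices: np.ndarray) -> "Topology":
        """Topology restricted to the given particle indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return Topology(
            molecule_id=self.molecule_id[idx], mol_class=self.mol_class[idx],
            chain=self.chain[idx], resname=self.resname[idx],
            resid=self.resid[idx], name=self.name[idx], mass=self.mass[idx])

    def concat(self, other: "Topology") -> "Topology":
        shift = int(self.molecule_id.max()) + 1 if self.n_atoms else 0
        return Topology(
            molecule_id=np.concatenate([self.molecule_id, other.molecule_id + shift]),
            mol_class=np.concatenate([self.mol_class, other.mol_class]),
            chain=np.concatenate([self.chain, other.chain]),
            resname=np.concatenate([self.resname, other.resname]),
            resid=np.concatenate([self.resid, other.resid]),
            name=np.concatenate([self.name, other.name]),
            mass=np.concatenate([self.mass, other.mass]),
        )


@dataclass
class Frame:
    """One configuration: positions (n, 3) Å, a time stamp in ns, and a box."""

    positions: np.ndarray
    time: float = 0.0
    box: Box = field(default_factory=Box.nonperiodic)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("frame coordinates must be finite")


@dataclass
class Trajectory:
    """An ordered sequence of frames over one topology."""

    topology: Topology
    frames: list[Frame]
    stride_ns: float | None = None

    def __post_init__(self):
        for fr in self.frames:
            if len(fr.positions) != self.topology.n_atoms:
                raise TopologyError(
                    f"frame has {len(fr.positions)} particles, topology has "
                    f"{self.topology.n_atoms}")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class ReplicateSet:
    """M replicate scalar time series on a shared time grid (ns)."""

    times: np.ndarray           # (T,)
    series: np.ndarray          # (M, T)
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if self.series.shape[1] != len(self.times):
            raise ValueError("series length does not match the time grid")

    @property
    def n_replicates(self) -> int:
        return self.series.shape[0]


# ---------------------------------------------------------------------------
# Classification and unwrapping
# ---------------------------------------------------------------------------

def classify_particles(resnames, class_map: dict[str, str] | None = None) -> np.ndarray:
    """Map residue names to molecule classes; unknown names fall back to ion."""
    cmap = DEFAULT_CLASS_MAP if class_map is None else class_map
    out = np.empty(len(resnames), dtype=object)
    unknown = set()
    for i, rn in enumerate(resnames):
        cls = cmap.get(str(rn).upper())
        if cls is None:
            unknown.add(str(rn))
            cls = "ion"
        out[i] = cls
    if unknown:
        logger.warning("unknown residue names classed as 'ion': %s",
                       sorted(unknown))
    return out


def unwrap_group(positions: np.ndarray, box: Box,
                 warn_label: str = "group") -> np.ndarray:
    """Make a compact particle group whole across periodic boundaries.

    Each particle is mapped to its nearest image relative to the first
    particle, then refined once relative to the running centroid.  Valid for
    groups (molecules, micelles) compact relative to half the cell; a group
    wider than half the shortest box extent after unwrapping triggers an
    ambiguity warning.
    """
    pos = np.asarray(positions, dtype=float)
    if not box.periodic or len(pos) < 2:
        return pos.copy()
    ref = pos[0]
    out = ref + box.minimum_image_displacement(pos - ref)
    for _ in range(2):
        centroid = out.mean(axis=0)
        out = centroid + box.minimum_image_displacement(out - centroid)
    extent = np.linalg.norm(out - out.mean(axis=0), axis=1).max() * 2
    if extent > box.shortest_extent:
        warnings.warn(
            f"{warn_label} spans {extent:.1f} Å, wider than half-box; "
            "unwrapping is ambiguous", stacklevel=2)
    return out


def unwrap_molecule(frame: Frame, topology: Topology, molecule_id: int) -> np.ndarray:
    """Whole-molecule coordinates of one molecule in a frame."""
    idx = np.flatnonzero(topology.molecule_id == molecule_id)
    if len(idx) == 0:
        raise TopologyError(f"molecule id {molecule_id} not in topology")
    return unwrap_group(frame.positions[idx], frame.box,
                        warn_label=f"molecule {molecule_id}")


# ---------------------------------------------------------------------------
# Readers / writers (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _molecule_ids_from_universe(u, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Molecule grouping: one residue per non-protein molecule; one chain
    (contiguous run of non-decreasing resids under one chain id) per protein
    molecule.  Formats without chain ids (GRO) get alternating A/B labels
    per protein run, matching the dimer pairing convention.
    Returns (molecule_id, chain_label) arrays."""
    n = len(u.atoms)
    mol_id = np.zeros(n, dtype=int)
    chain = np.array([""] * n, dtype=object)
    try:
        chain_src = [str(c) for c in u.atoms.chainIDs]
    except AttributeError:
        try:
            chain_src = [str(s) for s in u.atoms.segids]
        except AttributeError:
            chain_src = [""] * n
    labels_meaningful = len({c for i, c in enumerate(chain_src)
                             if classes[i] == "protein"}) > 1
    resids = u.atoms.resids
    next_id = -1
    prev_res = None
    prev_protein = False
    prot_runs = -1
    for i, atom in enumerate(u.atoms):
        if classes[i] == "protein":
            new_run = (not prev_protein
                       or chain_src[i] != chain_src[i - 1]
                       or resids[i] < resids[i - 1])
            if new_run:
                next_id += 1
                prot_runs += 1
            mol_id[i] = next_id
            chain[i] = (chain_src[i] if labels_meaningful
                        else "AB"[prot_runs % 2])
            prev_protein = True
            prev_res = None
        else:
            rkey = atom.residue.resindex
            if rkey != prev_res:
                next_id += 1
                prev_res = rkey
            mol_id[i] = next_id
            prev_protein = False
    return mol_id, chain


def read_structure(path, file_format: str | None = None,
                   class_map: dict[str, str] | None = None
                   ) -> tuple[Topology, Frame]:
    """Read a PDB/GRO structure into a classified topology plus one frame."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty structure file: {path}")
    kwargs = {"format": file_format} if file_format else {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), **kwargs)
    except Exception as exc:  # MDAnalysis raises assorted types
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc

    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    classes = classify_particles(resnames, class_map)
    mol_id, chain = _molecule_ids_from_universe(u, classes)
    try:
        masses = u.atoms.masses.astype(float)
        if not np.all(masses > 0):
            masses = np.ones(len(u.atoms))
    except Exception:
        masses = np.ones(len(u.atoms))
    topology = Topology(
        molecule_id=mol_id,
        mol_class=classes,
        chain=chain,
        resname=resnames,
        resid=np.array([a.resid for a in u.atoms], dtype=int),
        name=np.array([a.name for a in u.atoms], dtype=object),
        mass=masses,
    )
    box = _box_from_dimensions(u.dimensions)
    frame = Frame(positions=u.atoms.positions.astype(float), time=0.0, box=box)
    return topology, frame


def _box_from_dimensions(dims) -> Box:
    if dims is None or np.allclose(dims[:3], 0):
        return Box.nonperiodic()
    from MDAnalysis.lib.mdamath import triclinic_vectors
    return Box(np.asarray(triclinic_vectors(dims), dtype=float))


def read_trajectory(path, topology: Topology, stride_ns: float | None = None,
                    structure_path=None) -> Trajectory:
    """Read an XTC/DCD (or any MDAnalysis-supported) trajectory.

    Times come from the file when present, otherwise synthesized from
    ``stride_ns``.  A particle-count mismatch raises ``TopologyError``;
    a file truncated mid-stream raises ``FormatError`` reporting the number
    of frames recovered.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower().lstrip(".")
    reader = _open_reader(str(path), suffix, topology.n_atoms, structure_path)
    if reader.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"trajectory has {reader.n_atoms} particles, topology has "
            f"{topology.n_atoms}")
    frames: list[Frame] = []
    try:
        for i, ts in enumerate(reader):
            box = _box_from_dimensions(ts.dimensions)
            time = (ts.time / 1000.0 if getattr(ts, "time", None) is not None
                    else 0.0)
            if stride_ns is not None:
                time = i * stride_ns
            frames.append(Frame(positions=ts.positions.astype(float),
                                time=time, box=box))
    except (OSError, EOFError, ValueError) as exc:
        raise FormatError(
            f"truncated trajectory {path}: recovered {len(frames)} frames "
            f"({exc})") from exc
    finally:
        reader.close()
    return Trajectory(topology=topology, frames=frames, stride_ns=stride_ns)


def _open_reader(path: str, suffix: str, n_atoms: int, structure_path):
    from MDAnalysis import coordinates
    if structure_path is not None:
        import MDAnalysis as mda
        return mda.Universe(str(structure_path), path).trajectory
    readers = {
        "xtc": coordinates.XTC.XTCReader,
        "trr": coordinates.TRR.TRRReader,
        "dcd": coordinates.DCD.DCDReader,
    }
    if suffix not in readers:
        raise FormatError(f"unsupported trajectory format: .{suffix}")
    try:
        return readers[suffix](path, n_atoms=n_atoms)
    except TypeError:
        return readers[suffix](path)


def to_mdanalysis(topology: Topology, frame: Frame):
    """Build an MDAnalysis Universe from a topology + frame (for writing)."""
    import MDAnalysis as mda

    n = topology.n_atoms
    # residues: consecutive runs of (molecule_id, resid)
    keys = list(zip(topology.molecule_id, topology.resid))
    res_index = np.zeros(n, dtype=int)
    r = -1
    prev = None
    for i, k in enumerate(keys):
        if k != prev:
            r += 1
            prev = k
        res_index[i] = r
    n_res = r + 1
    first_atom = np.searchsorted(res_index, np.arange(n_res))
    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=res_index,
                           trajectory=True)
    u.add_TopologyAttr("names", topology.name.astype(str))
    u.add_TopologyAttr("resnames", topology.resname[first_atom].astype(str))
    # non-protein residues are renumbered globally so that a re-read groups
    # molecules correctly even in formats without chain ids; protein keeps
    # its residue numbering (the analyses key on it)
    resids_out = topology.resid[first_atom].copy()
    nonprot = topology.mol_class[first_atom] != "protein"
    resids_out[nonprot] = (np.arange(int(nonprot.sum())) % 99999) + 1
    u.add_TopologyAttr("resids", resids_out)
    u.add_TopologyAttr("masses", topology.mass)
    chains = np.where(topology.chain == "", "X", topology.chain)
    u.add_TopologyAttr("chainIDs", chains.astype(str))
    u.atoms.positions = frame.positions.astype(np.float32)
    dims = frame.box.to_mdanalysis_dimensions()
    if dims is not None:
        u.dimensions = dims
    return u


def write_structure(path, topology: Topology, frame: Frame) -> None:
    """Write a topology + frame to GRO or PDB (chosen by file extension)."""
    u = to_mdanalysis(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
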