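"""Run configuration: every analysis parameter in one serializable record.

Defaults follow the coarse-grained conventions the census was validated
under: 6 Å single-linkage cutoff at bead scale, minimum micelle size 10
monomers, contact-count dimer assignment (6 Å, ≥10 contacts), equilibration
over the second half of each series, and the two hydrogen-bond criteria
(2.5 Å/150° backbone, 3.5 Å/120° aliphatic).  A YAML file overrides any
subset; command-line flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class SynthSpec:
    """Synthetic assembly-box recipe (counts and sizes)."""

    n_dimer_micelles: int = 5
    dimer_s: int = 69
    dimer_r_head: float = 21.0
    n_empty_micelles: int = 4
    empty_s: int = 42
    empty_r_head: float = 16.0
    beads_per_surfactant: int = 12
    jitter: float = 0.5
    n_free_monomers: int = 7
    n_water: int = 200
    box_edge: float | None = None


@dataclass
class RunConfig:
    # census
    cluster_cutoff: float = 6.0        # Å
    min_micelle_size: int = 10
    contact_cutoff: float = 6.0        # Å
    min_contacts: int = 10
    equilibration_fraction: float = 0.5  # fraction of the series discarded
    t_eq: float | None = None            # ns; overrides the fraction
    # gyration
    rg_formula: str = "pairwise"         # "pairwise" | "mass-weighted"
    include_protein_in_rg: bool = False
    # histograms
    histogram_bins: int = 50
    # hydrogen bonds
    backbone_distance: float = 2.5       # Å
    backbone_angle: float = 150.0        # degrees
    aliphatic_distance: float = 3.5
    aliphatic_angle: float = 120.0
    # densities
    density_bin_width: float = 0.5       # Å
    density_r_max: float = 30.0
    reference_resid: int = 33
    reference_chain: str = "A"
    # I/O
    stride_ns: float | None = None
    seed: int = 0
    synth: SynthSpec = field(default_factory=SynthSpec)

    def __post_init__(self):
        for name in ("cluster_cutoff", "contact_cutoff", "density_bin_width",
                     "density_r_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw = {**raw, "synth": SynthSpec(**raw["synth"])}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def resolve_t_eq(self, times) -> float:
        """Equilibration onset in ns for a given time grid."""
        if self.t_eq is not None:
            return float(self.t_eq)
        if len(times) == 0:
            return 0.0
        lo, hi = float(min(times)), float(max(times))
        return lo + (hi - lo) * self.equilibration_fraction
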