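"""End-to-end workflows: synthetic-system generation, the coarse-grained
census workflow (census → aggregation statistics → ergodic measure → Rg →
finite-size adequacy), and the atomistic dimer-structure workflow (order
parameters → hydrogen-bond maps → helicity → density profiles).

Every workflow writes CSV/JSON into an output directory and returns the
report dict it wrote; each report echoes the fully resolved configuration
so a run is auditable from its outputs alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import density_profiles as dp
from . import dimer_geometry as dg
from . import gyration as gyr
from . import hbond_helicity as hb
from . import micelle_census as mc
from .config import RunConfig
from .io_model import Frame, ReplicateSet, Trajectory, write_structure
from .synthetic_data import MicelleSpec, make_assembly_box

logger = logging.getLogger(__name__)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_synth(config: RunConfig, out_dir, seed: int | None = None) -> dict:
    """Generate a synthetic assembly box; write GRO + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    sp = config.synth
    dimers = [MicelleSpec(s=sp.dimer_s, r_head=sp.dimer_r_head,
                          beads_per_surfactant=sp.beads_per_surfactant,
                          jitter=sp.jitter)
              for _ in range(sp.n_dimer_micelles)]
    empties = [MicelleSpec(s=sp.empty_s, r_head=sp.empty_r_head,
                           beads_per_surfactant=sp.beads_per_surfactant,
                           jitter=sp.jitter)
               for _ in range(sp.n_empty_micelles)]
    topo, frame, truth = make_assembly_box(
        dimers, empties, n_free=sp.n_free_monomers, n_water=sp.n_water,
        box_edge=sp.box_edge, seed=seed)
    write_structure(out / "assembly.gro", topo, frame)
    _write_json(out / "ground_truth.json", truth)
    report = {"config": config.to_dict(), "seed": seed,
              "n_particles": topo.n_atoms,
              "files": ["assembly.gro", "ground_truth.json"]}
    _write_json(out / "synth_report.json", report)
    return report


def run_census_workflow(config: RunConfig,
                        trajectories: list[Trajectory],
                        out_dir) -> dict:
    """Census every replicate trajectory, then aggregate: per-frame census
    CSV, class histograms, ergodic measure of the micelle count, per-class
    Rg, s*/Rg ratios, and the finite-size adequacy verdict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_series = []
    census_rows = []
    all_censuses = []
    rg_frames = []
    for rep, traj in enumerate(trajectories):
        censuses = [mc.census_frame(
            fr, traj.topology, config.cluster_cutoff,
            config.min_micelle_size, config.contact_cutoff,
            config.min_contacts) for fr in traj]
        all_censuses.extend(censuses)
        series = mc.aggregation_series(
            traj, config.cluster_cutoff, config.min_micelle_size,
            config.contact_cutoff, config.min_contacts, replicate=rep)
        all_series.append(series)
        for c in censuses:
            for m in c.micelles:
                census_rows.append({
                    "replicate": rep, "time": c.time, "micelle": m.label,
                    "class": m.mol_class, "size": m.size,
                    "molecule_ids": ";".join(map(str, m.molecule_ids))})
        res = gyr.micelle_rg_series(traj, censuses,
                                    include_protein=config.include_protein_in_rg,
                                    formula=config.rg_formula)
        res.table["replicate"] = rep
        rg_frames.append(res.table)

    pd.DataFrame(census_rows).to_csv(out / "census.csv", index=False)
    agg = pd.concat([s.table.assign(replicate=s.replicate)
                     for s in all_series], ignore_index=True)
    agg.to_csv(out / "aggregation.csv", index=False)
    for weighting in ("observation", "frame"):
        mc.size_histogram(all_censuses, weighting=weighting).to_csv(
            out / f"size_histogram_{weighting}.csv", index=False)

    # ergodic measure across replicates (micelle count, all classes)
    ergodic_out = {}
    if len(all_series) >= 2:
        times = all_series[0].times
        for cls, col in (("all", "n_all"), ("empty", "n_empty"),
                         ("dimer", "n_dimer")):
            counts = np.vstack([s.table[col].to_numpy() for s in all_series])
            erg = mc.ergodic_measure(ReplicateSet(times, counts, label=cls))
            ergodic_out[cls] = erg
        pd.DataFrame({"time": times, **{f"omega_{c}": e.omega
                                        for c, e in ergodic_out.items()}}
                     ).to_csv(out / "ergodic.csv", index=False)

    t_eq = config.resolve_t_eq(all_series[0].times)
    adequacy = mc.finite_size_check(all_series[0], t_eq=t_eq)
    # adequacy over pooled replicates: average the per-replicate counts
    if len(all_series) > 1:
        pooled = pd.concat([s.table for s in all_series])
        sel = pooled[pooled["time"] > t_eq]
        nd = float(sel["n_dimer"].mean())
        ne = float(sel["n_empty"].mean())
        reasons = ([] if nd >= 3 else ["dimer micelles < 3"]) + \
                  ([] if ne >= 3 else ["empty micelles < 3"])
        adequacy = mc.FiniteSizeReport(passed=not reasons, mean_n_dimer=nd,
                                       mean_n_empty=ne, t_eq=t_eq,
                                       reasons=reasons)
    _write_json(out / "adequacy.json", adequacy.to_dict())

    rg_table = pd.concat(rg_frames, ignore_index=True)
    rg_table.to_csv(out / "rg.csv", index=False)
    rg_all = gyr.GyrationResult(table=rg_table,
                                include_protein=config.include_protein_in_rg,
                                formula=config.rg_formula)
    rg_summary = rg_all.class_summary(t_eq=t_eq)

    summary = {"config": config.to_dict(), "t_eq": t_eq,
               "adequacy": adequacy.to_dict(), "classes": {}}
    eq = pd.concat([s.table for s in all_series])
    eq = eq[eq["time"] > t_eq] if (eq["time"] > t_eq).any() else eq
    for cls in ("dimer", "empty", "all"):
        mean_s = float(eq[f"mean_s_{cls}"].mean())
        entry = {"mean_aggregation_number": mean_s,
                 "mean_count": float(eq[f"n_{cls}"].mean())}
        row = rg_summary[rg_summary["mol_class"] == cls]
        if cls == "all":
            row = rg_summary
            mean_rg = float((row["mean_rg"] * row["n"]).sum() / row["n"].sum()) \
                if len(row) else float("nan")
        else:
            mean_rg = float(row["mean_rg"].iloc[0]) if len(row) else float("nan")
        entry["mean_rg"] = mean_rg
        if np.isfinite(mean_rg) and mean_rg > 0 and np.isfinite(mean_s):
            entry["s_over_rg"] = gyr.aggregation_rg_ratio(mean_s, mean_rg)
        summary["classes"][cls] = entry
    if ergodic_out:
        summary["ergodic_decay_ratio_all"] = ergodic_out["all"].decay_ratio(
            t_late=t_eq)
    _write_json(out / "census_report.json", summary)
    return summary


def run_dimer_workflow(config: RunConfig, trajectory: Trajectory,
                       out_dir) -> dict:
    """Atomistic structure-comparison workflow on a two-chain trajectory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo = trajectory.topology
    prot_mols = sorted(topo.molecules(mol_class="protein"))
    if len(prot_mols) > 2:
        logger.warning("%d protein chains present; analyzing the first "
                       "dimer only", len(prot_mols))
        keep = np.flatnonzero(
            (topo.mol_class != "protein")
            | np.isin(topo.molecule_id, prot_mols[:2]))
        topo = topo.subset(keep)
        trajectory = Trajectory(
            topology=topo,
            frames=[Frame(positions=fr.positions[keep], time=fr.time,
                          box=fr.box) for fr in trajectory],
            stride_ns=trajectory.stride_ns)

    rows = []
    mats = []
    for fr in trajectory:
        g = dg.analyze_dimer_frame(topo, fr.positions, time=fr.time)
        mats.append(g.distance_matrix)
        rows.append({"time": fr.time, "d_k28": g.d_k28, "d_k54": g.d_k54,
                     "psi_a": g.psi_a, "psi_b": g.psi_b, "phi": g.phi,
                     "d_marker": g.d_marker})
    params = pd.DataFrame(rows)
    params.to_csv(out / "dimer_order_parameters.csv", index=False)
    resids = np.unique(topo.resid[topo.select(mol_class="protein")])
    mean_mat = np.nanmean(np.stack(mats), axis=0)
    pd.DataFrame(mean_mat, index=resids, columns=resids).to_csv(
        out / "residue_distance_matrix.csv")

    bins = config.histogram_bins
    hists = {
        "k28_k54": dg.histogram2d(params["d_k28"], params["d_k54"], bins),
        "crick": dg.histogram2d(params["psi_a"], params["psi_b"], bins,
                                ranges=[[0, 180], [0, 180]]),
        "twist_marker": dg.histogram2d(params["phi"], params["d_marker"],
                                       bins),
    }
    for name, h in hists.items():
        np.savetxt(out / f"hist2d_{name}.csv", h.density, delimiter=",")

    hb_summary = {}
    backbone = hb.HBondCriterion(distance_cutoff=config.backbone_distance,
                                 angle_cutoff=config.backbone_angle)
    aliphatic = hb.HBondCriterion(
        donor_heavy=("CA",), donor_hydrogens=("HA", "HA1", "HA2", "HA3"),
        distance_cutoff=config.aliphatic_distance,
        angle_cutoff=config.aliphatic_angle)
    has_h = len(topo.select(mol_class="protein",
                            name=("H", "HN", "HA", "HA1", "HA2"))) > 0
    if has_h:
        for label, crit in (("backbone", backbone), ("aliphatic", aliphatic)):
            hmap = hb.propensity_map(trajectory, crit, scope="inter")
            pd.DataFrame(hmap.p, index=hmap.resids, columns=hmap.resids
                         ).to_csv(out / f"hbond_map_{label}.csv")
            marg = hb.marginal_profile(hmap)
            pd.DataFrame({"resid": hmap.resids, "participation": marg}
                         ).to_csv(out / f"hbond_marginal_{label}.csv",
                                  index=False)
            hb_summary[label] = {"max_propensity": float(hmap.p.max()),
                                 "n_frames": hmap.n_frames}
        hel = hb.fractional_helicity(trajectory, backbone)
        pd.DataFrame({"resid": hel.resids,
                      **{f"chain_{c}": v for c, v in hel.helicity.items()}}
                     ).to_csv(out / "helicity.csv", index=False)

    density_summary = {}
    reference = {"mol_class": "protein", "chain": config.reference_chain,
                 "resid": config.reference_resid, "name": ("CA", "BB")}
    if len(topo.select(**reference)) == 1:
        for species, target in dp.SPECIES_PRESETS.items():
            if len(topo.select(**target)) == 0:
                continue
            prof = dp.number_density_profile(
                trajectory, reference, target,
                bin_width=config.density_bin_width,
                r_max=config.density_r_max, species=species)
            pd.DataFrame({"r": prof.bin_centers,
                          "mean_count": prof.mean_counts,
                          "density": prof.density}
                         ).to_csv(out / f"density_{species}.csv", index=False)
            entry = {}
            plat = dp.plateau_estimate(prof)
            entry["plateau"] = plat.value
            entry["plateau_molarity"] = plat.molarity
            entry["is_plateau"] = plat.is_plateau
            peak = dp.first_peak(prof)
            entry["first_peak"] = peak
            density_summary[species] = entry

    summary = {"config": config.to_dict(),
               "order_parameters": {
                   "mean_d_k28": float(params["d_k28"].mean()),
                   "mean_d_k54": float(params["d_k54"].mean()),
                   "mean_psi_a": float(params["psi_a"].mean()),
                   "mean_psi_b": float(params["psi_b"].mean()),
                   "mean_phi": float(params["phi"].mean()),
                   "fraction_right_handed": float((params["phi"] < 0).mean())},
               "hydrogen_bonds": hb_summary,
               "densities": density_summary}
    _write_json(out / "dimer_report.json", summary)
    return summary


def single_frame_trajectory(topology, frame: Frame, n_frames: int = 1,
                            dt: float = 10.0) -> Trajectory:
    """Repeat one static configuration as an n-frame trajectory (for
    ensemble-style statistics over a known fixed structure)."""
    frames = [Frame(positions=frame.positions.copy(), time=i * dt,
                    box=frame.box) for i in range(n_frames)]
    return Trajectory(topology=topology, frames=frames, stride_ns=dt)
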