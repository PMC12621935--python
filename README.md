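# micellekit

Analysis toolkit for determining the **preferred aggregation number** and
structure of surfactant micelles that encapsulate a transmembrane protein
dimer, from molecular-dynamics trajectories of self-assembly.

Surfactant micelles (dodecylphosphocholine in particular) are the standard
membrane mimic for NMR structure determination of transmembrane domains
such as the amyloid precursor protein C99 homodimer.  Simulations of such
systems usually *assume* the micelle around the protein has the same
aggregation number s\* as a pure micelle.  Testing that assumption requires
a census over large self-assembly simulations: identify every micelle,
classify it as dimer-encapsulating or empty, track the class-resolved mean
aggregation numbers and radii of gyration, verify the run is converged and
the box large enough, and then compare the dimer's structure across micelle
sizes.  `micellekit` implements that full stack, plus a synthetic-
configuration generator with exactly known ground truth so every stage is
testable without running any MD.

## What it computes

* **Micelle census** — single-linkage clustering of surfactant molecules
  (edge when any inter-molecule bead pair is within a cutoff, minimum-image
  convention; default 6 Å at coarse-grained bead scale), a minimum micelle
  size of 10 monomers, and contact-count classification of each micelle as
  *dimer* or *empty*.
* **Convergence and finite size** — the ergodic measure of the micelle
  count over M replicate runs,

  Ω(t) = (1/M) Σᵢ [nᵢ(t) − N(t)]²,

  which decays to its noise floor as the replicates agree, and an adequacy
  rule requiring at least three micelles of each class at equilibrium.
* **Radius of gyration** — mass-weighted form
  R_g² = Σ mᵢ|rᵢ − r_com|² / Σ mᵢ and the equal-mass pairwise form
  R_g² = (1/2N²) Σ_{i≠j} d²ᵢⱼ (identical for equal masses; no centroid
  needed), with per-class statistics and the coarse-grained→atomistic
  matching rule: pick the atomistic aggregation number whose micelle
  reproduces the coarse-grained R_g.
* **Dimer order parameters** — chain-symmetrized residue-pair COM distance
  maps, K28/K54 anchor distances, the Crick angle ψ of the G33 marker
  (0° Gly-in … 180° Gly-out), and the twist dihedral φ over
  (G29A, G37A, G37B, G29B) Cα with right-handed = negative.
* **Hydrogen bonds and helicity** — backbone NH⋯O=C bonds (H⋯O ≤ 2.5 Å,
  donor–H–acceptor angle ≥ 150°) and aliphatic CαH⋯O=C bonds (≤ 3.5 Å,
  ≥ 120°); residue-pair propensity maps P_ij with per-residue marginals
  (column mean + row mean), and fractional helicity (residue i helical when
  backbone-bonded to i±3, 4 or 5).
* **Number-density profiles** — shell-counted densities about a reference
  atom (an RDF without bulk normalization), plateau estimation with
  molarity conversion (0.033 Å⁻³ ≈ 55 mol/L), and water-penetration peak
  location.

## Worked example

Build a synthetic assembly box with known ground truth — 5 micelles of 69
surfactants each encapsulating a two-helix dimer, 4 empty micelles of 42,
and 7 free monomers — then run the census workflow on it:

```python
from micellekit import MicelleSpec, make_assembly_box
from micellekit.config import RunConfig
from micellekit.workflows import run_census_workflow, single_frame_trajectory

dimers  = [MicelleSpec(s=69, r_head=21.0, jitter=0.5) for _ in range(5)]
empties = [MicelleSpec(s=42, r_head=16.0, jitter=0.5) for _ in range(4)]
topo, frame, truth = make_assembly_box(dimers, empties, n_free=7,
                                       n_water=200, seed=1)
traj = single_frame_trajectory(topo, frame, n_frames=4)
report = run_census_workflow(RunConfig(), [traj], "out")
print(report["classes"])
```

prints (values from this exact run):

```
dimer: mean_aggregation_number 69.0, mean_count 5.0, mean_rg 12.97
empty: mean_aggregation_number 42.0, mean_count 4.0, mean_rg 10.06
all:   mean_aggregation_number 57.0, mean_count 9.0
adequacy: passed (5 dimer ≥ 3, 4 empty ≥ 3)
```

The census recovers the constructed composition exactly: class means 69
and 42, overall size-weighted mean (5·69 + 4·42)/9 = 57.0, and the box
passes the finite-size rule.  The R_g values are those of the synthetic
micelle geometry (head shell plus inward tails), smaller than the head
radius because the tails pull mass inward.

The same workflows are available from the shell:

```sh
micelle-census synth  --out synth --seed 1
micelle-census census --top synth/assembly.gro --out census
micelle-census dimer  --top dimer.pdb --out dimer_out
```

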