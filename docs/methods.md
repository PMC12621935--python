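# Methods

This note documents the models, conventions and numerical choices behind
`micellekit`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Data model and periodic boundaries

Coordinates are ångström internally (GRO nanometres converted on read and
write).  The cell is a general 3×3 triclinic lattice; a dodecahedral cell
is a special case of triclinic, so one code path covers cubic test boxes
and production cells alike.  Minimum-image displacements reduce the
fractional coordinates by rounding and then search the 27 neighbour
lattice translations, which is exact for particles within about one cell
of each other and is validated against brute-force image enumeration.

Molecules are grouped as one residue per surfactant/water/ion and one
chain per protein molecule.  Formats without chain identifiers (GRO) get
chains reconstructed from residue-number discontinuities, labelled
A/B alternately so that consecutive protein chains pair into dimers.

All centre-of-mass and R_g computations operate on *whole* (unwrapped)
coordinates.  Unwrapping maps each particle to its nearest image relative
to a reference and then refines twice against the running centroid; this
is exact for groups compact relative to half the cell (micelles are), and
a group wider than half the shortest box extent triggers an ambiguity
warning rather than silent nonsense.  An R_g exceeding half the shortest
box extent likewise raises a wrap-suspicion warning.

## Micelle census

**Clustering rule.** Micelles are single-linkage components of the contact
graph on surfactant molecules, with an edge when *any* inter-molecule bead
pair is within the cutoff under minimum image.  Defaults: 6.0 Å for
coarse-grained bead systems, 4.0 Å for atomistic heavy atoms, both
configurable.  Single linkage with a contact cutoff is the standard
micelle census; on the synthetic boxes it recovers the constructed
membership exactly for any cutoff in the 5–8 Å band, because generated
micelles are internally connected at sub-cutoff spacing while neighbouring
micelles are separated by a clearance larger than the cutoff.  Component
labels are deterministic (numbered by smallest member molecule id), so the
census is invariant to particle ordering.

**Minimum size.** Components below 10 monomers are free monomers, not
micelles; the threshold is inclusive (a 10-monomer component is a
micelle).

**Classification.** Each protein dimer is assigned to the micelle with the
greatest number of surfactant beads within the contact cutoff (default
6.0 Å) of any dimer bead, provided at least 10 such contacts exist; ties
break to the smaller micelle label and are logged, as are unencapsulated
dimers.  Micelles with an assigned dimer are class *dimer*, others
*empty*.

**Equilibration.** Statistics are taken over t > t_eq.  By default t_eq is
the midpoint of the series (equilibration fraction 0.5, matching the
convention of discarding the first half); an absolute t_eq in ns overrides
it.

**Ergodic measure.** Ω(t) is the population variance (1/M normalization,
not 1/(M−1)) of the per-replicate micelle count about the cross-replicate
mean.  Identical replicates give Ω ≡ 0; two constant series {3, 5} give
Ω ≡ 1.

**Finite-size adequacy.** The box passes when the equilibrated
time-averaged counts of both dimer-encapsulating and empty micelles reach
3 (inclusive).  Fewer of either class means the box biases the preferred
aggregation number and the census should not be trusted.

**Histogram weightings.** Aggregation-number histograms are emitted in two
weightings — per micelle-frame observation and per frame (each frame's
micelles share unit weight) — because either normalization is defensible
and they differ when micelle counts fluctuate.

## Radius of gyration

Both operators act on bare point sets, so callers choose the point set
(all beads by default; monomer centres of mass if preferred).  The
pairwise form is evaluated through the O(N) algebraic identity
Σ_{i≠j} d²ᵢⱼ = 2N Σ|rᵢ|² − 2|Σ rᵢ|², not the literal double sum, and is
verified against the double loop and against the mass-weighted form under
equal masses (agreement ≤ 1e-10).

Whether the encapsulated dimer's particles count toward a micelle's R_g is
a flag (default: excluded) and both variants are reported, since either
convention is found in practice.  Note the direction of the effect depends
on geometry: a compact protein at the micelle centre lowers R_g, while
long helices protruding through the head shell raise it.

Class statistics follow the convention: mean over frames within a
replicate, standard deviation across replicates.

CG→atomistic matching selects the candidate aggregation number minimizing
|R_g − target|, ties to the smaller size (logged).  The s\*/R_g ratio is
reported to one decimal.

## Dimer order parameters

**Helix axis.** Direction is the first principal component of the
backbone-atom window (default residues 30–52, the transmembrane span),
oriented N→C.  The axis *point* is refined by minimizing the radial
circle-fit residual over axis orientations (Kåsa fit inside a
Levenberg–Marquardt loop, seeded by the PCA axis).  This matters: the raw
centroid of a helical arc spanning a non-integer number of turns is biased
off-axis by up to the Cα radius (≈2.3 Å), and the PCA direction itself is
biased by a few tenths of a degree; the cylinder fit removes both biases,
making the Crick-angle endpoints exact on ideal fixtures.

**Crick angle.** ψ is the angle between (a) the vector connecting the two
helix centres — taken as the fitted axis centres, the unbiased reading of
"helix centre of mass" for an arc — and (b) the axis-to-Cα radial vector
of the marker residue G33, both projected normal to the chain's axis.
Glycine has no side chain, so the radial Cα direction is the natural
marker; an Hα-based variant can be obtained by passing a different marker
atom selection.  ψ ∈ [0°, 180°], 0° = Gly-in, 180° = Gly-out.

**Twist dihedral.** φ is the standard four-point dihedral over the Cα
atoms (G29A, G37A, G37B, G29B), IUPAC sign convention (cis = 0, clockwise
positive viewed along the central bond), range (−180°, 180°]; negative φ
is a right-handed coiled-coil.  One geometric fact worth knowing when
interpreting fixtures: for two parallel right-handed helices the 29→37
chord on each helix surface carries a fixed tangential component, so a
Gly-in dimer (both markers at the interface) has an inherent φ offset of
about +25° even at zero axis-crossing angle.  At marker phase 90° the
offset vanishes by symmetry, and there the measured φ tracks the
constructed axis-crossing angle in both sign and magnitude; handedness
tests are therefore run at the symmetric phase.

**Distance maps.** Entry (i, j) is the average of d(i on A, j on B) and
d(j on A, i on B), making the matrix symmetric and chain-relabelling
invariant.  Missing residues mask their entries with NaN and a warning.

## Hydrogen bonds and helicity

The distance is hydrogen-to-acceptor and the angle is
donor–hydrogen–acceptor for *both* criteria — a 2.5 Å cutoff is only
physical for an H⋯O distance, and the same reading is applied to the
3.5 Å aliphatic criterion for consistency.  Explicit hydrogens are
required; their absence is an error instructing explicit-hydrogen input,
not a silent skip.  Any Cα hydrogen qualifies as an aliphatic donor
(glycine contributes both).

Propensity maps count a (donor residue, acceptor residue) pair at most
once per frame regardless of how many atom pairs qualify, normalized by
total frames.  Inter-chain maps cover dimer-interface bonds; intra-chain
bonds feed fractional helicity, where residue i is helical in a frame when
it participates (either role) in a backbone bond to i±3, 4 or 5.  The
detector is a dense vectorized pair scan — fixture- and trajectory-scale
systems make spatial hashing unnecessary — and is verified identical to an
exhaustive O(n²) loop on every fixture.

## Number densities

Bin k of a profile holds the mean per-frame count of target atoms at
minimum-image distance r ∈ [k·w, (k+1)·w) from the single reference atom
(default: the G33 Cα of peptide A), divided by the exact shell volume
(4π/3)((k+1)³−k³)w³.  Counts are averaged over frames before dividing,
which with fixed bins equals averaging densities.  Defaults: bin width
0.5 Å, r_max 30 Å (capped at half the shortest box extent), plateau window
the outer third of the profile.  A plateau whose relative SD exceeds 25 %
is flagged non-plateau.  Molarity conversion is ρ × 10²⁷/N_A; 0.033 Å⁻³ ↔
54.8 ≈ 55 mol/L.  The first-peak locator returns the centre of the first
local-maximum bin in the search range, or none for monotone profiles.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *geometry and bookkeeping* of the target
systems, none of the physics — no energies, no dynamics, no side chains
beyond backbone atoms.

* **Micelles**: head beads on a Fibonacci sphere lattice (quasi-uniform
  without rejection sampling) of radius r_head, tails on inward radial
  segments down to a 2 Å core, optional Gaussian jitter.  With zero jitter
  the head-shell point set has R_g exactly r_head (points on a sphere
  centred at their centroid), a closed-form anchor for the R_g operators.
* **Assembly boxes**: micelle centres on a shuffled cubic grid with
  spacing 2·max(r_head) + 12 Å clearance; free monomers placed uniformly
  with rejection (bounded retries, then a placement error); solvent
  uniform.  Ground-truth membership, classes and free monomers are
  returned alongside the configuration.  The reference composition (5
  dimer micelles of 69, 4 empty of 42) mirrors the class structure of a
  500-surfactant/5-dimer self-assembly at 50 surfactants per peptide.
* **Helices**: backbone atom offsets relative to Cα are extracted once
  from a canonical α-helix built by internal coordinates (φ = −57.8°,
  ψ = −47.0°, standard bond geometry, carbonyl O anti to the next amide N,
  amide H on the N–Cα/N–C bisector at 1.01 Å) and re-laid onto any
  (rise, twist, radius) helix.  At the defaults (1.5 Å, 100°, 2.3 Å) the
  i→i+4 H⋯O geometry is ≈1.9 Å at ≈162°, comfortably inside the backbone
  criterion; a 3.5 Å/180° "extended" parameterization has no backbone
  contacts at all.
* **Dimers**: two helices at a stated axis-crossing angle and closest
  approach; each helix is rolled so the G33 radial direction makes the
  requested angle with the partner direction (0° Gly-in, 180° Gly-out).
  Crossing is applied symmetrically about the connection axis; negative
  crossing constructs a right-handed pairing.
* **Kinetics**: replicate micelle counts
  nᵢ(t) = round(N_eq + (N0ᵢ − N_eq)e^(−t/τ)) + U{−a..a}, floored at zero,
  with per-replicate initial counts N0ᵢ = N0 + U{−5..5}.  The initial
  spread emulates random starting configurations assembling different
  numbers of early aggregates; it is what makes the ergodic measure decay
  (from ≈ Var(N0ᵢ) + noise floor down to the noise floor, an expected
  ≈16× drop for the defaults) rather than sit flat at the noise variance.
  Zero spread and zero noise give identical replicates and Ω ≡ 0.
* **Bulk solvent**: Poisson-uniform points at a stated number density
  (default anchor 0.033 Å⁻³, bulk water oxygen).

Every generator is deterministic given (spec, seed); per-replicate and
per-micelle streams derive from the master seed via spawn keys, so
enlarging a set never perturbs existing members.

Because the generators are geometric, passing tests demonstrate that the
*analysis* is correct on known ground truth — they say nothing about
force-field accuracy, sampling convergence of real MD, or the physical
values of s\* and R_g, which must come from real trajectories.

## Problem sizes

The shipped tests and the acceptance script run the census on a ~6 700
particle box, 20-seed Monte-Carlo checks for the density plateau and the
ergodic decay, 50 randomized dimers for handedness, and 100 random point
sets for the R_g identity; the whole suite completes in seconds.  The same
code paths scale to production trajectories (the clustering uses a k-d
tree with periodic boxes; per-frame cost is near-linear in bead count).

## Known limitations

* Single-linkage clustering can bridge transiently touching micelles into
  one component for frames where shells overlap within the cutoff; the
  census reports what the contact graph supports, and fusion/fission
  kinetics are out of scope.
* The triclinic minimum-image search covers ±1 lattice translations after
  fractional reduction, exact for points within about one cell; extremely
  skewed cells should be reduced first.
* Hydrogen-bond detection requires explicit hydrogens; no heavy-atom-only
  inference is attempted.
* No DSSP-style secondary structure, no Crick parameterization beyond the
  single-residue angle, no shape descriptors beyond R_g, and no
  bulk-normalized g(r).
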