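# Methods

This note documents the models and procedures implemented in `ruvmotor`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## The system

A branch-migration complex consists of a RuvA–Holliday-junction core flanked
by two homo-hexameric RuvB AAA+ motors.  Each motor encircles one emerging
DNA duplex; four of its six subunits (A–D) grip the phosphate backbone of a
single strand through conserved head-domain arginines, forming an asymmetric
spiral staircase, while the remaining two (E, F) close the ring without
touching DNA.  RuvA domain III (RuvA^D3) tethers the motor to the core: one
copy rides subunit D throughout the cycle, a second binds subunit E during
the productive states.  A subunit has three rigid bodies: the large ATPase
domain (residues 21–181), the small ATPase domain (182–254) and the DNA-
binding head (255–330); nucleotides bind at subunit interfaces, clamped by
the *cis* subunit's Walker-A motif (Lys65).

## Decomposition

Chains are mapped to subunit labels either by a user manifest (authoritative
when present) or inferred: the four chains with head-arginine–phosphate
contacts (heavy-atom cutoff 4.0 Å, a standard salt-bridge distance) are
labelled A–D by descending height along the motor axis; the two contact-free
chains become E (ring-adjacent to D) and F (adjacent to A).  Positional
conformational clusters [A]–[F] are always recomputed from geometry with the
same rule, so a manifest that deliberately maps a rotated state still gets
meaningful cluster labels.

**Motor axis.**  With DNA present the pore axis is the principal axis of the
DNA phosphate trace, oriented so the DNA exit side is positive; the
translocating strand runs straight through the pore, making this the
best-conditioned estimate of the motor frame.  The minimum-variance axis of
the six large-domain centroids is the fallback without DNA; for a spiral
staircase the centroid heights correlate with azimuth, which measurably
tilts that six-point estimate — the reason the DNA-derived axis is
preferred.

**Occupancy.**  A nucleotide (component codes AGS/ATP → ATP, ADP → ADP)
whose centroid lies within 12 Å of the *cis* subunit's Lys65 Cα fills that
pocket; the generous, *cis*-anchored cutoff is unambiguous because
neighbouring pockets are ≈30 Å apart, and two nucleotides inside one cutoff
raise an explicit ambiguity error.  A Mg²⁺ ion within 3.5 Å of the
nucleotide's phosphates upgrades ADP to ADP·Mg.  Absence of a modelled
nucleotide is reported as apo — occupancy is read from coordinates only,
never estimated from density.  Ligand occupancy factors are carried through
verbatim and never thresholded.

## Angle fingerprints

The anchor-residue lists defining the inter-domain angles are fixed: large
{36, 73, 80, 174, 55, 155, 170, 94, 121}, small {249, 227, 209, 196}, head
{282, 284, 265, 306, 263}; triangle ranges 20–180 / 181–256 / 257–325.
Four-point torsions require a documented split of each list into two
sub-centroids:

* *d*₁ = torsion over (c{36,73,80,174}, c{55,155,170,94,121}, c{249,227},
  c{209,196});
* *d*₂ = torsion over (c{249,227}, c{209,196}, c{282,284,265}, c{306,263});
* triangle = angle at the small-domain centroid (the middle domain
  connecting large and head — the only vertex choice that measures
  large/head scissoring about the hinge) between directions to the large-
  and head-domain centroids.

Absolute values of *d*₁/*d*₂ depend on this construction; analyses should
rely on differences (dynamic ranges) across states, which are robust to any
consistent choice.  Dihedrals follow the IUPAC sign convention in
(−180°, 180°], cross-checked in the test suite against two independent
constructions and against biotite/MDAnalysis.

## Variability, RMSD statistics, displacement

The variability map superposes every model on a reference subunit (default
C, the most invariant staircase position) and reports, per Cα, the RMS
distance from its across-states mean position — the standard deviation of
the atom's position about its centroid.  For two states this reduces to
half the displacement; for isotropic Gaussian noise of width σ over *n*
models it follows σ·E[χ₍₃₍ₙ₋₁₎₎]/√n, which the tests verify.

Domain RMSD statistics superpose every pair of subunit instances (e.g. the
42 subunits of seven states) within one domain's Cα range and report the
pairwise matrix and its mean.  Superposition is an in-package Kabsch SVD
with the reflection branch folded back (proper rotations only); collinear
point sets are rejected as degenerate.

Displacement fields store Cα-to-Cα vectors between two states aligned on a
chosen subunit, keeping vectors above a 1.0 Å filter.  The rendering
conventions — draw every other vector, multiply arrow lengths by 2.5 — are
applied only when exporting BILD arrow files; stored magnitudes are never
scaled.

## Trajectory, lever, rotation, contacts, gate

* **Cluster-[E] trajectory**: states aligned on subunit C; the tracked point
  is the full-subunit Cα centroid of whichever subunit occupies cluster [E]
  in each state.  Both the summed path length and the net first-to-last
  displacement are reported, since the two coincide only for a straight
  path.  State order comes from the manifest, never from inference.
* **Lever lift**: states aligned on converter subunit E (the fulcrum); the
  lift is the signed displacement of the DNA-phosphorus centroid (or the
  engaged head-domain centroid) along the motor axis between first and last
  state, positive toward the DNA exit.
* **Motor rotation**: two states superposed on a shared core reference; the
  rotation is the circular mean of the azimuthal shifts of the six
  large-domain centroids about the pore axis.  A core-superposition RMSD
  above 2 Å flags the result.  A thin DNA segment poorly constrains
  rotation about its own axis, so an azimuthally extended core (the
  RuvA–junction core in real data, the generated core disc in synthetic
  data) should be used as the reference.
* **DNA contacts**: arginine guanidinium nitrogens (Cζ, then Cα as
  fallbacks) within 4.0 Å of backbone phosphate/phosphate-oxygen atoms; the
  spacing is the mean axial distance between contacted-phosphate centroids
  of consecutive staircase subunits.
* **Gate distance**: cis-Arg21 Cζ to trans-Glu128 Cδ of the pocket formed
  with the *trans* neighbour (the pocket of subunit A interfaces with F),
  with a flagged Cα–Cα fallback when side chains are unmodelled.

All metrics are built from relative geometry and are invariant under a
common rigid transform of their inputs (property-tested).

## Nucleotide-cycle state machine

The cycle is modelled as deterministic and sequential — the event order is
established structurally, so no rates, thermodynamics or stochasticity are
introduced.  Hydrolysis is two sub-events matching the observed occupancy
series (γ-phosphate cleavage s2→s3, Mg²⁺ release s3→s4); ATP is counted as
hydrolysed at the cleavage step.  The s5→s1′ cluster switch relabels every
subunit's chemistry to its successor position (A→F, B→A, …), increments the
register, advances the DNA by two nucleotides and rotates the motor by 60°.
RuvA^D3 re-binding after a switch is instantaneous by default (a latency
parameter exists, default 0).  The priming of subunit E for its later ADP
release (its N terminus folding away during s4→s5) is logged as an
annotation on the event, not as an event of its own, since it belongs to
the next cycle's chemistry.

Out-of-register initiation patterns (four or five ATP) are resolved to the
cycle entry pattern by forward-only single-pocket chemistry
(ATP→ADP·Mg→ADP→apo→ATP); the returned event list is shortest, with
subunits resolved converter-first (F, E, D, C, B, A) — matching the
observation that the early five-ATP state resolves by hydrolysis in
subunit F.

## Synthetic assembly generator

The generator emulates, at Cα/phosphorus resolution, exactly the features
the metrics consume:

* **Ideal B-DNA**: two antiparallel strands with per-nucleotide P and
  base-centroid pseudo-atoms on a helix with rise 3.4 Å/bp and twist 36°/bp
  (canonical fibre values; both are parameters, with sanity bounds 2–4 Å and
  20–45°).  The backbone radius defaults to 1.0 Å — a deliberately thin
  helix, so that the through-space P(i)→P(i+2) distance,
  √((2·rise)² + (2·r·sin twist)²) = 6.90 Å, matches the ≈7 Å two-nucleotide
  contact period of the staircase.  This coarse backbone is *not* at the
  crystallographic phosphate radius (~9.4 Å); only axial geometry and
  contact bookkeeping are meaningful, not groove geometry.
* **Hexamer**: one fixed rigid subunit template (pseudo-Cα for residues
  1–330 in three domain clouds, plus gate and contact pseudo-atoms and
  single-atom nucleotide ligands with authentic component codes), placed at
  60° azimuthal spacing on a 32 Å ring; A–D follow the DNA contacts (every
  2 nt, 7 Å staircase rise), E and F close the ring below D and above A.
  RuvA^D3 tethers are 5-atom blobs docked within contact distance of
  subunits D and E (one tether in the first state, two thereafter — the
  deposited series' stoichiometry).
* **Programmed motions** (all recorded as ground truth before noise):
  a per-transition lift of DNA + staircase along the axis (default series
  use 1.75 Å × 4 transitions = 7.0 Å, the power stroke); a per-transition
  step of subunit E (default toward the core, emulating the converter
  trajectory); arbitrary per-domain rigid poses, with helpers that rotate
  about the *d*₁/*d*₂ torsion axes so the programmed angle change is exact;
  and a whole-motor rotation for rotation pairs, which also carry an
  azimuthally extended core-reference disc.
* **Noise**: isotropic Gaussian per atom, applied after all rigid motions,
  seeded; a fixed seed reproduces coordinates bit-for-bit.

What passing tests on synthetic data do **not** show: real cryo-EM models
have sequence-dependent side chains, partial occupancies, missing residues,
correlated (not isotropic) coordinate error, flexible rather than rigid
domains, and a genuine four-way junction core.  The generator makes no
attempt at these; it validates the geometry and bookkeeping of the
analysis, not its robustness to modelling artefacts.

## Numerical conventions and degenerate inputs

Angles in degrees, distances in Å throughout.  Angles are reported in
(−180°, 180°]; azimuths are measured in a deterministic frame derived from
the axis.  Rigid transforms are validated to 1e-8 orthonormality; Kabsch
rejects <3 points or collinear sets; dihedrals reject coincident or
collinear consecutive points; a point on the rotation axis is an error
naming the point.  Operations that need residues fail loudly listing the
gaps — no silent imputation.  Alternate conformers collapse on read to the
highest-occupancy conformer (ties by altloc order); repeated atom records
without altlocs are parse errors.  Residue numbering is 1-based with
inclusive ranges, taken verbatim from the source file.  Reports round
angles to 0.1° and distances to 0.01 Å; machine-readable tables keep full
precision under a `# units:` header line.

Problem sizes in the shipped analyses are deliberately compact: 40-bp DNA,
five-state series, ~2200 atoms per state — the closed-form and
ground-truth checks do not benefit from larger systems.

## Known limitations

* Occupancy requires modelled ligands; density-level evidence (partial
  occupancy, ordered waters) is out of scope.
* Absolute *d*₁/*d*₂/triangle values are construction-dependent (see above);
  only state-to-state differences should be compared across software.
* Subunit labelling assumes exactly four DNA-engaged subunits; unusual
  states need an explicit manifest mapping.
* The cycle model is a bookkeeping machine: it orders events and counts
  ATP/nucleotides but carries no kinetics and cannot represent off-pathway
  or partially occupied states beyond the supported initiation patterns.
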