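# Methods

This note documents the models and numerical choices behind `parapore`, in
the order a user meets them: the data model, the synthetic system, and each
analysis. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

All coordinates are in Å, times in ns. The pore axis is +x by convention
(every geometry operation takes the axis as a parameter defaulting to +x);
the membrane normal is z. Frames must be uniformly spaced in time
(tolerance 10⁻⁶ ns) — every time statistic in the package is a per-frame
fraction, and uniform spacing is what makes frame fractions equal to time
fractions. Non-uniform trajectories are rejected rather than silently
reweighted.

van der Waals radii come from a Bondi-style element table (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, H 1.20 Å; monatomic ions by element, e.g. Na 2.27,
Cl 1.75). Unknown elements fall back to 1.70 Å with a logged warning. The
geometry read-outs (pore profile, SASA) only require the radius set to be
internally consistent; Bondi is also close to the default set of the
classic pore-dimension programs. Formal charges are residue-level
(Arg/Lys +1, Asp/Glu −1, His neutral at simulated pH, termini ignored;
Na⁺/Cl⁻/K⁺ ions by residue name) and are attached to one conventional
side-chain atom so that residue sums are exact.

PDB I/O (single- and multi-MODEL, wwPDB v3.3 columns) is delegated to
biotite; a line-by-line pre-scan supplies format errors with line numbers
and per-MODEL atom counts before parsing. altLoc entries other than ''/'A'
are dropped. The internal frame-table format is a plain CSV
(`frame,time_ns,atom_id,x,y,z`, 6-decimal coordinates) that round-trips
bit-exactly at that precision; PDB round-trips are exact to the format's
10⁻³ Å printed precision.

## Synthetic toy-pore system

The generator emulates the *statistical* structure of an applied-field
permeation simulation, not its physics: no forces, water, lipids or
electrostatics, and no attempt at absolute conductances.

**Scaffold.** Pseudo-atoms of radius *a* (default 1.5 Å) on a cylindrical
shell of radius *R + a* spanning x ∈ [−L/2, +L/2] (defaults R = 5 Å,
L = 60 Å), so the maximal inscribed sphere along the axis has radius
exactly *R*. Ring spacing (1 Å axial; angular count ⌈2π(R+a)/a⌉) is
validated so no probe of radius *a* can slip through the wall; sparser
spacings raise a geometry error. Optional constriction rings place atom
centres at a chosen radius and station (inscribed radius = ring radius −
*a*). Marker residues: four single-atom `BNK` residues at x = 0, 90°
apart on the shell (their centre of geometry is exactly the origin — the
bottleneck tetrad), and four `ENT` residues with a Cα at each pore end at
the corners of a box slightly wider (R + 1 Å) than the pore radius, so
every in-pore ion is strictly inside the cuboid in y/z. Scaffold atoms
carry their construction radius directly; after a PDB round-trip radii are
re-derived from the element table, so profile analyses of re-read files
use element radii (documented, intentional). Transport-only runs can omit
the shell (`scaffold=False`): radial containment is enforced by the walk
parameters, not by the atoms, and no transport statistic reads the shell.

**Ion walk.** Two species (`NA`, `CL`), default 20 ions each,
initialised uniformly in the cylinder. Per frame each ion takes an
isotropic Gaussian step (σ = 0.2 Å/frame default) plus a species drift
along x. The radial wall at *R* reflects (fold-back); the axial boundary
at ±(L/2 + 5 Å) wraps to the opposite end with explicit offset
bookkeeping, so a stationary steady-state flux exists, the mean in-pore
ion count is stationary, and displacement statistics can use the unwrapped
coordinate exactly. The ion-leakage pathway that complicates real
periodic-box junction simulations is deliberately absent — that is the
point of the synthetic control. All randomness comes from a single seeded
`numpy` Generator in a fixed draw order (initial positions species by
species, then one (n_ions, 3) normal block per frame), so runs are
bit-reproducible.

**Voltage presets.** Charge selectivity is modelled as species-dependent
drift only: drift = mobility × voltage, with mobility 0.25 Å frame⁻¹ V⁻¹.
This calibration makes the canonical 0.4 V condition produce the reference
drift of 0.1 Å/frame used by the drift-recovery checks, and keeps 1.4 V
runs (drift 0.35 Å/frame) well below the wrap-detection limit of half the
axial period per frame. `anion-selective` drifts only Cl⁻,
`cation-selective` only Na⁺, and `nonselective` drifts both identically —
the null control for selectivity fits. The study voltages are
±0.4, ±0.8 and ±1.4 V.

What passing tests on this system do **not** show: correct handling of
explicit electrostatics, ion–ion correlation, water friction, or
non-straight pore axes. They do show that every counting rule, filter,
sum and regression in the analysis layer is implemented exactly.

## Contact maps

Entry (i, j) is the mean, over every window frame and every interface pair
of the group, of the minimum atom–atom distance between residue i of
region A and residue j of region B. "Closest atoms" includes hydrogens
when present. The average is a single flat mean over (frame × interface)
samples, which equals the mean of interface means whenever sample counts
are balanced (they are, by construction of an interface group). Contact
classification is strictly `< threshold` (default 5 Å), so a mean distance
of exactly 5 Å is not a contact. The default analysis window everywhere is
the last half of the trajectory (`"last:0.5"`), the conventional
production-window choice.

## Interface metrics

**Hydrogen bonds.** The criterion is an explicit parameter because
published analyses rarely state the defaults of the suite they used. With
explicit hydrogens: donor–acceptor (N…O) distance ≤ 3.5 Å and D–H…A angle
≥ 120°. Heavy-atom-only fallback (the default, since typical inputs here
are heavy-atom models): N…O ≤ 3.5 Å and C(=O)…N angle at the acceptor
≥ 100°. Both directions between the two segments are counted.

**Persistence counts.** A pair "interacts" in a frame iff the minimum
distance between the two selections is ≤ 4.0 Å — the same cutoff used for
ion contacts — and a pair is counted iff its interacting fraction is
strictly above the 0.35 threshold. For electrostatic-interaction counting
the selections should be restricted to the charged-group heavy atoms
(Arg NE/NH1/NH2, Lys NZ, Asp OD1/OD2, Glu OE1/OE2; table provided), with
backbone O/N added when main-chain contacts are to be included.

**SASA.** Shrake–Rupley quadrature on a deterministic Fibonacci-sphere
lattice (default 960 points/atom; < 16 rejected). Per-atom area =
exposed-point fraction × 4π(r_vdw + probe)², probe 1.4 Å; all atoms
occlude, selected or not. Per-residue areas are also reported normalised
by the side-chain heavy-atom count — a residue-size proxy appropriate for
heavy-atom models (hydrogens excluded from the divisor by the same
reasoning as the H-bond default). The quadrature was checked against a
seeded 10⁵-point Monte-Carlo integrator on two-sphere geometries (2 %
agreement) and against the analytic isolated sphere (1 %).

**RMSD.** Optimal rigid superposition uses the Kabsch algorithm via
`scipy.spatial.transform.Rotation.align_vectors` after centring; RMSD is
rssd/√n. Superposition needs ≥ 3 atoms. A cross-check against
MDAnalysis' implementation is part of the test suite.

## Pore profile

At each station x₀ the profiler maximises
`radius(c) = min over atoms (|c − atom| − r_vdw)` over centres c in the
plane through x₀ perpendicular to the axis, by coarse grid search
(0.25 Å default) over a lateral disc (search bound default 15 Å) followed
by a 2-D Nelder–Mead polish (tolerance 0.01 Å) constrained to the disc.
Atoms further than 10 Å along the axis are excluded from the minimum —
they cannot bind an inscribed sphere of pore-scale radius. Negative
maxima are reported as-is with a `blocked` flag; stations with no atoms in
range are masked. Per-station independent maximisation (rather than the
connected Monte-Carlo walk of the original pore-dimension program) is
deterministic and adequate for near-straight paracellular pores whose axis
is known and supplied; this divergence is intentional. Profiles report
mean ± SD of the diameter (2 × radius) over the window.

## Ion transport

**Crossing plane.** The bottleneck tetrad's centre is the *unweighted
centre of geometry* of its atoms, evaluated per frame (the tetrad may
drift); mass weighting is an option flag, the difference being negligible
for symmetric tetrads. The tetrad must resolve to exactly four residues.

**Cuboid.** Per-axis min/max of the window-averaged positions of the
eight entrance Cα atoms (four per end). Membership is strict in y and z
and closed in x; the x faces are where ions legitimately enter and leave,
while the y/z faces separate pore from leak paths.

**Crossing detection.** An ion is selected iff at some consecutive window
frames t, t+1 the sign of (x_ion − x_COM) changes and the ion is inside
the cuboid at both frames. One record per ion — the first crossing — so an
ion oscillating across the plane is never double-counted: the displacement
formula sums each selected ion's full-window increments, and duplicating
ions would duplicate displacement. A `require_inside="always"` flag
implements the stricter whole-window-membership reading; the at-crossing
rule is the default because the cuboid's job is to certify *where* the
crossing happened. The cuboid test also suppresses spurious sign flips
from axial wrapping, since wrapped ions are outside the x bounds at the
wrap step.

**Total displacement.** D = Σᵢ Σₜ (xᵢ(t+1) − xᵢ(t)) over the selected
ions on the *unwrapped* axis coordinate; by telescoping this equals
Σᵢ (xᵢ(end) − xᵢ(start)) exactly, which is asserted to machine precision
as an invariant. Unwrapping preference order: explicit wrap bookkeeping
(synthetic runs) → minimum-image continuity with the box length (valid
when per-frame steps are below half the period) → raw coordinates.

**Mean ion count and contact time.** Mean over window frames of the number
of species ions strictly inside the cuboid; per-residue ion contact time is
the percentage of frames with minimum atom–ion distance strictly below
4 Å, averaged over the subunit copies of the residue.

**Selectivity regression.** Per-species ordinary least squares of D
against voltage (`scipy.stats.linregress`), requiring ≥ 2 distinct
voltages; slope (Å/V), intercept, R² and the slope standard error are
reported. The null check compares the two species' slopes in units of
their combined standard error.

## Charge fingerprint

Net pore charge = Σ over non-shielded listed residues of
formal_charge × multiplicity, with multiplicity 4 encoding the tetrameric
pore scaffold (residues contributed by interlocking neighbours also appear
four times per pore). Histidine is neutral at simulated pH. Shielded
residues — those whose charge is neutralised by persistent salt-bridge
partners — are excluded from the sum but listed in the ladder with zero
contribution. The built-in CLDN10a and CLDN10b linings evaluate to +8 e
and −12 e respectively.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic systems
chosen at desk scale: 1000-frame, 40-ion walks for transport statistics
(30 runs per selectivity fit: six voltages × five seeds), 100 short random
trajectories for the telescoping identity, single-frame cylinders of
~1700 shell atoms for the profiler, and toy oligomers (5 chains × 10
residues × 5 frames) for the brute-force oracle comparisons. These sizes
make every property sharp (analytic expectations, 4σ bands) while keeping
the whole suite around fifteen seconds. All stochastic checks are seeded;
the acceptance script derives every seed from its `--seed` argument.

## Known limitations

* The pore axis must be (approximately) straight and known; there is no
  curved-axis pathfinding and no pore-surface rendering.
* No binary trajectory formats (DCD/XTC) or MD-engine topology formats in
  the core; inputs are PDB or the documented frame-table CSV.
* H-bond and "interaction" definitions are geometric conventions exposed
  as parameters, not reproductions of any specific analysis suite's
  defaults.
* The synthetic generator's charge selectivity is kinematic (drift), not
  electrostatic; absolute currents/conductances are out of scope.
* Poisson–Boltzmann surface potentials and secondary-structure assignment
  are out of scope.
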