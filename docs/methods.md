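# Methods

## The zipper model

The system modelled is a minimal steric-zipper oligomer of the
six-residue peptide VEALYL: up to six strands in two β-sheets, strands
1–3 forming sheet 1 and strands 4–6 sheet 2.  That numbering is not
arbitrary: the canonical pair lists — interstrand 1–2, 2–3, 4–5, 5–6 and
intersheet 1–4, 1–5, 2–5, 2–6, 3–6 — admit exactly one two-colouring of
strands into sheets under which every interstrand pair lies within one
sheet and every intersheet pair spans both, and it is this one.
Sub-oligomers ("m-n" schemes) are restrictions of the hexamer; because
the source of each scheme's strand selection is underdetermined (removing
an edge strand is not the same as removing a central one), the defaults
keep strands {1,2,3} of sheet 1 first (3-0 → {1,2,3}; 2-1 → {1,2,4};
2-2 → {1,2,4,5}; 3-1 → {1,2,3,4}; 3-2 → {1,2,3,4,5}; 2-0 → {1,2};
1-1 → {1,4}) and every operation accepts an explicit selection override.

Glycine mutants (V1G … L6G, A3GL4G) are built by side-chain truncation:
all atoms beyond the backbone N, Cα, C, O (keeping backbone hydrogens
where present) are deleted and the residue renamed GLY.  No rotamer
search is needed or performed, and the operation is idempotent.

## Analysis operators

**Superposition.** RMSD and RMSF use a least-squares rigid fit (Kabsch,
SVD form with the determinant sign correction, so reflections are never
returned).  Collinear selections are rejected rather than silently fit.
The test suite cross-checks the fit against an independent quaternion
(Kearsley) eigenvalue oracle to 1e-6 Å.

**RMSD / RMSF.** Per-frame Cα RMSD is measured against the initial
(native) structure after per-frame superposition on all Cα atoms.  RMSF
is reported per residue per chain; the reference is the initial
structure by default, with the post-fit ensemble mean available via
`reference_mode="mean"`.  For a noise-only ensemble with isotropic
per-atom displacement σ and no superposition, RMSF → σ√3; this closed
form anchors the estimator tests.

**Hydrogen bonds.** Distance-only criterion: two polar heavy atoms (N or
O) on *different strands* strictly closer than 3.5 Å.  Donor/acceptor
roles and angles are deliberately not modelled — the populations this
feeds are cutoff statistics, not energetics.  Detection uses a k-d tree;
correctness is pinned to an O(n²) all-pairs oracle in the tests.

**Native contacts and Q_f.** A native contact joins the side-chain
centers of mass (heavy atoms only, mass-weighted; glycine falls back to
Cα) of two residues that are not sequence-adjacent within a chain, at a
distance strictly below 6.5 Å in the native structure.  The analysis
tradition this implements quotes both 6.5 Å (general) and 6.0 Å
(intersheet); the default is 6.5 Å everywhere with an optional
per-class `intersheet_cutoff` override, and each record carries the
cutoff it was detected with, which Q_f then reuses per contact.
Contacts are classified interstrand/intersheet through the topology pair
lists; same-strand nonadjacent contacts are kept as `intrastrand` but
belong to neither class.  Q_f of a frame is the fraction of native
contacts whose current COM distance is below their cutoff.

**Distances.** The interstrand distance averages Cα–Cα distances of
register-paired residues over the topology's interstrand pairs
(i↔i for parallel neighbours, i↔7−i for antiparallel ones, from the
strand direction flags); the intersheet distance is the distance between
the unweighted Cα centroids of the two sheets.  Topologies lacking the
relevant pairs (1-1 has no interstrand pair; 3-0 and 2-0 no second
sheet) return NaN as the explicit not-applicable marker.

**Populations and per-residue averages.** Populations pool frames over
all supplied trajectories with equal frame weight, after discarding a
configurable leading burn-in fraction (default 0; the underlying
simulation practice discarded the first 15 ns of 20 ns runs, i.e. this
is a knob, not a constant).  An interaction is *stable* when its
population strictly exceeds 0.40.  The per-residue average credits each
endpoint of each present interaction to its residue position (so a
1–1 cross-strand contact adds two participations to position 1),
time-averages, and divides by the number of peptides.

**Stability rule.** A run is unstable when the summary statistic of its
post-burn-in Cα RMSD window strictly exceeds 5 Å.  The default statistic
is the mean — runs are classified by their plateau (stable zippers sit
near 2.5 Å, disordered ones near 20 Å) — with `max` available as a
stricter option.  The rule is monotone: raising every RMSD value can
never flip unstable to stable.  The oligomer comparison labels the
schemes that pass the rule, ordered by size, as candidate
intermediates; this is descriptive bookkeeping, not a kinetic model.
MM-PBSA free energies enter only as externally supplied means;
`relative_energy(a, b) = a − b`.

## The synthetic ensemble generator

The generator exists to give the estimators input with known ground
truth, not to simulate physics.  The ideal builder places Cα traces in
extended conformation (3.5 Å step) with strands stacked at 4.8 Å inside
each sheet and the sheets 10 Å apart — the cross-β repeat and dry-
interface scale of steric zippers — plus backbone N/C/O placed so that
stacked strands form sub-3.5 Å N···O pairs, and one side-chain
pseudo-atom per non-Gly residue carrying the full side-chain mass,
alternating above/below the strand (β pleat) with the two sheets facing
each other.  Because strands are exact translates, the interstrand and
intersheet metrics recover the builder parameters exactly, which the
construction-recovery tests exploit.

Default stacking is parallel in-register; antiparallel stacking
(alternating strand direction with stacking level, as in the real
VEALYL crystal zipper) is available via `ZipperGeometry.antiparallel`
and the topology's direction flags.  The parallel default keeps the
register pairing and pleat geometry maximally transparent in an
idealized stand-in that makes no claim of reproducing the crystal
packing.

On top of the ideal coordinates the generator applies, per frame at
linear progress f ∈ [0, 1]:

- i.i.d. isotropic Gaussian displacement per atom with residue-dependent
  σ.  Defaults (0.4, 0.25, 0.2, 0.2, 0.25, 0.4) Å give RMSF ≈ 0.35 Å in
  the core rising to ≈ 0.7 Å at the termini, the termini-heavy
  fluctuation pattern of a stable zipper.  The noise has no temporal
  autocorrelation; it validates estimators, and passing tests say
  nothing about force-field realism, solvent effects, or correlated
  motions in real trajectories.
- rigid drift f·v for each "expelled" strand (a disaggregation event).
  The default disaggregation scenario drifts an edge strand 30 Å along
  the stacking axis (plus 10 Å out of plane) — translating one strand of
  a hexamer by d can raise the post-fit RMSD by at most
  √(w(1−w))·d ≈ 0.37·d, so tens of Å of drift are what genuinely
  disordered runs (plateauing near 20 Å RMSD) correspond to.
- a linear sheet-spacing ramp: sheet 2 shifts by f·Δ along the sheet
  axis, so the final-frame intersheet distance is exactly
  spacing + Δ in the noise-free case (mutant-like compression or
  expansion).
- per-strand twist: rotation about the stacking axis through the
  strand's own Cα centroid by f · angle · (stacking level), leaving the
  level-0 strand fixed and moving termini more than cores.

A run is 200 frames at 0.1 ns spacing by default — one 20 ns trajectory
saved every 0.1 ns.  Randomness is a single seed expanded into one
child stream per frame (`numpy` `SeedSequence.spawn`), so trajectories
are bit-reproducible and any single frame can be regenerated in
isolation.  With n_frames = 1 the progress f is defined as 0 (the frame
is the unperturbed input).

## Numerical and I/O choices

- Coordinates are Å throughout; chain order in a PDB file defines the
  1-based strand index; multi-MODEL PDB is the trajectory format, read
  and written via biotite.  MODEL blocks with inconsistent atom counts
  are rejected.  PDB stores three decimals, so round trips are exact to
  1e-3 Å; element-derived masses are reassigned on read (the builder's
  pseudo-atom masses are not persisted by the format).
- Side-chain COM uses heavy atoms only — robust to crystal-derived
  files without hydrogens; including hydrogens would shift COMs by
  ~0.1 Å, inside the slack of the 6.5 Å cutoff.
- All cutoff comparisons are strict (<, and > 0.40 for population
  stability, > 5 Å for instability), so boundary values fall on the
  conservative side: a contact at exactly the cutoff is absent, a run at
  exactly 5 Å is stable.
- Degenerate inputs fail loudly: empty RMSD series, empty native-contact
  lists, missing Cα atoms, mismatched selections and collinear
  superposition targets all raise with the offending item named.

## Problem sizes

Test ensembles use 6-strand, 180-atom structures with 20–200 frames
(2000 frames where a sampling-law tolerance of a few percent is being
asserted); oracle-equivalence checks run 100 randomized fixtures of at
most 300 atoms.  These sizes make every statistical tolerance in the
suite a consequence of the stated sampling laws rather than of tuning.

## Known limitations

- The generator's noise model is white in time; population estimates on
  real (autocorrelated) trajectories have larger effective error bars
  than the binomial law used in the tests.
- Hydrogen bonds ignore geometry beyond distance; DSSP-style secondary
  structure, angle-dependent H-bond definitions and free-energy surfaces
  are out of scope, as is running molecular dynamics or the MM-PBSA
  solver itself.
- The candidate-intermediate ordering is purely stability-based; no
  kinetic pathway is computed.
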