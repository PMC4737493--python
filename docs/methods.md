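# Methods

This note documents the models, conventions and numerical choices behind
`gsmech`, in the spirit of a package's own methods appendix. Everything
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## Scope and data model

The package analyzes replicated conformational ensembles of a protein
system: a shared `Topology` (atom names, elements, 1-based residue serials,
chains, optional partial charges, optional orthorhombic box) and, per
replicate, an `(n_frames, n_atoms, 3)` coordinate array in Ångström with a
fixed frame interval (default 20 ps). Three independent replicates is the
default study design: every summary statistic treats each replicate's mean
as one observation and reports grand mean ± SEM over replicates.
Replicate-mean comparisons use the two-sided Student t-test; stability-map
comparisons use the Welch test; relative binding energies are tested against
zero with a one-sample t-test. Analyses default to discarding the leading
20% of frames as equilibration (configurable).

Multi-model PDB I/O is delegated to biotite behind the package's own
containers; element symbols falling back from the atom name when the element
columns are blank, altloc A kept with a warning, and hybrid-36 serials used
above 99 999 atoms. Waters are recognized by residue name
({HOH, WAT, TIP3, SOL}, configurable).

## Hydrogen-bond criteria

Strong: heavy-atom donor–acceptor distance ≤ 2.8 Å; weak: ≤ 3.2 Å; both
require a donor–H–acceptor angle ≥ 120°. The distance is read as the
heavy-atom separation (the angle criterion is what involves the hydrogen).
Distance and angle cutoffs are inclusive, with a 10⁻⁹ Å/degree slack so a
pair constructed exactly on the boundary is not lost to round-off. Salt
bridges are distance-only and strict (< 4.0 Å). Donors without resolvable
hydrogens degrade to a distance-only test with a warning — relevant when
crystal waters carry no hydrogens.

## Superposition, RMSD and RMSF

Superposition is the closed-form Kabsch construction (SVD with determinant
correction), requiring ≥ 3 non-collinear atoms. RMSD series fit each frame
on a fit selection and measure on a possibly different selection (e.g.
ligand RMSD after a protein fit). RMSF superposes each replicate onto its
iterated mean structure (two iterations by default; the fitting reference is
a package choice) and reports √⟨|r−⟨r⟩|²⟩ per atom, or residue-averaged.

Fitting absorbs six rigid degrees of freedom out of 3N, so a harmonic
ensemble with per-coordinate σ recovers the theoretical RMSF σ√3 with a
relative bias of order 1/N atoms; recovery tests therefore use fixtures of
60–120 atoms, where the bias is ≲ 2% and the 5% recovery tolerance is
comfortably met at 2000 frames. The core region is the ⌊0.9·N⌋ residues of
lowest RMSF, ties broken by ascending serial for determinism.

## Water bridges, density grids, RDFs

A water-mediated bridge is a simple path endpoint → w₁ → … → w_k → endpoint
(k ≤ 3 by default, motivated by the ~7–8.5 Å gap between residue 324 and the
phosphate groups accommodating two to three water diameters) in which every
link passes the requested criteria class. Link direction (donor vs acceptor)
is decided by which side carries hydrogens; chains never repeat a water; a
frame counts once toward the frequency however many chains it contains.
The search equals exhaustive enumeration over water subsets (verified
against a brute-force oracle in the tests). Strong-class chains are a subset
of weak-class chains by construction.

Density grids count water-oxygen incidences on a cubic lattice (0.33 Å
default spacing; origin snapped down to a spacing multiple; optional
superposition of frames on a fit selection first). The isopleth threshold is
`fraction × max cell count` (default 0.8) and returns the mask of cells at
or above it. Σcounts equals the number of in-bounds (water, frame)
incidences exactly.

RDFs use g(r) = ⟨n(r, r+dr)⟩ / (ρ·4πr²dr) with ρ = N/V for boxed
(periodic-convention) fixtures and the count-matched density of the
enclosing r_max sphere otherwise; an ideal-gas fixture gives g = 1 within
sampling error.

## Secondary structure

Backbone hydrogen bonds are scored with the electrostatic criterion
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, bonded when
E < −0.5 kcal/mol; amide hydrogens are reconstructed on the
N–CA / N–C(prev) bisector at 1.01 Å when absent. A residue is α-helical (H)
when both flanking i→i+4 turns are intact (its predecessor's and its own),
3₁₀ (G) analogously from i→i+3 turns, loop (L) otherwise. This two-turn
convention is deliberately local: a residue's class depends only on the two
turns that place it inside a minimal helix, which keeps the loop-probability
statistic interpretable per residue. Its visible consequence is that the
last few residues of an ideal helix, lacking an own i→i+4 partner, read as
loop; loop-probability analyses therefore target interior residues. Strand
and turn classes are out of scope (the analyses only contrast helix vs
loop), and 3₁₀ counts as non-loop by default (switchable).

## Synthetic generators

All generators derive their random streams by stable hashing of
(seed, generator name, replicate index); identical specs are
bitwise-reproducible and adding a generator never perturbs another. The
defaults mirror the study conditions: three replicates, 20 ps frame
spacing, bridge occupancies near 31%/12%, RMSF amplitudes near 0.74/1.00 Å,
loop probabilities up to 50%, energy means near −24/−20 kcal/mol with
0.04 kcal·mol⁻¹·ns⁻¹ drift and ~2 kcal/mol frame noise.

- *Harmonic ensembles*: frames are a reference plus iid isotropic Gaussian
  displacements; expected RMSF is σ√3 per atom.
- *Bridge sites*: a hydroxyl-like donor and phosphate-like acceptor triad
  `gap` Å apart; in a Bernoulli(occupancy) subset of frames, equally spaced
  colinear waters realize an exactly valid strong-criteria chain, otherwise
  they swing far off axis; decoy waters sit permanently out of range. The
  construction is exact, so detector output equals the returned labels.
- *Helix/coil*: an ideal α-helix (φ=−57°, ψ=−47°) whose per-residue toggle
  displaces that residue's carbonyl 12 Å radially off the helix axis,
  destroying every turn it accepts without creating spurious bonds. Under
  the two-turn rule an interior residue is loop iff its own or its
  predecessor's toggle fired, so the toggle rate is calibrated as
  q = 1 − √(1 − p), making the marginal per-residue loop probability equal
  the designed p exactly for uniform profiles (for non-uniform profiles the
  marginal blends adjacent targets geometrically; realized labels are
  returned for exact comparisons).
- *Energy series*: value(t) = mean + slope·t + N(0, noise).
- *Bar networks*: explicit or random (i, j, multiplicity) bars with seeded
  generic attachments for the rank oracle.

What the generators do **not** emulate: water dynamics and exchange,
force-field energetics, correlated backbone motion, periodic solvation.
Passing recovery tests demonstrates that the estimators are unbiased and
correctly calibrated at the designed effect sizes — not that the original
trajectories would reproduce any particular number.

## Effective binding energies

The single-trajectory convention extracts complex, receptor and ligand from
the same ensemble, so ΔG_frame reduces to receptor–ligand cross terms. The
built-in toy model is screened Coulomb (332.0637·q₁q₂/(4·r); the uniform
interior dielectric of 4 stands in for the screening of a highly charged
binding site), Lennard-Jones (Lorentz–Berthelot over per-element
parameters), and a nonpolar surface term γ·ΔSASA with
γ = 0.00542 kcal·mol⁻¹·Å⁻² (β = 0.92 kcal/mol is treated as
species-independent and cancels in the difference). A numerical
Poisson–Boltzmann solver is deliberately out of scope; externally computed
per-frame component tables (frame, time_ns, e_mm, g_polar, g_nonpolar) pass
through the same interface after validation. Configurational-entropy changes
are excluded.

Per-replicate SEMs use block averaging (five blocks) to respect frame
autocorrelation (switchable to the naive iid estimator). Replicate SEMs
combine by root-sum-square, as does SEM_total of ΔΔG — so SEM_total is
never smaller than either input. ΔΔG matches replicates by index and is
antisymmetric under label swap. Association-constant conversions use
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹; positive ΔΔG (weaker binding) maps to a
fold > 1 decrease.

## Rigidity

Bodies are residues; bar multiplicities follow the molecular body-bar
convention (rotatable covalent 5, locked 6, H-bond/salt bridge 5,
hydrophobic 2). Network construction from a structure scores hydrogen bonds
with a 12–10 radial well of depth −8 kcal/mol at 2.8 Å modulated by cos² of
the angular deviation from linearity; salt bridges get an energy below the
unfolding ladder (never removed); hydrophobic tethers join C/S pairs within
the van-der-Waals sum + 0.25 Å. Precomputed H-bond energies can be supplied
instead.

The (6,6) pebble game decides independence by gathering seven pebbles on a
bar's endpoints; the accepted count is the generic rank, internal DOF is
6B − 6 − rank, and two bodies are co-rigid when a hypothetical extra bar
between them would be redundant — an equivalence relation, so clusters
partition the bodies. Bars are processed in canonical sorted order, making
the output insertion-order independent. The independent cross-check is a
rigidity-matrix rank/null-space oracle at random generic attachments; the
two agree exactly on DOF and partition across random networks (verified for
100 seeds at ≤ 12 bodies).

Thermal unfolding retains an H-bond bar at cutoff c iff |E| ≥ c, over the
ladder 0.0–6.0 kcal/mol in 0.1 steps (the grid includes 0.0). rc_ij is the
largest cutoff at which i and j are co-rigid; never-co-rigid pairs carry a
NaN sentinel excluded from all arithmetic (rc_ii = 6.0 by convention).
Ensemble maps average element-wise over structures with sentinel
bookkeeping; difference maps are reference-minus-perturbed with per-pair
Welch tests at α = 0.05, requiring ≥ 2 valid observations and ≤ 50%
sentinels per side.

## Pipeline, determinism, problem sizes

The `gsmech run` pipeline executes validate → geometry → solvation →
secstruct → energetics → rigidity on synthetic fixtures, writing TSV/JSON/
OpenDX artifacts, the echoed config, a MANIFEST, and a summary whose bytes
are identical across reruns of the same config. All randomness flows from
the single config seed.

Default problem sizes are chosen so the estimators' sampling errors are
well inside the recovery tolerances while the full suite runs in seconds on
one CPU: 2000 frames for bridge-occupancy recovery (3 binomial SE ≈ 3%),
1000 frames for loop probability, 2000 frames × 120 atoms for RMSF, 4000
frames × 3 replicates for ΔΔG, 100 random networks of ≤ 12 bodies for the
pebble-game/oracle equivalence.

## Known limitations

- Secondary structure implements only the helix/loop contrast; no strands,
  bends, or full eight-class output.
- The toy energy model is a pedagogical stand-in for a solvation solver:
  magnitudes are not comparable to solver output, only the aggregation and
  error-propagation machinery is.
- Non-periodic RDF normalization is count-matched, which forces the
  large-r average toward 1; shell *ratios* are meaningful, absolute peak
  heights depend on the chosen r_max.
- The pebble game's pair-rigidity queries are O(B²) per cutoff; fine for
  residue-level networks of hundreds of bodies, not tuned for
  atom-resolution decamers.
- Histidine protonation, hydrogen addition, mmCIF, and binary trajectory
  formats are out of scope.
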