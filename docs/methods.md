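# Methods

`masfold` implements an integrative structure-determination protocol for a
protein chain bound to a large assembly: solid-state NMR carbon–carbon
cross-peaks become ambiguous distance restraints, a single chain is folded by
restrained simulated annealing inside a density envelope, the folded chain is
rigid-body docked at multiple positions of an experimental cryo-EM map, all
docked copies are refined jointly under non-crystallographic-symmetry (NCS)
restraints, and a final localized refinement frees only a mobile tail (the
neck-linker analogue). This note records the model, its parameters, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Distance restraints

An assigned ¹³C–¹³C cross-peak implies spatial proximity of the two carbons.
Each peak becomes one flat-bottom restraint:

- intra-residue pairs: bounds 1.5–6.5 Å (target 4.0 ± 2.5 Å)
- inter-residue pairs: bounds 2.0–7.2 Å (target 4.6 ± 2.6 Å)

A peak consistent with several atom-pair assignments is an *ambiguous*
restraint, evaluated on the effective distance
`d_eff = (Σ_p d_p⁻⁶)^(−1/6)` over its candidate pairs, so any one satisfied
candidate satisfies the restraint. Restraints with more than 5 candidates are
dropped. A mixed candidate set (some intra-, some inter-residue) takes the
looser inter-residue bounds: ambiguity must never over-restrain. Restraints
with identical (order-insensitive, atom-pair-symmetric) assignment sets are
merged, pooling their source experiments.

Sequence-separation classes: intra (i = j), sequential (|i−j| = 1), medium
(1 < |i−j| < 5), long (|i−j| ≥ 5). Two conventions for the medium class
appear in print (strict and inclusive lower edge); the strict form is adopted
so sequential and medium are disjoint. Restraints-per-residue uses the full
construct length as denominator, so published per-residue figures are
reproduced only approximately (1339/349 = 3.84 against a printed 3.85); the
difference is documented rather than silently adjusted.

The contact matrix counts unambiguous restraints at (i, j) and (j, i), with
intra-residue counts on the diagonal. Ambiguous restraints can contribute
fractionally (1/|assignments| per candidate) but are off by default, since
the published matrix convention is unstated.

## Energy model

All terms are differentiable with analytic gradients (checked against central
finite differences in the test suite). Units: kcal/mol, Å; dihedral force
constants in rad⁻² internally, converted from degrees at the boundary.

- **Distance**: `k·(d_eff − U)²` above the upper bound, `k·(L − d_eff)²`
  below the lower, zero inside. k ramps 2 → 30 kcal·mol⁻¹·Å⁻² across cooling.
- **Torsion**: quadratic in the wrapped excess `max(0, |Δ| − tol)` with Δ in
  (−180°, 180°]; k = 10 kcal·mol⁻¹·rad⁻² at high temperature, 200 during
  cooling. When a torsion table omits a tolerance, ±20° is assumed
  (TALOS-style uncertainty); configurable.
- **Covalent**: harmonic bonds, angles and impropers about ideal values from
  a compact Engh–Huber-style table shipped as `data/ideal_geometry.yaml`
  (k_bond 600 kcal·mol⁻¹·Å⁻², k_angle and k_improper 80 kcal·mol⁻¹·rad⁻²).
  The model is heavy-atom only: backbone N, CA, C, O plus up to three pseudo
  side-chain carbons (CB, CG, CD) per residue. Hydrogens are omitted — the
  restraints are ¹³C–¹³C and the map term is backbone-only, so protons add
  cost without testable benefit. This is a deliberate simplification of the
  all-atom internal-coordinate model used in production NMR software.
- **NCS**: for every unordered subunit pair, the copies are optimally
  superposed and only the RMSD excess over the tolerance (default 1.0 Å) is
  penalized quadratically (k = 50 kcal·mol⁻¹·Å⁻² per pair by default). Pure
  rigid-body differences cost nothing; gradients use the envelope theorem at
  the optimal transform.
- **Map**: `E = k·(1 − CC)`, k = 50 kcal/mol, where CC is the Pearson
  correlation between the target map and a density simulated from the
  selected atoms (backbone N, C′, CA, O by default, optionally limited to a
  residue mask). The production software's cross-correlation
  probability-distribution potential has its exact functional form in prior
  literature; this CC-based term is the declared surrogate. CC is evaluated
  over the fixed support of the observed map (voxels above a small fraction
  of its maximum), keeping the term smooth; gradients flow analytically
  through the Gaussian kernels. Atom Gaussians are truncated at 3σ
  (≤ 0.3 % of mass).
- **Gyration**: a weak radius-of-gyration restraint standing in for a
  gyration-volume compaction term; automatically disabled whenever a map
  term is active, since the two conflict.
- An optional simple backbone hydrogen-bond distance term can be assembled
  from distance restraints on O···N pairs; it is off by default.

Density simulation uses isotropic unit-integral Gaussians with
σ = resolution/(π√2), a common EM convention (the source protocol delegates
this step to visualization software, so the convention is stated here).

## Sampling

Dynamics are Cartesian velocity-Verlet with standard element masses and a
per-step velocity-rescaling thermostat — the simplest scheme consistent with
maintained stage temperatures. Cartesian dynamics with strong covalent terms
replace internal-coordinate torsion dynamics; at desk scale this is simpler
and directly testable, and is documented as a deviation from the production
protocol. The starting timestep is 1 fs and is self-adjusted: any step that
changes total (potential + kinetic) energy by more than 2 % (relative, with
a small absolute floor) is rejected and the timestep halves, down to a
0.1 fs floor, recovering gradually afterwards. The 2 % figure is a declared
surrogate — the production software's tolerance is unpublished.

The default annealing schedule is the production protocol: two
high-temperature stages at 3000 K (10 ps or 10,000 steps, whichever
completes first), Maxwell-distributed initial velocities at 3000 K, then
cooling from 3000 K to 25 K in 25 K decrements (120 stages) with 0.4 ps of
dynamics per temperature. Force-constant ramps are linear in cooling-stage
index (the source says only "ramped"); endpoints are exact at the first and
last stage. A non-dividing decrement is rejected by default; schedules built
with `strict=False` clamp the final stage to the end temperature instead,
which is how the reduced ladder "3000 → 25 K by 125 K" is realized.

Annealing ends with a gradient-based Cartesian minimization (L-BFGS-B; the
production protocol names Powell's scheme — the contract here is only that
energy never increases and the gradient norm falls below a threshold).
Batch runs (`run_batch`) are independent seeded repeats sorted by final
total energy, including the map term; "lowest-energy structure" always means
index 0 of that ordering.

In the localized (stage-4) refinement the core (residues 1–320 in the
production numbering) moves as one rigid body with 6 degrees of freedom
during dynamics — net force and torque about its center of mass drive
translation and exact rotations, so the core's internal geometry is
preserved to machine precision — and is held fixed during the final
minimization; the mobile tail is fully free.

## Docking

`dock_positions` scores a deterministic quasi-uniform rotation set
(super-Fibonacci sampling, default 2000 orientations, seedless) against a
coarse translation grid by mean interpolated map density at CA positions,
shortlists non-overlapping sites, and locally refines the best few
orientations per site (pseudo-symmetric folds make a single coarse
orientation unreliable) with Powell's method on the 6 rigid parameters,
maximizing real-space CC computed over the placed chain's own density
support. Placements are returned sorted by descending CC with a
non-max-suppression separation (default: the chain's radius of gyration).
Ranking uses *highest* CC; the source text's "lowest cross-correlation"
phrasing is taken as a wording slip, since best fit = highest correlation.

## Synthetic data

The generator produces every input with known ground truth:

- **Toy folds**: ideal-geometry chains from per-element backbone dihedrals
  (helix −60/−45, strand −120/+120, loop 100/125 — the loop angles fold two
  helices into a packed hairpin). Pseudo side chains are one to three
  carbons at idealized positions, enough to exercise sidechain–sidechain
  restraints without rotamer machinery.
- **Peak lists**: one peak per pair of NMR-visible carbons within a cutoff
  (recommended ≤ 7.2 Å, the inter-residue upper bound). Labeling schemes are
  simplified residue-type visibility masks (`data/labeling_schemes.yaml`):
  `glucose_16` is carbonyl/outer-side-chain-dominated and deliberately
  sparse (≈ 3.7 restraints per residue on the standard fixture),
  `glucose_2` is Cα-dominated, `uniform_13C` sees every carbon. True
  isotopomer statistics of glucose labeling are out of scope. A seeded
  fraction of peaks receives decoy assignments; decoys are accepted only if
  the resulting r⁻⁶ effective distance at the true coordinates stays inside
  the bounds, preserving the generator's master guarantee: *the true
  coordinates satisfy every emitted restraint* (before noise exceeding
  tolerances). Pseudo chemical shifts are deterministic per (residue, atom)
  site; intensities fall off as d⁻⁶.
- **Torsions**: φ/ψ measured from the true coordinates with optional
  Gaussian noise; the standard fixture uses noise 0 and tolerance ±20°.
- **Lattices**: copies placed on a helical lattice (lateral radius, axial
  rise, twist about z) with a clash check, plus the blurred map and the true
  placements.
- **Second state**: shift dimensions belonging to perturbed residues are
  displaced by ±shift_delta (seeded sign) and intensities of touched peaks
  scaled, so per-residue comparison recovers exactly the planted set.

The standard fixture ("fixture A", master seed 7): 30-residue
helix-loop-helix, glucose_16 scheme, cutoff 7.2 Å, ambiguity rate 0.15,
4-copy lattice (radius 28 Å, rise 12 Å, twist 90°), 8 Å map on a 2 Å grid.
Its text files are committed under `tests/data/fixture_a/` and the test
suite verifies the generator reproduces them bit-exactly; the map is binary
and therefore regenerated at run time rather than committed.

What the synthetic benchmarks show: that the implementation converges to the
restraint-defined structure, recovers planted placements, and respects the
NCS tolerance — i.e., correctness of the machinery. What they do not show:
performance on real spectra (peak overlap, assignment errors, non-Gaussian
map noise, rotamer-level side-chain detail are all absent), so passing tests
are a statement about the method's implementation, not about real-data
accuracy.

## Scaled problem sizes

Tests and the reproduction script run desk-scale analogues, chosen as the
package's own benchmark conditions: 4 subunits instead of 22; annealing
batches of 1–2 instead of 100 (1000 per subunit in the localized stage);
short high-temperature stages (0.1–1 ps) and coarse or reduced cooling
ladders (6–36 stages, 0.02–0.4 ps per stage); docking with 120–300
orientations. Recovery experiments seed stage 1 from the true fold degraded
by 0.6 Å per-coordinate Gaussian noise — the analogue of starting from a
related medium-resolution structure, which is how the production protocol
was seeded. Dihedral-space perturbations of similar size were considered and
rejected as a start model: they translate into global shape changes that a
shape-preserving envelope term then fights, which models a *wrong* prior
structure rather than a noisy one.

## Known limitations

- No Lennard-Jones or electrostatic terms: sterics enter only through
  covalent geometry, restraints and the map, plus a soft repulsion used when
  rebuilding missing residues. Toy folds do not need more; real refinement
  would.
- The velocity-rescaling thermostat does not sample a canonical ensemble;
  ensemble spreads here characterize restraint satisfaction, not Boltzmann
  statistics.
- The rigid-body integrator for the stage-4 core is first-order in the
  angular update; it preserves internal geometry exactly but is not
  symplectic. The timestep guard absorbs the resulting energy drift.
- Violation statistics pool per-conformer means as mean ± sd across the
  ensemble; the published pooling convention is unstated. The "distance
  restraints beyond the upper bound" row is interpreted as the mean
  violation magnitude over violated restraints.
- `read_mrc` requires cubic voxels and normalizes axis order; anisotropic
  maps are rejected rather than resampled.
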