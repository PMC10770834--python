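# Methods

This note records the models implemented in `bindscope`, the defaults
and why they were chosen, the numerical decisions, what the synthetic
generators do and do not emulate, and the known limitations.

## Binding model

The fluorescence enhancement of a protein titrated with ligand is
modelled as 1:1 association under the free-ligand approximation (total
ligand ≈ free ligand, valid when the protein concentration is well
below 1/Kb):

ΔF(c) = ΔFmax·Kb·c / (1 + Kb·c),  ΔF = F(c) − F(0) at the analysis
wavelength (default 340 nm, the tryptophan emission region; a
parameter, since the convention varies between instruments and
systems). Intensities are read exactly on grid points and linearly
interpolated between them; no smoothing or band-shape model is applied
to measured spectra.

The default estimator is unweighted ordinary least squares in
double-reciprocal space (1/ΔF against 1/c), matching how such data are
conventionally linearized and reported; Kb = intercept/slope,
ΔFmax = 1/intercept, and r² is the squared Pearson correlation of the
transformed variables. Pairs with ΔF ≤ 0 cannot enter the reciprocal
transform; they are excluded and reported separately rather than
treated as errors. A direct nonlinear hyperbolic fit
(`fit_hyperbolic`) is provided as a labelled alternative because the
reciprocal transform gives the smallest ΔF values the largest leverage;
it is never the default.

**Error propagation caveat.** ΔF is a difference of two large
intensities. Independent multiplicative noise of CV ε on F and F₀
produces absolute noise ≈ ε·√(F² + F₀²) on ΔF, which for a small
enhancement at low ligand concentration can be an order of magnitude
larger than ε relative to ΔF itself — and the reciprocal fit then
amplifies it further. With the default synthetic conditions (F₀ = 500,
ΔFmax = 200, 1% per-point noise) the median Kb error through the full
spectral route is tens of percent, whereas 1% noise applied directly
to the ΔF observations gives ≈ 2% median Kb error. Parameter-recovery
claims in the test suite therefore distinguish the two noise
placements explicitly. Practically, accurate Kb values from this
estimator require either signal averaging of the band or instrument
noise well below 1% per reading.

## Van 't Hoff analysis

ln Kb is regressed on 1/T by OLS: ΔH = −R·slope, ΔS = R·intercept,
with R = 8.314 J mol⁻¹ K⁻¹ exactly. ΔG(T) is reported from
ΔG = ΔH − TΔS (exact identity on the regression products); the direct
relation −RT·ln Kb(T) is carried as a cross-check column, and on
well-behaved data the two agree to within the regression residuals
(≤ 2% on the reference dataset). Temperatures given in Celsius are
converted with K = °C + 273.15. Energies are held in J/mol internally
and reported in kJ/mol to one decimal; r² to four decimals.

Force classification follows the standard sign heuristic for
protein–ligand association: ΔH > 0 and ΔS > 0 → hydrophobic;
ΔH < 0 and ΔS < 0 → hydrogen bonding / van der Waals;
|ΔH| ≤ 1000 J/mol with ΔS > 0 → electrostatic (the near-zero-enthalpy
case); anything else is reported as indeterminate rather than forced
into a class. The 1 kJ/mol threshold is a convention, exposed as a
parameter.

A two-temperature Van 't Hoff regression is formally exact (two points,
r² = 1) but statistically fragile; three or more temperatures are
recommended and the reference analyses use three.

## Frontier-orbital descriptors

All descriptors follow the frozen-orbital definitions on energies in
eV exactly as supplied (no Hartree conversion, no sign
re-interpretation): ΔE = E_LUMO − E_HOMO, µ = (E_LUMO + E_HOMO)/2,
η = ΔE/2, I = −E_HOMO, A = −E_LUMO, χ = (I + A)/2, ω = µ²/(2η). A zero
gap makes ω undefined and is rejected. The identities ΔE = 2η,
χ = −µ, and ω ≥ 0 (for η > 0) hold to ≤ 10⁻¹² eV and are enforced by
property tests. The tabulator prints ω at full floating precision,
matching how such tables are published (9 decimals).

## Contact profiling

Hydrogen bonds: heavy-atom donor–acceptor distance ≤ 3.5 Å between
protein N/O (plus S on CYS/MET) and ligand N/O. When explicit
hydrogens are attached (≤ 1.25 Å, same residue) to either partner, at
least one must give an H–donor–acceptor angle ≤ 30°, and that
hydrogen's heavy atom is reported as the donor; with no hydrogens on
either partner the criterion is distance-only and the protein atom is
recorded as the donor by convention. The 3.5 Å / 30° geometry matches
the default used by GROMACS hydrogen-bond analysis, so per-frame
trajectory counts and static-complex profiles use one criterion.

Hydrophobic contacts: every protein-carbon/ligand-carbon pair ≤ 4.0 Å,
a common profiler convention. All carbons count — no exclusion of
carbons bonded to polar atoms — because typed-interaction engines
disagree on that rule and the cutoff is exposed as a parameter. One
atom pair meeting a criterion is one interaction; no clustering.
Counts are therefore comparable between runs of this profiler but not
directly to visualizer tallies, whose counting conventions are
unspecified; agreement on *which residues dominate* is the meaningful
comparison. Waters (HOH and synonyms) and common ions are excluded
from both sides.

PDB input is restricted to fixed-width ATOM/HETATM/MODEL/ENDMDL
records, parsed with line-numbered errors; elements are taken from
columns 77–78 and inferred from the atom name when absent. The reader
is deliberately small and auditable since trajectory input also flows
through it; binary trajectory formats are out of scope.

## Trajectory observables

Coordinates are held in Å and converted to nm (÷10) or nm² (÷100) only
at reporting, following the units in which MD summaries are
conventionally tabulated.

- **Superposition** is Kabsch's SVD solution with determinant sign
  correction. Selections with fewer than 3 atoms or collinear
  geometry are rejected (the rotation is underdetermined). The
  implementation is checked against a brute-force 2° rotation-grid
  search on small toys.
- **RMSD** is computed per frame after superposition onto a reference
  frame (default frame 0) over backbone atoms when present, else all
  atoms.
- **RMSF** uses the two-pass average-structure reference: frames are
  superposed to frame 0, averaged, re-superposed to that average, and
  fluctuations taken about the final mean — the behaviour of
  `gmx rmsf`. The fit group can be chosen independently of the
  analysis group; fitting on the fluctuating atoms themselves absorbs
  part of a localized fluctuation into the rigid-body fit (about 10%
  for one mobile residue among twenty), which the tests demonstrate.
- **Rg** is the mass-weighted RMS distance from the centre of mass,
  with masses from an element lookup; hydrogens included when present.
- **SASA** is Shrake–Rupley with a deterministic golden-spiral
  (Fibonacci) sphere of n = 960 points per atom (overridable), probe
  1.4 Å, van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
  P 1.80 Å (overridable). Neighbour search uses a KD-tree. The
  single-sphere and two-overlapping-sphere closed forms are reproduced
  within one point-quantum and 2% respectively, and n = 960 agrees
  with n = 3840 within 1% on 50-atom toys.
- **Covariance analysis** superposes frames to the average structure,
  builds the 3N×3N covariance of the selected coordinates (mean over
  frames), and reports the trace, descending eigenvalues and
  projections on the top two modes. The trace equals the sum of
  per-coordinate variances identically. Default selection is Cα,
  flag-selectable, since published essential-dynamics analyses vary
  between Cα and backbone.

## Synthetic generators

The generators define the study conditions under which the package is
validated.

- **Titrations**: ligand 0–50 µM in 5 µM steps at 298.15/308.15/318.15
  K; Kb(T) from ΔH = 5600 J/mol, ΔS = 104.8 J mol⁻¹ K⁻¹ (the
  hydrophobic, entropy-driven regime; Kb(298.15 K) ≈ 3.11×10⁴ M⁻¹);
  emission is a Gaussian band (σ = 25 nm) centred at 340 nm on a
  300–500 nm, 1 nm grid, peaking at F₀ + ΔF(c) with F₀ = 500 and
  ΔFmax = 200 a.u.; multiplicative Gaussian noise per intensity
  reading, CV 1% by default (fluorescence noise scales with signal).
  The free-ligand approximation matches the fitted model; a
  mass-balance quadratic option exists, labelled, for sensitivity
  studies. Real spectra differ in lineshape (tryptophan emission is
  asymmetric), in baseline drift, and in noise correlation — so
  passing recovery tests demonstrates estimator correctness, not
  instrument realism.
- **Trajectories**: per-frame independent Gaussian displacement of each
  atom with its residue's amplitude per axis, then a random rigid
  rotation/translation of the frame. The expected RMSF of a residue
  with amplitude a is √3·a when the superposition is anchored by
  static atoms; the generator has no inter-frame correlation, so
  time-correlation observables are out of its scope.
- **Complexes**: a rigid scaffold of residues (polar atoms at the slot
  ends, carbons between, 4 Å apart along the chain axis, residues
  10 Å apart) with ligand atoms placed 2.8–3.2 Å from polar slots and
  3.5–3.9 Å from carbon slots; construction guarantees every
  non-planted protein–ligand distance exceeds 4.5 Å and verifies it,
  raising on infeasible requests (more than two hydrogen bonds or
  three hydrophobic contacts per residue). The finished complex gets
  a random rigid orientation so profiling is never tested on
  axis-aligned geometry. No explicit hydrogens are planted, so
  hydrogen-bond recovery exercises the distance-only branch.

All generators are bit-reproducible from their (design, seed) inputs.

## Problem sizes used in the validation suite

The test and acceptance runs use toy scales chosen to make every check
exact or statistically stable: 10–24-residue scaffolds (40–96 atoms),
trajectories of 30–600 frames, 200 replicates for noise-recovery
medians, 960-point SASA spheres (240 in multi-frame summaries), and a
2° Euler grid (≈ 3×10⁶ rotations) for the superposition oracle. These
sizes are the package's validation conditions, not limits of the
implementation; all operations are O(N log N) or better per frame
except SASA (O(N·n_points·neighbours)) and the one-off grid oracle.

## Known limitations

- The double-reciprocal estimator is exact only under the free-ligand,
  single-site model; cooperative or multi-site binding, quenching-type
  systems (Stern–Volmer analysis) and inner-filter corrections are out
  of scope.
- ΔH from a three-temperature regression on rounded Kb values is
  sensitive to that rounding (two-significant-figure inputs shift it
  by several percent); ΔG and ΔS are robust.
- Contact counts depend on the chosen cutoffs and the
  one-pair-one-interaction convention; only qualitative residue
  rankings transfer across profilers.
- Secondary-structure assignment, docking, quantum-chemistry and MD
  engines are intentionally absent: the package analyses their
  outputs, it does not produce them.
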