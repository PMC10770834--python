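# bindscope

Quantitative analysis of spectroscopic protein–ligand binding studies,
built around the lysozyme–digitoxin class of experiment: a ligand
enhances the intrinsic tryptophan fluorescence of a protein, and the
titration carries the binding constant; repeating the titration at
several temperatures carries the thermodynamics; docking-derived
structures carry the contact geometry; and molecular-dynamics
trajectories carry the stability observables. `bindscope` implements
the full downstream analysis chain for such a study, with seeded
synthetic-data generators so every stage can be exercised and validated
without any external download.

## What it computes

**Binding constant (double-reciprocal fit).** For 1:1 association with
fluorescence enhancement ΔF = F − F₀ read at a fixed analysis
wavelength (default 340 nm),

    1/ΔF = 1/ΔFmax + 1/(Kb·[L]·ΔFmax)

is fitted by ordinary least squares of 1/ΔF on 1/[L]; then
Kb = intercept/slope (M⁻¹) and ΔFmax = 1/intercept. A direct
hyperbolic fit is available as a labelled alternative.

**Van 't Hoff thermodynamics.** Regression of ln Kb on 1/T gives
ΔH = −R·slope and ΔS = R·intercept, with ΔG(T) = ΔH − TΔS (and
−RT·ln Kb kept as a cross-check column). The signs of ΔH and ΔS
classify the dominant force (both positive → hydrophobic; both
negative → hydrogen bonding / van der Waals; |ΔH| ≈ 0 with ΔS > 0 →
electrostatic).

**Frontier-orbital descriptors.** From HOMO/LUMO energies (eV):
ΔE = E_LUMO − E_HOMO, µ = (E_LUMO + E_HOMO)/2, η = ΔE/2, I = −E_HOMO,
A = −E_LUMO, χ = (I + A)/2, ω = µ²/(2η).

**Contact profiling.** Per-residue hydrogen bonds (donor–acceptor
≤ 3.5 Å, H–D–A ≤ 30° when explicit hydrogens exist) and hydrophobic
C–C contacts (≤ 4.0 Å) between protein and ligand in a PDB complex.

**Trajectory observables (from scratch).** Kabsch superposition and
RMSD, two-pass RMSF, mass-weighted radius of gyration, Shrake–Rupley
SASA on a deterministic golden-spiral sphere, per-frame intermolecular
hydrogen-bond counts, and essential-dynamics covariance analysis
(trace, eigenvalues, projections) — all from multi-model PDB or XYZ
text trajectories, reported in nm-based units.

## Worked example

```sh
python examples/binding_thermodynamics.py
```

prints (noiseless synthetic titrations generated from ΔH = 5.6 kJ/mol,
ΔS = 104.8 J mol⁻¹ K⁻¹):

```
25 C: Kb = 3.114e+04 M^-1  (true 3.114e+04), r^2 = 1.0000
35 C: Kb = 3.35e+04 M^-1  (true 3.35e+04), r^2 = 1.0000
45 C: Kb = 3.589e+04 M^-1  (true 3.589e+04), r^2 = 1.0000

dH = 5.6 kJ/mol  (generator truth 5.6)
dS = 104.8 J/(mol K)  (generator truth 104.8)
dG(25 C) = -25.6 kJ/mol
dG(35 C) = -26.7 kJ/mol
dG(45 C) = -27.7 kJ/mol
force class: hydrophobic
```

The Kb values rise with temperature and both ΔH and ΔS come back
positive, so the association is classified as hydrophobically driven;
ΔG is negative throughout, i.e. binding is spontaneous at all three
temperatures. The other scripts in `examples/` demonstrate the
descriptor table, contact profiling of a planted complex, trajectory
summaries, and fit robustness under noise — each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same functions:

```sh
bindscope vant-hoff --kb 3.1e4@25C --kb 3.3e4@35C --kb 3.6e4@45C
bindscope fmo --in orbitals.csv
bindscope contacts --in complex.pdb
bindscope traj --in trajectory.pdb --select ca
bindscope simulate titration --seed 1 --out data/
```

## Layout

- `src/bindscope/spectra.py` — spectrum/titration model, I/O, ΔF and RLS extraction
- `src/bindscope/binding.py` — double-reciprocal fit, Van 't Hoff, force classes
- `src/bindscope/fmo.py` — conceptual-DFT descriptors
- `src/bindscope/structure.py` — PDB reading, H-bond/hydrophobic profiling
- `src/bindscope/trajectory.py` — RMSD/RMSF/Rg/SASA/H-bond/covariance observables
- `src/bindscope/synthetic.py` — titration/trajectory/complex generators
- `src/bindscope/pipeline.py` — orchestration and report writing
- `docs/methods.md` — models, defaults, numerical choices, limitations
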