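"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in this package can be exercised without external
data:

* ``generate_titration`` builds fluorescence enhancement titrations at
  several temperatures whose binding constants follow a chosen
  enthalpy/entropy pair through Kb(T) = exp(-dH/(RT) + dS/R),
* ``generate_trajectory`` perturbs a base structure with per-residue
  Gaussian displacements plus rigid-body jitter,
* ``generate_complex`` builds a small protein-like scaffold with a
  ligand planted so that an exact, known set of hydrogen-bond and
  hydrophobic-contact pairs — and nothing else — sits inside the
  detection cutoffs.

All generators are bit-reproducible from (design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .binding import GAS_CONSTANT
from .spectra import EmissionSpectrum, TitrationSeries
from .structure import Atom, ContactProfile, Structure, interaction_summary
from .trajectory import Trajectory

__all__ = [
    "TitrationDesign",
    "FluctuationDesign",
    "SyntheticTitration",
    "PlantedContacts",
    "kb_from_thermo",
    "generate_titration",
    "generate_trajectory",
    "generate_complex",
    "make_toy_protein",
]

_DEFAULT_CONCENTRATIONS = tuple(np.arange(0, 55, 5) * 1e-6)  # 0-50 uM step 5
_DEFAULT_TEMPERATURES = (298.15, 308.15, 318.15)  # K
_WAVELENGTH_GRID = np.arange(300.0, 501.0, 1.0)  # nm


def kb_from_thermo(delta_h: float, delta_s: float, temperature: float) -> float:
    """Binding constant implied by (dH, dS) at one temperature (M^-1)."""
    return math.exp(-delta_h / (GAS_CONSTANT * temperature) + delta_s / GAS_CONSTANT)


@dataclass(frozen=True)
class TitrationDesign:
    """Ground-truth description of a synthetic titration experiment.

    Defaults emulate the study conditions this package targets: ligand
    from 0 to 50 uM in 5 uM steps at 25/35/45 C, thermodynamics near the
    hydrophobically driven regime (dH = 5600 J/mol, dS = 104.8
    J/(mol K), i.e. Kb(298.15 K) ~ 3.1e4 M^-1), an emission band
    centred at 340 nm, and 1% multiplicative intensity noise.
    """

    delta_h: float = 5600.0  # J/mol
    delta_s: float = 104.8  # J/(mol K)
    temperatures: tuple[float, ...] = _DEFAULT_TEMPERATURES  # K
    concentrations: tuple[float, ...] = _DEFAULT_CONCENTRATIONS  # mol/L
    delta_f_max: float = 200.0  # a.u.
    baseline_f0: float = 500.0  # a.u.
    band_center: float = 340.0  # nm
    band_width: float = 25.0  # nm (Gaussian sigma)
    noise_cv: float = 0.01  # fractional
    excitation_wavelength: float = 295.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.concentrations:
            raise ValueError("concentrations must include 0 (the reference)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.band_width <= 0 or self.delta_f_max <= 0 or self.baseline_f0 <= 0:
            raise ValueError("band parameters must be positive")


@dataclass
class SyntheticTitration:
    """Generated series plus the ground truth needed to score estimators."""

    series_by_temperature: dict[float, TitrationSeries]
    kb_by_temperature: dict[float, float]
    design: TitrationDesign


def _free_ligand(total: np.ndarray, kb: float, protein_total: float) -> np.ndarray:
    """Free-ligand concentration from the 1:1 mass balance (quadratic)."""
    # c_free solves Kb*c^2 + (1 + Kb*(P - L))*c - L = 0 for each total L
    p = protein_total
    out = np.empty_like(total)
    for i, lt in enumerate(total):
        a = kb
        b = 1.0 + kb * (p - lt)
        c = -lt
        out[i] = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    return out


def generate_titration(
    design: TitrationDesign,
    protein_concentration: float | None = None,
) -> SyntheticTitration:
    """Generate one titration series per design temperature.

    The enhancement follows dF(c) = dFmax*Kb*c/(1+Kb*c) with c the total
    ligand concentration (the free-ligand approximation the
    double-reciprocal model assumes).  Passing ``protein_concentration``
    switches to the labelled mass-balance alternative, where c is the
    free concentration from the 1:1 binding quadratic — useful for
    sensitivity studies, never the default.  Each spectrum is the
    Gaussian emission band scaled to peak at F0 + dF(c), with
    independent multiplicative Gaussian noise (CV = ``noise_cv``) per
    intensity reading.
    """
    rng = np.random.default_rng(design.seed)
    grid = _WAVELENGTH_GRID
    band = np.exp(-0.5 * ((grid - design.band_center) / design.band_width) ** 2)
    series_by_t: dict[float, TitrationSeries] = {}
    kb_by_t: dict[float, float] = {}
    concs = np.asarray(design.concentrations, dtype=float)
    for t in design.temperatures:
        kb = kb_from_thermo(design.delta_h, design.delta_s, t)
        kb_by_t[t] = kb
        if protein_concentration is None:
            c_eff = concs
        else:
            c_eff = _free_ligand(concs, kb, protein_concentration)
        df = design.delta_f_max * kb * c_eff / (1.0 + kb * c_eff)
        spectra = []
        for c_total, dfi in zip(concs, df):
            peak = design.baseline_f0 + (0.0 if c_total == 0 else dfi)
            intensities = peak * band
            if design.noise_cv > 0:
                intensities = intensities * (
                    1.0 + rng.normal(0.0, design.noise_cv, size=grid.size)
                )
                intensities = np.clip(intensities, 0.0, None)
            spectra.append(
                EmissionSpectrum(
                    wavelengths=grid.copy(),
                    intensities=intensities,
                    excitation_wavelength=design.excitation_wavelength,
                    temperature=t,
                    ligand_concentration=float(c_total),
                )
            )
        series_by_t[t] = TitrationSeries(spectra=spectra)
    return SyntheticTitration(
        series_by_temperature=series_by_t,
        kb_by_temperature=kb_by_t,
        design=design,
    )


# ---------------------------------------------------------------------------
# trajectories


def make_toy_protein(n_residues: int = 12) -> Structure:
    """Small helical poly-alanine-like scaffold with N/CA/C/O backbone
    atoms per residue; deterministic."""
    if n_residues < 1:
        raise ValueError("need >= 1 residue")
    atoms: list[Atom] = []
    serial = 1
    rise, radius, turn = 1.5, 2.3, math.radians(100.0)
    for i in range(n_residues):
        theta = i * turn
        ca = np.array([radius * math.cos(theta), radius * math.sin(theta), rise * i])
        offsets = {
            "N": np.array([-0.8, 0.9, -0.6]),
            "CA": np.zeros(3),
            "C": np.array([1.0, 0.6, 0.7]),
            "O": np.array([1.4, 1.6, 0.9]),
        }
        for name, off in offsets.items():
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ALA",
                    residue_number=i + 1,
                    chain="A",
                    coord=ca + off,
                )
            )
            serial += 1
    return Structure(atoms=atoms)


@dataclass
class FluctuationDesign:
    """Ground-truth description of a synthetic trajectory.

    Each atom is displaced independently per frame by a Gaussian with
    its residue's amplitude (A, per axis); the whole frame then gets a
    random rigid-body jitter.  The expected recovered RMSF of a residue
    with amplitude ``a`` is ``sqrt(3)*a`` (three independent axes), up
    to sampling error at finite ``n_frames``.
    """

    base_structure: Structure
    per_residue_amplitude: Mapping[tuple[str, int], float] | float = 0.3
    rigid_jitter: tuple[float, float] = (5.0, 1.0)  # (max deg, max A)
    n_frames: int = 100
    seed: int = 0

    def amplitude_for(self, key: tuple[str, int]) -> float:
        if isinstance(self.per_residue_amplitude, (int, float)):
            return float(self.per_residue_amplitude)
        return float(self.per_residue_amplitude.get(key, 0.0))

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        amps = (
            [self.per_residue_amplitude]
            if isinstance(self.per_residue_amplitude, (int, float))
            else list(self.per_residue_amplitude.values())
        )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be >= 0")


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(-max_deg, max_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def generate_trajectory(
    design: FluctuationDesign,
) -> tuple[Trajectory, dict[tuple[str, int], float]]:
    """Build a synthetic trajectory; returns it with the planted
    per-residue displacement amplitudes (A, per axis)."""
    base = design.base_structure
    coords0 = base.coords
    amp = np.array([design.amplitude_for(a.residue_key) for a in base.atoms])
    rng = np.random.default_rng(design.seed)
    max_deg, max_trans = design.rigid_jitter
    frames = np.empty((design.n_frames, len(base), 3))
    for f in range(design.n_frames):
        displaced = coords0 + rng.normal(size=(len(base), 3)) * amp[:, None]
        rot = _random_rotation(rng, max_deg)
        trans = rng.uniform(-max_trans, max_trans, size=3) if max_trans > 0 else np.zeros(3)
        center = displaced.mean(axis=0)
        frames[f] = (displaced - center) @ rot.T + center + trans
    planted = {a.residue_key: design.amplitude_for(a.residue_key) for a in base.atoms}
    return Trajectory(topology=base, frames=frames), planted


# ---------------------------------------------------------------------------
# planted-contact complexes

_HB_RANGE = (2.8, 3.2)  # A, planted donor-acceptor distances
_PHOBIC_RANGE = (3.5, 3.9)  # A, planted C-C distances
_MIN_OTHER_DISTANCE = 4.5  # A, every non-planted protein-ligand pair

# residue template: polar atoms at the ends, carbons in the middle, all
# 4 A apart along z so one planted partner never grazes a second slot
_RESIDUE_TEMPLATE = (
    ("N", "N", 0.0),
    ("CA", "C", 4.0),
    ("CB", "C", 8.0),
    ("CG", "C", 12.0),
    ("O", "O", 16.0),
)
_HB_SLOTS = ("N", "O")
_PHOBIC_SLOTS = ("CA", "CB", "CG")
_RESIDUE_SPACING = 10.0  # A along x


@dataclass
class PlantedContacts:
    """Ground truth for a generated complex."""

    hbond_pairs: list[tuple[int, int, float]]  # (protein serial, ligand serial, A)
    hydrophobic_pairs: list[tuple[int, int, float]]
    per_residue_counts: dict[tuple[str, int], tuple[int, int]]


def generate_complex(
    n_hbonds: int,
    n_hydrophobic: int,
    seed: int = 0,
    hbond_residues: Sequence[int] | None = None,
    hydrophobic_residues: Sequence[int] | None = None,
) -> tuple[Structure, PlantedContacts]:
    """Build a complex with exactly the requested planted contacts.

    Ligand heteroatoms are placed 2.8-3.2 A from protein N/O atoms
    (hydrogen bonds) and ligand carbons 3.5-3.9 A from protein carbons
    (hydrophobic contacts); every other protein-ligand distance exceeds
    4.5 A.  No explicit hydrogens are generated, so hydrogen bonds are
    detected on distance alone.  Optional residue lists pin each planted
    contact to a residue number (1-based); each residue offers two
    hydrogen-bond slots and three hydrophobic slots.  The finished
    complex is given a random rigid orientation.
    """
    if n_hbonds < 0 or n_hydrophobic < 0:
        raise ValueError("contact counts must be >= 0")
    rng = np.random.default_rng(seed)

    if hbond_residues is not None and len(hbond_residues) != n_hbonds:
        raise ValueError("hbond_residues must list one residue per planted bond")
    if hydrophobic_residues is not None and len(hydrophobic_residues) != n_hydrophobic:
        raise ValueError("hydrophobic_residues must list one residue per contact")
    if hbond_residues is None:
        n_hb_res = math.ceil(n_hbonds / len(_HB_SLOTS))
        hbond_residues = [1 + i // len(_HB_SLOTS) for i in range(n_hbonds)]
        start = n_hb_res
    else:
        start = max(hbond_residues, default=0)
    if hydrophobic_residues is None:
        hydrophobic_residues = [
            start + 1 + i // len(_PHOBIC_SLOTS) for i in range(n_hydrophobic)
        ]

    n_residues = max([2] + list(hbond_residues) + list(hydrophobic_residues))

    atoms: list[Atom] = []
    serial = 1
    atom_by_slot: dict[tuple[int, str], Atom] = {}
    res_names = ("ASN", "TRP", "VAL", "THR", "GLY", "ALA")
    for res in range(1, n_residues + 1):
        x = res * _RESIDUE_SPACING
        for name, element, z in _RESIDUE_TEMPLATE:
            a = Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=res_names[(res - 1) % len(res_names)],
                residue_number=res,
                chain="A",
                coord=np.array([x, 0.0, z]),
            )
            atoms.append(a)
            atom_by_slot[(res, name)] = a
            serial += 1

    slot_use: dict[tuple[int, str], bool] = {}

    def take_slot(res: int, slots: tuple[str, ...], kind: str) -> Atom:
        for name in slots:
            if not slot_use.get((res, name)):
                slot_use[(res, name)] = True
                return atom_by_slot[(res, name)]
        raise ValueError(
            f"infeasible packing: residue {res} has no free {kind} slot "
            f"(max {len(slots)} per residue)"
        )

    hb_pairs: list[tuple[int, int, float]] = []
    ph_pairs: list[tuple[int, int, float]] = []
    counts: dict[tuple[str, int], list[int]] = {}
    lig_serial = serial
    lig_atoms: list[Atom] = []

    def plant(target: Atom, dist_range: tuple[float, float], name: str, element: str) -> Atom:
        nonlocal lig_serial
        d = rng.uniform(*dist_range)
        a = Atom(
            serial=lig_serial,
            name=name,
            element=element,
            residue_name="LIG",
            residue_number=900,
            chain="L",
            coord=target.coord + np.array([0.0, d, 0.0]),
            is_ligand=True,
        )
        lig_serial += 1
        lig_atoms.append(a)
        return a

    for k, res in enumerate(hbond_residues):
        target = take_slot(int(res), _HB_SLOTS, "hydrogen-bond")
        lig = plant(target, _HB_RANGE, f"O{k + 1}", "O")
        d = float(np.linalg.norm(lig.coord - target.coord))
        hb_pairs.append((target.serial, lig.serial, d))
        counts.setdefault(("A", int(res)), [0, 0])[0] += 1
    for k, res in enumerate(hydrophobic_residues):
        target = take_slot(int(res), _PHOBIC_SLOTS, "hydrophobic")
        lig = plant(target, _PHOBIC_RANGE, f"C{k + 1}", "C")
        d = float(np.linalg.norm(lig.coord - target.coord))
        ph_pairs.append((target.serial, lig.serial, d))
        counts.setdefault(("A", int(res)), [0, 0])[1] += 1

    all_atoms = atoms + lig_atoms
    structure = Structure(atoms=all_atoms)

    # defensive check of the planted-only guarantee
    if lig_atoms:
        pc = np.array([a.coord for a in atoms])
        lc = np.array([a.coord for a in lig_atoms])
        dm = np.sqrt(((pc[:, None, :] - lc[None, :, :]) ** 2).sum(axis=2))
        planted = {(p, l) for p, l, _ in hb_pairs} | {(p, l) for p, l, _ in ph_pairs}
        for i, pa in enumerate(atoms):
            for j, la in enumerate(lig_atoms):
                if (pa.serial, la.serial) in planted:
                    continue
                if dm[i, j] <= _MIN_OTHER_DISTANCE:
                    raise ValueError(
                        "infeasible packing: unplanned pair "
                        f"{pa.serial}-{la.serial} at {dm[i, j]:.2f} A"
                    )

    # random rigid orientation of the whole complex
    rot = _random_rotation(rng, 180.0)
    trans = rng.uniform(-20.0, 20.0, size=3)
    coords = structure.coords
    structure = structure.with_coords(coords @ rot.T + trans)

    truth = PlantedContacts(
        hbond_pairs=hb_pairs,
        hydrophobic_pairs=ph_pairs,
        per_residue_counts={k: (v[0], v[1]) for k, v in sorted(counts.items())},
    )
    return structure, truth
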