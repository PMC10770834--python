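"""PDB reading and geometric protein-ligand contact profiling.

Atoms come from fixed-width ATOM/HETATM records; HETATM entries other
than waters and common ions are treated as ligand atoms.  Two contact
classes are profiled between protein and ligand:

* hydrogen bonds — polar heavy-atom pairs (protein N/O, plus S on
  CYS/MET; ligand N/O) with donor-acceptor distance <= 3.5 A; when
  explicit hydrogens are attached to either partner, some hydrogen must
  additionally satisfy an H-D-A angle <= 30 deg (the geometry GROMACS
  uses for its hydrogen-bond analysis),
* hydrophobic contacts — any protein-carbon / ligand-carbon pair within
  4.0 A.

One atom pair meeting a criterion counts as one interaction; no
clustering is applied.  Both cutoffs are parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Structure",
    "HydrogenBond",
    "HydrophobicContact",
    "ContactProfile",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "find_hbonds",
    "find_hydrophobic_contacts",
    "interaction_summary",
]

HBOND_DISTANCE_CUTOFF = 3.5  # A, donor-acceptor heavy atoms
HBOND_ANGLE_CUTOFF = 30.0  # deg, H-D-A
HYDROPHOBIC_CUTOFF = 4.0  # A, C-C

WATER_RESIDUES = {"HOH", "WAT", "H2O", "SOL", "TIP", "TIP3", "TIP4"}
ION_RESIDUES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "SO4", "PO4", "BR", "IOD"}
_COVALENT_H_CUTOFF = 1.25  # A, H considered bonded to a heavy atom

_TWO_LETTER_ELEMENTS = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coord: np.ndarray  # A
    is_ligand: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.residue_number)


@dataclass
class Structure:
    """Flat list of atoms with cached coordinate access."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure has no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_number,
                 a.chain, c, a.is_ligand)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms)

    def protein_indices(self) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if not a.is_ligand
            and a.residue_name not in WATER_RESIDUES
            and a.residue_name not in ION_RESIDUES
        ]

    def ligand_indices(self) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if a.is_ligand
            and a.residue_name not in WATER_RESIDUES
            and a.residue_name not in ION_RESIDUES
        ]


def _infer_element(name: str, residue_name: str) -> str:
    """Element from an atom name when PDB columns 77-78 are blank."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and residue_name.strip().upper() in ION_RESIDUES | {"HEM"}:
        return two.capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int, path: Path) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}, line {lineno}: malformed fixed-width PDB record") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name, residue_name)
    if not element:
        raise ValueError(f"{path}, line {lineno}: cannot infer element for atom '{name}'")
    is_ligand = line.startswith("HETATM") and residue_name not in WATER_RESIDUES
    return Atom(
        serial=serial,
        name=name,
        element=element.capitalize(),
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        coord=np.array([x, y, z]),
        is_ligand=is_ligand,
    )


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a PDB file as a list of Structures."""
    path = Path(path)
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(current)
            current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno, path))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return [Structure(atoms=m) for m in models]


def read_pdb(path: str | Path) -> Structure | list[Structure]:
    """Read a PDB file: a single Structure, or a list when multi-model."""
    models = read_pdb_models(path)
    return models[0] if len(models) == 1 else models


def write_pdb(models: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one or more models in fixed-width PDB format."""
    if isinstance(models, Structure):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for a in model.atoms:
            rec = "HETATM" if a.is_ligand else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{rec}{a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                f"{a.chain:1.1s}{a.residue_number:4d}    "
                f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contact geometry


@dataclass(frozen=True)
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    distance: float  # A, donor-acceptor heavy atoms
    angle: float | None  # deg, H-D-A; None when no explicit hydrogens


@dataclass(frozen=True)
class HydrophobicContact:
    protein_atom: Atom
    ligand_atom: Atom
    distance: float  # A


@dataclass
class ContactProfile:
    hydrogen_bonds: list[HydrogenBond]
    hydrophobic_contacts: list[HydrophobicContact]
    per_residue_counts: dict[tuple[str, int], tuple[int, int]]


def _is_polar_protein(atom: Atom) -> bool:
    if atom.element in ("N", "O"):
        return True
    return atom.element == "S" and atom.residue_name in ("CYS", "MET")


def _is_polar_ligand(atom: Atom) -> bool:
    return atom.element in ("N", "O")


def _attached_hydrogens(structure: Structure, heavy: Atom) -> list[Atom]:
    out = []
    for a in structure.atoms:
        if a.element != "H":
            continue
        if a.residue_key != heavy.residue_key or a.is_ligand != heavy.is_ligand:
            continue
        if float(np.linalg.norm(a.coord - heavy.coord)) <= _COVALENT_H_CUTOFF:
            out.append(a)
    return out


def _hda_angle(h: Atom, donor: Atom, acceptor: Atom) -> float:
    """Angle at the donor between D->H and D->A, degrees."""
    v1 = h.coord - donor.coord
    v2 = acceptor.coord - donor.coord
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _require_both_sides(structure: Structure) -> tuple[list[int], list[int]]:
    prot = structure.protein_indices()
    lig = structure.ligand_indices()
    if not lig:
        raise ValueError("no ligand in structure")
    if not prot:
        raise ValueError("no protein atoms in structure")
    return prot, lig


def find_hbonds(
    structure: Structure,
    d_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list[HydrogenBond]:
    """Protein-ligand hydrogen bonds (criteria in the module docstring).

    A heavy-atom pair within ``d_cutoff`` is accepted outright when
    neither partner carries explicit hydrogens; otherwise at least one
    attached hydrogen must give an H-D-A angle <= ``angle_cutoff`` (that
    hydrogen's heavy atom is reported as the donor).
    """
    prot_idx, lig_idx = _require_both_sides(structure)
    prot_polar = [structure.atoms[i] for i in prot_idx
                  if _is_polar_protein(structure.atoms[i])]
    lig_polar = [structure.atoms[i] for i in lig_idx
                 if _is_polar_ligand(structure.atoms[i])]
    bonds: list[HydrogenBond] = []
    for p in prot_polar:
        for l in lig_polar:
            d = float(np.linalg.norm(p.coord - l.coord))
            if d > d_cutoff:
                continue
            h_p = _attached_hydrogens(structure, p)
            h_l = _attached_hydrogens(structure, l)
            if not h_p and not h_l:
                bonds.append(HydrogenBond(donor=p, acceptor=l, distance=d, angle=None))
                continue
            best: tuple[float, Atom, Atom] | None = None
            for donor, acceptor, hs in ((p, l, h_p), (l, p, h_l)):
                for h in hs:
                    ang = _hda_angle(h, donor, acceptor)
                    if ang <= angle_cutoff and (best is None or ang < best[0]):
                        best = (ang, donor, acceptor)
            if best is not None:
                bonds.append(
                    HydrogenBond(donor=best[1], acceptor=best[2], distance=d, angle=best[0])
                )
    bonds.sort(key=lambda b: (
        (b.donor if not b.donor.is_ligand else b.acceptor).residue_number, b.distance))
    return bonds


def find_hydrophobic_contacts(
    structure: Structure,
    d_cutoff: float = HYDROPHOBIC_CUTOFF,
) -> list[HydrophobicContact]:
    """Protein-carbon / ligand-carbon pairs within ``d_cutoff``."""
    prot_idx, lig_idx = _require_both_sides(structure)
    prot_c = [structure.atoms[i] for i in prot_idx if structure.atoms[i].element == "C"]
    lig_c = [structure.atoms[i] for i in lig_idx if structure.atoms[i].element == "C"]
    contacts: list[HydrophobicContact] = []
    if prot_c and lig_c:
        dm = cdist(np.array([a.coord for a in prot_c]),
                   np.array([a.coord for a in lig_c]))
        for i, j in zip(*np.nonzero(dm <= d_cutoff)):
            contacts.append(
                HydrophobicContact(prot_c[i], lig_c[j], float(dm[i, j]))
            )
    contacts.sort(key=lambda c: (c.protein_atom.residue_number, c.distance))
    return contacts


def interaction_summary(
    structure: Structure,
    hb_distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    hb_angle_cutoff: float = HBOND_ANGLE_CUTOFF,
    hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF,
) -> ContactProfile:
    """Combined per-residue contact profile of a protein-ligand complex."""
    hbonds = find_hbonds(structure, hb_distance_cutoff, hb_angle_cutoff)
    phobic = find_hydrophobic_contacts(structure, hydrophobic_cutoff)
    counts: dict[tuple[str, int], list[int]] = {}
    for b in hbonds:
        prot = b.donor if not b.donor.is_ligand else b.acceptor
        counts.setdefault(prot.residue_key, [0, 0])[0] += 1
    for c in phobic:
        counts.setdefault(c.protein_atom.residue_key, [0, 0])[1] += 1
    per_residue = {k: (v[0], v[1]) for k, v in sorted(counts.items())}
    return ContactProfile(
        hydrogen_bonds=hbonds,
        hydrophobic_contacts=phobic,
        per_residue_counts=per_residue,
    )
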