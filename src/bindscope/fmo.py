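"""Conceptual-DFT reactivity descriptors from frontier-orbital energies.

Within the frozen-orbital (Koopmans) approximation the HOMO and LUMO
energies of a molecule determine a family of global reactivity indices:
the HOMO–LUMO gap ``dE = E_LUMO - E_HOMO``, the electronic chemical
potential ``mu = (E_LUMO + E_HOMO)/2``, the chemical hardness
``eta = dE/2``, the vertical ionization potential ``I = -E_HOMO`` and
electron affinity ``A = -E_LUMO``, the Mulliken electronegativity
``chi = (I + A)/2 = -mu``, and the Parr electrophilicity index
``omega = mu**2 / (2*eta)``.

All energies are in eV; no unit conversion is performed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "OrbitalEnergies",
    "FMODescriptors",
    "compute_descriptors",
    "descriptor_table",
    "read_orbitals",
]


@dataclass(frozen=True)
class OrbitalEnergies:
    """HOMO/LUMO energy pair for one species, in eV."""

    e_homo: float
    e_lumo: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.e_homo <= self.e_lumo):
            raise ValueError(
                f"e_homo ({self.e_homo}) must not exceed e_lumo ({self.e_lumo})"
            )


@dataclass(frozen=True)
class FMODescriptors:
    """Global reactivity descriptors derived from one HOMO/LUMO pair (eV)."""

    energy_gap: float
    chemical_potential: float
    hardness: float
    ionization_potential: float
    electron_affinity: float
    electronegativity: float
    electrophilicity: float


def compute_descriptors(orbitals: OrbitalEnergies) -> FMODescriptors:
    """Derive all global reactivity descriptors from a HOMO/LUMO pair.

    Raises
    ------
    ValueError
        If ``e_homo == e_lumo`` (zero hardness, electrophilicity undefined).
    """
    gap = orbitals.e_lumo - orbitals.e_homo
    if gap == 0.0:
        raise ValueError("zero hardness: electrophilicity undefined")
    mu = (orbitals.e_lumo + orbitals.e_homo) / 2.0
    eta = gap / 2.0
    ip = -orbitals.e_homo
    ea = -orbitals.e_lumo
    chi = (ip + ea) / 2.0
    omega = mu * mu / (2.0 * eta)
    return FMODescriptors(
        energy_gap=gap,
        chemical_potential=mu,
        hardness=eta,
        ionization_potential=ip,
        electron_affinity=ea,
        electronegativity=chi,
        electrophilicity=omega,
    )


#: Row order of the standard descriptor report.
_ROW_ORDER = [
    ("HOMO", lambda o, d: o.e_homo),
    ("LUMO", lambda o, d: o.e_lumo),
    ("Energy gap", lambda o, d: d.energy_gap),
    ("Chemical potential", lambda o, d: d.chemical_potential),
    ("Global hardness", lambda o, d: d.hardness),
    ("Ionization potential", lambda o, d: d.ionization_potential),
    ("Electron affinity", lambda o, d: d.electron_affinity),
    ("Electronegativity", lambda o, d: d.electronegativity),
    ("Electrophilicity", lambda o, d: d.electrophilicity),
]


def descriptor_table(orbital_sets: Sequence[OrbitalEnergies]) -> pd.DataFrame:
    """Tabulate descriptors for several species, one column per species.

    Rows follow the conventional report order (HOMO, LUMO, gap, chemical
    potential, hardness, I, A, electronegativity, electrophilicity).
    """
    if len(orbital_sets) < 1:
        raise ValueError("at least one orbital-energy set required")
    labels = [o.label or f"species_{i}" for i, o in enumerate(orbital_sets)]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate species labels: {labels}")
    columns = {}
    for label, orb in zip(labels, orbital_sets):
        desc = compute_descriptors(orb)
        columns[label] = [fn(orb, desc) for _, fn in _ROW_ORDER]
    return pd.DataFrame(columns, index=[name for name, _ in _ROW_ORDER])


def read_orbitals(path: str | Path) -> list[OrbitalEnergies]:
    """Read ``label,e_homo,e_lumo`` rows from a delimited text file.

    Comma or tab delimited; ``#`` lines and a header row (non-numeric
    second column) are skipped.
    """
    path = Path(path)
    sets: list[OrbitalEnergies] = []
    with path.open(newline="") as fh:
        text = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    delim = "\t" if text and "\t" in text[0] else ","
    for lineno, line in enumerate(text, start=1):
        fields = [f.strip() for f in line.rstrip("\n").split(delim)]
        if len(fields) != 3:
            raise ValueError(f"{path}, line {lineno}: expected 3 fields, got {len(fields)}")
        try:
            homo, lumo = float(fields[1]), float(fields[2])
        except ValueError:
            if lineno == 1:  # tolerate a header row
                continue
            raise ValueError(f"{path}, line {lineno}: non-numeric orbital energy")
        sets.append(OrbitalEnergies(e_homo=homo, e_lumo=lumo, label=fields[0]))
    if not sets:
        raise ValueError(f"{path}: no orbital-energy rows found")
    return sets
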