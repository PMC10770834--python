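"""Molecular-dynamics trajectory observables, implemented from scratch.

All observables operate on trajectories read from multi-model PDB or
per-frame XYZ text; coordinates are held in Angstrom internally and
reported in the nm-based units conventional for MD summaries (nm for
distances, nm^2 for areas and covariance traces; fixed /10 and /100
conversions).

Observables:

* Kabsch least-squares rigid superposition (SVD with determinant sign
  correction) and per-frame RMSD,
* RMSF about the iteratively superposed time-average structure
  (two-pass, matching the usual GROMACS behaviour),
* mass-weighted radius of gyration,
* Shrake-Rupley solvent-accessible surface area with a deterministic
  golden-spiral point sphere (default 960 points, probe 1.4 A),
* per-frame intermolecular hydrogen-bond counts (3.5 A / 30 deg),
* essential-dynamics covariance analysis of selected atoms (trace,
  eigenvalues, projections on the leading eigenvectors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    HBOND_ANGLE_CUTOFF,
    HBOND_DISTANCE_CUTOFF,
    Structure,
    find_hbonds,
    read_pdb_models,
)

__all__ = [
    "AtomRadii",
    "Trajectory",
    "TrajectorySummary",
    "CovarianceResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "rg_series",
    "sasa",
    "sasa_series",
    "count_hbonds_series",
    "covariance_analysis",
    "summarize",
    "select_atoms",
    "read_xyz",
]

ANGSTROM_PER_NM = 10.0

#: Van der Waals radii (A), Bondi-style defaults.
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_PROBE_RADIUS = 1.4  # A, water probe

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
}

BACKBONE_NAMES = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class AtomRadii:
    """Element -> van der Waals radius (A) plus the probe radius (A)."""

    radii: dict[str, float]
    probe_radius: float = DEFAULT_PROBE_RADIUS

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.probe_radius < 0:
            raise ValueError("radii must be positive")

    @classmethod
    def default(cls) -> "AtomRadii":
        return cls(radii=dict(DEFAULT_VDW_RADII))

    def for_elements(self, elements: Sequence[str]) -> np.ndarray:
        out = np.empty(len(elements))
        for i, el in enumerate(elements):
            try:
                out[i] = self.radii[el]
            except KeyError:
                raise ValueError(f"no van der Waals radius for element '{el}'") from None
        return out


@dataclass
class Trajectory:
    """Topology plus an (n_frames, n_atoms, 3) coordinate array in A."""

    topology: Structure
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology {len(self.topology)}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Trajectory":
        models = read_pdb_models(path)
        frames = np.array([m.coords for m in models])
        return cls(topology=models[0], frames=frames)

    @classmethod
    def from_xyz(cls, path: str | Path, topology: Structure | None = None) -> "Trajectory":
        elements, frames = read_xyz(path)
        if topology is None:
            from .structure import Atom  # local to avoid a cycle at import time

            atoms = [
                Atom(serial=i + 1, name=el, element=el, residue_name="UNK",
                     residue_number=i + 1, chain="A", coord=frames[0][i])
                for i, el in enumerate(elements)
            ]
            topology = Structure(atoms=atoms)
        return cls(topology=topology, frames=np.asarray(frames))


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a (possibly multi-frame) XYZ file; coordinates in A."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}, line {i + 1}: expected atom count") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}, line {i + 1}: truncated frame")
        coords = np.empty((n, 3))
        els = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}, line {i + 3 + j}: malformed XYZ row")
            els.append(parts[0].capitalize())
            coords[j] = [float(v) for v in parts[1:4]]
        if elements and els != elements:
            raise ValueError(f"{path}: frames differ in atom identities")
        elements = els
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no XYZ frames")
    return elements, np.array(frames)


def select_atoms(topology: Structure, selection: str | Sequence[int] = "all") -> np.ndarray:
    """Resolve a selection ('all', 'ca', 'backbone', 'protein', or explicit
    indices) to an index array.  'backbone' falls back to all atoms when
    no backbone names are present."""
    if not isinstance(selection, str):
        idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection")
        if idx.min() < 0 or idx.max() >= len(topology):
            raise ValueError("selection index out of range")
        return idx
    sel = selection.lower()
    if sel == "all":
        return np.arange(len(topology))
    if sel == "protein":
        idx = topology.protein_indices()
    elif sel == "ca":
        idx = [i for i, a in enumerate(topology.atoms)
               if a.name == "CA" and not a.is_ligand]
    elif sel == "backbone":
        idx = [i for i, a in enumerate(topology.atoms)
               if a.name in BACKBONE_NAMES and not a.is_ligand]
        if not idx:
            idx = list(range(len(topology)))
    else:
        raise ValueError(f"unknown selection '{selection}'")
    if not idx:
        raise ValueError(f"selection '{selection}' matches no atoms")
    return np.asarray(idx)


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile[selection] @ rotation.T + translation`` best fits
    ``reference[selection]`` in the least-squares sense; ``rmsd`` is in A
    over the selection.  SVD-based with determinant sign correction so
    the result is a proper rotation.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if selection is None:
        sel = np.arange(reference.shape[0])
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise ValueError("degenerate superposition: need >= 3 selected atoms")
    ref = reference[sel]
    mob = mobile[sel]
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    p = mob - mob_c
    q = ref - ref_c
    # collinear selections leave the rotation about the line undetermined
    if np.linalg.matrix_rank(q - q.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate superposition: selected atoms are collinear")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_c - rotation @ mob_c
    moved = p @ rotation.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _superpose_frames(
    frames: np.ndarray, reference: np.ndarray, selection: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ``reference`` over ``selection``;
    the transform found on the selection is applied to all atoms."""
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        rot, trans, _ = kabsch_superpose(reference, frames[f], selection)
        out[f] = frames[f] @ rot.T + trans
    return out


def rmsd_series(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    selection: str | Sequence[int] = "backbone",
) -> np.ndarray:
    """Per-frame RMSD (nm) after superposition onto the reference frame."""
    sel = select_atoms(traj.topology, selection)
    if isinstance(reference, (int, np.integer)):
        if not 0 <= reference < traj.n_frames:
            raise ValueError(f"reference frame {reference} out of range")
        ref = traj.frames[reference]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (traj.n_atoms, 3):
            raise ValueError("reference coordinate shape mismatch")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, r = kabsch_superpose(ref, traj.frames[f], sel)
        out[f] = r
    return out / ANGSTROM_PER_NM


def _average_structure(frames: np.ndarray, selection: np.ndarray) -> np.ndarray:
    """Two-pass iterative average: superpose to frame 0, average, then
    re-superpose to that average and average again."""
    aligned = _superpose_frames(frames, frames[0], selection)
    avg = aligned.mean(axis=0)
    aligned = _superpose_frames(frames, avg, selection)
    return aligned.mean(axis=0), aligned


def rmsf(
    traj: Trajectory,
    selection: str | Sequence[int] = "ca",
    fit_selection: str | Sequence[int] | None = None,
) -> tuple[dict[tuple[str, int], float], np.ndarray]:
    """Per-residue RMSF (nm) about the time-averaged structure.

    Frames are superposed to the iteratively refined average structure
    over ``fit_selection`` (the analysis ``selection`` by default);
    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2).  Returns (residue -> nm
    map over the selected representative atoms, per-selected-atom array
    in nm).  A separate fit group avoids the superposition absorbing
    part of a localized fluctuation.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    sel = select_atoms(traj.topology, selection)
    fit_sel = sel if fit_selection is None else select_atoms(traj.topology, fit_selection)
    _, aligned = _average_structure(traj.frames, fit_sel)
    coords = aligned[:, sel, :]
    mean = coords.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    fluct_nm = fluct / ANGSTROM_PER_NM
    per_residue: dict[tuple[str, int], float] = {}
    for idx, value in zip(sel, fluct_nm):
        per_residue[traj.topology.atoms[idx].residue_key] = float(value)
    return per_residue, fluct_nm


# ---------------------------------------------------------------------------
# scalar frame observables


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration of one frame, in nm."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses))) / ANGSTROM_PER_NM


def _masses_for(topology: Structure, indices: np.ndarray) -> np.ndarray:
    out = np.empty(indices.size)
    for i, idx in enumerate(indices):
        el = topology.atoms[idx].element
        try:
            out[i] = ATOMIC_MASSES[el]
        except KeyError:
            raise ValueError(f"no atomic mass for element '{el}'") from None
    return out


def rg_series(traj: Trajectory, selection: str | Sequence[int] = "protein") -> np.ndarray:
    """Per-frame radius of gyration (nm) over the selection."""
    sel = select_atoms(traj.topology, selection)
    masses = _masses_for(traj.topology, sel)
    return np.array(
        [radius_of_gyration(traj.frames[f][sel], masses) for f in range(traj.n_frames)]
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    coords: np.ndarray,
    elements: Sequence[str],
    radii: AtomRadii | None = None,
    n_sphere_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area of one frame.

    Each atom's probe-inflated sphere carries ``n_sphere_points`` test
    points; a point is accessible when outside every neighbour's
    inflated sphere.  Returns (total, per-atom) areas in nm^2.
    """
    coords = np.asarray(coords, dtype=float)
    if radii is None:
        radii = AtomRadii.default()
    r = radii.for_elements(list(elements)) + radii.probe_radius
    n = coords.shape[0]
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    per_atom = np.empty(n)
    max_r = float(r.max())
    for i in range(n):
        pts = coords[i] + r[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], r[i] + max_r)
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < r[i] + r[j]]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > r[j] * r[j]
        frac = accessible.mean()
        per_atom[i] = frac * 4.0 * math.pi * r[i] * r[i]
    per_atom /= ANGSTROM_PER_NM**2
    return float(per_atom.sum()), per_atom


def sasa_series(
    traj: Trajectory,
    selection: str | Sequence[int] = "protein",
    radii: AtomRadii | None = None,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-frame total SASA (nm^2) over the selection."""
    sel = select_atoms(traj.topology, selection)
    elements = [traj.topology.atoms[i].element for i in sel]
    return np.array(
        [sasa(traj.frames[f][sel], elements, radii, n_sphere_points)[0]
         for f in range(traj.n_frames)]
    )


def count_hbonds_series(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    d_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> np.ndarray:
    """Per-frame count of hydrogen bonds between two disjoint atom groups.

    Applies the same geometric criteria as ``structure.find_hbonds``,
    with ``group_a`` playing the protein role and ``group_b`` the ligand
    role.
    """
    a = set(int(i) for i in group_a)
    b = set(int(i) for i in group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if a & b:
        raise ValueError(f"overlapping groups: {sorted(a & b)}")
    from .structure import Atom  # deferred to avoid import-cycle at module load

    counts = np.empty(traj.n_frames, dtype=int)
    order = sorted(a) + sorted(b)
    template = [traj.topology.atoms[i] for i in order]
    roles = [i in b for i in order]
    for f in range(traj.n_frames):
        atoms = [
            Atom(t.serial, t.name, t.element, t.residue_name, t.residue_number,
                 t.chain, traj.frames[f][i], is_ligand=role)
            for t, i, role in zip(template, order, roles)
        ]
        counts[f] = len(find_hbonds(Structure(atoms), d_cutoff, angle_cutoff))
    return counts


@dataclass
class CovarianceResult:
    """Essential-dynamics products over the selected atoms."""

    trace: float  # nm^2
    eigenvalues: np.ndarray  # nm^2, descending
    projections: np.ndarray  # (n_frames, 2), nm


def covariance_analysis(
    traj: Trajectory,
    selection: str | Sequence[int] = "ca",
) -> CovarianceResult:
    """Covariance of superposed selected coordinates: trace (nm^2),
    sorted eigenvalues and per-frame projections on the top two modes."""
    if traj.n_frames < 2:
        raise ValueError("covariance analysis needs >= 2 frames")
    sel = select_atoms(traj.topology, selection)
    if sel.size < 2:
        raise ValueError("covariance analysis needs >= 2 selected atoms")
    _, aligned = _average_structure(traj.frames, sel)
    x = aligned[:, sel, :].reshape(traj.n_frames, -1) / ANGSTROM_PER_NM
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    projections = centered @ evecs[:, :2]
    return CovarianceResult(
        trace=float(np.trace(cov)),
        eigenvalues=evals,
        projections=projections,
    )


@dataclass
class TrajectorySummary:
    """Time-averaged structural properties, nm-based units."""

    mean_rmsd: float  # nm
    mean_rmsf: float  # nm, mean over residues
    mean_rg: float  # nm
    mean_sasa: float  # nm^2
    covariance_trace: float  # nm^2
    per_residue_rmsf: dict[tuple[str, int], float]
    hbond_counts: np.ndarray | None = None


def summarize(
    traj: Trajectory,
    rmsd_selection: str | Sequence[int] = "backbone",
    rmsf_selection: str | Sequence[int] = "ca",
    radii: AtomRadii | None = None,
    n_sphere_points: int = 960,
    count_intermolecular_hbonds: bool = False,
) -> TrajectorySummary:
    """Run every observable and emit one summary row.

    RMSD is measured against frame 0 over the backbone (all atoms when
    no backbone names exist); RMSF over C-alpha representatives
    (falling back to all atoms); Rg and SASA over all protein atoms.
    Intermolecular hydrogen bonds (protein vs ligand) are counted only
    on request and only when ligand atoms exist.
    """
    top = traj.topology
    try:
        rmsf_sel: str | Sequence[int] = rmsf_selection
        select_atoms(top, rmsf_sel)
    except ValueError:
        rmsf_sel = "all"
    per_res, _ = rmsf(traj, rmsf_sel)
    rmsds = rmsd_series(traj, 0, rmsd_selection)
    has_protein = bool(top.protein_indices())
    rg_sel = "protein" if has_protein else "all"
    rgs = rg_series(traj, rg_sel)
    sasas = sasa_series(traj, rg_sel, radii, n_sphere_points)
    cov = covariance_analysis(traj, rmsf_sel)
    hbonds = None
    if count_intermolecular_hbonds:
        prot = top.protein_indices()
        lig = top.ligand_indices()
        if lig:
            hbonds = count_hbonds_series(traj, prot, lig)
    return TrajectorySummary(
        mean_rmsd=float(rmsds.mean()),
        mean_rmsf=float(np.mean(list(per_res.values()))),
        mean_rg=float(rgs.mean()),
        mean_sasa=float(sasas.mean()),
        covariance_trace=cov.trace,
        per_residue_rmsf=per_res,
        hbond_counts=hbonds,
    )
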