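"""Orchestration: end-to-end runs producing delimited text reports.

Each pipeline consumes the text formats the analysis modules read,
executes a full stage chain, and writes a diff-able report with a
``#``-prefixed provenance header (package version, seed, config hash).
Reports use kJ/mol for energies (1 decimal), J/(mol K) for entropies,
and nm-based units for trajectory observables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import fit_double_reciprocal, vant_hoff
from .fmo import descriptor_table, read_orbitals
from .spectra import celsius_to_kelvin, delta_f_series, read_titration
from .trajectory import (
    AtomRadii,
    Trajectory,
    count_hbonds_series,
    rg_series,
    rmsd_series,
    sasa_series,
    summarize,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_binding_pipeline",
    "run_fmo_pipeline",
    "run_trajectory_pipeline",
]

logger = logging.getLogger("bindscope")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for the orchestrated pipelines.

    ``titration_files`` maps temperature in Celsius to a titration file;
    trajectory inputs are multi-model PDB paths, one per system.
    """

    titration_files: dict[float, str] = field(default_factory=dict)
    orbitals_file: str | None = None
    trajectory_files: dict[str, str] = field(default_factory=dict)
    analysis_wavelength: float = 340.0  # nm
    hbond_distance_cutoff: float = 3.5  # A
    hbond_angle_cutoff: float = 30.0  # deg
    hydrophobic_cutoff: float = 4.0  # A
    probe_radius: float = 1.4  # A
    n_sphere_points: int = 960
    rmsd_selection: str = "backbone"
    rmsf_selection: str = "ca"
    seed: int = 0
    output_dir: str = "bindscope_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.titration_files = {float(k): str(v) for k, v in cfg.titration_files.items()}
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"# bindscope {__version__}",
        f"# config_hash={config.config_hash()} seed={config.seed}",
    ]


def _write_report(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\n".join(_provenance(config)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    logger.info("wrote %s", path)


def run_binding_pipeline(config: RunConfig) -> pd.DataFrame:
    """Titration files -> per-temperature binding fits -> thermodynamics.

    Emits one row per temperature with Kb, r^2, dG (and, on the final
    rows, dH, dS and the force class once >= 2 temperatures exist);
    single-temperature input yields the Kb row with thermodynamic
    columns marked unavailable.
    """
    if not config.titration_files:
        raise PipelineError("binding", "no titration files configured")
    fits = {}
    for t_c, path in sorted(config.titration_files.items()):
        if not Path(path).exists():
            raise PipelineError("binding", f"missing titration file: {path}")
        t_k = celsius_to_kelvin(t_c)
        try:
            series = read_titration(path, excitation_wavelength=295.0, temperature=t_k)
            dfs = delta_f_series(series, wavelength=config.analysis_wavelength)
            if dfs.excluded:
                logger.info(
                    "binding: %s: excluded %d non-positive dF pairs", path, len(dfs.excluded)
                )
            fits[t_k] = fit_double_reciprocal(
                dfs.points, wavelength=config.analysis_wavelength, temperature=t_k
            )
        except ValueError as exc:
            raise PipelineError("binding", f"{path}: {exc}") from exc

    thermo = None
    if len(fits) >= 2:
        try:
            thermo = vant_hoff({t: f.kb for t, f in fits.items()})
        except ValueError as exc:
            raise PipelineError("vant-hoff", str(exc)) from exc

    rows = []
    for t_k, fit in sorted(fits.items()):
        row = {
            "temperature_C": round(t_k - 273.15, 2),
            "Kb_per_M": fit.kb,
            "r_squared": round(fit.r_squared, 4),
            "delta_G_kJ_per_mol": (
                round(thermo.delta_g_by_temperature[t_k] / 1000.0, 1) if thermo else float("nan")
            ),
            "delta_G_direct_kJ_per_mol": (
                round(thermo.delta_g_direct_by_temperature[t_k] / 1000.0, 1)
                if thermo
                else float("nan")
            ),
            "delta_H_kJ_per_mol": round(thermo.delta_h / 1000.0, 1) if thermo else float("nan"),
            "delta_S_J_per_mol_K": round(thermo.delta_s, 1) if thermo else float("nan"),
            "force_class": thermo.force_class if thermo else "unavailable",
        }
        rows.append(row)
    report = pd.DataFrame(rows)
    _write_report(report, Path(config.output_dir) / "binding_report.tsv", config)
    return report


def run_fmo_pipeline(config: RunConfig) -> pd.DataFrame:
    """Orbital-energy file -> full reactivity-descriptor table."""
    if not config.orbitals_file:
        raise PipelineError("fmo", "no orbitals file configured")
    if not Path(config.orbitals_file).exists():
        raise PipelineError("fmo", f"missing orbitals file: {config.orbitals_file}")
    try:
        sets = read_orbitals(config.orbitals_file)
        table = descriptor_table(sets)
    except ValueError as exc:
        raise PipelineError("fmo", str(exc)) from exc
    out = table.reset_index().rename(columns={"index": "parameter"})
    _write_report(out, Path(config.output_dir) / "fmo_report.tsv", config)
    return table


def run_trajectory_pipeline(config: RunConfig) -> pd.DataFrame:
    """Trajectories -> one time-averaged summary row each, plus
    per-frame RMSD/Rg/SASA (and H-bond) series files."""
    if not config.trajectory_files:
        raise PipelineError("trajectory", "no trajectory files configured")
    radii = AtomRadii(radii=dict(AtomRadii.default().radii), probe_radius=config.probe_radius)
    rows = []
    out_dir = Path(config.output_dir)
    for label, path in config.trajectory_files.items():
        if not Path(path).exists():
            raise PipelineError("trajectory", f"missing trajectory file: {path}")
        try:
            traj = Trajectory.from_pdb(path)
            has_ligand = bool(traj.topology.ligand_indices())
            summary = summarize(
                traj,
                rmsd_selection=config.rmsd_selection,
                rmsf_selection=config.rmsf_selection,
                radii=radii,
                n_sphere_points=config.n_sphere_points,
                count_intermolecular_hbonds=has_ligand,
            )
            series = pd.DataFrame(
                {
                    "frame": np.arange(traj.n_frames),
                    "rmsd_nm": rmsd_series(traj, 0, config.rmsd_selection),
                    "rg_nm": rg_series(traj),
                    "sasa_nm2": sasa_series(
                        traj, radii=radii, n_sphere_points=config.n_sphere_points
                    ),
                }
            )
            if summary.hbond_counts is not None:
                series["n_hbonds"] = summary.hbond_counts
            _write_report(series, out_dir / f"series_{label}.tsv", config)
        except ValueError as exc:
            raise PipelineError("trajectory", f"{label} ({path}): {exc}") from exc
        rows.append(
            {
                "system": label,
                "mean_rmsd_nm": summary.mean_rmsd,
                "mean_rmsf_nm": summary.mean_rmsf,
                "mean_rg_nm": summary.mean_rg,
                "mean_sasa_nm2": summary.mean_sasa,
                "covariance_trace_nm2": summary.covariance_trace,
            }
        )
    report = pd.DataFrame(rows)
    _write_report(report, out_dir / "trajectory_report.tsv", config)
    return report
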