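"""Readers and writers for the pipeline's text formats.

* rate tables: delimited text with columns ``temperature_K`` and
  ``rate_per_s`` (or ``ln_rate``), optional ``sd_ln_rate``; ``#`` comments;
* energy tables: ``time_ps``, ``energy_total``, optional ``energy_<region>``
  columns and an optional integer ``cluster`` column; one file per replicate;
* manifests: YAML files listing the replicate files of one state ensemble
  together with the state and temperature;
* coordinates: multi-model PDB (via Biopython) or plain whitespace XYZ
  frames with a sidecar atom table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .fluctuation import EnergyTrajectory, StateEnsemble
from .mmrt import FitResult, RateProfile
from .structure import CoordinateTrajectory

__all__ = [
    "read_rate_profile",
    "write_rate_profile",
    "read_energy_table",
    "write_energy_table",
    "read_manifest",
    "write_manifest",
    "read_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "write_fit_report",
]


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


# -- rate profiles -----------------------------------------------------------

def read_rate_profile(path: str | Path, label: str = "") -> RateProfile:
    df = _read_table(path)
    if "temperature_K" not in df.columns:
        raise SchemaError(f"{path}: missing column 'temperature_K'")
    if "rate_per_s" in df.columns:
        rates, log_scale = df["rate_per_s"].to_numpy(), False
    elif "ln_rate" in df.columns:
        rates, log_scale = df["ln_rate"].to_numpy(), True
    else:
        raise SchemaError(f"{path}: need a 'rate_per_s' or 'ln_rate' column")
    sd = df["sd_ln_rate"].to_numpy() if "sd_ln_rate" in df.columns else None
    return RateProfile(
        temperatures=df["temperature_K"].to_numpy(),
        rates=rates,
        log_scale=log_scale,
        replicate_sd=sd,
        label=label or str(path),
    )


def write_rate_profile(profile: RateProfile, path: str | Path) -> None:
    cols = {"temperature_K": profile.temperatures}
    cols["ln_rate" if profile.log_scale else "rate_per_s"] = profile.rates
    if profile.replicate_sd is not None:
        cols["sd_ln_rate"] = profile.replicate_sd
    pd.DataFrame(cols).to_csv(path, index=False)


# -- energy tables -----------------------------------------------------------

def read_energy_table(
    path: str | Path,
    temperature: float,
    state: str = "reactant",
    replicate_id: str = "",
) -> EnergyTrajectory:
    df = _read_table(path)
    for col in ("time_ps", "energy_total"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    regions = {
        c.removeprefix("energy_"): df[c].to_numpy()
        for c in df.columns
        if c.startswith("energy_") and c != "energy_total"
    }
    labels = df["cluster"].to_numpy() if "cluster" in df.columns else None
    return EnergyTrajectory(
        times=df["time_ps"].to_numpy(),
        energies=df["energy_total"].to_numpy(),
        temperature=temperature,
        state=state,
        replicate_id=replicate_id or Path(path).stem,
        region_energies=regions,
        cluster_labels=labels,
    )


def write_energy_table(traj: EnergyTrajectory, path: str | Path) -> None:
    cols = {"time_ps": traj.times, "energy_total": traj.energies}
    for name, col in traj.region_energies.items():
        cols[f"energy_{name}"] = col
    if traj.cluster_labels is not None:
        cols["cluster"] = traj.cluster_labels
    pd.DataFrame(cols).to_csv(path, index=False)


# -- manifests ---------------------------------------------------------------

def read_manifest(path: str | Path) -> StateEnsemble:
    """Load a state ensemble from a YAML manifest.

    Schema::

        state: reactant | ts_analogue
        temperature_K: 320.0
        burn_in_fraction: 0.1        # optional
        replicates:
          - {file: rs_0.csv, replicate_id: rs_0}
          - ...

    Replicate paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"manifest not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("state", "temperature_K", "replicates"):
        if key not in doc:
            raise SchemaError(f"{path}: manifest missing key {key!r}")
    trajs = []
    for entry in doc["replicates"]:
        fpath = Path(entry["file"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise SchemaError(f"{path}: replicate file not found: {fpath}")
        trajs.append(
            read_energy_table(
                fpath,
                temperature=float(doc["temperature_K"]),
                state=doc["state"],
                replicate_id=entry.get("replicate_id", fpath.stem),
            )
        )
    return StateEnsemble(
        trajectories=trajs,
        burn_in_fraction=float(doc.get("burn_in_fraction", 0.1)),
    )


def write_manifest(
    ensemble: StateEnsemble, directory: str | Path, name: str
) -> Path:
    """Write replicate energy tables plus a manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for traj in ensemble.trajectories:
        fname = f"{name}_{traj.replicate_id}.csv"
        write_energy_table(traj, directory / fname)
        entries.append({"file": fname, "replicate_id": traj.replicate_id})
    doc = {
        "state": ensemble.state,
        "temperature_K": float(ensemble.temperature),
        "burn_in_fraction": float(ensemble.burn_in_fraction),
        "replicates": entries,
    }
    mpath = directory / f"{name}_manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return mpath


# -- coordinates -------------------------------------------------------------

def read_pdb_trajectory(path: str | Path, time_step_ps: float = 10.0) -> CoordinateTrajectory:
    """Read a multi-model PDB file; each MODEL becomes one frame.

    Atom order must be identical across models (standard for trajectory-style
    multi-model files).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames, names, resids, chains = [], None, None, None
    for model in structure:
        coords, nm, ri, ch = [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append(atom.coord)
                    nm.append(atom.get_name())
                    ri.append(residue.id[1])
                    ch.append(chain.id)
        frames.append(np.asarray(coords, dtype=float))
        if names is None:
            names, resids, chains = nm, ri, ch
    if not frames:
        raise SchemaError(f"{path}: no models found")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise SchemaError(f"{path}: atom count varies across models")
    return CoordinateTrajectory(
        frames=np.stack(frames),
        atom_names=np.array(names),
        residue_ids=np.array(resids),
        chain_ids=np.array(chains),
        time_step_ps=time_step_ps,
    )


def read_xyz_trajectory(
    xyz_path: str | Path, atoms_path: str | Path, time_step_ps: float = 10.0
) -> CoordinateTrajectory:
    """Plain whitespace XYZ frames plus a sidecar atom table.

    The sidecar is a delimited table with columns ``atom_name``,
    ``residue_id``, ``chain_id`` (one row per atom); the XYZ file holds
    F·N lines of three floats.
    """
    atoms = _read_table(atoms_path)
    for col in ("atom_name", "residue_id", "chain_id"):
        if col not in atoms.columns:
            raise SchemaError(f"{atoms_path}: missing column {col!r}")
    coords = np.loadtxt(xyz_path, comments="#")
    if coords.ndim == 1:
        coords = coords[None, :]
    n = len(atoms)
    if coords.shape[0] % n != 0 or coords.shape[1] != 3:
        raise SchemaError(
            f"{xyz_path}: {coords.shape[0]} rows not a multiple of "
            f"{n} atoms (or not 3 columns)"
        )
    return CoordinateTrajectory(
        frames=coords.reshape(-1, n, 3),
        atom_names=atoms["atom_name"].to_numpy(),
        residue_ids=atoms["residue_id"].to_numpy(),
        chain_ids=atoms["chain_id"].to_numpy().astype(str),
        time_step_ps=time_step_ps,
    )


def write_xyz_trajectory(
    traj: CoordinateTrajectory, xyz_path: str | Path, atoms_path: str | Path
) -> None:
    pd.DataFrame(
        {
            "atom_name": traj.atom_names,
            "residue_id": traj.residue_ids,
            "chain_id": traj.chain_ids,
        }
    ).to_csv(atoms_path, index=False)
    np.savetxt(xyz_path, traj.frames.reshape(-1, 3), fmt="%.6f")


# -- reports -----------------------------------------------------------------

def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Machine-readable JSON fit report plus a key:value text twin."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    lines = [
        f"dH_T0_kJ_mol: {result.params.dH_T0:.6g}",
        f"dS_T0_kJ_mol_K: {result.params.dS_T0:.6g}",
        f"dCp_kJ_mol_K: {result.params.dCp:.6g}",
        f"T0_K: {result.params.T0:.6g}",
        f"sd_dCp: {result.param_sd['dCp']:.6g}",
        f"residual_sd_ln_rate: {result.residual_sd:.6g}",
        f"topt_K: {'none' if result.topt is None else f'{result.topt:.6g}'}",
        f"n_iter_T0: {result.n_iter_T0}",
    ]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
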