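"""Readers, writers and run configuration shared by all modules.

Coordinates are always Å, energies kJ/mol.  PDB handles host/water/crystal
structures (B-factors preserved); a compact CSV trajectory format carries
what PDB cannot — per-frame water orientations as quaternions:

    frame,water_id,x,y,z,qw,qx,qy,qz
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__

WATER_RESNAMES = {"HOH", "WAT", "SOL"}

#: maximum host-coordinate drift tolerated across frames (no alignment here)
HOST_DRIFT_TOL = 1e-3


@dataclass
class Structure:
    """Parsed PDB content: host heavy sites, water oxygens, B-factors."""

    host_positions: np.ndarray
    host_elements: list
    host_b_factors: np.ndarray
    water_positions: np.ndarray
    water_b_factors: np.ndarray


def read_structure(path) -> Structure:
    """Read a PDB file into hosts and waters (waters by residue name
    HOH/WAT/SOL, oxygen atoms only).  1-based PDB serials become 0-based
    array indices; B-factors are retained for reporting."""
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = pdb.PDBFile.read(str(path)).get_structure(
            model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise ValueError(f"{path}: malformed PDB ({exc})") from exc
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    is_water = np.isin(arr.res_name, list(WATER_RESNAMES))
    water_o = is_water & (np.char.strip(arr.element) == "O")
    host = ~is_water
    return Structure(
        host_positions=arr.coord[host].astype(float),
        host_elements=list(arr.element[host]),
        host_b_factors=arr.b_factor[host].astype(float),
        water_positions=arr.coord[water_o].astype(float),
        water_b_factors=arr.b_factor[water_o].astype(float),
    )


def write_structure(path, host_positions=None, water_positions=None,
                    host_element="C", b_factors=None,
                    occupancies=None) -> None:
    """Write hosts (HETATM, residue LIG) and waters (HETATM, residue HOH)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    hosts = np.asarray(host_positions if host_positions is not None
                       else np.zeros((0, 3)), dtype=float).reshape(-1, 3)
    waters = np.asarray(water_positions if water_positions is not None
                        else np.zeros((0, 3)), dtype=float).reshape(-1, 3)
    n = len(hosts) + len(waters)
    if n == 0:  # valid, headered, empty structure
        Path(path).write_text(f"REMARK   6 grandgist {__version__}\nEND\n")
        return
    arr = struc.AtomArray(n)
    arr.coord = np.concatenate([hosts, waters]) if n else np.zeros((0, 3))
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["LIG"] * len(hosts) + ["HOH"] * len(waters))
    arr.atom_name = np.array([host_element] * len(hosts) + ["O"] * len(waters))
    arr.element = np.array([host_element] * len(hosts) + ["O"] * len(waters))
    arr.hetero = np.ones(n, dtype=bool)
    arr.set_annotation("b_factor", np.asarray(
        b_factors if b_factors is not None else np.zeros(n), dtype=float))
    arr.set_annotation("occupancy", np.asarray(
        occupancies if occupancies is not None else np.ones(n), dtype=float))
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def write_cluster_pdb(path, clusters) -> None:
    """One pseudo-atom per cluster centroid; PDB occupancy column carries
    the cluster occupancy."""
    write_structure(path, water_positions=clusters.centroids,
                    occupancies=(clusters.occupancies if len(clusters)
                                 else None))


# ---------------------------------------------------------------------------
# trajectories

def write_trajectory_csv(path, frames) -> None:
    """Write frames of (positions, quaternions) in the compact CSV schema.

    Quaternions follow the file schema's scalar-first order (qw first);
    in-memory arrays are scalar-last.
    """
    with open(path, "w") as fh:
        fh.write(f"# grandgist {__version__} compact trajectory; "
                 "units Å; quaternion scalar-first\n")
        fh.write("frame,water_id,x,y,z,qw,qx,qy,qz\n")
        for i, (pos, quat) in enumerate(frames):
            pos = np.asarray(pos, dtype=float).reshape(-1, 3)
            quat = np.asarray(quat, dtype=float).reshape(-1, 4)
            for j, (p, q) in enumerate(zip(pos, quat)):
                fh.write(f"{i},{j},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
                         f"{q[3]:.8f},{q[0]:.8f},{q[1]:.8f},{q[2]:.8f}\n")


def read_trajectory(path):
    """Read an ordered frame list of (positions, quaternions).

    Accepts the compact CSV format, a multi-model PDB (orientations default
    to identity — PDB cannot carry them), or a directory of per-frame PDBs.
    Host coordinates drifting by more than 1e-3 Å across PDB frames raise an
    error, since no alignment is implemented.
    """
    import pandas as pd

    path = Path(path)
    if path.is_dir():
        frames = []
        host_ref = None
        for sub in sorted(path.glob("*.pdb")):
            s = read_structure(sub)
            host_ref = _check_host_drift(host_ref, s.host_positions, sub)
            frames.append((s.water_positions,
                           _identity_quats(len(s.water_positions))))
        if not frames:
            raise ValueError(f"{path}: no per-frame PDBs found")
        return frames
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        required = ["frame", "water_id", "x", "y", "z", "qw", "qx", "qy", "qz"]
        if list(df.columns) != required:
            raise ValueError(f"{path}: expected columns {required}")
        frames = []
        for _, grp in df.groupby("frame", sort=True):
            pos = grp[["x", "y", "z"]].to_numpy()
            quat = grp[["qx", "qy", "qz", "qw"]].to_numpy()  # to scalar-last
            if len(quat):  # renormalize away file-precision truncation
                quat = quat / np.linalg.norm(quat, axis=1, keepdims=True)
            frames.append((pos, quat))
        return frames
    return _read_multimodel_pdb(path)


def _identity_quats(n):
    q = np.zeros((n, 4))
    q[:, 3] = 1.0
    return q


def _check_host_drift(ref, hosts, where):
    if ref is None:
        return hosts
    if ref.shape != hosts.shape or (
            len(ref) and np.max(np.abs(ref - hosts)) > HOST_DRIFT_TOL):
        raise ValueError(
            f"{where}: host coordinates drift beyond {HOST_DRIFT_TOL} Å "
            "across frames and no alignment is implemented")
    return ref


def _read_multimodel_pdb(path):
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    n_models = f.get_model_count()
    frames = []
    host_ref = None
    for m in range(1, n_models + 1):
        arr = f.get_structure(model=m)
        is_water = np.isin(arr.res_name, list(WATER_RESNAMES))
        water_o = is_water & (np.char.strip(arr.element) == "O")
        host_ref = _check_host_drift(host_ref, arr.coord[~is_water].astype(float),
                                     f"{path} model {m}")
        pos = arr.coord[water_o].astype(float)
        frames.append((pos, _identity_quats(len(pos))))
    return frames


def write_frames_pdb(path, frames, host_positions=None) -> None:
    """Write water frames (plus fixed hosts) as a multi-model PDB."""
    lines = []
    hosts = np.asarray(host_positions if host_positions is not None
                       else np.zeros((0, 3))).reshape(-1, 3)
    for i, frame in enumerate(frames, start=1):
        pos = np.asarray(frame[0] if isinstance(frame, tuple) else frame,
                         dtype=float).reshape(-1, 3)
        lines.append(f"MODEL     {i:4d}")
        serial = 1
        for h in hosts:
            lines.append(_pdb_atom_line(serial, "C", "LIG", serial, h, hetero=True))
            serial += 1
        for w in pos:
            lines.append(_pdb_atom_line(serial, "O", "HOH", serial, w, hetero=True))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom_line(serial, name, resname, resid, xyz, hetero=False,
                   occupancy=1.0, b_factor=0.0):
    record = "HETATM" if hetero else "ATOM  "
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record}{serial:5d} {name_field} {resname:<3s} A{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}"
            f"{b_factor:6.2f}          {name[:1]:>2s}")


# ---------------------------------------------------------------------------
# run configuration

class SamplerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    B_grid: list[float] = Field(default_factory=lambda: [
        -16.0, -14.0, -12.0, -10.0, -8.0, -6.0, -4.0, -2.0, 0.0])
    n_moves: int = Field(default=50_000, gt=0)
    record_every: int = Field(default=10, gt=0)
    seeds: list[int] = Field(default_factory=lambda: [0])
    temperature: float = Field(default=298.0, gt=0)
    max_translation: float = Field(default=0.3, gt=0)
    mu_ex: float = Field(default=-25.9)
    V_std: float = Field(default=30.0, gt=0)


class GridSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    origin: list[float] = Field(default_factory=lambda: [0.0, 0.0, 0.0])
    spacing: float = Field(default=0.5, gt=0)
    dims: list[int] = Field(default_factory=lambda: [10, 10, 10])


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cluster_cutoff: float = Field(default=2.4, gt=0)
    match_dist: float = Field(default=1.4, gt=0)
    occupancy_min: float = Field(default=0.3, ge=0, le=1)
    recovery_max_dist: float = Field(default=2.0, gt=0)
    pairing_dist: float = Field(default=1.0, gt=0)
    subsample_interval: int = Field(default=1, gt=0)
    discard_fraction: float = Field(default=0.2, ge=0, lt=1)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    system: str = "toy_host"
    water_model: str = "lj_probe"
    out_prefix: str = "run"
    sampler: SamplerSettings = Field(default_factory=SamplerSettings)
    grid: GridSettings = Field(default_factory=GridSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locations = "; ".join(
            "/".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors())
        raise ValueError(f"{path}: invalid config ({locations})") from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.model_dump(), sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# output bundles

def _header(seed) -> str:
    return f"# grandgist {__version__}; seed {seed}; units Å, kJ/mol\n"


def write_csv_with_header(path, df, seed) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False)


def write_outputs(prefix, seed, config: RunConfig | None = None,
                  titration_curve=None, profile=None, gist_result=None,
                  clusters=None, trace=None) -> list[Path]:
    """Write whichever result objects are present as a deterministic file
    set under ``prefix``; every file carries package version and seed."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(suffix, writer):
        p = prefix.parent / (prefix.name + suffix)
        writer(p)
        written.append(p)

    if config is not None:
        emit(".config.yaml", lambda p: save_config(config, p))
    if titration_curve is not None:
        emit(".titration.csv",
             lambda p: write_csv_with_header(p, titration_curve.to_frame(), seed))
    if profile is not None:
        emit(".profile.csv",
             lambda p: write_csv_with_header(p, profile.to_frame(), seed))
    if gist_result is not None:
        emit(".gist.csv",
             lambda p: write_csv_with_header(p, gist_result.to_frame(), seed))
        from .gist import density_map, write_dx

        emit(".density.dx",
             lambda p: write_dx(density_map(gist_result), gist_result.grid, p))
    if clusters is not None:
        emit(".clusters.pdb", lambda p: write_cluster_pdb(p, clusters))
    if trace is not None:
        emit(".trace.csv",
             lambda p: write_csv_with_header(p, trace.to_frame(), seed))
    return written
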