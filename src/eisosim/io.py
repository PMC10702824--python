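"""File formats: config files, state snapshots, trajectory exports, TIFF.

Configs are flat key/value TOML or JSON files whose keys are exactly the
:class:`~eisosim.model.SimulationConfig` field names; unknown keys are
rejected.  Snapshots are CSV with columns ``i, j, x, y, z, is_bar,
is_frozen``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import LatticeState, SimulationConfig, build_config, init_lattice

__all__ = [
    "load_config_file",
    "config_to_dict",
    "save_state_csv",
    "load_state_csv",
    "save_trajectory",
    "read_tiff",
    "write_tiff",
    "save_ground_truth",
]


def load_config_file(path, **overrides) -> SimulationConfig:
    """Load a simulation config from TOML or JSON (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    elif path.suffix.lower() == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r} (use .toml or .json)")
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat key/value table")
    raw.update(overrides)
    return build_config(raw)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_hash(config: SimulationConfig) -> str:
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_state_csv(state: LatticeState, path) -> None:
    Lx, Ly = state.shape
    ii, jj = np.meshgrid(np.arange(Lx), np.arange(Ly), indexing="ij")
    df = pd.DataFrame({
        "i": ii.ravel(), "j": jj.ravel(),
        "x": state.x.ravel(), "y": jj.ravel().astype(float), "z": state.z.ravel(),
        "is_bar": state.bar.ravel().astype(int),
        "is_frozen": state.frozen_z.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def load_state_csv(path, config: SimulationConfig) -> LatticeState:
    df = pd.read_csv(path)
    state = init_lattice(config)
    Lx, Ly = state.shape
    if len(df) != Lx * Ly:
        raise ValueError("snapshot size does not match the configured lattice")
    idx = (df["i"].to_numpy(), df["j"].to_numpy())
    state.x[idx] = df["x"].to_numpy()
    state.z[idx] = df["z"].to_numpy()
    return state


def save_trajectory(traj, outdir) -> None:
    """Write trajectory.csv, snapshots/, events.csv and provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = {
        "sweep": traj.sweeps,
        "total_energy": traj.energy_total,
        "spring": traj.energy_spring,
        "drag": traj.energy_drag,
        "elastic_plain": traj.energy_elastic_plain,
        "elastic_bar": traj.energy_elastic_bar,
        "acceptance": traj.acceptance,
    }
    if traj.phi_left is not None:
        from .model import bar_region

        _, rows = bar_region(traj.config)
        for k, j in enumerate(rows):
            cols[f"phi_left_{j}"] = traj.phi_left[:, k]
            cols[f"phi_right_{j}"] = traj.phi_right[:, k]
    pd.DataFrame(cols).to_csv(outdir / "trajectory.csv", index=False)

    snapdir = outdir / "snapshots"
    snapdir.mkdir(exist_ok=True)
    for sweep, st in traj.snapshots:
        save_state_csv(st, snapdir / f"sweep_{sweep:08d}.csv")

    pd.DataFrame(traj.events, columns=["side", "row", "sweep"]).to_csv(
        outdir / "events.csv", index=False)

    prov = {
        "config": config_to_dict(traj.config),
        "config_hash": config_hash(traj.config),
        "seed": traj.config.seed,
        "eisosim_version": __version__,
        "plateau_sweep": traj.plateau_sweep,
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))


def read_tiff(path, pixel_size_nm: float, channel: str = ""):
    """Read a single- or multi-page TIFF into ImageFrame(s)."""
    import tifffile

    from .quant import ImageFrame

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return ImageFrame(arr.astype(float), pixel_size_nm, channel)
    return [ImageFrame(a.astype(float), pixel_size_nm, f"{channel}{k}")
            for k, a in enumerate(arr)]


def write_tiff(frames, path) -> None:
    import tifffile

    if not isinstance(frames, (list, tuple)):
        frames = [frames]
    data = np.stack([f.data.astype(np.float32) for f in frames])
    tifffile.imwrite(path, data.squeeze())


def save_ground_truth(truth, path) -> None:
    d = dataclasses.asdict(truth)
    for key, val in d.items():
        if isinstance(val, np.ndarray):
            d[key] = val.tolist()
    Path(path).write_text(json.dumps(d, indent=1))
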