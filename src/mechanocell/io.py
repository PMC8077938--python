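"""Config files, trajectory CSV interchange, and run manifests.

Trajectories are exchanged as long-format CSV with the mandatory header

    trajectory_id,step,time,x,y,x_unwrapped,y_unwrapped,theta

(floats at 9 significant digits; ``theta`` empty when orientation is unused).
Config files are flat YAML with exactly one of a ``scaled:`` or
``dimensional:`` block plus optional ``simulation:`` settings.  Every CLI run
writes a JSON manifest (parameters, seed, code version, timestamp, outputs)
sufficient to reproduce its outputs bit-exactly.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import Ensemble, SimulationConfig, Trajectory
from .params import DimensionalParams, ScaledParams, nondimensionalize
from .potentials import ImageLattice, PotentialSpec

__all__ = [
    "read_config",
    "write_trajectories",
    "read_trajectories",
    "write_manifest",
    "ConfigError",
    "SchemaError",
]

_CSV_COLUMNS = ["trajectory_id", "step", "time", "x", "y", "x_unwrapped", "y_unwrapped", "theta"]

_SCALED_KEYS = {"alpha", "DT", "ksteric", "phi_nu", "nu"}
_DIMENSIONAL_KEYS = {"sigma", "temperature", "D0", "Deff", "E", "nu", "P", "k", "muT"}
_SIMULATION_KEYS = {
    "dt",
    "total_time",
    "box_size",
    "contact_radius",
    "boundary",
    "n_trajectories",
    "seed",
    "record_stride",
}
_POTENTIAL_KEYS = {"lattice_spacing", "cutoff_shells"}

_SIM_DEFAULTS = {"dt": 1.0e-3, "total_time": 100.0}


class ConfigError(ValueError):
    """Malformed or ambiguous configuration file."""


class SchemaError(ValueError):
    """Trajectory CSV does not match the declared schema."""


def read_config(path) -> tuple[ScaledParams, SimulationConfig, PotentialSpec]:
    """Parse a YAML config into validated parameter/config/potential objects.

    Exactly one of ``scaled:`` or ``dimensional:`` must be present; unknown
    keys are an error (naming them), missing required keys likewise.
    Defaults: ksteric 1e3, box 12, contact radius 1.5, reflecting boundary,
    dt 1e-3, total_time 100.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown_blocks = set(raw) - {"scaled", "dimensional", "simulation", "potential"}
    if unknown_blocks:
        raise ConfigError(f"unknown config blocks: {sorted(unknown_blocks)}")
    has_scaled = "scaled" in raw
    has_dim = "dimensional" in raw
    if has_scaled and has_dim:
        raise ConfigError("config has both 'scaled' and 'dimensional' blocks; provide exactly one")
    if not (has_scaled or has_dim):
        raise ConfigError("config needs a 'scaled' or 'dimensional' block")

    if has_scaled:
        block = dict(raw["scaled"])
        unknown = set(block) - _SCALED_KEYS
        if unknown:
            raise ConfigError(f"unknown keys in 'scaled': {sorted(unknown)}")
        missing = {"alpha", "DT"} - set(block)
        if missing:
            raise ConfigError(f"missing required keys in 'scaled': {sorted(missing)}")
        params = ScaledParams(**block)
    else:
        block = dict(raw["dimensional"])
        unknown = set(block) - _DIMENSIONAL_KEYS
        if unknown:
            raise ConfigError(f"unknown keys in 'dimensional': {sorted(unknown)}")
        missing = _DIMENSIONAL_KEYS - {"muT"} - set(block)
        if missing:
            raise ConfigError(f"missing required keys in 'dimensional': {sorted(missing)}")
        params = nondimensionalize(DimensionalParams(**block))

    sim_block = dict(raw.get("simulation") or {})
    unknown = set(sim_block) - _SIMULATION_KEYS
    if unknown:
        raise ConfigError(f"unknown keys in 'simulation': {sorted(unknown)}")
    sim = {**_SIM_DEFAULTS, **sim_block}
    config = SimulationConfig(**sim)

    pot_block = dict(raw.get("potential") or {})
    unknown = set(pot_block) - _POTENTIAL_KEYS
    if unknown:
        raise ConfigError(f"unknown keys in 'potential': {sorted(unknown)}")
    lattice = None
    if config.boundary == "periodic" or pot_block:
        lattice = ImageLattice(
            spacing=pot_block.get("lattice_spacing", config.box_size),
            cutoff_shells=pot_block.get("cutoff_shells", 2),
        )
    spec = PotentialSpec(alpha=params.alpha, ksteric=params.ksteric, image_lattice=lattice)
    return params, config, spec


def _trajectory_frame(trajs) -> pd.DataFrame:
    if isinstance(trajs, Ensemble):
        trajs = trajs.trajectories
    frames = []
    for i, t in enumerate(trajs):
        stride = t.config.record_stride
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": i,
                    "step": np.arange(len(t)) * stride,
                    "time": t.times,
                    "x": t.positions[:, 0],
                    "y": t.positions[:, 1],
                    "x_unwrapped": t.unwrapped[:, 0],
                    "y_unwrapped": t.unwrapped[:, 1],
                    "theta": np.full(len(t), np.nan) if t.thetas is None else t.thetas,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=_CSV_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_trajectories(trajs, path) -> None:
    """Write trajectories (or an Ensemble) to long-format CSV at 9 significant digits."""
    frame = _trajectory_frame(trajs)
    frame.to_csv(path, index=False, float_format="%.9g")


def read_trajectories(path, config: SimulationConfig | None = None) -> list[Trajectory]:
    """Read a trajectory CSV back into Trajectory objects.

    Raises :class:`SchemaError` naming the first missing column on schema
    mismatch.  ``config`` supplies geometry metadata (defaults to a
    free-space config at the file's sampling interval).
    """
    frame = pd.read_csv(path)
    for col in _CSV_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    trajs = []
    for _, group in frame.groupby("trajectory_id", sort=True):
        times = group["time"].to_numpy(dtype=float)
        sample_dt = times[1] - times[0] if len(times) > 1 else 1.0
        cfg = config or SimulationConfig(
            dt=sample_dt, total_time=max(times[-1], sample_dt), boundary="none", record_stride=1
        )
        thetas = group["theta"].to_numpy(dtype=float)
        trajs.append(
            Trajectory(
                times=times,
                positions=group[["x", "y"]].to_numpy(dtype=float),
                unwrapped=group[["x_unwrapped", "y_unwrapped"]].to_numpy(dtype=float),
                config=cfg,
                thetas=None if np.all(np.isnan(thetas)) else thetas,
            )
        )
    return trajs


def write_manifest(path, params, config, outputs, extra=None) -> dict:
    """Write a JSON run manifest and return it.

    The manifest (parameters, config, seed, code version, timestamp, output
    list) plus the code version suffices to reproduce a run bit-exactly.
    """
    manifest = {
        "package": "mechanocell",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "params": None if params is None else asdict(params),
        "config": None if config is None else asdict(config),
        "outputs": [str(o) for o in outputs],
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
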