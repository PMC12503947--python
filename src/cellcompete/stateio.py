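"""Lossless checkpointing of a running simulation to HDF5, plus run manifests.

A checkpoint reproduces the lattice, the cell registry, the three random
substreams, the step counter and the recorded metrics/events exactly, so a
resumed run is bit-identical to an uninterrupted one with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import List

import h5py
import numpy as np

from .config import SimulationConfig
from .engine import CellRegistry, LatticeState
from .simulation import Simulation

FORMAT_VERSION = 1


class StateIOError(RuntimeError):
    """Raised for corrupted, truncated or version-mismatched state files."""


def _grid_digest(grid: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(grid).tobytes()).hexdigest()


def save_state(sim: Simulation, path: str, config: SimulationConfig) -> None:
    """Write a complete checkpoint of ``sim`` to ``path``."""
    reg = sim.registry
    n = reg.next_id
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["step_count"] = sim.step_count
        f.attrs["next_id"] = n
        f.attrs["record_every"] = sim.record_every
        f.attrs["config_json"] = json.dumps(config.to_dict(), sort_keys=True)
        f.attrs["config_digest"] = config.digest()
        f.attrs["grid_sha256"] = _grid_digest(sim.state.grid)
        f.create_dataset("grid", data=sim.state.grid, compression="gzip")
        g = f.create_group("registry")
        for name in CellRegistry._FIELDS:
            g.create_dataset(name, data=getattr(reg, name)[:n])
        f.attrs["rng_lattice"] = json.dumps(sim.rng_lattice.bit_generator.state)
        f.attrs["rng_decisions"] = json.dumps(sim.rng_decisions.bit_generator.state)
        f.attrs["rng_cycle"] = json.dumps(sim.rng_cycle.bit_generator.state)
        f.attrs["metrics_json"] = json.dumps(sim.metrics_rows)
        f.attrs["events_json"] = json.dumps(sim.event_log.rows)


def load_state(path: str) -> tuple[Simulation, SimulationConfig]:
    """Reconstruct a simulation from a checkpoint; verifies integrity."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs["format_version"])
            if version != FORMAT_VERSION:
                raise StateIOError(
                    f"state format version {version} != {FORMAT_VERSION}")
            grid = f["grid"][...]
            if f.attrs["grid_sha256"] != _grid_digest(grid):
                raise StateIOError(f"grid digest mismatch in {path}")
            config = SimulationConfig.from_dict(
                json.loads(f.attrs["config_json"]))
            n = int(f.attrs["next_id"])
            reg = CellRegistry(capacity=max(8, n))
            for name in CellRegistry._FIELDS:
                getattr(reg, name)[:n] = f["registry"][name][...]
            reg.next_id = n
            params_by_code, contact, potts = config.build_parameters()
            sim = Simulation(LatticeState(grid), reg, params_by_code, contact,
                             potts, seed=0,
                             record_every=int(f.attrs["record_every"]))
            for attr, rng in (("rng_lattice", sim.rng_lattice),
                              ("rng_decisions", sim.rng_decisions),
                              ("rng_cycle", sim.rng_cycle)):
                rng.bit_generator.state = json.loads(f.attrs[attr])
            sim.step_count = int(f.attrs["step_count"])
            sim.metrics_rows = json.loads(f.attrs["metrics_json"])
            sim.event_log.rows = json.loads(f.attrs["events_json"])
            return sim, config
    except StateIOError:
        raise
    except (OSError, KeyError, ValueError) as exc:
        raise StateIOError(f"cannot read state file {path}: {exc}") from exc


@dataclass
class RunManifest:
    """Audit record of one run: what produced which files."""

    config_digest: str
    code_version: str
    seed: int
    start_step: int
    end_step: int
    files: List[str] = field(default_factory=list)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def check_inventory(self, directory: str) -> List[str]:
        """Names listed but missing on disk (empty list = complete)."""
        return [f for f in self.files
                if not os.path.exists(os.path.join(directory, f))]
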