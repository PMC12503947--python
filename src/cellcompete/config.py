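"""Run configuration: validated settings in printed table units, converted
to lattice units exactly once when a simulation is built.

A config file (YAML or JSON) holds up to four blocks::

    run:     domain_size, horizon_tau0 (or steps), record_every, seed,
             stop_on_extinction
    potts:   kT, neighborhood
    init:    mode, colony_radius, resting_area, jitter_frac, relax_steps,
             mixture_fraction
    types:   {A: {...}, B: {...}}   # printed-unit overrides of the defaults
    contact: {J_AA: ..., ...}       # printed-unit contact-energy overrides

Every omitted field falls back to the published defaults.
"""

from __future__ import annotations

import copy as _copy
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

from .params import (TABLE1_DEFAULTS, TABLE2_DEFAULTS, TYPE_A, TYPE_B,
                     CellTypeParams, ContactEnergyTable, PottsParams,
                     conversion_record, convert_params)

_RUN_KEYS = {"domain_size", "horizon_tau0", "steps", "record_every", "seed",
             "stop_on_extinction"}
_POTTS_KEYS = {"kT", "neighborhood"}
_INIT_KEYS = {"mode", "colony_radius", "resting_area", "jitter_frac",
              "relax_steps", "mixture_fraction"}


@dataclass
class SimulationConfig:
    domain_size: int = 300
    horizon_tau0: float = 24.0
    steps: Optional[int] = None          # explicit override of the horizon
    record_every: int = 45               # ~ tau0 / 5
    seed: int = 0
    stop_on_extinction: bool = True

    kT: float = 10.0
    neighborhood: str = "moore"

    mode: str = "central_colony"
    colony_radius: float = 75.0
    resting_area: float = 1300.0
    jitter_frac: float = 0.08
    relax_steps: int = 5
    mixture_fraction: float = 0.5

    type_overrides: Dict[str, Dict[str, float]] = field(default_factory=dict)
    contact_overrides: Dict[str, float] = field(default_factory=dict)

    # ------------------------------------------------------------------
    @staticmethod
    def printed_default(key: str) -> float:
        return TABLE1_DEFAULTS[key]

    @staticmethod
    def printed_contact_default(key: str) -> float:
        return TABLE2_DEFAULTS[key]

    def timer_mean_printed(self) -> float:
        """Mean S/G2/M timer of the wild type, the run's natural time unit."""
        return self.type_overrides.get("B", {}).get(
            "timer_mean", TABLE1_DEFAULTS["timer_mean"])

    @property
    def n_steps(self) -> int:
        if self.steps is not None:
            return int(self.steps)
        return int(round(self.horizon_tau0 * self.timer_mean_printed()))

    def copy(self) -> "SimulationConfig":
        return _copy.deepcopy(self)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.domain_size < 20:
            raise ValueError(f"run.domain_size must be >= 20, got {self.domain_size}")
        if self.steps is None and self.horizon_tau0 <= 0:
            raise ValueError("run.horizon_tau0 must be > 0")
        if self.record_every < 1:
            raise ValueError("run.record_every must be >= 1")
        if not (math.isfinite(self.kT) and self.kT > 0):
            raise ValueError(f"potts.kT must be finite and > 0, got {self.kT}")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError(f"potts.neighborhood {self.neighborhood!r} unknown")
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise ValueError("init.mixture_fraction must lie in [0, 1]")
        for tag, over in self.type_overrides.items():
            if tag not in ("A", "B"):
                raise ValueError(f"types block: unknown cell type {tag!r}")
            unknown = set(over) - set(TABLE1_DEFAULTS)
            if unknown:
                raise ValueError(
                    f"types.{tag}: unknown parameter keys {sorted(unknown)}")
        unknown = set(self.contact_overrides) - set(TABLE2_DEFAULTS)
        if unknown:
            raise ValueError(f"contact: unknown keys {sorted(unknown)}")
        # instantiating the parameter objects runs the range checks
        self.build_parameters()
        self.initial_condition_spec()

    # ------------------------------------------------------------------
    def build_parameters(self) -> Tuple[Dict[int, CellTypeParams],
                                        ContactEnergyTable, PottsParams]:
        """Converted lattice-unit parameters keyed by type code.

        In pseudo-clone mode the central patch is a *relabelled subset* of
        the host population: type A inherits type B's parameters, adhesion is
        label-blind (all cell-cell energies = J_BB, both cell-medium = J_BM)
        and contact-dependent apoptosis is disabled for both labels, since no
        genetically heterotypic interface exists.
        """
        overrides = {t: dict(v) for t, v in self.type_overrides.items()}
        contact_over = dict(self.contact_overrides)
        if self.mode == "pseudo_clone":
            overrides["A"] = dict(overrides.get("B", {}))
            overrides.setdefault("A", {})["p_con_max"] = 0.0
            overrides.setdefault("B", {})["p_con_max"] = 0.0
            j_bb = contact_over.get("J_BB", TABLE2_DEFAULTS["J_BB"])
            j_bm = contact_over.get("J_BM", TABLE2_DEFAULTS["J_BM"])
            contact_over.update(J_AA=j_bb, J_AB=j_bb, J_AM=j_bm)
        per_tag, contact = convert_params(overrides, contact_over)
        potts = PottsParams(kT=self.kT, neighborhood_order=self.neighborhood)
        return {TYPE_A: per_tag["A"], TYPE_B: per_tag["B"]}, contact, potts

    def initial_condition_spec(self):
        from .experiments import InitialConditionSpec

        return InitialConditionSpec(
            domain_size=self.domain_size, mode=self.mode,
            colony_radius=self.colony_radius, resting_area=self.resting_area,
            jitter_frac=self.jitter_frac, relax_steps=self.relax_steps,
            mixture_fraction=self.mixture_fraction)

    # ------------------------------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        return {
            "run": {"domain_size": self.domain_size,
                    "horizon_tau0": self.horizon_tau0, "steps": self.steps,
                    "record_every": self.record_every, "seed": self.seed,
                    "stop_on_extinction": self.stop_on_extinction},
            "potts": {"kT": self.kT, "neighborhood": self.neighborhood},
            "init": {"mode": self.mode, "colony_radius": self.colony_radius,
                     "resting_area": self.resting_area,
                     "jitter_frac": self.jitter_frac,
                     "relax_steps": self.relax_steps,
                     "mixture_fraction": self.mixture_fraction},
            "types": {t: dict(v) for t, v in self.type_overrides.items()},
            "contact": dict(self.contact_overrides),
        }

    def digest(self) -> str:
        """SHA-256 of the canonical JSON form; identifies a run setup."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def conversion_log(self) -> Dict[str, float]:
        return conversion_record()

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "SimulationConfig":
        data = dict(data or {})
        known_blocks = {"run", "potts", "init", "types", "contact"}
        unknown = set(data) - known_blocks
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        cfg = cls()

        def take(block: str, allowed: set) -> Dict[str, Any]:
            sub = data.get(block) or {}
            if not isinstance(sub, dict):
                raise ValueError(f"config block {block!r} must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"{block}: unknown keys {sorted(bad)}")
            return sub

        run = take("run", _RUN_KEYS)
        for key in run:
            setattr(cfg, key, run[key])
        potts = take("potts", _POTTS_KEYS)
        if "kT" in potts:
            cfg.kT = float(potts["kT"])
        if "neighborhood" in potts:
            cfg.neighborhood = potts["neighborhood"]
        init = take("init", _INIT_KEYS)
        for key in init:
            setattr(cfg, key, init[key])
        cfg.type_overrides = {t: dict(v)
                              for t, v in (data.get("types") or {}).items()}
        cfg.contact_overrides = dict(data.get("contact") or {})
        cfg.validate()
        return cfg


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML or JSON config; defaults fill omissions."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".json"):
        data = json.loads(text) if text.strip() else {}
    else:
        import yaml

        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root of {path} must be a mapping")
    return SimulationConfig.from_dict(data)
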