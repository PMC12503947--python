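"""Simulation driver: alternates lattice relaxation with the decision epoch.

One simulation timestep is (i) a Monte-Carlo step of width*height copy
attempts, then (ii) the decision epoch: target-area growth, sizer-timer
cycle progression with divisions, and the elimination sweep driven by a
single whole-lattice contact scan. Three named random substreams (lattice
proposals, decision draws, cycle draws) are spawned from one seed so that
changes in one layer do not perturb the random trajectory of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _kernels
from .decisions import (EventLog, cycle_update_all, divide_cell,
                        elimination_sweep, growth_increment)
from .engine import (PHASE_APOPTOTIC, CellRegistry, LatticeState,
                     _forward_offsets, monte_carlo_step)
from .params import (TYPE_A, TYPE_B, CellTypeParams, ContactEnergyTable,
                     PottsParams)


@dataclass
class ScanResult:
    """Per-step contact summary for the living cells."""

    cell_ids: np.ndarray        # (n,) identifiers, slot order
    counts: np.ndarray          # (n, 3): same-type, other-type, medium contacts
    adjacency: np.ndarray       # (n, n) bool cell-cell contact
    rho: np.ndarray             # (n,) local density, sites^-1
    p_AB: np.ndarray            # (n,) heterotypic boundary fraction


def scan_contacts(state: LatticeState, registry: CellRegistry,
                  potts: PottsParams) -> ScanResult:
    """One lattice pass: contact counts, adjacency, local density, p_AB."""
    ids = registry.alive_ids()
    slot_of = np.full(registry.next_id, -1, dtype=np.int64)
    slot_of[ids] = np.arange(ids.shape[0])
    type_of = registry.type_code[: registry.next_id]
    counts, adj = _kernels.contact_scan(
        state.grid, type_of, slot_of, ids.shape[0],
        _forward_offsets(potts.offsets()))
    areas = registry.area[ids].astype(np.float64)
    inv = np.where(areas > 0, 1.0 / np.maximum(areas, 1), 0.0)
    rho = inv + adj @ inv
    total = counts.sum(axis=1)
    p_AB = np.where(total > 0, counts[:, 1] / np.maximum(total, 1), 0.0)
    return ScanResult(ids, counts, adj, rho, p_AB)


class Simulation:
    """A competition run: lattice + registry + parameters + RNG streams."""

    def __init__(self, state: LatticeState, registry: CellRegistry,
                 params_by_code: Dict[int, CellTypeParams],
                 contact: ContactEnergyTable, potts: PottsParams,
                 seed: int | np.random.SeedSequence,
                 record_every: int = 45) -> None:
        self.state = state
        self.registry = registry
        self.params_by_code = params_by_code
        self.contact = contact
        self.potts = potts
        self.record_every = int(record_every)
        if isinstance(seed, np.random.SeedSequence):
            ss = seed
        else:
            ss = np.random.SeedSequence(int(seed))
        lattice_ss, decision_ss, cycle_ss = ss.spawn(3)
        self.rng_lattice = np.random.Generator(np.random.PCG64(lattice_ss))
        self.rng_decisions = np.random.Generator(np.random.PCG64(decision_ss))
        self.rng_cycle = np.random.Generator(np.random.PCG64(cycle_ss))
        self.step_count = 0
        self.event_log = EventLog()
        self.metrics_rows: List[dict] = []
        self._last_scan: Optional[ScanResult] = None

    # ------------------------------------------------------------------
    def counts(self) -> Tuple[int, int]:
        reg = self.registry
        ids = reg.alive_ids()
        return (int(np.sum(reg.type_code[ids] == TYPE_A)),
                int(np.sum(reg.type_code[ids] == TYPE_B)))

    def _growth_epoch(self) -> None:
        reg = self.registry
        n = reg.next_id
        live = reg.alive[:n] & (reg.phase[:n] != PHASE_APOPTOTIC)
        for code, p in self.params_by_code.items():
            m = live & (reg.type_code[:n] == code)
            if np.any(m):
                reg.target_area[:n][m] = growth_increment(
                    reg.area[:n][m], reg.target_area[:n][m],
                    p.growth_rate, p.crowding_k)

    def _division_epoch(self, tallies: Dict[str, Dict[int, int]]) -> None:
        for cid in cycle_update_all(self.registry):
            cid = int(cid)
            if self.registry.area[cid] < 2:
                continue  # deferred: timer stays <= 0, retried next step
            divide_cell(self.state, self.registry, cid,
                        self.params_by_code, self.rng_cycle)
            code = int(self.registry.type_code[cid])
            tallies["divisions"][code] = tallies["divisions"].get(code, 0) + 1

    def step(self) -> None:
        """Advance one simulation timestep (Monte-Carlo + decision epoch)."""
        monte_carlo_step(self.state, self.registry, self.contact,
                         self.potts, self.rng_lattice)
        tallies = self.event_log.blank()
        self._growth_epoch()
        self._division_epoch(tallies)
        scan = scan_contacts(self.state, self.registry, self.potts)
        elim = elimination_sweep(
            self.state, self.registry, scan.cell_ids, scan.rho, scan.p_AB,
            self.params_by_code, self.rng_decisions)
        for col, d in elim.items():
            for code, k in d.items():
                tallies[col][code] = tallies[col].get(code, 0) + k
        self._last_scan = scan
        self.step_count += 1
        self.event_log.append(self.step_count, tallies)
        if self.step_count % self.record_every == 0:
            self.record_metrics()

    def record_metrics(self) -> None:
        reg = self.registry
        scan = self._last_scan
        row = {"step": self.step_count}
        for code, tag in ((TYPE_A, "A"), (TYPE_B, "B")):
            ids = reg.alive_ids()
            m = reg.type_code[ids] == code
            row[f"n_{tag}"] = int(m.sum())
            row[f"mean_area_{tag}"] = float(reg.area[ids][m].mean()) if m.any() else np.nan
            if scan is not None and scan.cell_ids.size:
                sm = reg.type_code[scan.cell_ids] == code
                row[f"mean_rho_{tag}"] = float(scan.rho[sm].mean()) if sm.any() else np.nan
                row[f"mean_pAB_{tag}"] = float(scan.p_AB[sm].mean()) if sm.any() else np.nan
            else:
                row[f"mean_rho_{tag}"] = np.nan
                row[f"mean_pAB_{tag}"] = np.nan
        self.metrics_rows.append(row)

    def run(self, n_steps: int, stop_on_extinction: bool = True) -> None:
        """Run ``n_steps`` timesteps; optionally stop when a type dies out.

        The initial condition is recorded as step 0 if nothing has been
        recorded yet.
        """
        if not self.metrics_rows:
            self._last_scan = scan_contacts(self.state, self.registry, self.potts)
            self.record_metrics()
        for _ in range(n_steps):
            self.step()
            if stop_on_extinction:
                n_a, n_b = self.counts()
                if n_a == 0 or n_b == 0:
                    if self.step_count % self.record_every != 0:
                        self.record_metrics()
                    break

    def metrics_frame(self):
        import pandas as pd

        return pd.DataFrame(self.metrics_rows)
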