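"""Decision-making layer: growth, sizer-timer cell cycle, division and the
three elimination modes (density apoptosis, contact apoptosis, extrusion).

These rules run once between Monte-Carlo steps. Growth acts on the *target*
area: the lattice dynamics then pull the true area towards it. Cycle
progression is a G1 sizer followed by a fixed S/G2/M timer. Elimination is
probabilistic for the two apoptosis modes (independent per-step Bernoulli
hazards) and deterministic for extrusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .engine import (PHASE_APOPTOTIC, PHASE_G1, PHASE_S_G2_M, CellRegistry,
                     LatticeState, cell_geometry)
from .params import MEDIUM, CellTypeParams

#: An apoptotic cell whose area shrinks below this is removed from the
#: lattice outright (its sites become medium). In practice the extrusion rule
#: usually removes shrinking cells first; the floor guarantees termination.
APOPTOTIC_REMOVAL_FLOOR = 10

_CYCLE_DRAW_MIN = 1.0


def draw_sizer(params: CellTypeParams, rng: np.random.Generator,
               size: int | None = None) -> np.ndarray | float:
    """G1 sizer threshold ~ Gaussian(sizer_mean, sizer_sd), truncated >= 1."""
    return _truncated_normal(params.sizer_mean, params.sizer_sd, rng, size)

def draw_timer(params: CellTypeParams, rng: np.random.Generator,
               size: int | None = None) -> np.ndarray | float:
    """S/G2/M duration ~ Gaussian(timer_mean, timer_sd), truncated >= 1."""
    return _truncated_normal(params.timer_mean, params.timer_sd, rng, size)


def _truncated_normal(mean, sd, rng, size):
    n = 1 if size is None else size
    out = rng.normal(mean, sd, size=n)
    bad = out < _CYCLE_DRAW_MIN
    while np.any(bad):  # resample; vanishingly rare at the default CVs
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < _CYCLE_DRAW_MIN
    return float(out[0]) if size is None else out


def growth_increment(area, target_area, G: float, k: float, dt: float = 1.0):
    """Crowding-damped target-area growth (explicit Euler, dt = 1 step).

    dA_T/dt = G * exp(-k * (A - A_T)^2) applied while A <= A_T; a compressed
    cell (A well below A_T) has its growth exponentially suppressed — this is
    contact inhibition of proliferation. Returns the new target area.
    Accepts scalars or aligned arrays.
    """
    area = np.asarray(area, dtype=np.float64)
    target = np.asarray(target_area, dtype=np.float64)
    if np.any(area < 0) or np.any(target < 0) or G < 0 or k < 0 or dt < 0:
        raise ValueError("growth_increment requires nonnegative inputs")
    inc = G * dt * np.exp(-k * (area - target) ** 2)
    new_target = np.where(area <= target, target + inc, target)
    if new_target.ndim == 0:
        return float(new_target)
    return new_target


def cycle_update(registry: CellRegistry, cell_id: int) -> bool:
    """Advance one cell's cycle by one step; True if division triggers.

    G1 ends when the area reaches the sizer threshold; the pre-drawn S/G2/M
    timer then counts down, and division triggers the step it reaches zero.
    Apoptotic cells do not cycle.
    """
    ph = registry.phase[cell_id]
    if ph == PHASE_APOPTOTIC or not registry.alive[cell_id]:
        return False
    if ph == PHASE_G1:
        if registry.area[cell_id] >= registry.sizer_threshold[cell_id]:
            registry.phase[cell_id] = PHASE_S_G2_M
        return False
    registry.timer_remaining[cell_id] -= 1.0
    return bool(registry.timer_remaining[cell_id] <= 0.0)


def cycle_update_all(registry: CellRegistry) -> np.ndarray:
    """Vectorised cycle update over all living cells; returns ids to divide."""
    n = registry.next_id
    live = registry.alive[:n] & (registry.phase[:n] != PHASE_APOPTOTIC)
    in_g1 = live & (registry.phase[:n] == PHASE_G1)
    promote = in_g1 & (registry.area[:n] >= registry.sizer_threshold[:n])
    registry.phase[:n][promote] = PHASE_S_G2_M
    in_s = live & (registry.phase[:n] == PHASE_S_G2_M) & ~promote
    registry.timer_remaining[:n][in_s] -= 1.0
    trigger = in_s & (registry.timer_remaining[:n] <= 0.0)
    return np.flatnonzero(trigger)


def divide_cell(state: LatticeState, registry: CellRegistry, cell_id: int,
                params_by_code: Dict[int, CellTypeParams],
                rng: np.random.Generator) -> Tuple[int, int]:
    """Split a cell across its centroid, daughters arranged along the long axis.

    The mother's sites are ranked by their projection onto the principal
    (semi-major) axis and partitioned at the median, which realises a cleavage
    line through the centroid perpendicular to the long axis, as equal as
    lattice discreteness allows. Each daughter receives a fresh identifier,
    target area equal to its actual area (mechanical equilibrium at birth),
    phase G1, fresh sizer/timer draws and generation = mother + 1.
    """
    if registry.area[cell_id] < 2:
        raise ValueError(f"cell {cell_id} has area < 2; division deferred")
    coords = np.argwhere(state.grid == cell_id)
    _, _, axis = cell_geometry(state, cell_id)
    proj = coords @ axis
    order = np.lexsort((coords[:, 1], coords[:, 0], proj))
    half = coords.shape[0] // 2
    first, second = coords[order[:half]], coords[order[half:]]

    tcode = int(registry.type_code[cell_id])
    p = params_by_code[tcode]
    gen = int(registry.generation[cell_id]) + 1
    ids: List[int] = []
    for part in (first, second):
        cid = registry.new_cell(
            type_code=tcode, area=part.shape[0],
            target_area=float(part.shape[0]), lam=p.lam,
            sizer_threshold=draw_sizer(p, rng),
            timer_remaining=draw_timer(p, rng),
            phase=PHASE_G1, generation=gen)
        state.grid[part[:, 0], part[:, 1]] = cid
        ids.append(cid)
    registry.retire(cell_id)
    return ids[0], ids[1]


def local_density(registry: CellRegistry, neighbours: Iterable[int],
                  cell_id: int) -> float:
    """Local density rho = 1/A_self + sum of 1/A_i over contacting cells.

    ``neighbours`` are the identifiers of cells sharing at least one boundary
    contact (medium excluded); zero-area neighbours (pending removal) are
    skipped.
    """
    a = registry.area[cell_id]
    if a <= 0:
        raise ValueError(f"cell {cell_id} has nonpositive area")
    rho = 1.0 / a
    for nb in neighbours:
        an = registry.area[nb]
        if an > 0:
            rho += 1.0 / an
    return float(rho)


def p_apoptosis_density(rho, params: CellTypeParams):
    """Logistic per-step hazard of crowding-induced apoptosis.

    P(rho) = p_den_max / (1 + exp(-beta * (rho - rho_half))); saturates at
    p_den_max for rho >> rho_half and equals p_den_max/2 at the midpoint.
    """
    rho = np.asarray(rho, dtype=np.float64)
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    out = params.p_den_max / (1.0 + np.exp(-params.beta * (rho - params.rho_half)))
    return float(out) if out.ndim == 0 else out


def p_apoptosis_contact(p_AB, params: CellTypeParams):
    """Hill per-step hazard of contact-dependent apoptosis.

    P(p_AB) = p_con_max * p_AB^nH / (S^nH + p_AB^nH); zero without heterotypic
    contact, half-maximal at p_AB = S regardless of the Hill coefficient.
    Physical boundary fractions lie in [0, 1]; the curve itself is defined for
    any p_AB >= 0 (note the fitted midpoint S = 1.35 sits above 1, so the
    hazard never reaches half-maximum in a simulation).
    """
    p = np.asarray(p_AB, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("p_AB must be >= 0")
    pn = np.where(p > 0, p, 1.0) ** params.hill_n  # avoid 0**n warnings path
    pn = np.where(p > 0, pn, 0.0)
    out = params.p_con_max * pn / (params.steepness_S ** params.hill_n + pn)
    return float(out) if out.ndim == 0 else out


@dataclass
class EventLog:
    """Per-step, per-type tallies of divisions and eliminations.

    Population bookkeeping closes every step:
    N(t+1) = N(t) + divisions - deaths_total, per type.
    """

    rows: List[dict] = field(default_factory=list)

    COLUMNS = ("divisions", "apo_density", "apo_contact", "extrusions",
               "removals_floor", "removals_zero", "deaths_total")

    def blank(self) -> Dict[str, Dict[int, int]]:
        return {col: {} for col in self.COLUMNS}

    def append(self, step: int, tallies: Dict[str, Dict[int, int]]) -> None:
        row = {"step": step}
        for col in self.COLUMNS:
            for code, n in tallies.get(col, {}).items():
                row[f"{col}_{'A' if code == 1 else 'B'}"] = n
        self.rows.append(row)

    def to_frame(self):
        import pandas as pd

        cols = ["step"] + [f"{c}_{t}" for c in self.COLUMNS for t in ("A", "B")]
        df = pd.DataFrame(self.rows)
        for c in cols:
            if c not in df.columns:
                df[c] = 0
        return df[cols].fillna(0).astype({c: int for c in cols})


def _tally(d: Dict[int, int], code: int, n: int = 1) -> None:
    d[code] = d.get(code, 0) + n


def elimination_sweep(
    state: LatticeState,
    registry: CellRegistry,
    cell_ids: np.ndarray,
    rho: np.ndarray,
    p_AB: np.ndarray,
    params_by_code: Dict[int, CellTypeParams],
    rng: np.random.Generator,
    removal_floor: int = APOPTOTIC_REMOVAL_FLOOR,
) -> Dict[str, Dict[int, int]]:
    """Apply the three elimination modes to every living cell, once per step.

    ``cell_ids`` / ``rho`` / ``p_AB`` are aligned arrays for the living cells
    (from the per-step contact scan). For each non-apoptotic cell two
    independent uniform variates are drawn against the density and contact
    hazards; either success marks the cell apoptotic (target area -> 0).
    Extrusion then deletes any cell strictly smaller than a quarter of its
    type's mean area this step, and apoptotic cells below the removal floor
    are deleted. Returns per-type tallies.
    """
    tallies: Dict[str, Dict[int, int]] = {c: {} for c in EventLog.COLUMNS}
    n = cell_ids.shape[0]
    if n == 0:
        return tallies
    codes = registry.type_code[cell_ids]
    phases = registry.phase[cell_ids]
    areas = registry.area[cell_ids]

    # (i) stochastic apoptosis initiation — two independent Bernoulli draws
    eligible = phases != PHASE_APOPTOTIC
    p_den = np.zeros(n)
    p_con = np.zeros(n)
    for code, p in params_by_code.items():
        m = codes == code
        if np.any(m):
            p_den[m] = p_apoptosis_density(rho[m], p)
            p_con[m] = p_apoptosis_contact(p_AB[m], p)
    u = rng.random((n, 2))
    hit_den = eligible & (u[:, 0] < p_den)
    hit_con = eligible & (u[:, 1] < p_con)
    for idx in np.flatnonzero(hit_den):
        _tally(tallies["apo_density"], int(codes[idx]))
    for idx in np.flatnonzero(hit_con):
        _tally(tallies["apo_contact"], int(codes[idx]))
    newly = hit_den | hit_con
    registry.phase[cell_ids[newly]] = PHASE_APOPTOTIC
    registry.target_area[cell_ids[newly]] = 0.0
    phases = registry.phase[cell_ids]

    # (ii) extrusion: area strictly below a quarter of the type mean
    kill = np.zeros(n, dtype=bool)
    for code in np.unique(codes):
        m = codes == code
        mean_area = areas[m].mean()
        ext = m & (areas < mean_area / 4.0)
        for idx in np.flatnonzero(ext & ~kill):
            _tally(tallies["extrusions"], int(codes[idx]))
        kill |= ext

    # (iii) apoptotic cells below the removal floor
    floor_kill = (phases == PHASE_APOPTOTIC) & (areas < removal_floor) & ~kill
    for idx in np.flatnonzero(floor_kill):
        _tally(tallies["removals_floor"], int(codes[idx]))
    kill |= floor_kill

    # cells eaten to zero area by the lattice dynamics
    zero_kill = (areas <= 0) & ~kill
    for idx in np.flatnonzero(zero_kill):
        _tally(tallies["removals_zero"], int(codes[idx]))
    kill |= zero_kill

    kill_ids = cell_ids[kill]
    if kill_ids.size:
        mask = np.zeros(registry.next_id, dtype=bool)
        mask[kill_ids] = True
        g = state.grid
        g[mask[g]] = MEDIUM
        for cid in kill_ids:
            registry.retire(int(cid))
        for code in (1, 2):
            k = int(np.sum(registry.type_code[kill_ids] == code))
            if k:
                _tally(tallies["deaths_total"], code, k)
    return tallies
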