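"""Physical layer: lattice state, mechanical energy and Metropolis dynamics.

A tissue lives on a fixed, non-periodic square lattice. Every site holds a
cell identifier (0 = medium); a one-site medium frame at the domain edge is
immutable, which implements the closed boundary. The mechanical energy is

    E = sum over unordered neighbour pairs (i, j), n_i != n_j of J(sigma_i, sigma_j)
      + sum over cells alpha of lambda_alpha * (A_alpha - A^T_alpha)^2

i.e. interfacial adhesion plus an area-elastic penalty; there is no perimeter
term. Dynamics are Metropolis-Hastings identity flips at temperature kT: one
Monte-Carlo step performs width*height copy attempts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from . import _kernels
from .params import MEDIUM, ContactEnergyTable, PottsParams

# Cell-cycle phase codes.
PHASE_G1 = 0
PHASE_S_G2_M = 1
PHASE_APOPTOTIC = 2

_EIG_TIE_TOL = 1e-9


class CellRegistry:
    """Per-cell bookkeeping in flat arrays indexed by cell identifier.

    Identifier 0 is the medium sentinel and is never a cell. Identifiers are
    never reused; dead cells keep their row with ``alive = False``.
    """

    _FIELDS = ("type_code", "area", "target_area", "lam", "phase",
               "sizer_threshold", "timer_remaining", "generation", "alive")

    def __init__(self, capacity: int = 256) -> None:
        capacity = max(capacity, 8)
        self.type_code = np.zeros(capacity, np.int8)
        self.area = np.zeros(capacity, np.int64)
        self.target_area = np.zeros(capacity, np.float64)
        self.lam = np.zeros(capacity, np.float64)
        self.phase = np.zeros(capacity, np.int8)
        self.sizer_threshold = np.zeros(capacity, np.float64)
        self.timer_remaining = np.zeros(capacity, np.float64)
        self.generation = np.zeros(capacity, np.int32)
        self.alive = np.zeros(capacity, np.bool_)
        self.next_id = 1

    @property
    def capacity(self) -> int:
        return self.type_code.shape[0]

    def _grow(self, needed: int) -> None:
        cap = self.capacity
        new_cap = cap
        while new_cap <= needed:
            new_cap *= 2
        for name in self._FIELDS:
            arr = getattr(self, name)
            grown = np.zeros(new_cap, arr.dtype)
            grown[:cap] = arr
            setattr(self, name, grown)

    def new_cell(self, type_code: int, area: int, target_area: float,
                 lam: float, sizer_threshold: float, timer_remaining: float = 0.0,
                 phase: int = PHASE_G1, generation: int = 0) -> int:
        cid = self.next_id
        if cid >= self.capacity:
            self._grow(cid)
        self.type_code[cid] = type_code
        self.area[cid] = area
        self.target_area[cid] = target_area
        self.lam[cid] = lam
        self.phase[cid] = phase
        self.sizer_threshold[cid] = sizer_threshold
        self.timer_remaining[cid] = timer_remaining
        self.generation[cid] = generation
        self.alive[cid] = True
        self.next_id += 1
        return cid

    def retire(self, cid: int) -> None:
        self.alive[cid] = False
        self.area[cid] = 0
        self.target_area[cid] = 0.0

    def alive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def counts_by_type(self) -> Dict[int, int]:
        ids = self.alive_ids()
        out: Dict[int, int] = {}
        for code in np.unique(self.type_code[ids]):
            out[int(code)] = int(np.sum(self.type_code[ids] == code))
        return out


@dataclass
class LatticeState:
    """2D grid of cell identifiers with an immutable one-site medium frame."""

    grid: np.ndarray  # int32, shape (height, width)

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid, dtype=np.int32)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def n_sites(self) -> int:
        return self.grid.size

    def frame_is_medium(self) -> bool:
        g = self.grid
        return bool((g[0, :] == MEDIUM).all() and (g[-1, :] == MEDIUM).all()
                    and (g[:, 0] == MEDIUM).all() and (g[:, -1] == MEDIUM).all())

    def site_counts(self) -> Dict[int, int]:
        ids, counts = np.unique(self.grid, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i != MEDIUM}

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy())


def _forward_offsets(offsets: np.ndarray) -> np.ndarray:
    """Half of a symmetric offset set, so each unordered pair is seen once."""
    keep = (offsets[:, 0] > 0) | ((offsets[:, 0] == 0) & (offsets[:, 1] > 0))
    return np.ascontiguousarray(offsets[keep])


def total_energy(state: LatticeState, registry: CellRegistry,
                 contact: ContactEnergyTable, potts: PottsParams) -> float:
    """Full Hamiltonian: adhesion over boundary pairs + area elasticity."""
    J = contact.matrix()
    type_of = registry.type_code[: registry.next_id].astype(np.int8)
    if int(self_max := state.grid.max()) >= registry.next_id:
        raise KeyError(f"grid holds identifier {self_max} unknown to the registry")
    e_contact = _kernels.contact_energy_total(
        state.grid, type_of, J, _forward_offsets(potts.offsets()))
    ids = registry.alive_ids()
    dev = registry.area[ids] - registry.target_area[ids]
    e_elastic = float(np.sum(registry.lam[ids] * dev**2))
    return float(e_contact) + e_elastic


def delta_energy(state: LatticeState, registry: CellRegistry,
                 site: Tuple[int, int], candidate_id: int,
                 contact: ContactEnergyTable, potts: PottsParams) -> float:
    """Local energy change of flipping ``site`` to ``candidate_id``.

    Equals total_energy(after) - total_energy(before) to floating tolerance,
    but touches only the affected contact pairs and the two affected cells'
    elastic terms. Flipping to the current identity is a no-op (0).
    """
    r, c = site
    if r <= 0 or r >= state.height - 1 or c <= 0 or c >= state.width - 1:
        raise ValueError(f"site {site} lies on the immutable frame")
    type_of = registry.type_code[: registry.next_id]
    return float(_kernels.site_delta(
        state.grid, type_of, registry.area, registry.target_area, registry.lam,
        contact.matrix(), r, c, candidate_id, potts.offsets()))


def metropolis_accept(dE: float, kT: float, rng: np.random.Generator) -> bool:
    """Accept with probability 1 if dE <= 0, else exp(-dE/kT)."""
    if kT <= 0:
        raise ValueError("kT must be > 0")
    if dE <= 0.0:
        return True
    return bool(rng.random() < np.exp(-dE / kT))


def monte_carlo_step(state: LatticeState, registry: CellRegistry,
                     contact: ContactEnergyTable, potts: PottsParams,
                     rng: np.random.Generator) -> Tuple[int, int]:
    """One Monte-Carlo step: width*height proposals at random interior sites.

    Candidate identities are drawn uniformly from the distinct neighbouring
    identifiers differing from the source site's own; proposals in a uniform
    neighbourhood are consumed without effect. The random stream is consumed
    in fixed-size blocks, so trajectories are reproducible bit-for-bit.

    Returns ``(attempts, accepted_flips)``.
    """
    n = state.n_sites
    rows = rng.integers(1, state.height - 1, size=n).astype(np.int64)
    cols = rng.integers(1, state.width - 1, size=n).astype(np.int64)
    u_pick = rng.random(n)
    u_acc = rng.random(n)
    type_of = registry.type_code[: registry.next_id]
    flips = _kernels.mc_step_kernel(
        state.grid, type_of, registry.area, registry.target_area, registry.lam,
        contact.matrix(), potts.kT, rows, cols, u_pick, u_acc, potts.offsets())
    return n, int(flips)


def cell_geometry(state: LatticeState, cell_id: int
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, second-moment (covariance) tensor and principal axis.

    The principal axis is the eigenvector of the site-coordinate covariance
    with the larger eigenvalue; near-degenerate spectra (and single-site
    cells) fall back to the first lattice axis. Coordinates are (row, col).
    """
    coords = np.argwhere(state.grid == cell_id)
    if coords.shape[0] == 0:
        raise KeyError(f"no sites hold identifier {cell_id}")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= _EIG_TIE_TOL * max(1.0, evals[1]):
        axis = np.array([1.0, 0.0])
    else:
        axis = evecs[:, 1]
        # deterministic sign: first nonzero component positive
        lead = axis[np.nonzero(np.abs(axis) > 1e-12)[0][0]]
        if lead < 0:
            axis = -axis
    return centroid, cov, axis


def contact_profile(state: LatticeState, registry: CellRegistry, cell_id: int,
                    potts: PottsParams) -> Dict[str, float]:
    """Boundary-contact counts of one cell, by neighbour category.

    Counts (site-in-cell, site-not-in-cell) neighbour pairs; ``p_AB`` is the
    fraction of the whole boundary (medium included in the denominator) in
    heterotypic contact.
    """
    coords = np.argwhere(state.grid == cell_id)
    if coords.shape[0] == 0:
        raise KeyError(f"no sites hold identifier {cell_id}")
    own_type = registry.type_code[cell_id]
    same = other = medium = 0
    g = state.grid
    H, W = g.shape
    for dr, dc in potts.offsets():
        rr = coords[:, 0] + dr
        cc = coords[:, 1] + dc
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        nb = g[rr[ok], cc[ok]]
        nb = nb[nb != cell_id]
        medium += int(np.sum(nb == MEDIUM))
        nb_cells = nb[nb != MEDIUM]
        same += int(np.sum(registry.type_code[nb_cells] == own_type))
        other += int(np.sum(registry.type_code[nb_cells] != own_type))
    total = same + other + medium
    return {
        "same_type": same,
        "other_type": other,
        "medium": medium,
        "total": total,
        "p_AB": other / total if total > 0 else 0.0,
    }


def count_fragments(state: LatticeState, cell_id: int) -> int:
    """Connected components (8-connectivity) of one cell; >1 = fragmented.

    Diagnostic only: no connectivity constraint is enforced during dynamics
    (kT = 10 keeps fragmentation rare), but runs can monitor this.
    """
    mask = state.grid == cell_id
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return int(n)
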