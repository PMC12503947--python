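"""Numba kernels for the lattice layer.

Everything here is deliberately free of Python objects: the lattice is an
int32 grid of cell identifiers (0 = medium) and per-cell bookkeeping arrives
as flat arrays indexed by identifier. Randomness is supplied as pre-drawn
arrays so that a Monte-Carlo step consumes a fixed, reproducible amount of
the random stream regardless of how many proposals are accepted.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def site_delta(grid, type_of, area, target, lam_of, J, r, c, b, offsets):
    """Energy change of flipping site (r, c) to identifier ``b``.

    Only the contact pairs touching the site and the elastic terms of the two
    affected cells change, so the difference is computed locally.
    """
    a = grid[r, c]
    if a == b:
        return 0.0
    ta = type_of[a]
    tb = type_of[b]
    dE = 0.0
    for q in range(offsets.shape[0]):
        m = grid[r + offsets[q, 0], c + offsets[q, 1]]
        tm = type_of[m]
        if m != a:
            dE -= J[ta, tm]
        if m != b:
            dE += J[tb, tm]
    if a != 0:
        da = area[a] - target[a]
        dE += lam_of[a] * ((da - 1.0) ** 2 - da**2)
    if b != 0:
        db = area[b] - target[b]
        dE += lam_of[b] * ((db + 1.0) ** 2 - db**2)
    return dE


@njit(cache=True)
def mc_step_kernel(grid, type_of, area, target, lam_of, J, kT,
                   rows, cols, u_pick, u_acc, offsets):
    """One Monte-Carlo step: len(rows) copy attempts, Metropolis acceptance.

    For each attempt t, the source site is (rows[t], cols[t]); the candidate
    identity is drawn uniformly from the *distinct* neighbour identifiers that
    differ from the site's own (u_pick[t] selects among them). Attempts whose
    neighbourhood is uniform are consumed without effect. Area bookkeeping is
    updated incrementally. Returns the number of accepted flips.
    """
    flips = 0
    cand = np.empty(offsets.shape[0], np.int32)
    for t in range(rows.shape[0]):
        r = rows[t]
        c = cols[t]
        a = grid[r, c]
        d = 0
        for q in range(offsets.shape[0]):
            m = grid[r + offsets[q, 0], c + offsets[q, 1]]
            if m != a:
                seen = False
                for s in range(d):
                    if cand[s] == m:
                        seen = True
                        break
                if not seen:
                    cand[d] = m
                    d += 1
        if d == 0:
            continue
        b = cand[int(u_pick[t] * d)]
        dE = site_delta(grid, type_of, area, target, lam_of, J, r, c, b, offsets)
        if dE <= 0.0 or u_acc[t] < np.exp(-dE / kT):
            grid[r, c] = b
            area[a] -= 1
            area[b] += 1
            flips += 1
    return flips


@njit(cache=True)
def contact_scan(grid, type_of, slot_of, n_slots, forward_offsets):
    """Tally boundary contacts and cell-cell adjacency in one lattice pass.

    Each unordered neighbour pair with differing identifiers is visited once
    (via the forward half of the neighbourhood) and credited to both members.

    Returns
    -------
    counts : (n_slots, 3) int64
        Per living cell (by slot): contacts with [same-type other cell,
        other-type cell, medium].
    adj : (n_slots, n_slots) bool
        Cell-cell contact adjacency (medium excluded).
    """
    H, W = grid.shape
    counts = np.zeros((n_slots, 3), np.int64)
    adj = np.zeros((n_slots, n_slots), np.bool_)
    for r in range(H):
        for c in range(W):
            a = grid[r, c]
            for q in range(forward_offsets.shape[0]):
                rr = r + forward_offsets[q, 0]
                cc = c + forward_offsets[q, 1]
                if rr < 0 or rr >= H or cc < 0 or cc >= W:
                    continue
                b = grid[rr, cc]
                if a == b:
                    continue
                ta = type_of[a]
                tb = type_of[b]
                sa = slot_of[a]
                sb = slot_of[b]
                if a != 0:
                    if b == 0:
                        counts[sa, 2] += 1
                    elif tb == ta:
                        counts[sa, 0] += 1
                    else:
                        counts[sa, 1] += 1
                if b != 0:
                    if a == 0:
                        counts[sb, 2] += 1
                    elif ta == tb:
                        counts[sb, 0] += 1
                    else:
                        counts[sb, 1] += 1
                if a != 0 and b != 0:
                    adj[sa, sb] = True
                    adj[sb, sa] = True
    return counts, adj


@njit(cache=True)
def contact_energy_total(grid, type_of, J, forward_offsets):
    """Total contact energy: each unordered boundary pair counted once."""
    H, W = grid.shape
    E = 0.0
    for r in range(H):
        for c in range(W):
            a = grid[r, c]
            for q in range(forward_offsets.shape[0]):
                rr = r + forward_offsets[q, 0]
                cc = c + forward_offsets[q, 1]
                if rr < 0 or rr >= H or cc < 0 or cc >= W:
                    continue
                b = grid[rr, cc]
                if a != b:
                    E += J[type_of[a], type_of[b]]
    return E
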