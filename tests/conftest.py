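import numpy as np
import pytest

import cellcompete as cc


@pytest.fixture(scope="session")
def default_params():
    """Converted Table defaults: ({code: CellTypeParams}, contact, potts)."""
    per_tag, contact = cc.convert_params()
    potts = cc.PottsParams()
    return ({cc.TYPE_A: per_tag["A"], cc.TYPE_B: per_tag["B"]}, contact, potts)


def build_square_cell(side=10, pad=1, type_code=cc.TYPE_A, target=None,
                      lam=1.0):
    """One side x side square cell surrounded by medium."""
    L = side + 2 * pad
    grid = np.zeros((L, L), dtype=np.int32)
    grid[pad:pad + side, pad:pad + side] = 1
    state = cc.LatticeState(grid)
    reg = cc.CellRegistry()
    reg.new_cell(type_code=type_code, area=side * side,
                 target_area=float(side * side if target is None else target),
                 lam=lam, sizer_threshold=1e9)
    return state, reg


def build_three_cell_toy():
    """Three block cells (A, A, B) in a 12x9 lattice with medium frame."""
    grid = np.zeros((9, 12), dtype=np.int32)
    grid[1:8, 1:5] = 1    # type A
    grid[1:8, 5:8] = 2    # type A
    grid[1:8, 8:11] = 3   # type B
    state = cc.LatticeState(grid)
    reg = cc.CellRegistry()
    for cid, code, area in ((1, cc.TYPE_A, 28), (2, cc.TYPE_A, 21),
                            (3, cc.TYPE_B, 21)):
        got = reg.new_cell(type_code=code, area=area, target_area=float(area),
                           lam=1.0, sizer_threshold=1e9)
        assert got == cid
    return state, reg


def random_tissue(L=20, n_cells=5, seed=0, lam=1.0):
    """Random (possibly fragmented) multi-cell configuration for oracles."""
    rng = np.random.default_rng(seed)
    grid = np.zeros((L, L), dtype=np.int32)
    grid[1:-1, 1:-1] = rng.integers(0, n_cells + 1, size=(L - 2, L - 2))
    state = cc.LatticeState(grid)
    reg = cc.CellRegistry()
    counts = state.site_counts()
    for cid in range(1, n_cells + 1):
        reg.new_cell(type_code=cc.TYPE_A if cid % 2 else cc.TYPE_B,
                     area=counts.get(cid, 0),
                     target_area=float(rng.integers(1, 60)),
                     lam=lam, sizer_threshold=1e9)
    return state, reg, rng


def brute_force_energy(state, reg, contact, potts):
    """Independent Hamiltonian oracle: pure-python pair enumeration."""
    J = contact.matrix()
    g = state.grid
    H, W = g.shape
    seen = set()
    e = 0.0
    for r in range(H):
        for c in range(W):
            for dr, dc in potts.offsets():
                rr, cc_ = r + dr, c + dc
                if not (0 <= rr < H and 0 <= cc_ < W):
                    continue
                key = frozenset({(r, c), (rr, cc_)})
                if key in seen:
                    continue
                seen.add(key)
                a, b = g[r, c], g[rr, cc_]
                if a != b:
                    e += J[reg.type_code[a], reg.type_code[b]]
    for cid in reg.alive_ids():
        e += reg.lam[cid] * (reg.area[cid] - reg.target_area[cid]) ** 2
    return e
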