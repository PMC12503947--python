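"""Experiment layer: initial conditions, competition runs, fitness statistics
and parameter sweeps (phase diagrams).

The canonical numerical experiment embeds a central colony of mutant type-A
cells in a confluent wild-type type-B tissue on a closed square domain, runs
the coupled lattice/decision dynamics, and summarises the colony's fate by
its net per-capita growth rate alpha (from an exponential fit to the
replicate-mean population size) and by the fraction of replicates whose
type-A count ends above its starting value.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .decisions import draw_sizer, draw_timer
from .engine import CellRegistry, LatticeState, monte_carlo_step
from .params import (TYPE_A, TYPE_B, CellTypeParams, ContactEnergyTable,
                     PottsParams)
from .simulation import Simulation


@dataclass(frozen=True)
class InitialConditionSpec:
    """Geometry of the starting tissue.

    modes:
      central_colony - type-A disc of radius ``colony_radius`` centred in a
          type-B tissue;
      pseudo_clone - same geometry, but the central patch is a relabelled
          subset of the host population (identical parameters, neutral
          adhesion, no label-based contact killing);
      tiled_mixture - each cell independently assigned type A with
          probability ``mixture_fraction``.
    """

    domain_size: int
    mode: str = "central_colony"
    colony_radius: float = 75.0
    resting_area: float = 1300.0
    jitter_frac: float = 0.08
    relax_steps: int = 5
    mixture_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("central_colony", "pseudo_clone", "tiled_mixture"):
            raise ValueError(f"unknown initial-condition mode {self.mode!r}")
        if self.domain_size < 20:
            raise ValueError("domain_size too small")
        if self.resting_area <= 0:
            raise ValueError("resting_area must be > 0")
        if self.mode != "tiled_mixture":
            diameter = 2.0 * math.sqrt(self.resting_area / math.pi)
            if self.colony_radius + diameter > self.domain_size / 2.0:
                raise ValueError(
                    f"colony_radius {self.colony_radius} leaves less than one "
                    f"cell diameter of margin in a {self.domain_size}^2 domain")


def _hex_seed_points(spec: InitialConditionSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Jittered triangular lattice of cell seed points covering the interior.

    The spacing gives each seed a Voronoi area of about ``resting_area``. The
    lattice is anchored so the domain centre falls at the centroid of a
    triangle of seeds, which makes the number of cells inside a central disc
    reproduce the expected pi*R^2/A0 count (a 50-site-radius disc of
    1300-site cells holds six).
    """
    a0 = spec.resting_area
    s = math.sqrt(2.0 * a0 / math.sqrt(3.0))   # in-row spacing
    dy = s * math.sqrt(3.0) / 2.0              # row spacing
    L = spec.domain_size
    cy = cx = (L - 1) / 2.0
    # face-centred anchor: centre at centroid of an upward triangle of seeds
    oy = cy - dy / 3.0
    ox = cx - s / 2.0
    pts = []
    i_min = int(math.floor((1 - oy) / dy)) - 1
    i_max = int(math.ceil((L - 2 - oy) / dy)) + 1
    for i in range(i_min, i_max + 1):
        y = oy + i * dy
        row_ox = ox + (s / 2.0 if i % 2 else 0.0)
        j_min = int(math.floor((1 - row_ox) / s)) - 1
        j_max = int(math.ceil((L - 2 - row_ox) / s)) + 1
        for j in range(j_min, j_max + 1):
            pts.append((y, row_ox + j * s))
    pts = np.asarray(pts, dtype=np.float64)
    pts += rng.uniform(-spec.jitter_frac * s, spec.jitter_frac * s, pts.shape)
    inside = ((pts[:, 0] > 0.5) & (pts[:, 0] < L - 1.5)
              & (pts[:, 1] > 0.5) & (pts[:, 1] < L - 1.5))
    return pts[inside]


def make_initial_state(
    spec: InitialConditionSpec,
    params_by_code: Dict[int, CellTypeParams],
    contact: ContactEnergyTable,
    potts: PottsParams,
    rng: np.random.Generator,
) -> Tuple[LatticeState, CellRegistry]:
    """Confluent, mechanically relaxed two-type tissue.

    The interior is tessellated into near-resting-area cells (nearest-seed
    assignment on a jittered triangular lattice); every cell starts with
    target area = resting area, phase G1 and fresh sizer/timer draws. Cells
    whose centroid lies within ``colony_radius`` of the domain centre are
    type A (mode-dependent). A few Monte-Carlo steps at frozen targets
    relax the tessellation's straight interfaces.
    """
    L = spec.domain_size
    grid = np.zeros((L, L), dtype=np.int32)
    seeds = _hex_seed_points(spec, rng)
    rr, cc = np.meshgrid(np.arange(1, L - 1), np.arange(1, L - 1), indexing="ij")
    sites = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    _, owner = cKDTree(seeds).query(sites, k=1)
    # keep only seeds that own at least one site, relabel 1..n
    used, owner = np.unique(owner, return_inverse=True)
    n_cells = used.shape[0]
    grid[rr.ravel(), cc.ravel()] = owner.astype(np.int32) + 1
    state = LatticeState(grid)

    areas = np.bincount(owner, minlength=n_cells)
    cy = cx = (L - 1) / 2.0
    sums_r = np.bincount(owner, weights=sites[:, 0], minlength=n_cells)
    sums_c = np.bincount(owner, weights=sites[:, 1], minlength=n_cells)
    cent_r = sums_r / areas
    cent_c = sums_c / areas
    dist = np.hypot(cent_r - cy, cent_c - cx)
    if spec.mode == "tiled_mixture":
        is_a = rng.random(n_cells) < spec.mixture_fraction
    else:
        is_a = dist <= spec.colony_radius

    registry = CellRegistry(capacity=2 * n_cells + 8)
    for idx in range(n_cells):
        code = TYPE_A if is_a[idx] else TYPE_B
        p = params_by_code[code]
        cid = registry.new_cell(
            type_code=code, area=int(areas[idx]),
            target_area=spec.resting_area, lam=p.lam,
            sizer_threshold=draw_sizer(p, rng),
            timer_remaining=draw_timer(p, rng))
        assert cid == idx + 1
    for _ in range(spec.relax_steps):
        monte_carlo_step(state, registry, contact, potts, rng)
    return state, registry


# ----------------------------------------------------------------------
@dataclass
class FitnessResult:
    """Net growth rate of a population with fit diagnostics."""

    alpha: float               # per-step net growth rate
    alpha_se: float
    n_points: int
    r_squared: float
    survival_fraction: Optional[float] = None

    @property
    def outcome(self) -> str:
        return classify_outcome(self.alpha, self.alpha_se)


def fit_net_growth_rate(mean_counts: np.ndarray, time: np.ndarray,
                        discard_steps: float = 0.0) -> FitnessResult:
    """Exponential fit N(t) = N(0) exp(alpha t) to a mean population series.

    A log-linear least-squares fit over the pre-extinction segment (counts
    strictly positive) after discarding the first ``discard_steps`` of the
    series (initial relaxation transient). alpha is in per-step units.
    """
    counts = np.asarray(mean_counts, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    if counts.shape != t.shape:
        raise ValueError("mean_counts and time must be aligned")
    if counts.size == 0 or counts[0] <= 0:
        raise ValueError("need a series starting from a positive count")
    positive = counts > 0
    if not positive.all():
        cut = int(np.argmin(positive))  # first zero
        counts, t, positive = counts[:cut], t[:cut], positive[:cut]
    keep = t >= t[0] + discard_steps
    if keep.sum() < 3:
        keep = np.ones_like(t, dtype=bool)  # series too short to discard
    y = np.log(counts[keep])
    x = t[keep]
    n = x.size
    if n < 2:
        return FitnessResult(alpha=float("nan"), alpha_se=float("nan"),
                             n_points=n, r_squared=float("nan"))
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = float(np.sum(xc * y) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    sigma2 = float(np.sum(resid**2)) / dof
    se = math.sqrt(sigma2 / sxx)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return FitnessResult(alpha=slope, alpha_se=se, n_points=n, r_squared=r2)


def classify_outcome(alpha: float, alpha_se: float) -> str:
    """Sign of alpha with a +/- 2 SE dead band mapped to coexistence."""
    if not math.isfinite(alpha):
        return "undetermined"
    if math.isfinite(alpha_se) and abs(alpha) < 2.0 * alpha_se:
        return "coexistence"
    return "supercompetitor" if alpha > 0 else "loser"


# ----------------------------------------------------------------------
@dataclass
class CompetitionResult:
    """Output of one competition run."""

    metrics: "object"          # pandas DataFrame: step, n_A, n_B, densities
    events: "object"           # pandas DataFrame of per-step event tallies
    simulation: Simulation
    config: SimulationConfig
    seed: int


def run_competition(config: SimulationConfig, seed: int,
                    n_steps: Optional[int] = None) -> CompetitionResult:
    """Run one competition experiment, fully reproducible from (config, seed).

    Builds the converted parameters, the initial tissue, then alternates
    Monte-Carlo steps with the decision epoch for the configured horizon,
    recording per-type counts, densities and event tallies at the configured
    cadence. Extinction of either type ends the run gracefully.
    """
    params_by_code, contact, potts = config.build_parameters()
    ss = np.random.SeedSequence(int(seed))
    init_ss, sim_ss = ss.spawn(2)
    init_rng = np.random.Generator(np.random.PCG64(init_ss))
    spec = config.initial_condition_spec()
    state, registry = make_initial_state(spec, params_by_code, contact,
                                         potts, init_rng)
    sim = Simulation(state, registry, params_by_code, contact, potts,
                     seed=sim_ss, record_every=config.record_every)
    sim.run(n_steps if n_steps is not None else config.n_steps,
            stop_on_extinction=config.stop_on_extinction)
    return CompetitionResult(metrics=sim.metrics_frame(),
                             events=sim.event_log.to_frame(),
                             simulation=sim, config=config, seed=int(seed))


# ----------------------------------------------------------------------
#: sweep axis -> how it perturbs the type-A configuration (printed units)
_AXIS_APPLIERS = {
    "lam_ratio": ("type", "lam"),
    "k_ratio": ("type", "crowding_k"),
    "rho_half_ratio": ("type", "rho_half"),
    "sizer_ratio": ("type", "sizer_mean"),
    "growth_ratio": ("type", "growth_rate"),
    "hill_nA": ("type_abs", "hill_n"),
    "adhesion_ratio": ("contact", "J_AA"),
    "radius": ("init", "colony_radius"),
}


@dataclass
class SweepSpec:
    """A grid of type-A perturbations around the type-B defaults.

    ``axes`` maps axis names (see keys of the module-level table) to value
    grids; the sweep runs the cartesian product. Ratio axes multiply the
    type-B (default) value of the corresponding parameter; ``hill_nA`` is
    absolute; ``radius`` sets the initial colony radius in sites.
    """

    axes: Dict[str, Sequence[float]]
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.axes) - set(_AXIS_APPLIERS)
        if unknown:
            raise ValueError(f"unknown sweep axes: {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def grid_points(self) -> List[Dict[str, float]]:
        names = list(self.axes)
        return [dict(zip(names, combo))
                for combo in itertools.product(*(self.axes[n] for n in names))]


def apply_point(base: SimulationConfig, point: Dict[str, float]
                ) -> SimulationConfig:
    """Return a config with one grid point's type-A perturbations applied."""
    cfg = base.copy()
    for axis, value in point.items():
        kind, key = _AXIS_APPLIERS[axis]
        if kind == "type":
            ref = cfg.type_overrides.get("B", {}).get(
                key, SimulationConfig.printed_default(key))
            cfg.type_overrides.setdefault("A", {})[key] = ref * value
        elif kind == "type_abs":
            cfg.type_overrides.setdefault("A", {})[key] = value
        elif kind == "contact":
            ref = cfg.contact_overrides.get(
                "J_AB", SimulationConfig.printed_contact_default("J_AB"))
            cfg.contact_overrides["J_AA"] = ref * value
        elif kind == "init":
            cfg.colony_radius = float(value)
    return cfg


def _replicate_mean_counts(results: List[CompetitionResult],
                           n_steps: int, record_every: int
                           ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align replicate N_A(t) on the common recording grid and average.

    Runs that ended early because type A went extinct contribute zeros
    afterwards; runs that ended because type B went extinct carry their last
    type-A count forward.
    """
    steps = np.arange(0, n_steps + 1, record_every)
    series = np.zeros((len(results), steps.size))
    ends = np.zeros(len(results))
    for i, res in enumerate(results):
        m = res.metrics
        run_steps = m["step"].to_numpy()
        n_a = m["n_A"].to_numpy().astype(float)
        fill = 0.0 if n_a[-1] == 0 else n_a[-1]
        series[i] = np.interp(steps, run_steps, n_a,
                              left=n_a[0], right=fill)
        ends[i] = n_a[-1] if run_steps[-1] >= n_steps else fill
    return steps, series.mean(axis=0), ends


def run_sweep(sweep: SweepSpec, base_config: SimulationConfig,
              out_dir: Optional[str] = None, resume: bool = False,
              discard_tau0: float = 1.0):
    """Run every grid point of a sweep and tabulate fitness statistics.

    For each grid point, ``sweep.replicates`` competition runs with distinct
    deterministic seeds are executed; alpha is fitted on the replicate-mean
    type-A counts (first ``discard_tau0`` timer periods discarded) and the
    survival fraction is the share of replicates with N_A(end) > N_A(0).
    Returns a tidy DataFrame keyed by the grid coordinates. With ``out_dir``
    each completed point is written as JSON, and ``resume=True`` skips points
    already on disk. A failed point is recorded with NaN statistics, not
    fatal.
    """
    import pandas as pd

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    rows = []
    points = sweep.grid_points()
    for idx, point in enumerate(points):
        key = "point_" + "_".join(f"{k}={point[k]:g}" for k in sorted(point))
        path = os.path.join(out_dir, key + ".json") if out_dir else None
        if resume and path and os.path.exists(path):
            with open(path) as fh:
                rows.append(json.load(fh))
            continue
        row: Dict[str, float] = dict(point)
        try:
            cfg = apply_point(base_config, point)
            results = []
            for rep in range(sweep.replicates):
                rep_seed = int(np.random.SeedSequence(
                    [sweep.seed, idx, rep]).generate_state(1)[0] % (2**31))
                results.append(run_competition(cfg, seed=rep_seed))
            steps, mean_n, ends = _replicate_mean_counts(
                results, cfg.n_steps, cfg.record_every)
            tau0 = cfg.timer_mean_printed()
            fit = fit_net_growth_rate(mean_n, steps,
                                      discard_steps=discard_tau0 * tau0)
            n0 = results[0].metrics["n_A"].iloc[0]
            row.update(
                alpha=fit.alpha, alpha_se=fit.alpha_se,
                r_squared=fit.r_squared,
                survival_fraction=float(np.mean(ends > n0)),
                n_A_initial=float(n0), n_A_final_mean=float(np.mean(ends)),
                replicates=sweep.replicates,
                outcome=classify_outcome(fit.alpha, fit.alpha_se),
            )
            for tag in ("A", "B"):
                div = death = 0
                for res in results:
                    ev = res.events
                    div += int(ev[f"divisions_{tag}"].sum())
                    death += int(ev[f"deaths_total_{tag}"].sum())
                row[f"divisions_{tag}"] = div / sweep.replicates
                row[f"deaths_{tag}"] = death / sweep.replicates
        except Exception as exc:  # partial failures recorded, not fatal
            row.update(alpha=float("nan"), alpha_se=float("nan"),
                       survival_fraction=float("nan"),
                       outcome="failed", error=str(exc))
        rows.append(row)
        if path:
            with open(path, "w") as fh:
                json.dump(row, fh)
    return pd.DataFrame(rows)
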