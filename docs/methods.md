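# Methods

`cellcompete` simulates competition between two cell types in a confluent
epithelium as two coupled layers: a **physical layer** (a cellular Potts
model, CPM) that relaxes tissue mechanics, and a **decision layer** that
applies cell-autonomous rules — growth, cell-cycle progression, division,
apoptosis and extrusion — once between consecutive Monte-Carlo steps.

## Physical layer

Each cell is the set of lattice sites holding its integer identifier
(0 = medium). The energy is

    E = Σ_{neighbour pairs, n_i ≠ n_j} J(σ_i, σ_j)
      + Σ_cells λ_α (A_α − A_α^T)²

an adhesion term over heterogeneous neighbour pairs (each unordered pair
counted once) plus an area-elastic term penalising deviations of a cell's
area A from its target area A^T with compressional modulus λ. There is no
perimeter/contractility term: interfacial tension is carried entirely by the
contact energies. Dynamics are Metropolis identity flips: a random interior
site adopts the identity of a randomly chosen *distinct* neighbour with
probability 1 if ΔE ≤ 0 and exp(−ΔE/k_BT) otherwise. One Monte-Carlo step
(MCS) — the simulation's time unit — performs width × height copy attempts.

Choices the published description leaves open, and what this package does:

- **Neighbourhood**: Moore (8-neighbour) for both the contact sum and flip
  candidates; configurable to von Neumann. Moore is standard CPM practice
  and produces smooth interfaces at k_BT = 10.
- **Boundaries**: fixed, non-periodic domain realised as an immutable
  one-site medium frame; proposals never target frame sites.
- **Connectivity**: not constrained (k_BT = 10 keeps fragmentation rare);
  `count_fragments` is provided as a diagnostic.
- **Pair counting**: each unordered neighbour pair contributes once.
- Energy comparisons use a relative tolerance of 1e-9; eigen-decomposition
  ties in cell geometry break to the first lattice axis.

## Units

Published parameter tables are dimensionless in the scales A_S = 1400 sites
(mean sizer), τ0 = 225 steps (mean S/G2/M timer) and λ = 1. `convert_params`
maps them to lattice units once per run: G = 1.14·A_S/τ0 ≈ 7.093 sites/step,
k = 1.96e5/A_S² = 0.1 sites⁻², ρ_1/2 = 14.01/A_S ≈ 1.0007e-2 sites⁻¹,
β = 0.104·A_S = 145.6 sites, and contact energies scale by λA_S^{3/2}
(e.g. J_AA = 2.39e-4 → 12.52). The conversion factors are exposed via
`conversion_record()` for run logs.

## Decision layer (once per MCS)

1. **Growth** raises the *target* area: dA^T/dt = G·exp(−k (A − A^T)²),
   applied while A ≤ A^T (explicit Euler, dt = 1 MCS). A compressed cell
   (A < A^T) has growth damped exponentially — contact inhibition of
   proliferation. The published rule is guarded by a strict A < A^T, but
   newborns start at A = A^T exactly and would freeze under the strict
   reading, so the guard here is non-strict.
2. **Cycle**: G1 until A ≥ A_S (per-cell Gaussian draw, 1400 ± 35), then a
   fixed countdown of τ0 (225 ± 5.625) in S/G2/M, then division. Draws are
   truncated below at 1 by resampling (astronomically rare at these CVs).
3. **Division** splits the cell by ranking its sites along the principal
   (semi-major) axis and cutting at the median — a cleavage plane through
   the centroid perpendicular to the long axis, daughters arranged along it.
   Each daughter gets a fresh identifier, A^T = A (mechanical equilibrium at
   birth), phase G1, fresh draws, generation = mother + 1.
4. **Elimination**, for every living cell, using one whole-lattice contact
   scan per step:
   - *density apoptosis*: hazard p_den,max / (1 + exp(−β(ρ − ρ_1/2))) with
     ρ = 1/A + Σ 1/A_i over contacting cells;
   - *contact apoptosis*: hazard p_con,max p_AB^n / (S^n + p_AB^n) with
     p_AB the heterotypic fraction of all boundary contacts (medium included
     in the denominator: the fitted midpoint S = 1.35 > 1 is consistent with
     p_AB never reaching half-maximum);
   - the two hazards are independent per-step Bernoulli trials; either
     success sets phase = apoptotic and A^T = 0, after which the lattice
     erodes the cell;
   - *extrusion*: any cell with A strictly below a quarter of its type's
     current mean area (mean over living cells, apoptotic included) is
     deleted at once, its sites becoming medium;
   - apoptotic remnants below 10 sites are removed outright (a floor that
     guarantees termination; in practice extrusion removes them first).

The fitted hazard curves are interpreted as **per-MCS** probabilities. The
experimental time base behind the fits is not recoverable from the published
description; this is the single most consequential calibration choice in the
model (see "Desk-scale behaviour" below).

## Initial conditions and the experiment layer

`make_initial_state` tessellates the interior into near-1300-site cells
(nearest-seed assignment on a jittered triangular lattice of seed points,
spacing chosen so each seed owns ≈ A0 = 1300 sites) and relaxes the straight
interfaces for a few MCS at frozen targets. A0 = 1300 makes a radius-50 disc
hold exactly six cells, the published smallest-colony geometry; the seed
lattice is anchored with the domain centre at a triangle centroid so that
count is reproduced deterministically. Cells with centroid within the colony
radius are type A; `pseudo_clone` mode instead relabels a central patch of
an otherwise homogeneous population — identical parameters, label-blind
adhesion (J_AA = J_AB = J_BB) and contact apoptosis disabled for both
labels, since a pseudo-clone has no genetically heterotypic interface;
`tiled_mixture` assigns types independently per cell.

Fitness is summarised by the net per-capita growth rate α from a log-linear
fit of the replicate-mean type-A count over the pre-extinction horizon,
discarding the first τ0 as relaxation transient; outcomes are classified by
the sign of α with a ±2 SE dead band (coexistence). `run_sweep` executes
grids over λ, k, ρ_1/2, n_H, A_S, G, J_AA/J_AB ratios or colony radius with
deterministic per-point replicate seeds, resumable per grid point.

Three named random substreams (lattice, decision draws, cycle draws) are
spawned from one seed, so a change in one layer leaves the others'
trajectories untouched; (config, seed) determines every output bit.

## Desk-scale protocol and behaviour

The published experiments use a 1500² lattice (~1700 cells) for up to 260τ0
with up to 30 replicates — days of CPU time. This package's tests and the
acceptance script instead run a **desk-scale protocol**: a 300² domain
(~65 cells), colony radius 105 (the largest that keeps one cell diameter of
margin), 24τ0 horizons, and 2–5 replicates; these problem sizes are the
package's own choice of a protocol that completes in minutes.

At this scale one genuine model property dominates: **interface-curvature
amplified contact killing**. Boundary cells of a colony only a few cell
diameters across have p_AB ≈ 0.3–0.6 and per-step contact hazards of
0.005–0.04 — mean lifetimes well under one cell cycle — while replacement
divisions need at least τ0. Measured consequence (both hazards active,
defaults): a 12-cell colony (R = 75) is eliminated within ~1τ0, a 27-cell
colony (R = 105) within ~3–4τ0, and even a 101-cell colony (R = 200 on
500²) within ~8τ0, regardless of λ ∈ [0.5, 2] and of k. The per-capita
contact-death rate of the minority colony is ~2.4× the host's at equal
parameters — pure geometry (making J_AA = J_BB changes nothing). This is the
same mechanism the published critical-size analysis describes; at desk scale
*every* admissible colony is below critical size.

What passing tests therefore do and do not show:

- Hazard curves, energies, Metropolis law, bookkeeping, growth/cycle/
  division rules and the fitness estimator are verified against independent
  oracles — these hold at any scale.
- Mechanical competition directionality (stiffer wins; softer is compressed
  above homeostatic density and loses; λ-ordering of α) is demonstrated in
  the mechanical regime and as orderings of elimination rates when both
  hazards are active.
- Full-scale phase-boundary numbers (critical radius ≈ 125 px, survival
  thresholds in λ) require the 1500² protocol and are *not* reproduced at
  desk scale; with per-MCS hazards the desk-scale minority colony always
  loses the interface war, so desk-scale assertions about neutral or
  winning colonies are limited to the pseudo-clone (exactly neutral by
  construction) and to orderings, not signs, of α.

## Known limitations

- 2D only; no chemotaxis, no perimeter/contractility energy, no GPU path.
- The per-MCS interpretation of the fitted apoptosis probabilities is a
  calibration assumption; a coarser hazard epoch would weaken interface
  killing roughly proportionally and shift every desk-scale threshold.
- The synthetic tessellation produces mildly irregular polygonal cells with
  a common resting area; real epithelia have broader area/shape dispersion
  and boundary conditions other than a rigid frame.
- Division assumes the median cut yields two near-connected daughter
  groups; for highly non-convex cells (rare at k_BT = 10) a daughter can be
  born fragmented, which the fragmentation diagnostic can monitor.
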