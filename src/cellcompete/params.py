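"""Cell-type parameters, contact energies and unit conversion.

Published parameter tables express quantities in dimensionless units built
from three reference scales: the mean G1 sizer threshold ``A_S`` (an area, in
lattice sites), the mean S/G2/M timer ``tau_0`` (in Monte-Carlo steps) and the
area elastic modulus ``lambda`` (the lattice energy unit). Everything in the
simulator itself works in canonical lattice units — sites, steps and lattice
energy — so the table values are converted exactly once, here.

Conversions applied by :func:`convert_params`:

====================  =========================  =======================
quantity              printed unit               lattice unit
====================  =========================  =======================
growth rate G         A_S / tau_0                sites / step
crowding k            A_S^-2                     sites^-2
density rho_half      A_S^-1                     sites^-1
density beta          A_S                        sites
contact energies J    lambda * A_S^(3/2)         lattice energy
====================  =========================  =======================

lambda, kB*T, the timer/sizer means and SDs, and all probabilities are
already in lattice units and pass through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict

import numpy as np

# Integer codes used on the lattice / in the registry.
MEDIUM = 0
TYPE_A = 1
TYPE_B = 2

TYPE_NAMES = {MEDIUM: "M", TYPE_A: "A", TYPE_B: "B"}
TYPE_CODES = {"M": MEDIUM, "A": TYPE_A, "B": TYPE_B}

# Reference scales used by the published tables.
REF_SIZER = 1400.0   # sites, mean G1 sizer threshold A_S
REF_TIMER = 225.0    # Monte-Carlo steps, mean S/G2/M timer tau_0
REF_LAMBDA = 1.0     # lattice energy per sites^2, elastic modulus unit

#: Default per-type parameters in *printed* (dimensionless) units. Both cell
#: types share the same defaults; competition experiments perturb type A.
TABLE1_DEFAULTS: Dict[str, float] = {
    "lam": 1.0,            # area elastic modulus (lattice units already)
    "growth_rate": 1.14,   # in A_S / tau_0
    "crowding_k": 1.96e5,  # in A_S^-2
    "timer_mean": 225.0,   # steps
    "timer_sd": 5.625,     # steps
    "sizer_mean": 1400.0,  # sites
    "sizer_sd": 35.0,      # sites
    "p_den_max": 0.0015,
    "rho_half": 14.01,     # in A_S^-1
    "beta": 0.104,         # in A_S
    "p_con_max": 1.0,
    "steepness_S": 1.35,
    "hill_n": 3.6,
}

#: Default contact energies in units of lambda * A_S^(3/2).
TABLE2_DEFAULTS: Dict[str, float] = {
    "J_AA": 2.39e-4,
    "J_BB": 1.15e-4,
    "J_AB": 1.91e-4,
    "J_AM": 2.86e-4,
    "J_BM": 2.86e-4,
}

DEFAULT_KT = 10.0  # effective thermal energy kB*T, lattice energy units


@dataclass(frozen=True)
class CellTypeParams:
    """Per-type constants, in canonical lattice units (sites / steps / energy)."""

    lam: float                 # area elastic modulus
    growth_rate: float         # uncrowded target-area growth, sites/step
    crowding_k: float          # crowding sensitivity, sites^-2
    timer_mean: float          # S/G2/M duration mean, steps
    timer_sd: float
    sizer_mean: float          # G1 sizer threshold mean, sites
    sizer_sd: float
    p_den_max: float           # density-apoptosis saturation probability/step
    rho_half: float            # density at half-max apoptosis, sites^-1
    beta: float                # density-apoptosis sensitivity, sites
    p_con_max: float           # contact-apoptosis saturation probability/step
    steepness_S: float         # heterotypic-contact fraction at half-max
    hill_n: float              # Hill coefficient of the contact hazard

    def __post_init__(self) -> None:
        for name in ("lam", "growth_rate", "crowding_k", "timer_mean",
                     "sizer_mean", "rho_half", "beta", "steepness_S", "hill_n"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("timer_sd", "sizer_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_den_max", "p_con_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    def with_overrides(self, **kw: float) -> "CellTypeParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ContactEnergyTable:
    """Symmetric contact energies between the tags {A, B, M}, lattice units.

    Five independent values; medium-medium contact carries no energy (two
    medium sites always share the identifier 0 and are never a boundary pair).
    """

    J_AA: float
    J_BB: float
    J_AB: float
    J_AM: float
    J_BM: float

    def matrix(self) -> np.ndarray:
        """3x3 matrix indexed by type code (MEDIUM, TYPE_A, TYPE_B)."""
        m = np.zeros((3, 3), dtype=np.float64)
        m[TYPE_A, TYPE_A] = self.J_AA
        m[TYPE_B, TYPE_B] = self.J_BB
        m[TYPE_A, TYPE_B] = m[TYPE_B, TYPE_A] = self.J_AB
        m[TYPE_A, MEDIUM] = m[MEDIUM, TYPE_A] = self.J_AM
        m[TYPE_B, MEDIUM] = m[MEDIUM, TYPE_B] = self.J_BM
        return m

    def with_overrides(self, **kw: float) -> "ContactEnergyTable":
        return replace(self, **kw)


@dataclass(frozen=True)
class PottsParams:
    """Lattice-dynamics constants."""

    kT: float = DEFAULT_KT
    neighborhood_order: str = "moore"  # "moore" (8) or "von_neumann" (4)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kT) and self.kT > 0):
            raise ValueError(f"kT must be finite and > 0, got {self.kT!r}")
        if self.neighborhood_order not in ("moore", "von_neumann"):
            raise ValueError(
                f"unknown neighborhood_order {self.neighborhood_order!r}")

    def offsets(self) -> np.ndarray:
        """Neighbour displacement vectors, shape (n, 2)."""
        if self.neighborhood_order == "moore":
            offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)]
        else:
            offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        return np.array(offs, dtype=np.int64)


def _check_table(table: Dict[str, float], label: str) -> None:
    for key, v in table.items():
        if not isinstance(v, (int, float)) or not math.isfinite(float(v)):
            raise ValueError(f"{label}[{key!r}] must be finite, got {v!r}")
        if float(v) < 0:
            raise ValueError(f"{label}[{key!r}] must be >= 0, got {v!r}")


def convert_params(
    table1_units: Dict[str, Dict[str, float]] | None = None,
    table2_units: Dict[str, float] | None = None,
    *,
    ref_sizer: float = REF_SIZER,
    ref_timer: float = REF_TIMER,
    ref_lambda: float = REF_LAMBDA,
) -> tuple[Dict[str, CellTypeParams], ContactEnergyTable]:
    """Convert printed (dimensionless) table values to lattice units.

    Parameters
    ----------
    table1_units
        Mapping ``{"A": {...}, "B": {...}}`` of per-type values in printed
        units; missing types/keys fall back to the published defaults.
    table2_units
        Contact energies in units of ``ref_lambda * ref_sizer**1.5``.

    Returns
    -------
    (per_type, contact_table)
        ``per_type`` maps "A"/"B" to :class:`CellTypeParams` in lattice
        units; ``contact_table`` is the converted :class:`ContactEnergyTable`.
    """
    table1_units = table1_units or {}
    table2_units = table2_units or {}
    per_type: Dict[str, CellTypeParams] = {}
    for tag in ("A", "B"):
        raw = dict(TABLE1_DEFAULTS)
        raw.update(table1_units.get(tag, {}))
        unknown = set(raw) - set(TABLE1_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys for type {tag}: {sorted(unknown)}")
        _check_table(raw, f"table1[{tag}]")
        per_type[tag] = CellTypeParams(
            lam=raw["lam"] * ref_lambda,
            growth_rate=raw["growth_rate"] * ref_sizer / ref_timer,
            crowding_k=raw["crowding_k"] / ref_sizer**2,
            timer_mean=raw["timer_mean"],
            timer_sd=raw["timer_sd"],
            sizer_mean=raw["sizer_mean"],
            sizer_sd=raw["sizer_sd"],
            p_den_max=raw["p_den_max"],
            rho_half=raw["rho_half"] / ref_sizer,
            beta=raw["beta"] * ref_sizer,
            p_con_max=raw["p_con_max"],
            steepness_S=raw["steepness_S"],
            hill_n=raw["hill_n"],
        )
    raw2 = dict(TABLE2_DEFAULTS)
    raw2.update(table2_units)
    unknown = set(raw2) - set(TABLE2_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown contact-energy keys: {sorted(unknown)}")
    _check_table(raw2, "table2")
    energy_scale = ref_lambda * ref_sizer**1.5
    contact = ContactEnergyTable(**{k: v * energy_scale for k, v in raw2.items()})
    return per_type, contact


def conversion_record(
    ref_sizer: float = REF_SIZER,
    ref_timer: float = REF_TIMER,
    ref_lambda: float = REF_LAMBDA,
) -> Dict[str, float]:
    """The scale factors applied by :func:`convert_params`, for run logs."""
    return {
        "ref_sizer_sites": ref_sizer,
        "ref_timer_steps": ref_timer,
        "ref_lambda": ref_lambda,
        "growth_rate_scale": ref_sizer / ref_timer,
        "crowding_k_scale": ref_sizer**-2,
        "rho_half_scale": 1.0 / ref_sizer,
        "beta_scale": ref_sizer,
        "contact_energy_scale": ref_lambda * ref_sizer**1.5,
    }
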