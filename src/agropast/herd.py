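"""Cow agents: energy budgets, mass dynamics, demography, movement, subsidies.

Cows are held in structure-of-arrays form (mass, position, stage and
status flags) so the engine's step kernel can iterate them cheaply.  A cow
is a juvenile until its mass first reaches ``m_mature`` (the transition is
one-way), eats and metabolizes scaled by ``(mass / m_mature) ** 0.75``,
and dies when its mass falls below ``m_min``.  There is no sex structure
and no buying or selling of animals: only births, growth, starvation and
the drought subsidies move the herd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ManagementPlan, ModelParameters

__all__ = [
    "Herd",
    "initialize_herd",
    "mass_delta",
    "starvation_mass_loss_per_step",
    "reproduce_annual",
    "apply_subsidy",
    "clear_subsidy",
    "plough_allocation",
]


@dataclass
class Herd:
    """Structure-of-arrays cow container.

    Arrays are sized to a slot capacity; ``alive`` marks used slots.
    ``pending_intake`` carries raid intake (kg of standing crop) into the
    next energy update.
    """

    mass: np.ndarray
    r: np.ndarray
    c: np.ndarray
    alive: np.ndarray
    adult: np.ndarray
    transported: np.ndarray
    fed: np.ndarray
    working: np.ndarray
    pending_intake: np.ndarray

    @classmethod
    def empty(cls, capacity: int) -> "Herd":
        return cls(
            mass=np.zeros(capacity),
            r=np.zeros(capacity, dtype=np.int64),
            c=np.zeros(capacity, dtype=np.int64),
            alive=np.zeros(capacity, dtype=np.uint8),
            adult=np.zeros(capacity, dtype=np.uint8),
            transported=np.zeros(capacity, dtype=np.uint8),
            fed=np.zeros(capacity, dtype=np.uint8),
            working=np.zeros(capacity, dtype=np.uint8),
            pending_intake=np.zeros(capacity),
        )

    @property
    def n_slots(self) -> int:
        return self.mass.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def alive_idx(self) -> np.ndarray:
        return np.flatnonzero(self.alive == 1)

    def resident_idx(self) -> np.ndarray:
        return np.flatnonzero((self.alive == 1) & (self.transported == 0))

    def compact(self) -> "Herd":
        """Drop dead slots, preserving order."""
        keep = self.alive == 1
        return Herd(
            mass=self.mass[keep].copy(),
            r=self.r[keep].copy(),
            c=self.c[keep].copy(),
            alive=self.alive[keep].copy(),
            adult=self.adult[keep].copy(),
            transported=self.transported[keep].copy(),
            fed=self.fed[keep].copy(),
            working=self.working[keep].copy(),
            pending_intake=self.pending_intake[keep].copy(),
        )

    def append(self, mass, r, c, adult) -> None:
        """Append new cows (in-place array growth)."""
        n_new = len(mass)
        if n_new == 0:
            return
        self.mass = np.concatenate([self.mass, np.asarray(mass, dtype=np.float64)])
        self.r = np.concatenate([self.r, np.asarray(r, dtype=np.int64)])
        self.c = np.concatenate([self.c, np.asarray(c, dtype=np.int64)])
        self.alive = np.concatenate([self.alive, np.ones(n_new, dtype=np.uint8)])
        self.adult = np.concatenate(
            [self.adult, np.asarray(adult, dtype=np.uint8)])
        zeros = np.zeros(n_new, dtype=np.uint8)
        self.transported = np.concatenate([self.transported, zeros])
        self.fed = np.concatenate([self.fed, zeros.copy()])
        self.working = np.concatenate([self.working, zeros.copy()])
        self.pending_intake = np.concatenate(
            [self.pending_intake, np.zeros(n_new)])


def initialize_herd(
    landscape,
    params: ModelParameters,
    rng: np.random.Generator,
    adult_fraction: float = 0.7,
) -> Herd:
    """Spin-up herd at ``init_stocking_rate`` cows per woodland hectare.

    Adults start uniformly between ``max(m_mature, 1.15 m_min)`` and
    ``0.9 m_max`` (comfortably viable), juveniles between ``m_birth`` and
    ``m_mature``; all placed on random woodland patches.
    """
    wood_flat = np.flatnonzero(landscape.kind.ravel() == 0)
    wood_ha = wood_flat.size * landscape.patch_area
    n = max(0, int(round(params.init_stocking_rate * wood_ha)))
    herd = Herd.empty(n)
    herd.alive[:] = 1
    n_adult = int(round(adult_fraction * n))
    herd.adult[:n_adult] = 1
    lo = max(params.m_mature, 1.15 * params.m_min)
    hi = max(0.9 * params.m_max, lo + 1.0)
    herd.mass[:n_adult] = rng.uniform(lo, hi, n_adult)
    herd.mass[n_adult:] = rng.uniform(params.m_birth, params.m_mature, n - n_adult)
    pos = rng.choice(wood_flat, size=n, replace=True)
    herd.r[:] = pos // landscape.side
    herd.c[:] = pos % landscape.side
    return herd


def mass_delta(energy_mj: float, params: ModelParameters) -> float:
    """Mass change (kg) for a net step energy (MJ): anabolic gain or catabolic loss."""
    if energy_mj >= 0:
        return params.eta_a * energy_mj / params.eta_cow
    return energy_mj / (params.eta_c * params.eta_cow)


def starvation_mass_loss_per_step(params: ModelParameters, mass: float) -> float:
    """Closed-form mass loss per 8-h step on an empty patch (kg, positive)."""
    s = (mass / params.m_mature) ** 0.75
    return params.e_maint * s / (params.eta_c * params.eta_cow)


def reproduce_annual(
    herd: Herd,
    params: ModelParameters,
    rng: np.random.Generator,
) -> int:
    """Annual calving: each adult calves with probability ``1 - P_nr``.

    Transported adults calve at ``transported_repro_factor`` times that
    rate.  Calves appear at the mother's location with mass ``m_birth``.
    Returns the number of calves born.  One uniform draw is consumed per
    live adult, in slot order, so trajectories are seed-reproducible.
    """
    adults = np.flatnonzero((herd.alive == 1) & (herd.adult == 1))
    if adults.size == 0:
        return 0
    u = rng.random(adults.size)
    p = (1.0 - params.P_nr) * np.where(
        herd.transported[adults] == 1, params.transported_repro_factor, 1.0)
    mothers = adults[u < p]
    herd.append(
        mass=np.full(mothers.size, params.m_birth),
        r=herd.r[mothers],
        c=herd.c[mothers],
        adult=np.zeros(mothers.size, dtype=np.uint8),
    )
    return int(mothers.size)


def apply_subsidy(
    herd: Herd,
    plan: ManagementPlan,
    annual_rain_mm: float,
    params: ModelParameters,
) -> int:
    """Flag cows for this year's subsidy if rainfall is below the trigger.

    Selects exactly ``round(subsidy_fraction * n_alive)`` cows,
    largest-first (ties to the lower slot index).  ``feed`` mode marks cows
    to receive maintenance-covering feed each step (spend accrues in the
    engine's ledger at ``feed_price`` per kg); ``transport`` mode removes
    cows from the village for the year.  Returns the number flagged.
    """
    herd.fed[:] = 0
    herd.transported[:] = 0
    if plan.subsidy_mode == "none" or annual_rain_mm >= plan.low_rainfall_trigger:
        return 0
    alive = herd.alive_idx()
    k = int(round(plan.subsidy_fraction * alive.size))
    if k == 0:
        return 0
    # stable sort on -mass keeps lower slot index first among ties
    chosen = alive[np.argsort(-herd.mass[alive], kind="stable")[:k]]
    if plan.subsidy_mode == "feed":
        herd.fed[chosen] = 1
    else:
        herd.transported[chosen] = 1
    return k


def clear_subsidy(herd: Herd) -> None:
    """End-of-year return of transported cows and end of feed rations."""
    herd.fed[:] = 0
    herd.transported[:] = 0


def plough_allocation(
    n_available_cows: int,
    crop_area_ha: float,
    params: ModelParameters,
    steps_per_day: int = 3,
) -> tuple[float, int]:
    """Area ploughed in the ploughing window and cows needed to do it.

    ``area = min(crop_area, n_cows * plough_rate * window_steps)``; the
    number of working cows is the smallest team that achieves that area.
    Unploughed crop patches produce nothing that year.
    """
    window_steps = params.plough_window_days * steps_per_day
    per_cow = params.plough_rate * window_steps
    area = min(crop_area_ha, n_available_cows * per_cow)
    n_working = min(n_available_cows,
                    int(np.ceil(area / per_cow - 1e-12)) if per_cow > 0 else 0)
    return area, max(0, n_working)
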