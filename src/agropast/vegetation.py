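"""Rainfall-driven plant growth, harvest, grain storage, fencing, raiding.

Crop growth is linear in annual rainfall by default (the relation was
estimated from field data in the system this model emulates; a saturating
alternative can be swapped in by passing a custom response).  Woodland
growth pools herbaceous and woody production into one standing-biomass
stock per patch, scales linearly with rainfall relative to the reference
rainfall, and is logistically limited by the patch carrying capacity, with
the logistic factor evaluated at the start-of-season biomass so that an
empty patch at reference rainfall gains exactly ``g_wood * patch_area``.

Fencing ties crops to the woodland: brush fences on boundary crop patches
decay with an annual probability and each repair consumes
``fence_cost x boundary length`` of biomass from the nearest woodland patch
that can supply it — when the woodland is too denuded the fence stays
broken and the field is exposed to raiding.  Stone walls never decay and
consume nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ManagementPlan, ModelParameters
from .landscape import CROP, WOODLAND, Landscape, PATCH_SIDE_KM_PER_HA

__all__ = [
    "GrainStore",
    "YearlyAccount",
    "annual_crop_production",
    "annual_woodland_increment",
    "grow_crops",
    "grow_woodland",
    "harvest",
    "fence_segment_lengths_km",
    "maintain_fences",
    "raid_crops",
]


@dataclass
class GrainStore:
    """Per-vintage grain storage with a fixed carry-over horizon.

    ``vintages`` maps age in years (0 = this year's harvest) to kg of grain.
    Consumption draws oldest-first; at the end of each year :meth:`age`
    advances all vintages and discards those older than ``capacity_years``.
    """

    capacity_years: int = 0
    vintages: dict[int, float] = field(default_factory=dict)

    def deposit(self, kg: float) -> None:
        if kg < 0:
            raise ValueError("cannot deposit negative grain")
        if kg:
            self.vintages[0] = self.vintages.get(0, 0.0) + kg

    def consume(self, kg: float) -> float:
        """Draw up to ``kg`` oldest-first; returns the amount actually drawn."""
        if kg < 0:
            raise ValueError("cannot consume negative grain")
        drawn = 0.0
        for age in sorted(self.vintages, reverse=True):
            take = min(kg - drawn, self.vintages[age])
            self.vintages[age] -= take
            drawn += take
            if self.vintages[age] <= 0.0:
                del self.vintages[age]
            if drawn >= kg:
                break
        return drawn

    def age(self) -> float:
        """Advance vintages one year; returns kg discarded beyond capacity."""
        discarded = 0.0
        new: dict[int, float] = {}
        for age, kg in self.vintages.items():
            if age + 1 > self.capacity_years:
                discarded += kg
            elif kg > 0.0:
                new[age + 1] = new.get(age + 1, 0.0) + kg
        self.vintages = new
        return discarded

    def total(self) -> float:
        return float(sum(self.vintages.values()))


@dataclass
class YearlyAccount:
    """Per-year flows that the validation statistics compare to field data."""

    harvest: float = 0.0               # kg grain
    crop_eaten_by_raids: float = 0.0   # kg
    subsidy_spend: float = 0.0         # currency
    fence_wood_used: float = 0.0       # kg
    min_woodland_biomass: float = 0.0  # kg


def annual_crop_production(
    landscape: Landscape,
    annual_rain_mm: float,
    params: ModelParameters,
    plan: ManagementPlan,
    ploughed: np.ndarray | None = None,
) -> np.ndarray:
    """Per-patch seasonal standing-crop biomass (kg) for one year.

    ``crop_growth_rate * rain * patch_area``, multiplied by ``crop_boost``
    on enhanced patches; zero on woodland and on unploughed crop patches.
    """
    if annual_rain_mm < 0:
        raise ValueError("rainfall cannot be negative")
    crop = landscape.crop_mask()
    if ploughed is not None:
        crop = crop & ploughed
    out = np.zeros_like(landscape.biomass)
    base = params.crop_growth_rate * annual_rain_mm * landscape.patch_area
    out[crop] = base
    out[crop & landscape.enhanced] = base * plan.crop_boost
    return out


def annual_woodland_increment(
    landscape: Landscape,
    annual_rain_mm: float,
    params: ModelParameters,
    plan: ManagementPlan,
) -> np.ndarray:
    """Per-patch annual woodland biomass gain (kg), logistic-limited.

    ``g_wood * patch_area * (rain / reference_rainfall) * boost *
    (1 - B/K)`` evaluated at start-of-season biomass ``B``; clipped so a
    patch never exceeds the carrying capacity ``K``.
    """
    if annual_rain_mm < 0:
        raise ValueError("rainfall cannot be negative")
    wood = ~landscape.crop_mask()
    k = params.woodland_carrying_capacity
    rate = (params.g_wood * landscape.patch_area
            * annual_rain_mm / params.reference_rainfall)
    boost = np.where(landscape.enhanced, plan.wood_boost, 1.0)
    logistic = np.clip(1.0 - landscape.biomass / k, 0.0, 1.0)
    inc = np.where(wood, rate * boost * logistic, 0.0)
    return np.minimum(inc, np.maximum(k - landscape.biomass, 0.0))


def grow_crops(landscape, annual_rain_mm, params, plan, ploughed=None) -> np.ndarray:
    """Apply one season's crop growth to the landscape; returns the increments."""
    inc = annual_crop_production(landscape, annual_rain_mm, params, plan, ploughed)
    landscape.biomass += inc
    return inc


def grow_woodland(landscape, annual_rain_mm, params, plan) -> np.ndarray:
    """Apply one year's woodland growth to the landscape; returns the increments."""
    inc = annual_woodland_increment(landscape, annual_rain_mm, params, plan)
    landscape.biomass += inc
    return inc


def harvest(
    landscape: Landscape,
    store: GrainStore,
    params: ModelParameters,
    plan: ManagementPlan,
) -> float:
    """Split standing crop into stored grain and field residue.

    The grain fraction of each crop patch's standing biomass (whatever the
    raids left) enters the newest store vintage; the rest stays on the
    patch as dry-season grazing residue.  Returns the harvested grain kg.
    """
    crop = landscape.crop_mask()
    standing = landscape.biomass[crop]
    grain = float(standing.sum()) * params.grain_fraction
    landscape.residue[crop] += standing * (1.0 - params.grain_fraction)
    landscape.biomass[crop] = 0.0
    store.deposit(grain)
    return grain


def fence_segment_lengths_km(landscape: Landscape) -> np.ndarray:
    """Per-patch fence length (km) on boundary crop patches.

    A boundary crop patch needs fencing along each edge exposed to
    woodland or to the map boundary.
    """
    k = landscape.kind
    side_km = math.sqrt(landscape.patch_area) * PATCH_SIDE_KM_PER_HA
    pad = np.pad(k, 1, constant_values=WOODLAND)
    exposed = (
        (pad[:-2, 1:-1] == WOODLAND).astype(np.int64)
        + (pad[2:, 1:-1] == WOODLAND)
        + (pad[1:-1, :-2] == WOODLAND)
        + (pad[1:-1, 2:] == WOODLAND)
    )
    out = np.where(k == CROP, exposed * side_km, 0.0)
    return out


def nearest_wood_order(landscape: Landscape) -> dict[int, np.ndarray]:
    """For each boundary crop patch (flat index), woodland patch indices by distance.

    Distance is Euclidean between patch centres; ties resolve to the lower
    flat index.  Computed once per landscape (the kind grid is static).
    """
    side = landscape.side
    wood_flat = np.flatnonzero(landscape.kind.ravel() == WOODLAND)
    if wood_flat.size == 0:
        return {int(p): np.empty(0, dtype=np.int64)
                for p in np.flatnonzero(landscape.boundary_crop_mask().ravel())}
    wr, wc = np.divmod(wood_flat, side)
    order: dict[int, np.ndarray] = {}
    for p in np.flatnonzero(landscape.boundary_crop_mask().ravel()):
        pr, pc = divmod(int(p), side)
        d2 = (wr - pr) ** 2 + (wc - pc) ** 2
        order[int(p)] = wood_flat[np.argsort(d2, kind="stable")]
    return order


def maintain_fences(
    landscape: Landscape,
    params: ModelParameters,
    plan: ManagementPlan,
    rng: np.random.Generator,
    wood_order: dict[int, np.ndarray] | None = None,
) -> float:
    """Annual fence decay and repair; returns woodland biomass used (kg).

    With stone walls every fence is intact forever and nothing is consumed.
    Otherwise each intact boundary fence fails with ``fence_decay_prob``;
    repairing a broken fence consumes ``fence_cost x segment length`` of
    biomass from the nearest woodland patch holding at least that much —
    if none can supply it the fence stays broken (the denudation feedback).
    """
    if plan.stone_walls:
        landscape.fence_intact[:] = True
        return 0.0
    boundary = landscape.boundary_crop_mask()
    b_flat = np.flatnonzero(boundary.ravel())
    if b_flat.size == 0:
        return 0.0
    # decay draws are made for every boundary patch (fixed rng consumption)
    u = rng.random(b_flat.size)
    fences = landscape.fence_intact.ravel()
    fences[b_flat[u < params.fence_decay_prob]] = False

    if wood_order is None:
        wood_order = nearest_wood_order(landscape)
    lengths = fence_segment_lengths_km(landscape).ravel()
    biomass = landscape.biomass.ravel()
    kindf = landscape.kind.ravel()
    wood_used = 0.0
    for p in b_flat:
        if fences[p]:
            continue
        need = params.fence_cost * lengths[p]
        if need <= 0.0:
            fences[p] = True
            continue
        for w in wood_order[int(p)]:
            if kindf[w] == WOODLAND and biomass[w] >= need:
                biomass[w] -= need
                wood_used += need
                fences[p] = True
                break
    return wood_used


def raid_crops(
    landscape: Landscape,
    herd,
    params: ModelParameters,
    rng: np.random.Generator,
) -> float:
    """One 8-h step of crop raiding; returns kg of standing crop eaten.

    Each boundary crop patch with a broken fence and standing biomass is
    raided with probability ``fence_break_prob`` provided a live,
    non-transported cow stands on the patch or 4-adjacent to it; the cow
    consumes up to its allometric intake cap and is credited the energy at
    ``eta_crop`` by the engine's energy update.

    The simulation engine applies identical logic inside its step kernel;
    this standalone form is the unit-testable surface of the operation.
    """
    side = landscape.side
    biomass = landscape.biomass.ravel()
    fences = landscape.fence_intact.ravel()
    b_flat = np.flatnonzero(landscape.boundary_crop_mask().ravel())
    eaten_total = 0.0
    u = rng.random(b_flat.size)
    for j, p in enumerate(b_flat):
        if fences[p] or biomass[p] <= 0.0 or u[j] >= params.fence_break_prob:
            continue
        pr, pc = divmod(int(p), side)
        for i in range(herd.n_slots):
            if not herd.alive[i] or herd.transported[i]:
                continue
            if abs(herd.r[i] - pr) + abs(herd.c[i] - pc) <= 1:
                s = (herd.mass[i] / params.m_mature) ** 0.75
                eat = min(params.intake_max * s, biomass[p])
                biomass[p] -= eat
                herd.pending_intake[i] += eat
                eaten_total += eat
                break
    return eaten_total
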