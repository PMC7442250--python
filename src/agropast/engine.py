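"""Simulation engine: a 60-year run of the village system.

A model year is 365 days of three 8-hour steps.  The wet season is the
first 180 days: crop and woodland growth are deposited evenly across its
steps, ploughing happens in an opening window, and harvest closes it.  The
dry season that follows offers woodland browse and crop residue only.
Annually the scheduler applies the rainfall draw, the drought-subsidy
decision, fence decay and repair, reproduction, grain-store bookkeeping
and the sustainability check; the step-level dynamics (movement, grazing,
raiding, energy and mass updates) run in the shared kernel.

A run is *sustainable* when the herd, the seed supply (harvest plus
carried-over grain) and the woodland biomass each stay at or above their
minimum thresholds every year; by default a run halts at the first breach
and records the failure year.

Every biomass and energy flow is double-entry-accounted; ``RunResult``
carries per-year ledgers that close to floating-point accuracy, and the
run is bit-for-bit reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel, herd as herd_mod, vegetation
from ._kernel import (
    A_ANAB, A_CATAB, A_CROP_GROWTH, A_DIED_MASS, A_DISCARD, A_DM,
    A_FEED_KG, A_FEED_MJ, A_GRAZE_RES, A_GRAZE_WOOD, A_MAINT, A_RAID,
    A_SPEND, A_WOOD_GROWTH, A_WOOD_MIN, A_WORK, N_ACC, HAVE_NUMBA,
)
from .config import ManagementPlan, ModelParameters
from .landscape import Landscape, WOODLAND, generate_landscape, spatial_metrics
from .rainfall import RainfallSeries
from .vegetation import GrainStore

__all__ = [
    "RunResult",
    "run_simulation",
    "evaluate_sustainability",
    "resolve_thresholds",
    "InternalConsistencyError",
]

STEPS_PER_DAY = 3
DAYS_PER_YEAR = 365
WET_DAYS = 180
WET_STEPS = WET_DAYS * STEPS_PER_DAY            # 540
DRY_STEPS = (DAYS_PER_YEAR - WET_DAYS) * STEPS_PER_DAY  # 555


class InternalConsistencyError(RuntimeError):
    """A conservation ledger failed to close mid-run (never silent)."""


@dataclass
class RunResult:
    """Outcome of one simulation run.

    ``yearly`` holds one record per simulated year; ``sustainable`` is True
    iff every year met all three minima (equivalently ``failure_year`` is
    None).  ``inputs`` echoes parameters, plan, rainfall scenario, seed and
    the realized spatial metrics so sweep outputs are self-describing.
    """

    yearly: list[dict]
    sustainable: bool
    failure_year: Optional[int]
    inputs: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.yearly)

    def to_json(self, path=None) -> str:
        doc = {
            "sustainable": self.sustainable,
            "failure_year": self.failure_year,
            "inputs": self.inputs,
            "yearly": self.yearly,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def resolve_thresholds(
    params: ModelParameters,
    crop_area_ha: float,
    wood_capacity_kg: float,
) -> tuple[float, float, float]:
    """Resolve the (cows, seed, woodland) minima for a concrete landscape."""
    min_cows = params.min_cows_thresh
    min_seed = (params.min_seed_thresh if params.min_seed_thresh is not None
                else params.seed_per_ha * crop_area_ha)
    min_wood = (params.min_wood_thresh if params.min_wood_thresh is not None
                else params.min_wood_frac * wood_capacity_kg)
    return min_cows, min_seed, min_wood


def evaluate_sustainability(
    yearly: list[dict],
    min_cows: float,
    min_seed: float,
    min_wood: float,
) -> tuple[bool, Optional[int]]:
    """Score a yearly series against the three minima.

    True iff every year has ``n_cows >= min_cows``, ``seed_available >=
    min_seed`` and ``woodland_biomass >= min_wood``; otherwise the first
    violating year (1-based) is returned.
    """
    if not yearly:
        raise ValueError("need at least one yearly record")
    for rec in yearly:
        if (rec["n_cows"] < min_cows
                or rec["seed_available"] < min_seed
                or rec["woodland_biomass"] < min_wood):
            return False, rec["year"]
    return True, None


def _check_ledgers(rec: dict, tol: float = 1e-9) -> None:
    """Verify the year's energy and biomass ledgers close (relative tol)."""
    lhs = rec["energy_in_mj"]
    rhs = rec["energy_out_mj"]
    scale = max(abs(lhs), abs(rhs), 1.0)
    if abs(lhs - rhs) > tol * scale:
        raise InternalConsistencyError(
            f"energy ledger open in year {rec['year']}: {lhs} vs {rhs}")
    lhs = rec["wood_ledger_lhs"]
    rhs = rec["wood_ledger_rhs"]
    scale = max(abs(lhs), abs(rhs), 1.0)
    if abs(lhs - rhs) > tol * scale:
        raise InternalConsistencyError(
            f"woodland ledger open in year {rec['year']}: {lhs} vs {rhs}")
    lhs = rec["crop_ledger_lhs"]
    rhs = rec["crop_ledger_rhs"]
    scale = max(abs(lhs), abs(rhs), 1.0)
    if abs(lhs - rhs) > tol * scale:
        raise InternalConsistencyError(
            f"crop ledger open in year {rec['year']}: {lhs} vs {rhs}")


def run_simulation(
    params: ModelParameters,
    plan: ManagementPlan,
    rainfall: RainfallSeries,
    seed: int,
    run_to_completion: bool = False,
    use_jit: bool = True,
    landscape: Landscape | None = None,
    check_ledgers: bool = True,
    input_extra: dict | None = None,
) -> RunResult:
    """Run the agro-pastoral system for the length of the rainfall series.

    Deterministic per ``seed``: all stochastic inputs flow from one
    ``numpy`` generator in a fixed order, and the step kernel consumes
    pre-drawn arrays, so jitted and pure-Python execution agree bit for
    bit (``use_jit=False`` forces the pure path).
    """
    params.validate()
    plan.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    side = params.grid_side()

    if landscape is None:
        landscape = generate_landscape(
            side, plan.proportion_crops, plan.clumpiness, rng,
            patch_area=params.patch_area)
    else:
        side = landscape.side
    kind_flat = landscape.kind.ravel()
    crop_flat = np.flatnonzero(kind_flat == 1)
    wood_flat = np.flatnonzero(kind_flat == WOODLAND)
    n_crop, n_wood = crop_flat.size, wood_flat.size

    # enhanced (faster-growing) patches, chosen once
    if plan.enhanced_crop_frac > 0 and n_crop:
        k = int(round(plan.enhanced_crop_frac * n_crop))
        chosen = rng.choice(crop_flat, size=k, replace=False)
        landscape.enhanced.ravel()[chosen] = True
    if plan.enhanced_wood_frac > 0 and n_wood:
        k = int(round(plan.enhanced_wood_frac * n_wood))
        chosen = rng.choice(wood_flat, size=k, replace=False)
        landscape.enhanced.ravel()[chosen] = True

    # spin-up: woodland near equilibrium, herd at the stocking rate
    landscape.biomass.ravel()[wood_flat] = (
        params.init_wood_frac * params.woodland_carrying_capacity)
    herd = herd_mod.initialize_herd(landscape, params, rng)

    store = GrainStore(capacity_years=plan.storage_years)
    boundary_idx = np.flatnonzero(landscape.boundary_crop_mask().ravel())
    wood_order = (None if plan.stone_walls
                  else vegetation.nearest_wood_order(landscape))
    crop_area = n_crop * landscape.patch_area
    wood_capacity = n_wood * params.woodland_carrying_capacity
    min_cows, min_seed, min_wood = resolve_thresholds(
        params, crop_area, wood_capacity)

    metrics = spatial_metrics(landscape) if (n_crop and n_wood) else {}
    inputs = {
        "seed": int(seed),
        "scenario": rainfall.scenario,
        "parameters": dataclasses.asdict(params),
        "plan": dataclasses.asdict(plan),
        "thresholds": {"min_cows": min_cows, "min_seed": min_seed,
                       "min_wood": min_wood},
        **metrics,
    }
    if input_extra:
        inputs.update(input_extra)

    kernel = _kernel.simulate_steps_jit if (use_jit and HAVE_NUMBA) \
        else _kernel.simulate_steps_py
    n_patches = side * side
    win_rv = np.zeros(n_patches)
    win_ra = np.zeros(n_patches, dtype=np.int64)
    win_fv = np.zeros(n_patches)
    win_fr = np.zeros(n_patches, dtype=np.int64)
    gval = np.zeros(n_patches)
    qidx = np.zeros(side, dtype=np.int64)
    plough_window_steps = params.plough_window_days * STEPS_PER_DAY

    yearly: list[dict] = []
    sustainable = True
    failure_year: Optional[int] = None

    for y in range(len(rainfall)):
        rain = float(rainfall.values[y])
        herd = herd.compact()
        n_slots = herd.n_slots
        cow_mass_start = float(herd.mass[herd.alive == 1].sum())

        wood_pre_fence = float(landscape.biomass.ravel()[wood_flat].sum())
        n_subsidized = herd_mod.apply_subsidy(herd, plan, rain, params)
        fence_wood = vegetation.maintain_fences(
            landscape, params, plan, rng, wood_order=wood_order)

        # ploughing allocation (resident adults work, largest first)
        resident_adults = np.flatnonzero(
            (herd.alive == 1) & (herd.transported == 0) & (herd.adult == 1))
        area, n_working = herd_mod.plough_allocation(
            resident_adults.size, crop_area, params, STEPS_PER_DAY)
        herd.working[:] = 0
        if n_working:
            order = resident_adults[
                np.argsort(-herd.mass[resident_adults], kind="stable")]
            herd.working[order[:n_working]] = 1
        k_patches = int(area / landscape.patch_area + 1e-9)
        ploughed = np.zeros(n_patches, dtype=bool)
        ploughed[crop_flat[:k_patches]] = True

        crop_annual = vegetation.annual_crop_production(
            landscape, rain, params, plan, ploughed.reshape(side, side))
        wood_annual = vegetation.annual_woodland_increment(
            landscape, rain, params, plan)
        crop_step = (crop_annual / WET_STEPS).ravel()
        wood_step = (wood_annual / WET_STEPS).ravel()

        wood_total = wood_pre_fence - fence_wood
        wood_start = wood_pre_fence
        crop_standing_start = float(landscape.biomass.ravel()[crop_flat].sum())
        residue_start = float(landscape.residue.sum())
        acc = np.zeros(N_ACC)
        acc[A_WOOD_MIN] = wood_total

        move_wet = rng.integers(0, 4, size=(WET_STEPS, n_slots), dtype=np.int8)
        raid_u = rng.random((WET_STEPS, boundary_idx.size))
        wood_total = kernel(
            WET_STEPS, 0, side, STEPS_PER_DAY, True, True,
            kind_flat, landscape.biomass.ravel(), landscape.residue.ravel(),
            landscape.fence_intact.ravel(),
            crop_step, wood_step, boundary_idx,
            n_slots, herd.r, herd.c, herd.mass, herd.alive, herd.adult,
            herd.transported, herd.fed, herd.working,
            move_wet, raid_u,
            plan.moves_per_day, params.search_radius, plough_window_steps,
            params.eta_browse, params.eta_crop, params.eta_cow,
            params.eta_c, params.eta_a,
            params.e_maint, params.e_work, params.intake_max,
            params.forage_access_frac,
            params.m_min, params.juvenile_min_frac * params.m_birth,
            params.m_max, params.m_mature,
            params.fence_break_prob, params.feed_price,
            params.woodland_carrying_capacity,
            acc, herd.pending_intake, gval, win_rv, win_ra, win_fv, win_fr,
            qidx, wood_total)

        stored_carryover = store.total()
        harvest_kg = vegetation.harvest(landscape, store, params, plan)

        move_dry = rng.integers(0, 4, size=(DRY_STEPS, n_slots), dtype=np.int8)
        raid_dummy = np.zeros((1, boundary_idx.size))
        zero_step = np.zeros(n_patches)
        wood_total = kernel(
            DRY_STEPS, WET_STEPS, side, STEPS_PER_DAY, False, False,
            kind_flat, landscape.biomass.ravel(), landscape.residue.ravel(),
            landscape.fence_intact.ravel(),
            zero_step, zero_step, boundary_idx,
            n_slots, herd.r, herd.c, herd.mass, herd.alive, herd.adult,
            herd.transported, herd.fed, herd.working,
            move_dry, raid_dummy,
            plan.moves_per_day, params.search_radius, plough_window_steps,
            params.eta_browse, params.eta_crop, params.eta_cow,
            params.eta_c, params.eta_a,
            params.e_maint, params.e_work, params.intake_max,
            params.forage_access_frac,
            params.m_min, params.juvenile_min_frac * params.m_birth,
            params.m_max, params.m_mature,
            params.fence_break_prob, params.feed_price,
            params.woodland_carrying_capacity,
            acc, herd.pending_intake, gval, win_rv, win_ra, win_fv, win_fr,
            qidx, wood_total)

        residue_left = float(landscape.residue.sum())
        landscape.residue[:] = 0.0   # uneaten residue decays at year end
        # true end-of-year woodland stock from the arrays; the kernel's
        # incremental total must agree (guards the step bookkeeping)
        wood_end = float(landscape.biomass.ravel()[wood_flat].sum())
        if abs(wood_end - wood_total) > 1e-9 * max(wood_start + acc[A_WOOD_GROWTH], 1.0):
            raise InternalConsistencyError(
                f"incremental woodland total drifted in year {y + 1}: "
                f"{wood_total} vs {wood_end}")
        wood_total = wood_end

        consumed = store.consume(params.household_consumption)
        seed_available = harvest_kg + stored_carryover
        discarded = store.age()

        births = herd_mod.reproduce_annual(herd, params, rng)
        herd_mod.clear_subsidy(herd)
        n_cows = herd.n_alive
        cow_mass_end = float(herd.mass[herd.alive == 1].sum())

        energy_in = (acc[A_GRAZE_WOOD] * params.eta_browse
                     + (acc[A_GRAZE_RES] + acc[A_RAID]) * params.eta_crop
                     + acc[A_FEED_MJ] + acc[A_CATAB])
        energy_out = (acc[A_MAINT] + acc[A_WORK] + acc[A_ANAB]
                      + acc[A_DISCARD])
        crop_standing_end = float(landscape.biomass.ravel()[crop_flat].sum())

        rec = {
            "year": y + 1,
            "rain_mm": rain,
            "n_cows": n_cows,
            "n_adults": int(((herd.alive == 1) & (herd.adult == 1)).sum()),
            "births": births,
            "harvest_kg": harvest_kg,
            "seed_available": seed_available,
            "stored_kg": store.total(),
            "consumed_kg": consumed,
            "discarded_kg": discarded,
            "woodland_biomass": wood_total,
            "min_woodland_biomass": acc[A_WOOD_MIN],
            "crop_eaten_kg": acc[A_RAID],
            "fence_wood_used_kg": fence_wood,
            "subsidy_spend": acc[A_SPEND],
            "n_subsidized": n_subsidized,
            "ploughed_area_ha": area,
            "graze_wood_kg": acc[A_GRAZE_WOOD],
            "graze_residue_kg": acc[A_GRAZE_RES],
            "feed_kg": acc[A_FEED_KG],
            "residue_decayed_kg": residue_left,
            "cow_mass_start_kg": cow_mass_start,
            "cow_mass_end_kg": cow_mass_end,
            "cow_mass_delta_kg": acc[A_DM],
            "died_mass_kg": acc[A_DIED_MASS],
            "energy_in_mj": energy_in,
            "energy_out_mj": energy_out,
            # woodland: start + growth = end + grazed + fence wood
            "wood_ledger_lhs": wood_start + acc[A_WOOD_GROWTH],
            "wood_ledger_rhs": wood_total + acc[A_GRAZE_WOOD] + fence_wood,
            # crop: start + deposited = standing_end + raids + harvest/residue split + grazed residue rolled up
            "crop_ledger_lhs": crop_standing_start + residue_start
            + acc[A_CROP_GROWTH],
            "crop_ledger_rhs": crop_standing_end + acc[A_RAID]
            + harvest_kg + acc[A_GRAZE_RES] + residue_left,
        }
        if check_ledgers:
            _check_ledgers(rec)
        yearly.append(rec)

        ok, fy = evaluate_sustainability([rec], min_cows, min_seed, min_wood)
        if not ok and sustainable:
            sustainable = False
            failure_year = rec["year"]
            if not run_to_completion:
                break

    return RunResult(yearly=yearly, sustainable=sustainable,
                     failure_year=failure_year, inputs=inputs)
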