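import numpy as np
import pytest

from agropast.config import ManagementPlan, ModelParameters
from agropast.herd import Herd
from agropast.landscape import CROP, Landscape
from agropast.vegetation import (GrainStore, annual_woodland_increment,
                                 fence_segment_lengths_km, grow_crops,
                                 grow_woodland, harvest, maintain_fences,
                                 raid_crops)

RNG = np.random.default_rng


def make_landscape(kind):
    return Landscape(kind=np.asarray(kind, dtype=np.int8))


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def plan():
    return ManagementPlan()


# -- grain store --------------------------------------------------------------

def test_store_fifo_draws_oldest_vintage_first():
    store = GrainStore(capacity_years=3)
    store.deposit(1000.0)         # year 1 bumper
    assert store.age() == 0.0
    store.deposit(0.0)            # year 2: nothing harvested
    drawn = store.consume(300.0)
    assert drawn == 300.0
    assert store.vintages == {1: 700.0}   # drawn from the year-1 vintage


def test_store_zero_capacity_always_empty_after_aging():
    store = GrainStore(capacity_years=0)
    store.deposit(500.0)
    store.consume(200.0)
    discarded = store.age()
    assert discarded == 300.0
    assert store.total() == 0.0


def test_store_mass_conservation_over_random_ledger(rng):
    store = GrainStore(capacity_years=2)
    deposited = consumed = discarded = 0.0
    for _ in range(200):
        h = float(rng.uniform(0, 100))
        store.deposit(h)
        deposited += h
        consumed += store.consume(float(rng.uniform(0, 80)))
        discarded += store.age()
    assert deposited == pytest.approx(consumed + discarded + store.total(),
                                      rel=1e-12)


def test_store_rejects_negative_amounts():
    store = GrainStore()
    with pytest.raises(ValueError):
        store.deposit(-1.0)
    with pytest.raises(ValueError):
        store.consume(-1.0)


# -- growth -------------------------------------------------------------------

def test_crop_growth_linear_in_rain_and_zero_without(params, plan):
    kind = np.zeros((4, 4), dtype=np.int8)
    kind[0, :] = CROP
    ls0 = make_landscape(kind)
    assert grow_crops(ls0, 0.0, params, plan).sum() == 0.0

    ls1, ls2 = make_landscape(kind), make_landscape(kind)
    inc1 = grow_crops(ls1, 300.0, params, plan)
    inc2 = grow_crops(ls2, 600.0, params, plan)
    assert inc2.sum() == pytest.approx(2 * inc1.sum(), rel=1e-12)
    # only crop patches grow
    assert (inc1[kind == 0] == 0).all()
    per_patch = params.crop_growth_rate * 300.0 * ls1.patch_area
    assert inc1[0, 0] == pytest.approx(per_patch)


def test_enhanced_crop_patches_grow_by_boost(params, plan):
    kind = np.zeros((2, 2), dtype=np.int8)
    kind[0, :] = CROP
    ls = make_landscape(kind)
    ls.enhanced[0, 1] = True
    inc = grow_crops(ls, 500.0, params, plan)
    assert inc[0, 1] == pytest.approx(plan.crop_boost * inc[0, 0])


def test_unploughed_crop_patches_produce_nothing(params, plan):
    kind = np.zeros((2, 2), dtype=np.int8)
    kind[0, :] = CROP
    ls = make_landscape(kind)
    ploughed = np.zeros((2, 2), dtype=bool)
    ploughed[0, 0] = True
    inc = grow_crops(ls, 500.0, params, plan, ploughed=ploughed)
    assert inc[0, 0] > 0 and inc[0, 1] == 0.0


def test_woodland_growth_logistic_ceiling_and_reference_identity(params, plan):
    ls = make_landscape(np.zeros((3, 3), dtype=np.int8))
    ls.biomass[:] = params.woodland_carrying_capacity
    assert grow_woodland(ls, params.reference_rainfall, params, plan).sum() == 0.0

    empty = make_landscape(np.zeros((3, 3), dtype=np.int8))
    inc = annual_woodland_increment(empty, params.reference_rainfall, params, plan)
    assert inc[0, 0] == pytest.approx(params.g_wood * empty.patch_area)


def test_woodland_growth_monotone_in_rain(params, plan):
    gains = []
    for rain in (0.0, 100.0, 300.0, 550.0, 900.0):
        ls = make_landscape(np.zeros((3, 3), dtype=np.int8))
        ls.biomass[:] = 0.4 * params.woodland_carrying_capacity
        gains.append(annual_woodland_increment(ls, rain, params, plan).sum())
    assert all(a <= b for a, b in zip(gains, gains[1:]))
    assert gains[0] == 0.0


def test_woodland_growth_never_exceeds_capacity(params, plan):
    ls = make_landscape(np.zeros((3, 3), dtype=np.int8))
    ls.biomass[:] = 0.999 * params.woodland_carrying_capacity
    grow_woodland(ls, 5 * params.reference_rainfall, params, plan)
    assert (ls.biomass <= params.woodland_carrying_capacity + 1e-9).all()


# -- harvest ------------------------------------------------------------------

def test_harvest_splits_grain_and_residue(params, plan):
    kind = np.zeros((2, 2), dtype=np.int8)
    kind[0, :] = CROP
    ls = make_landscape(kind)
    ls.biomass[0, 0] = 100.0
    ls.biomass[0, 1] = 60.0
    store = GrainStore(capacity_years=1)
    grain = harvest(ls, store, params, plan)
    assert grain == pytest.approx(160.0 * params.grain_fraction)
    assert store.total() == pytest.approx(grain)
    assert ls.residue[0].sum() == pytest.approx(160.0 * (1 - params.grain_fraction))
    assert (ls.biomass[ls.crop_mask()] == 0).all()


# -- fencing ------------------------------------------------------------------

def test_stone_walls_never_decay_and_use_no_wood(params):
    kind = np.zeros((3, 3), dtype=np.int8)
    kind[1, 1] = CROP
    ls = make_landscape(kind)
    ls.fence_intact[1, 1] = False
    plan = ManagementPlan(stone_walls=True)
    used = maintain_fences(ls, params, plan, RNG(0))
    assert used == 0.0
    assert ls.fence_intact.all()


def test_denuded_woodland_blocks_fence_repair(params, plan):
    kind = np.zeros((3, 3), dtype=np.int8)
    kind[1, 1] = CROP
    ls = make_landscape(kind)
    ls.biomass[:] = 0.0   # woodland completely denuded
    p = ModelParameters(fence_decay_prob=1.0)
    used = maintain_fences(ls, p, plan, RNG(0))
    assert used == 0.0
    assert not ls.fence_intact[1, 1]


def test_fence_repair_wood_ledger_hand_bookkeeping(plan):
    # single interior crop patch: 4 exposed edges of ~48.99 m each
    kind = np.zeros((3, 3), dtype=np.int8)
    kind[1, 1] = CROP
    ls = make_landscape(kind)
    ls.biomass[ls.kind == 0] = 1000.0
    p = ModelParameters(fence_decay_prob=1.0)
    lengths = fence_segment_lengths_km(ls)
    assert lengths[1, 1] == pytest.approx(4 * np.sqrt(2400.0) / 1000.0)
    before = ls.biomass.sum()
    used = maintain_fences(ls, p, plan, RNG(0))
    assert used == pytest.approx(p.fence_cost * lengths[1, 1])
    assert before - ls.biomass.sum() == pytest.approx(used)
    assert ls.fence_intact[1, 1]


# -- raids --------------------------------------------------------------------

def _herd_at(r, c, mass, params):
    herd = Herd.empty(1)
    herd.alive[:] = 1
    herd.adult[:] = 1
    herd.mass[:] = mass
    herd.r[:] = r
    herd.c[:] = c
    return herd


def test_no_raids_through_intact_fences(params):
    kind = np.zeros((3, 3), dtype=np.int8)
    kind[1, 1] = CROP
    ls = make_landscape(kind)
    ls.biomass[1, 1] = 500.0
    herd = _herd_at(1, 1, params.m_mature, params)
    p = ModelParameters(fence_break_prob=1.0)
    assert raid_crops(ls, herd, p, RNG(0)) == 0.0


def test_raid_eats_up_to_intake_cap_and_conserves_mass(params):
    kind = np.zeros((3, 3), dtype=np.int8)
    kind[1, 1] = CROP
    ls = make_landscape(kind)
    ls.fence_intact[1, 1] = False
    ls.biomass[1, 1] = 500.0
    herd = _herd_at(1, 2, params.m_mature, params)  # adjacent cow
    p = ModelParameters(fence_break_prob=1.0)
    before = ls.biomass[1, 1]
    eaten = raid_crops(ls, herd, p, RNG(0))
    assert eaten == pytest.approx(p.intake_max)  # s = 1 at m_mature
    assert before - ls.biomass[1, 1] == pytest.approx(eaten)
    assert herd.pending_intake[0] == pytest.approx(eaten)

    # small field: the raid empties it exactly
    ls.biomass[1, 1] = 1.0
    herd.pending_intake[:] = 0.0
    eaten = raid_crops(ls, herd, p, RNG(1))
    assert eaten == pytest.approx(1.0)
    assert ls.biomass[1, 1] == 0.0


def test_raid_requires_nearby_cow(params):
    kind = np.zeros((5, 5), dtype=np.int8)
    kind[2, 2] = CROP
    ls = make_landscape(kind)
    ls.fence_intact[2, 2] = False
    ls.biomass[2, 2] = 500.0
    herd = _herd_at(0, 0, params.m_mature, params)  # far away
    p = ModelParameters(fence_break_prob=1.0)
    assert raid_crops(ls, herd, p, RNG(0)) == 0.0
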