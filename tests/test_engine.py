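import dataclasses

import numpy as np
import pytest

from _kernel_driver import kernel_steps
from agropast import _kernel
from agropast.config import ManagementPlan, ModelParameters
from agropast.engine import (InternalConsistencyError, evaluate_sustainability,
                             resolve_thresholds, run_simulation)
from agropast.herd import Herd
from agropast.landscape import Landscape
from agropast.rainfall import generate_rainfall

RNG = np.random.default_rng


def small(**over):
    """A 96-ha (20x20) village with area-scaled household consumption."""
    base = dict(village_area=96.0, household_consumption=9600.0)
    base.update(over)
    return ModelParameters(**base)


def tiny(**over):
    """A 34.56-ha (12x12) village for the slowest (pure-Python) checks."""
    base = dict(village_area=12 * 12 * 0.24, household_consumption=3456.0)
    base.update(over)
    return ModelParameters(**base)


# -- evaluate_sustainability ---------------------------------------------------

def year_rec(year, cows=10, seed=100.0, wood=1e6):
    return {"year": year, "n_cows": cows, "seed_available": seed,
            "woodland_biomass": wood}


def test_zero_thresholds_are_always_sustainable():
    yearly = [year_rec(y, cows=0, seed=0.0, wood=0.0) for y in range(1, 61)]
    assert evaluate_sustainability(yearly, 0, 0, 0) == (True, None)


def test_first_breach_year_is_reported():
    yearly = [year_rec(y) for y in range(1, 61)]
    yearly[16]["n_cows"] = 1   # year 17 dips below the 2-cow minimum
    assert evaluate_sustainability(yearly, 2, 50.0, 1000.0) == (False, 17)


def test_compliant_series_is_sustainable():
    yearly = [year_rec(y) for y in range(1, 61)]
    assert evaluate_sustainability(yearly, 2, 50.0, 1000.0) == (True, None)


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        evaluate_sustainability([], 0, 0, 0)


def test_threshold_resolution_defaults_and_overrides():
    p = ModelParameters()
    min_cows, min_seed, min_wood = resolve_thresholds(p, 100.0, 1e6)
    assert min_cows == p.min_cows_thresh
    assert min_seed == p.seed_per_ha * 100.0
    assert min_wood == p.min_wood_frac * 1e6
    p2 = ModelParameters(min_seed_thresh=77.0, min_wood_thresh=5.0)
    assert resolve_thresholds(p2, 100.0, 1e6)[1:] == (77.0, 5.0)


# -- full runs -----------------------------------------------------------------

def test_benign_regime_runs_all_60_years(historical):
    series = generate_rainfall("constant", historical)
    res = run_simulation(small(), ManagementPlan(), series, seed=3)
    assert res.sustainable and res.failure_year is None
    assert len(res.yearly) == 60


def test_unreachable_cow_minimum_fails_in_year_one(historical):
    series = generate_rainfall("constant", historical)
    res = run_simulation(small(min_cows_thresh=10_000), ManagementPlan(),
                         series, seed=3)
    assert not res.sustainable
    assert res.failure_year == 1
    assert len(res.yearly) == 1      # early halt


def test_run_to_completion_flag_keeps_going(historical):
    series = generate_rainfall("statistical-extreme", historical, rng=RNG(5))
    res = run_simulation(small(), ManagementPlan(), series, seed=3,
                         run_to_completion=True)
    assert len(res.yearly) == 60
    assert (not res.sustainable) == (res.failure_year is not None)


def test_runs_are_bit_identical_under_a_seed(historical):
    series = generate_rainfall("historical", historical, n_years=6)
    plan = ManagementPlan(storage_years=3, moves_per_day=1,
                          subsidy_mode="feed", subsidy_fraction=0.7)
    a = run_simulation(small(), plan, series, seed=11)
    b = run_simulation(small(), plan, series, seed=11)
    assert a.to_json() == b.to_json()
    c = run_simulation(small(), plan, series, seed=12)
    assert c.to_json() != a.to_json()


def test_jit_and_pure_python_paths_agree_bitwise(historical):
    series = generate_rainfall("historical", historical, n_years=3)
    plan = ManagementPlan(storage_years=2, moves_per_day=1,
                          subsidy_mode="transport", subsidy_fraction=0.7)
    fast = run_simulation(tiny(), plan, series, seed=5, use_jit=True)
    slow = run_simulation(tiny(), plan, series, seed=5, use_jit=False)
    assert fast.to_json() == slow.to_json()


def test_without_cows_no_harvest_and_woodland_reaches_capacity():
    """The plough feedback: no cows, no crops, whatever the rain."""
    p = small(init_stocking_rate=0.0)
    series = generate_rainfall("constant", [p.reference_rainfall] * 2)
    # stone walls so fence repair draws no woodland biomass
    res = run_simulation(p, ManagementPlan(stone_walls=True), series, seed=1,
                         run_to_completion=True)
    df = res.to_dataframe()
    assert (df["harvest_kg"] == 0).all()
    assert (df["n_cows"] == 0).all()
    n_wood = 400 - round(400 * 0.48)
    capacity = n_wood * p.woodland_carrying_capacity
    assert df["woodland_biomass"].iloc[-1] == pytest.approx(capacity, rel=1e-6)


def test_transport_subsidy_removes_grazing_in_trigger_years(historical):
    p = small()
    plan = ManagementPlan(subsidy_mode="transport", subsidy_fraction=1.0,
                          low_rainfall_trigger=1e9)  # always triggers
    series = generate_rainfall("constant", historical, n_years=2)
    res = run_simulation(p, plan, series, seed=2, run_to_completion=True)
    df = res.to_dataframe()
    assert (df["graze_wood_kg"] == 0).all()
    assert (df["harvest_kg"] == 0).all()     # nobody left to plough
    assert (df["n_subsidized"] > 0).all()


def test_yearly_ledgers_close(historical):
    """Energy and biomass ledgers close to 1e-9 relative every year."""
    series = generate_rainfall("historical", historical, n_years=8)
    plan = ManagementPlan(storage_years=3, moves_per_day=1)
    res = run_simulation(small(), plan, series, seed=9, check_ledgers=False,
                         run_to_completion=True)
    for rec in res.yearly:
        for lhs_key, rhs_key in (("energy_in_mj", "energy_out_mj"),
                                 ("wood_ledger_lhs", "wood_ledger_rhs"),
                                 ("crop_ledger_lhs", "crop_ledger_rhs")):
            lhs, rhs = rec[lhs_key], rec[rhs_key]
            assert abs(lhs - rhs) <= 1e-9 * max(abs(lhs), abs(rhs), 1.0)
        # herd mass ledger
        lhs = rec["cow_mass_end_kg"]
        rhs = (rec["cow_mass_start_kg"] + rec["cow_mass_delta_kg"]
               + rec["births"] * res.inputs["parameters"]["m_birth"]
               - rec["died_mass_kg"])
        assert abs(lhs - rhs) <= 1e-9 * max(abs(lhs), abs(rhs), 1.0)


def test_kernel_min_woodland_matches_stepwise_oracle():
    """One 50-step kernel call reports the same running woodland minimum
    as 50 single-step calls scanning the total after every step."""
    params = ModelParameters()
    kind = np.zeros((8, 8), dtype=np.int8)
    kind[:, :3] = 1
    rng = RNG(3)

    def fresh():
        ls = Landscape(kind=kind.copy())
        ls.biomass[kind == 0] = rng_init
        herd = Herd.empty(6)
        herd.alive[:] = 1
        herd.adult[:] = 1
        herd.mass[:] = 300.0
        herd.r[:] = 4
        herd.c[:] = np.arange(6) % 8
        return ls, herd

    rng_init = 50.0
    dirs = RNG(3).integers(0, 4, size=(50, 6), dtype=np.int8)
    ls_a, herd_a = fresh()
    acc_a, _ = kernel_steps(ls_a, herd_a, params, n_steps=50, move_dirs=dirs)

    ls_b, herd_b = fresh()
    mins = []
    for t in range(50):
        kernel_steps(ls_b, herd_b, params, n_steps=1, step_offset=t,
                     move_dirs=dirs[t:t + 1])
        mins.append(ls_b.biomass[ls_b.kind == 0].sum())
    assert acc_a[_kernel.A_WOOD_MIN] == pytest.approx(min(mins), rel=1e-12)
    assert np.array_equal(herd_a.mass, herd_b.mass)


def test_internal_consistency_error_is_loud(historical, monkeypatch):
    """A corrupted ledger raises instead of passing silently."""
    from agropast import engine as engine_mod
    series = generate_rainfall("constant", historical, n_years=1)

    original = engine_mod._check_ledgers

    def corrupt(rec, tol=1e-9):
        rec = dict(rec)
        rec["energy_in_mj"] += 1.0
        original(rec, tol)

    monkeypatch.setattr(engine_mod, "_check_ledgers", corrupt)
    with pytest.raises(InternalConsistencyError):
        run_simulation(small(), ManagementPlan(), series, seed=1)
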