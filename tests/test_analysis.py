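import numpy as np
import pandas as pd
import pytest

from agropast.analysis import (DegenerateFitError, adjust_fdr,
                               binned_sustainability, fit_sensitivity_model,
                               percent_difference, transform_to_probability,
                               validation_subset)

RNG = np.random.default_rng


def brute_force_bh(p):
    """Independent Benjamini-Hochberg step-up oracle."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# -- probability-scale transform ----------------------------------------------

def test_transform_symmetry_and_identity():
    assert transform_to_probability(0.0, 0.0) == pytest.approx(50.0)
    assert transform_to_probability(-1.0) + transform_to_probability(1.0) \
        == pytest.approx(100.0)


def test_transform_known_logit_values():
    assert transform_to_probability(-1.67) == pytest.approx(15.8, abs=0.2)
    assert transform_to_probability(-1.67, 4.49) == pytest.approx(94.4, abs=0.2)


def test_transform_rejects_nonfinite():
    with pytest.raises(ValueError):
        transform_to_probability(float("nan"))


# -- FDR ----------------------------------------------------------------------

def test_fdr_single_p_unchanged():
    assert adjust_fdr([0.37])[0] == pytest.approx(0.37)


def test_fdr_hand_computed_case():
    adj = adjust_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_fdr_ties_stay_equal():
    adj = adjust_fdr([0.2, 0.2, 0.2])
    assert np.allclose(adj, adj[0])
    assert adj[0] == pytest.approx(0.2)


def test_fdr_matches_brute_force_oracle_on_random_vectors():
    rng = RNG(0)
    for _ in range(1000):
        p = rng.random(int(rng.integers(1, 20)))
        adj = adjust_fdr(p)
        assert np.allclose(adj, brute_force_bh(p), atol=1e-12)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()


def test_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        adjust_fdr([])


# -- sensitivity GAM ----------------------------------------------------------

def simulate_logistic_table(n, rng, b0=-0.5, b_scen=-2.0, b_store=1.5,
                            b_a=0.8, b_b=0.0):
    scenario = rng.choice(["constant", "statistical-extreme"], size=n)
    storage = rng.choice([0, 3], size=n)
    da = rng.normal(0.0, 1.0, size=n)
    db = rng.normal(0.0, 1.0, size=n)
    logit = (b0 + b_scen * (scenario == "statistical-extreme")
             + b_store * (storage == 3) + b_a * da + b_b * db)
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame({
        "sustainable": y.astype(int), "scenario": scenario,
        "storage_years": storage, "delta_a": da, "delta_b": db,
    })


def test_gam_recovers_known_logistic_coefficients():
    rng = RNG(42)
    df = simulate_logistic_table(4000, rng)
    fit = fit_sensitivity_model(
        df, smooth_columns=(),
        intervention_factors={"storage_years": 0},
        delta_columns=["delta_a", "delta_b"])
    truths = {
        "C(scenario, Treatment(reference='constant'))[T.statistical-extreme]": -2.0,
        "C(storage_years, Treatment(reference=0))[T.3]": 1.5,
        "standardize(delta_a)": 0.8,
        "standardize(delta_b)": 0.0,
        "Intercept": -0.5,
    }
    for term, truth in truths.items():
        est = fit.table.loc[term, "estimate"]
        se = fit.table.loc[term, "se"]
        assert abs(est - truth) < 2 * se, term


def test_null_predictor_is_calibrated():
    """A predictor independent of the outcome is within 2 SE ~95% of fits."""
    rng = RNG(7)
    inside = 0
    n_fits = 40
    for _ in range(n_fits):
        df = simulate_logistic_table(600, rng)
        fit = fit_sensitivity_model(
            df, smooth_columns=(), intervention_factors={},
            scenario_column="none", delta_columns=["delta_b"])
        est = fit.table.loc["standardize(delta_b)", "estimate"]
        se = fit.table.loc["standardize(delta_b)", "se"]
        inside += abs(est) < 2 * se
    assert inside >= 0.9 * n_fits


def test_base_case_probability_equals_inverse_logit_intercept():
    rng = RNG(3)
    df = simulate_logistic_table(2000, rng)
    fit = fit_sensitivity_model(
        df, smooth_columns=(), intervention_factors={"storage_years": 0},
        delta_columns=["delta_a"])
    assert fit.transformed_probability() == pytest.approx(
        transform_to_probability(fit.intercept))
    # fdr-adjusted p never below raw p
    tab = fit.table.drop(index="Intercept")
    assert (tab["p_fdr"] >= tab["p"] - 1e-12).all()


def test_single_outcome_data_is_degenerate():
    df = pd.DataFrame({"sustainable": [1] * 50, "scenario": ["constant"] * 50,
                       "delta_a": np.linspace(-1, 1, 50)})
    with pytest.raises(DegenerateFitError):
        fit_sensitivity_model(df, smooth_columns=(), intervention_factors={},
                              delta_columns=["delta_a"])


def test_perfect_separation_is_degenerate():
    df = pd.DataFrame({
        "sustainable": [0] * 25 + [1] * 25,
        "delta_a": np.r_[np.linspace(-2, -1, 25), np.linspace(1, 2, 25)],
    })
    with pytest.raises(DegenerateFitError):
        fit_sensitivity_model(df, smooth_columns=(), intervention_factors={},
                              scenario_column="none",
                              delta_columns=["delta_a"])


# -- binned graphical analysis ------------------------------------------------

def test_binned_toy_table_hand_computed():
    df = pd.DataFrame({
        "proportion_crops": np.r_[np.linspace(0.1, 0.45, 10),
                                  np.linspace(0.55, 0.9, 10)],
        "sustainable": [1] * 8 + [0] * 2 + [0] * 9 + [1] * 1,
    })
    table = binned_sustainability(df, "proportion_crops", n_bins=2)
    assert len(table) == 2
    assert table["n_runs"].tolist() == [10, 10]
    assert table["prop_sustainable"].tolist() == [0.8, 0.1]
    assert table["n_runs"].sum() == len(df)


def test_binned_all_sustainable_and_empty_bins():
    df = pd.DataFrame({"x": [0.0, 0.1, 0.9, 1.0], "sustainable": 1})
    table = binned_sustainability(df, "x", n_bins=5)
    nonempty = table[~table["empty"]]
    assert (nonempty["prop_sustainable"] == 1.0).all()
    assert table["empty"].sum() == 3         # middle bins have no runs
    assert len(table) == 5                   # flagged, not dropped


def test_binned_stratification_partitions_rows():
    rng = RNG(1)
    df = pd.DataFrame({
        "x": rng.random(60),
        "sustainable": rng.integers(0, 2, 60),
        "scenario": np.repeat(["a", "b", "c"], 20),
    })
    table = binned_sustainability(df, "x", n_bins=4, strata=["scenario"])
    assert table.groupby("scenario")["n_runs"].sum().tolist() == [20, 20, 20]


def test_binned_rejects_non_numeric():
    df = pd.DataFrame({"x": list("abcd"), "sustainable": [0, 1, 0, 1]})
    with pytest.raises(ValueError):
        binned_sustainability(df, "x", 2)


# -- behavioral validation ----------------------------------------------------

def test_percent_difference_identical_samples():
    assert percent_difference([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)


def test_percent_difference_hand_case():
    d_mean, d_sd = percent_difference([2, 4], [1, 3])
    assert d_mean == pytest.approx(50.0)
    assert d_sd == pytest.approx(0.0)


def test_percent_difference_scaling_linearity():
    field = np.array([3.0, 5.0, 9.0, 11.0])
    d_mean, d_sd = percent_difference(1.1 * field, field)
    assert d_mean == pytest.approx(10.0)
    assert d_sd == pytest.approx(10.0)


def test_percent_difference_undefined_cases():
    with pytest.raises(ValueError):
        percent_difference([1, 2], [-1, 1])        # zero field mean
    with pytest.raises(ValueError):
        percent_difference([1, 2], [5, 5])         # zero field SD
    with pytest.raises(ValueError):
        percent_difference([1], [1, 2])


def test_validation_subset_filters_historical_management():
    df = pd.DataFrame({
        "scenario": ["historical", "historical", "random", "historical"],
        "years_run": [60, 10, 60, 60],
        "storage_years": [3, 3, 3, 0],
        "moves_per_day": [1, 1, 1, 1],
        "stone_walls": [False, False, False, False],
        "subsidy_mode": ["none"] * 4,
        "enhanced_crop_frac": [0.0] * 4,
        "enhanced_wood_frac": [0.0] * 4,
    })
    sub = validation_subset(df)
    assert sub.index.tolist() == [0]
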