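"""Sensitivity analysis and behavioral-validation statistics.

Whether a run was sustainable is a binary outcome, so the sensitivity of
the model to its inputs is summarized with a binomial (logit-link)
additive model over the sweep table: scaled, centered linear terms for the
small multiplicative perturbations of each underlying parameter (a local
linear approximation is appropriate at +/-5-10%), cubic B-spline smooths
for the two wide-ranging continuous inputs (proportion of crops and
Moran's I), and categorical factors for the rainfall scenario (reference:
constant) and each management intervention (reference: off).  p-values are
Benjamini-Hochberg FDR-adjusted; estimates are reported both on the logit
scale and transformed to the probability scale
(``100 / (1 + exp(-(intercept + estimate)))``).

A complementary graphical analysis bins runs into equal divisions of a
continuous variable and plots the within-bin proportion of sustainable
runs per stratum; and model outputs are compared against field data with
the percent-difference-in-mean-and-SD statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .reference import REFERENCE_ESTIMATES

__all__ = [
    "SensitivityFit",
    "DegenerateFitError",
    "fit_sensitivity_model",
    "transform_to_probability",
    "adjust_fdr",
    "binned_sustainability",
    "percent_difference",
    "validation_subset",
    "reference_transformed_probabilities",
]


class DegenerateFitError(RuntimeError):
    """The sensitivity model cannot be fitted (single outcome, separation)."""


@dataclass
class SensitivityFit:
    """A fitted binomial additive sensitivity model.

    ``table`` has one row per model term: estimate, standard error, raw and
    FDR-adjusted p-value, and (for non-spline terms) the probability-scale
    transform of intercept + estimate.
    """

    intercept: float
    table: pd.DataFrame
    smooth_terms: dict[str, pd.DataFrame]
    formula: str
    results: object = field(repr=False, default=None)

    def transformed_probability(self, term: str | None = None) -> float:
        """Percent probability of a sustainable run at intercept (+ term)."""
        est = 0.0 if term is None else float(self.table.loc[term, "estimate"])
        return transform_to_probability(self.intercept, est)


def transform_to_probability(intercept: float, estimate: float = 0.0) -> float:
    """Inverse-logit of (intercept + estimate), as a percent.

    ``transform_to_probability(-1.67)`` is the base-case probability of a
    run meeting all minima for 60 years; adding a term's logit-scale
    estimate gives the probability with that intervention (or with a
    one-unit change of that scaled predictor).
    """
    if not (np.isfinite(intercept) and np.isfinite(estimate)):
        raise ValueError("intercept and estimate must be finite")
    return float(100.0 / (1.0 + np.exp(-(intercept + estimate))))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _factor_term(name: str, reference) -> str:
    if isinstance(reference, str):
        return f"C({name}, Treatment(reference='{reference}'))"
    return f"C({name}, Treatment(reference={reference}))"


def fit_sensitivity_model(
    results: pd.DataFrame,
    outcome: str = "sustainable",
    scenario_column: str = "scenario",
    scenario_reference: str = "constant",
    intervention_factors: dict | None = None,
    smooth_columns: tuple = ("proportion_crops", "morans_i"),
    smooth_df: int = 6,
    delta_columns: list[str] | None = None,
) -> SensitivityFit:
    """Fit the binomial sensitivity GAM to a sweep results table.

    ``intervention_factors`` maps plan columns to their reference ("off")
    level; by default every standard intervention column present in the
    table is included.  ``delta_columns`` are the recorded perturbation
    deltas (default: every ``delta_*`` column with any variation), entered
    as scaled, centered linear terms.
    """
    df = results
    if outcome not in df:
        raise ValueError(f"results table lacks outcome column '{outcome}'")
    if "status" in df:
        df = df[df["status"] == "ok"]
    y = df[outcome]
    if y.nunique() < 2:
        raise DegenerateFitError(
            "all runs share one outcome; the binomial model is degenerate")

    terms = []
    if scenario_column in df and df[scenario_column].nunique() > 1:
        terms.append(_factor_term(scenario_column, scenario_reference))
    if intervention_factors is None:
        intervention_factors = {}
        for col, ref in (("storage_years", 0), ("moves_per_day", 0),
                         ("stone_walls", False), ("subsidy_mode", "none")):
            if col in df and df[col].nunique() > 1:
                intervention_factors[col] = ref
    for col, ref in intervention_factors.items():
        terms.append(_factor_term(col, ref))
    for col in smooth_columns:
        if col in df and df[col].nunique() > smooth_df:
            terms.append(f"bs({col}, df={smooth_df})")
    if delta_columns is None:
        delta_columns = [c for c in df.columns
                         if c.startswith("delta_") and df[c].nunique() > 1]
    for col in delta_columns:
        terms.append(f"standardize({col})")
    if not terms:
        raise DegenerateFitError("no usable predictors in results table")

    formula = f"{outcome} ~ " + " + ".join(terms)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            model = sm.GLM.from_formula(formula, data=df,
                                        family=sm.families.Binomial())
            fit = model.fit(maxiter=200)
    except PerfectSeparationWarning as exc:
        raise DegenerateFitError(
            "perfect separation: the predictors fully determine the "
            "outcome (too few runs for this many terms)") from exc
    except Exception as exc:
        raise DegenerateFitError(f"sensitivity model failed to fit: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise DegenerateFitError(
            "non-finite standard errors (possible perfect separation)")

    params = fit.params
    bse = fit.bse
    pvals = fit.pvalues
    intercept = float(params["Intercept"])

    names = [n for n in params.index if n != "Intercept"]
    is_smooth = {n: n.startswith("bs(") for n in names}
    linear_names = [n for n in names if not is_smooth[n]]
    adj = pd.Series(adjust_fdr(pvals[names].to_numpy()), index=names)

    table = pd.DataFrame({
        "estimate": params[names],
        "se": bse[names],
        "p": pvals[names],
        "p_fdr": adj,
    })
    table["transformed_probability_pct"] = [
        transform_to_probability(intercept, table.loc[n, "estimate"])
        if not is_smooth[n] else np.nan
        for n in names
    ]
    table.loc["Intercept"] = [intercept, float(bse["Intercept"]),
                              float(pvals["Intercept"]), np.nan,
                              transform_to_probability(intercept)]

    smooth_terms = {}
    for col in smooth_columns:
        rows = [n for n in names if n.startswith(f"bs({col}")]
        if rows:
            smooth_terms[col] = table.loc[rows, ["estimate", "se", "p"]]

    return SensitivityFit(intercept=intercept, table=table,
                          smooth_terms=smooth_terms, formula=formula,
                          results=fit)


def binned_sustainability(
    results: pd.DataFrame,
    variable: str,
    n_bins: int = 10,
    strata: list[str] | None = None,
    outcome: str = "sustainable",
) -> pd.DataFrame:
    """Proportion of sustainable runs in equal-width bins of a variable.

    Bins divide the variable's observed range across the whole table (so
    strata share an axis); within each stratum x bin the sustainable
    proportion and run count are reported.  Empty bins are flagged with
    ``empty=True`` and NaN proportion rather than dropped.
    """
    if variable not in results:
        raise ValueError(f"no column '{variable}' in results")
    if not pd.api.types.is_numeric_dtype(results[variable]):
        raise ValueError(f"column '{variable}' is not numeric")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    df = results
    if "status" in df:
        df = df[df["status"] == "ok"]
    lo = float(df[variable].min())
    hi = float(df[variable].max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, df[variable].to_numpy(),
                                  side="right") - 1, 0, n_bins - 1)
    df = df.assign(_bin=idx)

    groups = ([(None, df)] if not strata
              else list(df.groupby(strata, observed=True, sort=True)))
    rows = []
    for key, g in groups:
        counts = np.bincount(g["_bin"], minlength=n_bins)
        sus = np.bincount(g["_bin"], weights=g[outcome], minlength=n_bins)
        for b in range(n_bins):
            row = {}
            if strata:
                key_t = key if isinstance(key, tuple) else (key,)
                row.update(dict(zip(strata, key_t)))
            row.update({
                "bin": b,
                "bin_center": centers[b],
                "n_runs": int(counts[b]),
                "prop_sustainable": (sus[b] / counts[b]) if counts[b] else np.nan,
                "empty": counts[b] == 0,
            })
            rows.append(row)
    return pd.DataFrame(rows)


def percent_difference(model_sample, field_sample) -> tuple[float, float]:
    """Percent difference in mean and SD between model and field samples.

    ``100 * |mean(model) - mean(field)| / mean(field)`` and likewise for
    the sample standard deviation (n-1 denominator).
    """
    model = np.asarray(model_sample, dtype=np.float64)
    obs = np.asarray(field_sample, dtype=np.float64)
    if model.size < 2 or obs.size < 2:
        raise ValueError("both samples need at least 2 values")
    if obs.mean() == 0:
        raise ValueError("field mean is zero: percent difference undefined")
    if obs.std(ddof=1) == 0:
        raise ValueError("field SD is zero: percent difference undefined")
    d_mean = 100.0 * abs(model.mean() - obs.mean()) / abs(obs.mean())
    d_sd = 100.0 * abs(model.std(ddof=1) - obs.std(ddof=1)) / obs.std(ddof=1)
    return float(d_mean), float(d_sd)


#: default flags approximating the historically practised management:
#: traditional grain storage and daily herding moves, brush fences, no
#: subsidies, no growth-enhancement projects
DEFAULT_HISTORICAL_MANAGEMENT = {
    "storage_years": 3,
    "moves_per_day": 1,
    "stone_walls": False,
    "subsidy_mode": "none",
    "enhanced_crop_frac": 0.0,
    "enhanced_wood_frac": 0.0,
}


def validation_subset(
    results: pd.DataFrame,
    management: dict | None = None,
    require_completed: bool = True,
    n_years: int = 60,
) -> pd.DataFrame:
    """Select runs comparable to the historical system for validation.

    Keeps runs under the ``historical`` rainfall scenario that completed
    all ``n_years`` model years and match the historical-management flags
    (configurable via ``management``).
    """
    if management is None:
        management = DEFAULT_HISTORICAL_MANAGEMENT
    df = results
    if "status" in df:
        df = df[df["status"] == "ok"]
    df = df[df["scenario"] == "historical"]
    if require_completed and "years_run" in df:
        df = df[df["years_run"] >= n_years]
    for col, value in management.items():
        if col in df:
            df = df[df[col] == value]
    return df


def reference_transformed_probabilities() -> dict[str, float]:
    """Probability-scale (percent) transforms of the reference estimates.

    Applies ``transform_to_probability`` to the full-scale sensitivity
    estimates shipped in :mod:`agropast.reference`: the intercept alone for
    the base case, intercept + estimate for every other term.
    """
    intercept = REFERENCE_ESTIMATES["intercept"]
    out = {"intercept": transform_to_probability(intercept)}
    for name, est in REFERENCE_ESTIMATES.items():
        if name != "intercept":
            out[name] = transform_to_probability(intercept, est)
    return out
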