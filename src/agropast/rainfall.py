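"""Annual rainfall series: six scenarios plus a synthetic historical generator.

Simulations run for 60 years, the length of the historical annual-rainfall
record the model was built around.  Six scenarios are supported:

baselines
    ``constant``     every year equals the historical mean;
    ``historical``   the record verbatim (cycled/truncated to 60 years);
    ``random``       i.i.d. resampling with replacement (nonparametric bootstrap);
    ``statistical``  i.i.d. draws from a gamma distribution fitted to the
                     record by the method of moments (parametric bootstrap);

extremes (climate-change analogues)
    ``random-extreme`` / ``statistical-extreme``
        the same two bootstrap mechanisms with year-to-year deviations from
        the historical mean inflated so the generating standard deviation is
        ``sd_multiplier`` (default 1.5, following downscaled climate
        projections for southern Africa) times the historical SD; negative
        draws are truncated at zero.

No deposited rainfall record ships with the package;
:func:`synthesize_historical` produces a realistic stand-in: right-skewed
gamma annual totals with Markov drought persistence, so that multi-year
low-rainfall runs occur as they do in semi-arid records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RainfallSeries",
    "SCENARIOS",
    "BASELINE_SCENARIOS",
    "EXTREME_SCENARIOS",
    "generate_rainfall",
    "synthesize_historical",
    "read_rainfall_csv",
    "write_rainfall_csv",
]

BASELINE_SCENARIOS = ("constant", "historical", "random", "statistical")
EXTREME_SCENARIOS = ("random-extreme", "statistical-extreme")
SCENARIOS = BASELINE_SCENARIOS + EXTREME_SCENARIOS

N_YEARS = 60


@dataclass
class RainfallSeries:
    """A 60-year annual rainfall series (mm/yr) under a named scenario."""

    values: np.ndarray
    scenario: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("rainfall series must be one-dimensional")
        if (self.values < 0).any():
            raise ValueError("rainfall cannot be negative")

    def __len__(self) -> int:
        return len(self.values)


def _fit_gamma_moments(historical: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, scale) by method of moments on the annual totals."""
    mean = historical.mean()
    var = historical.var(ddof=1)
    if var <= 0:
        raise ValueError("historical series has zero variance; cannot fit gamma")
    shape = mean * mean / var
    scale = var / mean
    return shape, scale


def generate_rainfall(
    scenario: str,
    historical,
    rng: np.random.Generator | None = None,
    sd_multiplier: float = 1.5,
    n_years: int = N_YEARS,
) -> RainfallSeries:
    """Generate one annual rainfall series under a named scenario.

    ``historical`` is the reference record (>= 2 years).  The extreme
    scenarios rescale deviations from the historical mean by
    ``sd_multiplier`` before truncating negatives at zero, so the
    *generating* standard deviation is sd_multiplier x SD(historical).
    """
    historical = np.asarray(historical, dtype=np.float64)
    if historical.size < 2:
        raise ValueError("historical series must contain at least 2 years")
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be > 0")
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown rainfall scenario '{scenario}'; choose from {SCENARIOS}")

    mean = historical.mean()
    if scenario == "constant":
        values = np.full(n_years, mean)
    elif scenario == "historical":
        reps = int(np.ceil(n_years / historical.size))
        values = np.tile(historical, reps)[:n_years]
    else:
        if rng is None:
            raise ValueError(f"scenario '{scenario}' requires an rng")
        if scenario.startswith("random"):
            draws = rng.choice(historical, size=n_years, replace=True)
        else:  # statistical
            shape, scale = _fit_gamma_moments(historical)
            draws = rng.gamma(shape, scale, size=n_years)
        if scenario.endswith("-extreme"):
            draws = mean + sd_multiplier * (draws - mean)
        values = np.maximum(draws, 0.0)
    return RainfallSeries(values=values, scenario=scenario)


def synthesize_historical(
    n_years: int = N_YEARS,
    mean_mm: float = 550.0,
    cv: float = 0.35,
    drought_run_prob: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize a semi-arid annual rainfall record.

    Annual totals are gamma-distributed (right-skewed) with coefficient of
    variation ``cv``.  A two-state Markov chain adds drought persistence:
    in the drought state the gamma mean is halved; the drought state
    persists year-to-year with probability ``drought_run_prob`` and is
    entered from the normal state with probability ``drought_run_prob / 4``
    (so ``drought_run_prob = 0`` disables droughts entirely).  Deterministic
    under a fixed seed.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if mean_mm <= 0:
        raise ValueError("mean_mm must be > 0")
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if not (0.0 <= drought_run_prob < 1.0):
        raise ValueError("drought_run_prob must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()

    p_enter = drought_run_prob / 4.0
    values = np.empty(n_years)
    drought = False
    for i in range(n_years):
        target_mean = mean_mm * (0.5 if drought else 1.0)
        if cv < 1e-6:
            values[i] = target_mean
        else:
            shape = 1.0 / (cv * cv)
            values[i] = rng.gamma(shape, target_mean / shape)
        stay = drought_run_prob if drought else p_enter
        drought = rng.random() < stay
    return values


def read_rainfall_csv(path) -> np.ndarray:
    """Read an annual rainfall record from a two-column (year, mm) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("rainfall CSV must have (year, mm) columns")
    return df.iloc[:, 1].to_numpy(dtype=np.float64)


def write_rainfall_csv(values, path, start_year: int = 1) -> None:
    """Write an annual rainfall record as a two-column (year, mm) CSV."""
    values = np.asarray(values, dtype=np.float64)
    pd.DataFrame({
        "year": np.arange(start_year, start_year + values.size),
        "mm": values,
    }).to_csv(path, index=False)
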