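"""Model parameters and management plans: defaults, validation, YAML I/O, perturbation.

Two configuration objects drive every simulation:

``ModelParameters``
    The biological and physical constants of the village system — growth
    rates, energy densities, cow masses, fencing costs, sustainability
    minima.  These are the quantities the sensitivity sweep perturbs.

``ManagementPlan``
    The farmer-controlled levers — land allocation, spatial clumping of
    fields, growth-enhancement projects, cow movement, drought subsidies,
    stone walls, grain storage.

Numeric defaults are literature-plausible placeholders for a semi-arid
southern-African communal area and are meant to be substituted from field
data where available; the sweep and sensitivity analyses depend on relative
perturbations and scenario contrasts rather than on the absolute values.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field, fields
from typing import Optional, TextIO, Union

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "ManagementPlan",
    "ConfigurationError",
    "ValidationError",
    "load_config",
    "save_config",
    "perturb_parameters",
    "PERTURB_10PCT",
    "PERTURBED_PARAMETERS",
]


class ConfigurationError(ValueError):
    """A configuration file could not be parsed or names an unknown field."""


class ValidationError(ValueError):
    """A configuration violates a model invariant."""


@dataclass
class ModelParameters:
    """Biological/physical constants of the agro-pastoral system.

    Units are noted per field.  Masses kg, energies MJ, areas ha, one model
    step is 8 hours (3 steps per day).
    """

    # -- primary production -------------------------------------------------
    g_wood: float = 2500.0            # woodland biomass growth, kg/ha/yr at reference rainfall
    crop_growth_rate: float = 4.0     # standing crop biomass, kg/ha per mm annual rain
    woodland_carrying_capacity: float = 1200.0   # max standing woodland biomass per patch, kg
    reference_rainfall: float = 550.0  # mm/yr at which g_wood is defined

    # -- energetics ----------------------------------------------------------
    eta_browse: float = 9.0           # energy density of woodland browse, MJ/kg
    eta_crop: float = 12.0            # energy density of crop residue/grain eaten by cows, MJ/kg
    eta_cow: float = 14.0             # energy density of cow tissue, MJ/kg
    eta_c: float = 0.80               # catabolism efficiency (tissue -> usable energy)
    eta_a: float = 0.55               # anabolism efficiency (surplus energy -> tissue)
    e_maint: float = 10.0             # maintenance energy per 8-h step at reference mass, MJ
    e_work: float = 6.0               # extra energy per 8-h step of ploughing work, MJ
    intake_max: float = 4.0           # max biomass intake per 8-h step at reference mass, kg
    forage_access_frac: float = 0.006  # fraction of a patch's standing forage a cow can gather per visit

    # -- cow life history ----------------------------------------------------
    m_min: float = 180.0              # minimum viable adult mass, kg (death below this)
    m_max: float = 450.0              # maximum mass, kg
    m_birth: float = 35.0             # calf mass at birth, kg
    m_mature: float = 250.0           # juvenile -> adult transition mass, kg (also metabolic reference)
    P_nr: float = 0.45                # annual probability an adult does NOT calve
    juvenile_min_frac: float = 0.8    # juveniles die below this fraction of m_birth
    transported_repro_factor: float = 0.5  # reproduction multiplier while transported out

    # -- space ---------------------------------------------------------------
    village_area: float = 600.0       # ha
    patch_area: float = 0.24          # ha

    # -- fencing and raiding -------------------------------------------------
    fence_cost: float = 300.0         # woodland biomass per km of brush fence built/repaired, kg
    fence_break_prob: float = 0.02    # per-step probability a broken boundary patch is raided
    fence_decay_prob: float = 0.5     # per-year probability a brush fence segment fails

    # -- work ---------------------------------------------------------------
    plough_rate: float = 0.12         # ha ploughed per cow per 8-h step
    plough_window_days: int = 30      # ploughing window at the start of the wet season

    # -- harvest and household ----------------------------------------------
    grain_fraction: float = 0.5       # harvested grain share of standing crop biomass
    household_consumption: float = 60000.0  # grain drawn from the store per year, kg
    feed_price: float = 1.0           # abstract currency per kg of supplemental feed

    # -- sustainability minima ----------------------------------------------
    min_cows_thresh: float = 2.0      # head
    min_seed_thresh: Optional[float] = None  # kg; None -> seed_per_ha * crop area
    seed_per_ha: float = 15.0         # kg of seed needed per cropped ha (used when min_seed_thresh is None)
    min_wood_thresh: Optional[float] = None  # kg; None -> min_wood_frac * total woodland capacity
    min_wood_frac: float = 0.05

    # -- initialization / movement ------------------------------------------
    init_wood_frac: float = 0.8       # spin-up woodland biomass as a fraction of capacity
    init_stocking_rate: float = 0.3   # initial cows per ha of woodland
    search_radius: int = 10           # patch radius for farmer-directed cow moves

    def grid_side(self) -> int:
        """Side of the square patch grid implied by village and patch area."""
        n = self.village_area / self.patch_area
        side = int(round(math.sqrt(n)))
        return side

    def validate(self) -> None:
        errors = []
        positive = [
            "g_wood", "crop_growth_rate", "woodland_carrying_capacity",
            "reference_rainfall", "eta_browse", "eta_crop", "eta_cow",
            "e_maint", "intake_max", "m_min", "m_max", "m_birth", "m_mature",
            "village_area", "patch_area", "fence_cost", "plough_rate",
            "grain_fraction", "feed_price", "seed_per_ha",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                errors.append(f"{name} must be strictly positive")
        for name in ("e_work", "household_consumption", "min_cows_thresh",
                     "init_wood_frac", "init_stocking_rate", "min_wood_frac"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be non-negative")
        for name in ("P_nr", "eta_c", "eta_a", "fence_break_prob",
                     "fence_decay_prob", "transported_repro_factor",
                     "grain_fraction", "forage_access_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must lie in [0, 1]")
        if not (self.m_birth < self.m_mature < self.m_max):
            errors.append("require m_birth < m_mature < m_max")
        if not (self.m_min < self.m_max):
            errors.append("require m_min < m_max")
        if not (self.m_min < self.m_mature):
            errors.append("require m_min < m_mature (a fresh adult must be viable)")
        if not (0.0 < self.juvenile_min_frac < 1.0):
            errors.append("juvenile_min_frac must lie in (0, 1)")
        if self.min_seed_thresh is not None and self.min_seed_thresh <= 0:
            errors.append("min_seed_thresh must be strictly positive when given")
        if self.min_wood_thresh is not None and self.min_wood_thresh <= 0:
            errors.append("min_wood_thresh must be strictly positive when given")
        n = self.village_area / self.patch_area
        side = round(math.sqrt(n))
        if abs(side * side - n) > 1e-6 * n:
            errors.append(
                "village_area / patch_area must be a perfect square "
                f"(got {n:.3f})")
        if self.plough_window_days < 1:
            errors.append("plough_window_days must be >= 1")
        if self.search_radius < 1:
            errors.append("search_radius must be >= 1")
        if errors:
            raise ValidationError("invalid ModelParameters: " + "; ".join(errors))


@dataclass
class ManagementPlan:
    """Farmer-controlled management interventions."""

    proportion_crops: float = 0.48    # fraction of patches under crops
    clumpiness: float = 0.5           # spatial aggregation of crop patches, 0 random .. 1 one blob
    enhanced_crop_frac: float = 0.0   # fraction of crop patches growing faster
    enhanced_wood_frac: float = 0.0   # fraction of woodland patches growing faster
    crop_boost: float = 1.5           # growth multiplier on enhanced crop patches
    wood_boost: float = 1.5           # growth multiplier on enhanced woodland patches
    moves_per_day: int = 0            # farmer-directed cow relocations per day (0-3)
    subsidy_mode: str = "none"        # none | feed | transport
    subsidy_fraction: float = 0.0     # fraction of herd subsidized in trigger years
    stone_walls: bool = False         # "invincible" fences
    storage_years: int = 0            # grain carry-over horizon, years
    low_rainfall_trigger: float = 400.0  # annual mm below which subsidy activates

    def validate(self) -> None:
        errors = []
        if not (0.01 <= self.proportion_crops <= 0.99):
            errors.append("proportion_crops must lie in [0.01, 0.99]")
        for name in ("clumpiness", "enhanced_crop_frac", "enhanced_wood_frac",
                     "subsidy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must lie in [0, 1]")
        if self.crop_boost <= 0 or self.wood_boost <= 0:
            errors.append("growth boosts must be strictly positive")
        if self.moves_per_day not in (0, 1, 2, 3):
            errors.append("moves_per_day must be one of 0, 1, 2, 3")
        if self.subsidy_mode not in ("none", "feed", "transport"):
            errors.append("subsidy_mode must be one of none, feed, transport")
        if self.storage_years < 0:
            errors.append("storage_years must be >= 0")
        if self.low_rainfall_trigger < 0:
            errors.append("low_rainfall_trigger must be >= 0")
        if errors:
            raise ValidationError("invalid ManagementPlan: " + "; ".join(errors))


# Parameters the sensitivity sweep perturbs.  g_wood is perturbed by +/-10%
# (to span both literature and field-based growth estimates); everything else
# by +/-5%.  The plan-level crop_boost multiplier is also a 10% parameter and
# is handled by the sweep builder.
PERTURB_10PCT = ("g_wood",)
PERTURBED_PARAMETERS = (
    "g_wood", "crop_growth_rate", "woodland_carrying_capacity",
    "eta_browse", "eta_crop", "eta_cow", "eta_c", "eta_a",
    "e_maint", "e_work", "intake_max", "forage_access_frac",
    "m_min", "m_max", "m_birth", "m_mature", "P_nr",
    "fence_cost", "fence_break_prob", "plough_rate", "feed_price",
)


def _coerce(dc_field, value):
    if value is None:
        return None
    t = dc_field.type
    if t in ("int", int):
        if isinstance(value, float) and not value.is_integer():
            raise ConfigurationError(
                f"field '{dc_field.name}' expects an integer, got {value!r}")
        return int(value)
    if t in ("bool", bool):
        if not isinstance(value, bool):
            raise ConfigurationError(
                f"field '{dc_field.name}' expects a boolean, got {value!r}")
        return value
    if t in ("str", str):
        return str(value)
    if isinstance(value, (int, float)):
        return float(value)
    raise ConfigurationError(
        f"field '{dc_field.name}' expects a number, got {value!r}")


def _from_mapping(cls, mapping: dict):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in known:
            raise ConfigurationError(
                f"unknown field '{key}' for {cls.__name__}")
        kwargs[key] = _coerce(known[key], value)
    return cls(**kwargs)


def load_config(path_or_stream: Union[str, TextIO]) -> tuple[ModelParameters, ManagementPlan]:
    """Load and validate a YAML configuration.

    The file may contain ``parameters:`` and ``plan:`` sections, or flat
    top-level keys which are routed to whichever object owns the field.
    Missing fields take their documented defaults; an empty file yields the
    full default configuration.
    """
    if hasattr(path_or_stream, "read"):
        raw = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            raw = fh.read()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse configuration: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")

    param_map = dict(data.pop("parameters", None) or {})
    plan_map = dict(data.pop("plan", None) or {})
    param_fields = {f.name for f in fields(ModelParameters)}
    plan_fields = {f.name for f in fields(ManagementPlan)}
    for key, value in data.items():
        if key in param_fields:
            param_map.setdefault(key, value)
        elif key in plan_fields:
            plan_map.setdefault(key, value)
        else:
            raise ConfigurationError(f"unknown configuration field '{key}'")

    params = _from_mapping(ModelParameters, param_map)
    plan = _from_mapping(ManagementPlan, plan_map)
    params.validate()
    plan.validate()
    return params, plan


def save_config(params: ModelParameters, plan: ManagementPlan,
                path_or_stream: Union[str, TextIO, None] = None) -> str:
    """Serialize a configuration to YAML; returns the YAML text."""
    doc = {
        "parameters": dataclasses.asdict(params),
        "plan": dataclasses.asdict(plan),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path_or_stream is not None:
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)
    return text


def loads_config(text: str) -> tuple[ModelParameters, ManagementPlan]:
    """Load a configuration from a YAML string."""
    return load_config(io.StringIO(text))


def perturb_parameters(
    base: ModelParameters,
    rng: np.random.Generator,
    endpoints: bool = False,
) -> tuple[ModelParameters, dict[str, float]]:
    """Multiplicatively perturb the sweep-designated parameters.

    Each parameter in ``PERTURBED_PARAMETERS`` is independently multiplied by
    ``1 + delta`` with ``delta ~ Uniform(-0.05, +0.05)`` (``+/-0.10`` for the
    10% parameters).  With ``endpoints=True`` the delta is instead drawn from
    the two interval endpoints with equal probability.  Non-sweep parameters
    (areas, thresholds, spin-up settings) are untouched.

    Returns the perturbed copy and the realized delta vector, keyed by
    parameter name, for use as predictors in the sensitivity analysis.
    """
    out = dataclasses.replace(base)
    deltas: dict[str, float] = {}
    for name in PERTURBED_PARAMETERS:
        half = 0.10 if name in PERTURB_10PCT else 0.05
        if endpoints:
            delta = half if rng.random() < 0.5 else -half
        else:
            delta = rng.uniform(-half, half)
        deltas[name] = delta
        setattr(out, name, getattr(base, name) * (1.0 + delta))
    out.validate()
    return out, deltas
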