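"""Seeded synthetic FFQ cohorts with a latent diet-quality factor.

Each respondent carries a standard-normal latent quality ``q``. Item
intakes follow zero-inflated lognormal distributions whose log-location
shifts by ``direction * weight * latent_effect * q`` (direction +1 for
healthful items, -1 for unhealthful ones, 0 for neutral ones; parameters
live in the catalog's per-item ``simulation`` blocks). Reported energy is
the catalog energy implied by the intakes; every respondent's intakes are
then rescaled so that the reported-energy-to-BMR ratio lands inside the
Goldberg plausibility band, except for a controllable fraction of
misreporters whose ratio is placed outside it.

The prevalence of low diet quality (AHEI total below the threshold) is
calibrated by bisection on an additive healthfulness shift of the item
log-locations. The recorded true class is always the one the AHEI scorer
assigns to the generated intakes, so truth and scorer agree by
construction. Cardiometabolic covariates are Gaussian given the true class
with configurable standardized mean differences.

Reproducibility: every random draw comes from a named substream spawned
from the single cohort seed (one stream per demographic field, per item,
etc.), so results are deterministic for a seed and the first ``n`` rows do
not change when a cohort is enlarged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from . import ahei
from .ffq import ItemCatalog, load_demo_catalog
from .plausibility import GOLDBERG_HIGH, GOLDBERG_LOW, mifflin_st_jeor

PRESETS_SCHEMA_VERSION = 1

# substream namespaces
_NS_DEMOGRAPHICS = 0
_NS_LATENT = 1
_NS_ITEMS = 2
_NS_REPORTING = 3
_NS_COVARIATES = 4

_CALIBRATION_MAX_ITER = 25
_CALIBRATION_TOL = 0.01


class SimulationError(RuntimeError):
    """Raised when a cohort specification cannot be satisfied."""


def _presets_data() -> dict:
    text = resources.files("dietscreen").joinpath("data/presets.json").read_text()
    data = json.loads(text)
    if data.get("schema_version") != PRESETS_SCHEMA_VERSION:
        raise SimulationError("unsupported presets schema_version")
    return data


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n: int = 1000
    seed: int = 0
    age_mean: float = 45.4
    age_sd: float = 14.2
    age_range: tuple[float, float] = (18.0, 72.0)
    sex_ratio_female: float = 0.5
    bmi_mean: float = 27.7
    bmi_sd: float = 5.3
    latent_effect: float = 0.8
    target_prevalence_low: float | None = 0.59
    misreporter_fraction: float = 0.0
    ahei_threshold: float = ahei.DEFAULT_THRESHOLD
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    covariate_baselines: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("sex_ratio_female", "misreporter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.age_range
        if not (0.0 < lo < hi < 120.0):
            raise ValueError("age_range must lie within (0, 120)")
        if self.target_prevalence_low is not None and not (
            0.0 < self.target_prevalence_low < 1.0
        ):
            raise ValueError("target_prevalence_low must be in (0, 1)")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its generating truth.

    ``cohort`` is the respondent table (demographics + intakes);
    ``truth`` records the latent quality, AHEI total and true class per
    respondent; ``covariates`` the cardiometabolic variables;
    ``quality_shift`` the calibrated healthfulness shift.
    """

    cohort: pd.DataFrame
    truth: pd.DataFrame
    covariates: pd.DataFrame
    spec: CohortSpec
    quality_shift: float

    @property
    def latent_quality(self) -> pd.Series:
        return self.truth["latent_quality"]

    @property
    def true_class(self) -> pd.Series:
        return self.truth["true_class"]


def presets() -> dict[str, CohortSpec]:
    """Named cohort specifications: ``development`` and ``external``."""
    data = _presets_data()
    out = {}
    for name, raw in data["presets"].items():
        out[name] = CohortSpec(
            n=raw["n"],
            age_mean=raw["age_mean"],
            age_sd=raw["age_sd"],
            age_range=tuple(raw["age_range"]),
            sex_ratio_female=raw["sex_ratio_female"],
            bmi_mean=raw["bmi_mean"],
            bmi_sd=raw["bmi_sd"],
            latent_effect=raw["latent_effect"],
            target_prevalence_low=raw["target_prevalence_low"],
            misreporter_fraction=raw["misreporter_fraction"],
            covariate_effects=dict(data["covariate_effects"]),
            covariate_baselines=dict(data["covariate_baselines"]),
        )
    return out


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    )


def _sim_params(catalog: ItemCatalog) -> dict[str, np.ndarray]:
    """Stack per-item simulation metadata into arrays (catalog order)."""
    defaults = {"zero_prob": 0.2, "log_mean": -1.0, "log_sd": 0.7,
                "direction": 0.0, "weight": 0.0}
    cols = {k: [] for k in defaults}
    for item in catalog.items:
        sim = dict(item.simulation or {})
        for k, default in defaults.items():
            cols[k].append(float(sim.get(k, default)))
    return {k: np.asarray(v, dtype=float) for k, v in cols.items()}


def _draw_demographics(spec: CohortSpec) -> pd.DataFrame:
    n = spec.n
    sex = np.where(
        _stream(spec.seed, _NS_DEMOGRAPHICS, 0).random(n) < spec.sex_ratio_female,
        "female",
        "male",
    )
    age = np.clip(
        spec.age_mean
        + spec.age_sd * _stream(spec.seed, _NS_DEMOGRAPHICS, 1).standard_normal(n),
        *spec.age_range,
    )
    height = np.where(
        sex == "female",
        163.0 + 6.4 * _stream(spec.seed, _NS_DEMOGRAPHICS, 2).standard_normal(n),
        177.0 + 6.9 * _stream(spec.seed, _NS_DEMOGRAPHICS, 2).standard_normal(n),
    )
    height = np.clip(height, 140.0, 205.0)
    bmi = np.clip(
        spec.bmi_mean
        + spec.bmi_sd * _stream(spec.seed, _NS_DEMOGRAPHICS, 3).standard_normal(n),
        16.0,
        55.0,
    )
    weight = bmi * (height / 100.0) ** 2
    return pd.DataFrame(
        {
            "respondent_id": [f"S{i + 1:05d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 1),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
        }
    )


def _draw_intakes(
    spec: CohortSpec,
    catalog: ItemCatalog,
    q: np.ndarray,
    shift: float,
) -> np.ndarray:
    """Zero-inflated lognormal intakes, (n, n_items), before energy rescale."""
    n = spec.n
    params = _sim_params(catalog)
    X = np.empty((n, len(catalog)), dtype=float)
    for j in range(len(catalog)):
        effect = params["direction"][j] * (
            spec.latent_effect * params["weight"][j] * q + shift
        )
        # non-consumption is informative: healthful items are skipped more
        # often by low-quality diets (logistic link on the zero probability)
        p0 = params["zero_prob"][j]
        logit0 = np.log(p0 / (1.0 - p0)) if 0.0 < p0 < 1.0 else None
        if logit0 is None:
            p_zero = np.full(n, p0)
        else:
            p_zero = 1.0 / (1.0 + np.exp(-(logit0 - effect)))
        nonzero = _stream(spec.seed, _NS_ITEMS, j, 0).random(n) >= p_zero
        eps = _stream(spec.seed, _NS_ITEMS, j, 1).standard_normal(n)
        loc = params["log_mean"][j] + effect + params["log_sd"][j] * eps
        X[:, j] = np.where(nonzero, np.exp(loc), 0.0)
    return X


def _reporting_targets(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-respondent misreporter flag and target rEI:eBMR ratio."""
    n = spec.n
    mis = _stream(spec.seed, _NS_REPORTING, 0).random(n) < spec.misreporter_fraction
    under = _stream(spec.seed, _NS_REPORTING, 1).random(n) < 0.5
    u = _stream(spec.seed, _NS_REPORTING, 2).random(n)
    plausible_ratio = GOLDBERG_LOW + 0.1 + u * (GOLDBERG_HIGH - GOLDBERG_LOW - 0.2)
    under_ratio = 0.70 + u * (GOLDBERG_LOW - 0.05 - 0.70)
    over_ratio = GOLDBERG_HIGH + 0.05 + u * 0.55
    target = np.where(mis, np.where(under, under_ratio, over_ratio), plausible_ratio)
    return mis, target


def _realize(
    spec: CohortSpec,
    catalog: ItemCatalog,
    demo: pd.DataFrame,
    q: np.ndarray,
    target_ratio: np.ndarray,
    shift: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    X = _draw_intakes(spec, catalog, q, shift)
    energy = X @ catalog.nutrient_vector("energy_kcal")
    ebmr = mifflin_st_jeor(
        demo["sex"].to_numpy(),
        demo["weight_kg"].to_numpy(),
        demo["height_cm"].to_numpy(),
        demo["age"].to_numpy(),
    )
    scale = np.where(energy > 0, target_ratio * ebmr / np.maximum(energy, 1e-12), 1.0)
    X = X * scale[:, None]
    cohort = demo.copy()
    cohort[list(catalog.item_ids)] = X
    scores = ahei.score_cohort(cohort, catalog, threshold=spec.ahei_threshold)
    return cohort, scores


def generate_cohort(
    spec: CohortSpec, catalog: ItemCatalog | None = None
) -> SyntheticCohort:
    """Generate one synthetic cohort; deterministic given ``spec.seed``."""
    if catalog is None:
        catalog = load_demo_catalog()
    demo = _draw_demographics(spec)
    q = _stream(spec.seed, _NS_LATENT, 0).standard_normal(spec.n)
    _, target_ratio = _reporting_targets(spec)

    if spec.target_prevalence_low is None:
        shift = 0.0
        cohort, scores = _realize(spec, catalog, demo, q, target_ratio, shift)
    else:
        target = spec.target_prevalence_low
        lo, hi = -4.0, 4.0  # prevalence of "low" decreases in the shift
        cohort_lo, scores_lo = _realize(spec, catalog, demo, q, target_ratio, lo)
        prev_lo = float((scores_lo["quality_class"] == "low").mean())
        cohort_hi, scores_hi = _realize(spec, catalog, demo, q, target_ratio, hi)
        prev_hi = float((scores_hi["quality_class"] == "low").mean())
        if not (prev_hi <= target <= prev_lo):
            raise SimulationError(
                f"target prevalence {target} unreachable (attainable range "
                f"[{prev_hi:.3f}, {prev_lo:.3f}]); adjust latent_effect or the "
                "catalog simulation parameters"
            )
        shift, cohort, scores = 0.0, None, None
        for _ in range(_CALIBRATION_MAX_ITER):
            shift = 0.5 * (lo + hi)
            cohort, scores = _realize(spec, catalog, demo, q, target_ratio, shift)
            prev = float((scores["quality_class"] == "low").mean())
            if abs(prev - target) <= _CALIBRATION_TOL:
                break
            if prev > target:
                lo = shift
            else:
                hi = shift

    truth = pd.DataFrame(
        {
            "respondent_id": cohort["respondent_id"].to_numpy(),
            "latent_quality": q,
            "ahei_total": scores["ahei_total"].to_numpy(),
            "true_class": scores["quality_class"].to_numpy(),
        }
    )
    covariates = _draw_covariates(spec, truth)
    return SyntheticCohort(
        cohort=cohort,
        truth=truth,
        covariates=covariates,
        spec=spec,
        quality_shift=float(shift),
    )


def _draw_covariates(spec: CohortSpec, truth: pd.DataFrame) -> pd.DataFrame:
    baselines = spec.covariate_baselines or _presets_data()["covariate_baselines"]
    effects = dict(spec.covariate_effects or _presets_data()["covariate_effects"])
    is_low = (truth["true_class"] == "low").to_numpy()
    out = {"respondent_id": truth["respondent_id"].to_numpy()}
    for k, (name, base) in enumerate(sorted(baselines.items())):
        smd = float(effects.get(name, 0.0))
        eps = _stream(spec.seed, _NS_COVARIATES, k).standard_normal(spec.n)
        mean_shift = np.where(is_low, 0.5 * smd, -0.5 * smd)
        out[name] = base["mean"] + base["sd"] * (eps + mean_shift)
    return pd.DataFrame(out)
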