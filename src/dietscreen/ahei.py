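"""AHEI-2010 diet-quality scoring.

Eleven components, each worth 0-10 points (total 0-110). Adequacy
components (vegetables, fruit, whole grains, nuts/legumes, EPA+DHA, PUFA)
score 0 at or below the minimum criterion and 10 at or above the maximum
criterion, linearly prorated in between. Moderation components (SSB and
juice, red/processed meat, trans fat) run the other way. Sodium is scored
by decile rank within a reference population (lowest decile 10, highest 0).
Alcohol scores 10 inside a sex-specific moderate band, 0 at or above a
heavy-drinking cutoff, and non-drinkers (exactly zero drinks/day) receive
2.5 points.

Diets are classified high quality when the total reaches 65 of 110 points,
low quality otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ffq import ComponentIntakes, ItemCatalog, SEXES, cohort_component_intakes

#: Classification threshold on the 0-110 total (>= threshold -> high).
DEFAULT_THRESHOLD = 65.0

#: Points awarded when alcohol intake is exactly zero.
NONDRINKER_SCORE = 2.5


class ScoringError(ValueError):
    """Raised for invalid amounts or missing scoring context."""


@dataclass(frozen=True)
class ComponentRule:
    """Scoring rule for one AHEI component.

    ``min_criterion`` is the amount earning 0 points and ``max_criterion``
    the amount earning 10; either may be a per-sex mapping. ``kind`` selects
    the scoring shape: adequacy, moderation, range (alcohol) or decile
    (sodium).
    """

    component_id: str
    kind: str  # adequacy | moderation | range | decile
    min_criterion: float | Mapping[str, float] | None = None
    max_criterion: float | Mapping[str, float] | None = None
    band: Mapping[str, tuple[float, float]] | None = None  # alcohol only
    heavy_cutoff: Mapping[str, float] | None = None  # alcohol only
    nondrinker_score: float | None = None
    intake_field: str = ""

    def criterion(self, which: str, sex: str | None) -> float:
        value = getattr(self, which)
        if isinstance(value, Mapping):
            if sex is None:
                raise ScoringError(
                    f"{self.component_id}: sex is required for this component"
                )
            return float(value[sex])
        return float(value)


AHEI_RULES: dict[str, ComponentRule] = {
    "vegetables": ComponentRule(
        "vegetables", "adequacy", 0.0, 5.0, intake_field="vegetables"
    ),
    "fruit": ComponentRule("fruit", "adequacy", 0.0, 4.0, intake_field="fruit"),
    "whole_grains": ComponentRule(
        "whole_grains",
        "adequacy",
        0.0,
        {"female": 75.0, "male": 90.0},
        intake_field="whole_grains_g",
    ),
    "ssb_juice": ComponentRule(
        "ssb_juice", "moderation", 1.0, 0.0, intake_field="ssb_juice"
    ),
    "nuts_legumes": ComponentRule(
        "nuts_legumes", "adequacy", 0.0, 1.0, intake_field="nuts_legumes"
    ),
    "red_processed_meat": ComponentRule(
        "red_processed_meat",
        "moderation",
        1.5,
        0.0,
        intake_field="red_processed_meat",
    ),
    "trans_fat": ComponentRule(
        "trans_fat", "moderation", 4.0, 0.5, intake_field="trans_fat_pct_energy"
    ),
    "epa_dha": ComponentRule(
        "epa_dha", "adequacy", 0.0, 250.0, intake_field="epa_dha_mg"
    ),
    "pufa": ComponentRule(
        "pufa", "adequacy", 2.0, 10.0, intake_field="pufa_pct_energy"
    ),
    "sodium": ComponentRule("sodium", "decile", intake_field="sodium_mg"),
    "alcohol": ComponentRule(
        "alcohol",
        "range",
        band={"female": (0.5, 1.5), "male": (0.5, 2.0)},
        heavy_cutoff={"female": 2.5, "male": 3.5},
        nondrinker_score=NONDRINKER_SCORE,
        intake_field="alcohol_drinks",
    ),
}

COMPONENT_IDS = tuple(AHEI_RULES)


@dataclass(frozen=True)
class SodiumDecileContext:
    """Nine ordered cut points (mg/day) splitting a reference population
    into deciles. Computed with inclusive linear-interpolated percentiles;
    amounts tied with a boundary fall in the lower decile."""

    decile_boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.decile_boundaries, dtype=float)
        if b.shape != (9,):
            raise ScoringError("decile context requires exactly 9 boundaries")
        if np.any(np.diff(b) < 0):
            raise ScoringError("decile boundaries must be non-decreasing")

    def decile(self, amount: float | np.ndarray) -> np.ndarray:
        """Decile rank 1 (lowest) .. 10 (highest)."""
        b = np.asarray(self.decile_boundaries, dtype=float)
        return np.searchsorted(b, np.asarray(amount, dtype=float), side="left") + 1


def sodium_decile_context(
    population_sodium: Iterable[float],
) -> SodiumDecileContext:
    """Build the sodium decile context from a reference population.

    Boundaries are the 10th..90th percentiles (linear interpolation).
    """
    values = np.asarray(list(population_sodium), dtype=float)
    if values.size < 10:
        raise ScoringError(
            f"need at least 10 reference sodium values, got {values.size}"
        )
    bounds = np.percentile(values, np.arange(10, 100, 10), method="linear")
    return SodiumDecileContext(tuple(float(b) for b in bounds))


@dataclass(frozen=True)
class AHEIScore:
    """Component scores, total, and the low/high quality classification."""

    component_scores: Mapping[str, float]
    total: float
    quality_class: str  # "low" | "high"
    threshold: float = DEFAULT_THRESHOLD


def _score_vector(
    rule: ComponentRule,
    amount: np.ndarray,
    sex: str | None,
    ctx: SodiumDecileContext | None,
) -> np.ndarray:
    if np.any(amount < 0):
        raise ScoringError(f"{rule.component_id}: negative amount")
    if rule.kind == "adequacy":
        lo = rule.criterion("min_criterion", sex)
        hi = rule.criterion("max_criterion", sex)
        return np.interp(amount, [lo, hi], [0.0, 10.0])
    if rule.kind == "moderation":
        # min_criterion (score 0) exceeds max_criterion (score 10)
        zero_at = rule.criterion("min_criterion", sex)
        ten_at = rule.criterion("max_criterion", sex)
        return np.interp(amount, [ten_at, zero_at], [10.0, 0.0])
    if rule.kind == "range":
        if sex is None:
            raise ScoringError(f"{rule.component_id}: sex is required")
        lo, hi = rule.band[sex]
        heavy = float(rule.heavy_cutoff[sex])
        return np.interp(
            amount,
            [0.0, lo, hi, heavy],
            [float(rule.nondrinker_score), 10.0, 10.0, 0.0],
        )
    if rule.kind == "decile":
        if ctx is None:
            raise ScoringError("sodium scoring requires a SodiumDecileContext")
        rank = ctx.decile(amount)
        return 10.0 * (10.0 - rank) / 9.0
    raise ScoringError(f"unknown rule kind {rule.kind!r}")


def score_component(
    rule: ComponentRule | str,
    amount: float,
    sex: str | None = None,
    ctx: SodiumDecileContext | None = None,
) -> float:
    """Points (0-10) for one component amount.

    ``rule`` may be a :class:`ComponentRule` or a component id from
    :data:`AHEI_RULES`.
    """
    if isinstance(rule, str):
        rule = AHEI_RULES[rule]
    return float(_score_vector(rule, np.asarray([amount], dtype=float), sex, ctx)[0])


def score_ahei(
    ci: ComponentIntakes,
    sex: str,
    ctx: SodiumDecileContext,
    threshold: float = DEFAULT_THRESHOLD,
) -> AHEIScore:
    """Score one diet on all 11 components and classify it low/high."""
    if sex not in SEXES:
        raise ScoringError(f"sex must be one of {SEXES}, got {sex!r}")
    scores = {
        cid: score_component(rule, getattr(ci, rule.intake_field), sex, ctx)
        for cid, rule in AHEI_RULES.items()
    }
    total = float(sum(scores.values()))
    return AHEIScore(
        component_scores=scores,
        total=total,
        quality_class="high" if total >= threshold else "low",
        threshold=threshold,
    )


def score_cohort(
    cohort: pd.DataFrame,
    catalog: ItemCatalog,
    ctx: SodiumDecileContext | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Score a whole cohort table; returns one row per respondent.

    Columns: ``score_<component>`` for each component, ``ahei_total`` and
    ``quality_class``. When ``ctx`` is None the sodium decile boundaries are
    computed within the scored cohort itself.
    """
    comp = cohort_component_intakes(cohort, catalog)
    if ctx is None:
        ctx = sodium_decile_context(comp["sodium_mg"].to_numpy())
    sexes = cohort["sex"].to_numpy()
    out = pd.DataFrame(index=cohort.index)
    for cid, rule in AHEI_RULES.items():
        amounts = comp[rule.intake_field].to_numpy()
        col = np.empty(len(cohort), dtype=float)
        for sex in SEXES:
            mask = sexes == sex
            if mask.any():
                col[mask] = _score_vector(rule, amounts[mask], sex, ctx)
        out[f"score_{cid}"] = col
    out["ahei_total"] = out.sum(axis=1)
    out["quality_class"] = np.where(out["ahei_total"] >= threshold, "high", "low")
    return out
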