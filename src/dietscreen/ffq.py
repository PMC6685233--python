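"""Food-frequency questionnaire data model.

An :class:`ItemCatalog` describes the food questions of an FFQ: for every
item, the nutrients contributed per reported serving (energy, trans fat,
PUFA, long-chain n-3 fats, sodium, alcohol) and the servings (or grams, for
whole grains) it contributes to each diet-index component. Respondent
intakes are expressed in servings/day throughout; frequency-category x
portion encodings of the original instrument are assumed collapsed to
servings/day at ingest.

The catalog also carries optional per-item simulation metadata used by
:mod:`dietscreen.synth` (zero-inflation probability, lognormal location and
scale, healthful/unhealthful direction, signal weight).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CATALOG_SCHEMA_VERSION = 1

#: kcal per gram of fat (Atwater factor) for %-energy conversions.
KCAL_PER_G_FAT = 9.0

NUTRIENT_KEYS = (
    "energy_kcal",
    "trans_fat_g",
    "pufa_g",
    "epa_dha_mg",
    "sodium_mg",
    "alcohol_drinks",
)

MEMBERSHIP_KEYS = (
    "vegetables",
    "fruit",
    "whole_grains_g",
    "ssb_juice",
    "nuts_legumes",
    "red_processed_meat",
)

DEMOGRAPHIC_COLUMNS = ("respondent_id", "sex", "age", "height_cm", "weight_kg")

SEXES = ("female", "male")


class CatalogError(ValueError):
    """Raised when a catalog file violates the documented schema."""


class CohortError(ValueError):
    """Raised when a cohort table violates the expected layout."""


class UndefinedEnergyError(ValueError):
    """Raised when a %-energy component is requested for a zero-energy diet
    that nevertheless reports fat intake."""


@dataclass(frozen=True)
class FFQItem:
    """One food question of the FFQ.

    ``nutrients_per_serving`` and ``component_membership`` give the amount
    contributed by a single reported serving; both are non-negative.
    """

    item_id: str
    label: str
    question_text: str = ""
    serving_unit: str = "serving"
    nutrients_per_serving: Mapping[str, float] = field(default_factory=dict)
    component_membership: Mapping[str, float] = field(default_factory=dict)
    simulation: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.item_id:
            raise CatalogError("item_id must be a non-empty string")
        for key, value in self.nutrients_per_serving.items():
            if key not in NUTRIENT_KEYS:
                raise CatalogError(
                    f"item {self.item_id!r}: unknown nutrient key {key!r}; "
                    f"expected one of {NUTRIENT_KEYS}"
                )
            if value < 0:
                raise CatalogError(
                    f"item {self.item_id!r}: nutrient {key!r} is negative ({value})"
                )
        for key, value in self.component_membership.items():
            if key not in MEMBERSHIP_KEYS:
                raise CatalogError(
                    f"item {self.item_id!r}: unknown component {key!r}; "
                    f"expected one of {MEMBERSHIP_KEYS}"
                )
            if value < 0:
                raise CatalogError(
                    f"item {self.item_id!r}: component contribution {key!r} "
                    f"is negative ({value})"
                )

    def nutrient(self, key: str) -> float:
        return float(self.nutrients_per_serving.get(key, 0.0))

    def membership(self, key: str) -> float:
        return float(self.component_membership.get(key, 0.0))


@dataclass(frozen=True)
class ItemCatalog:
    """An ordered collection of FFQ items plus food-group definitions.

    Groups may overlap. Items listed in ``excluded_item_ids`` remain
    scoreable (their nutrients count toward the AHEI) but are never offered
    as predictors to the tree learner.
    """

    items: tuple[FFQItem, ...]
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    group_labels: Mapping[str, str] = field(default_factory=dict)
    excluded_item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CatalogError(f"duplicate item_id(s): {sorted(dupes)}")
        known = set(ids)
        for gid, members in self.groups.items():
            unknown = [m for m in members if m not in known]
            if unknown:
                raise CatalogError(
                    f"group {gid!r} references unknown item(s): {unknown}"
                )
        unknown_excl = [i for i in self.excluded_item_ids if i not in known]
        if unknown_excl:
            raise CatalogError(
                f"excluded_item_ids references unknown item(s): {unknown_excl}"
            )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> FFQItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no such item: {item_id!r}")

    @property
    def predictor_item_ids(self) -> tuple[str, ...]:
        """Item ids eligible as tree predictors (exclusions applied)."""
        excluded = set(self.excluded_item_ids)
        return tuple(i for i in self.item_ids if i not in excluded)

    def group_label(self, group_id: str) -> str:
        return self.group_labels.get(group_id, group_id.replace("_", " "))

    def nutrient_vector(self, key: str) -> np.ndarray:
        return np.array([it.nutrient(key) for it in self.items], dtype=float)

    def membership_vector(self, key: str) -> np.ndarray:
        return np.array([it.membership(key) for it in self.items], dtype=float)


@dataclass(frozen=True)
class Respondent:
    """One FFQ respondent: demographics, anthropometry and intakes."""

    respondent_id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    intakes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in ("age", "height_cm", "weight_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for item_id, value in self.intakes.items():
            if value < 0:
                raise ValueError(
                    f"intake for {item_id!r} is negative ({value})"
                )


@dataclass(frozen=True)
class ComponentIntakes:
    """The 11 AHEI component amounts plus total energy for one diet."""

    vegetables: float  # servings/day
    fruit: float  # servings/day
    whole_grains_g: float  # g/day
    ssb_juice: float  # servings/day
    nuts_legumes: float  # servings/day
    red_processed_meat: float  # servings/day
    trans_fat_pct_energy: float  # % of energy
    epa_dha_mg: float  # mg/day
    pufa_pct_energy: float  # % of energy
    sodium_mg: float  # mg/day
    alcohol_drinks: float  # drinks/day
    energy_kcal: float  # kcal/day

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Catalog I/O


def _load_structured_text(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise CatalogError(f"{path}: YAML parse error: {exc}") from exc
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CatalogError(
                f"{path}: JSON parse error at line {exc.lineno}, "
                f"column {exc.colno}: {exc.msg}"
            ) from exc
    if not isinstance(data, dict):
        raise CatalogError(f"{path}: top level must be a mapping")
    return data


def catalog_from_dict(data: Mapping) -> ItemCatalog:
    version = data.get("schema_version")
    if version != CATALOG_SCHEMA_VERSION:
        raise CatalogError(
            f"unsupported catalog schema_version {version!r}; "
            f"expected {CATALOG_SCHEMA_VERSION}"
        )
    raw_items = data.get("items")
    if not isinstance(raw_items, list) or not raw_items:
        raise CatalogError("catalog must contain a non-empty 'items' list")
    items = []
    for i, raw in enumerate(raw_items):
        if not isinstance(raw, dict) or "item_id" not in raw:
            raise CatalogError(f"items[{i}]: each item needs an 'item_id' field")
        try:
            items.append(
                FFQItem(
                    item_id=raw["item_id"],
                    label=raw.get("label", raw["item_id"]),
                    question_text=raw.get("question_text", ""),
                    serving_unit=raw.get("serving_unit", "serving"),
                    nutrients_per_serving=dict(raw.get("nutrients_per_serving", {})),
                    component_membership=dict(raw.get("component_membership", {})),
                    simulation=dict(raw["simulation"]) if "simulation" in raw else None,
                )
            )
        except CatalogError as exc:
            raise CatalogError(f"items[{i}]: {exc}") from exc
    groups = {
        gid: tuple(members)
        for gid, members in dict(data.get("groups", {})).items()
    }
    return ItemCatalog(
        items=tuple(items),
        groups=groups,
        group_labels=dict(data.get("group_labels", {})),
        excluded_item_ids=tuple(data.get("excluded_item_ids", [])),
    )


def load_catalog(path: str | Path) -> ItemCatalog:
    """Load and validate an item catalog from a JSON or YAML file."""
    return catalog_from_dict(_load_structured_text(path))


def load_demo_catalog() -> ItemCatalog:
    """The bundled demonstration catalog (~30 items, 8 food groups)."""
    text = (
        resources.files("dietscreen").joinpath("data/demo_catalog.json").read_text()
    )
    return catalog_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_groups(
    respondent: Respondent, catalog: ItemCatalog
) -> dict[str, float]:
    """Sum member item intakes for every food group in the catalog.

    Items the respondent did not report are treated as zero intake.
    """
    _check_intake_keys(respondent.intakes, catalog)
    return {
        gid: float(sum(respondent.intakes.get(m, 0.0) for m in members))
        for gid, members in catalog.groups.items()
    }


def _check_intake_keys(intakes: Mapping[str, float], catalog: ItemCatalog) -> None:
    unknown = set(intakes) - set(catalog.item_ids)
    if unknown:
        raise CohortError(
            f"intakes keyed by unknown item id(s): {sorted(unknown)}"
        )


def component_intakes(
    respondent: Respondent, catalog: ItemCatalog
) -> ComponentIntakes:
    """Compute the 11 AHEI component amounts for one respondent.

    Each amount is the intake-weighted sum of per-serving contributions.
    Trans fat and PUFA are converted to percent of energy with 9 kcal/g.
    """
    _check_intake_keys(respondent.intakes, catalog)
    x = np.array(
        [respondent.intakes.get(i, 0.0) for i in catalog.item_ids], dtype=float
    )
    row = _component_table(x[None, :], catalog)
    return ComponentIntakes(**{k: float(v[0]) for k, v in row.items()})


def _component_table(X: np.ndarray, catalog: ItemCatalog) -> dict[str, np.ndarray]:
    """Vectorized component amounts for an (n, n_items) intake matrix."""
    energy = X @ catalog.nutrient_vector("energy_kcal")
    trans_g = X @ catalog.nutrient_vector("trans_fat_g")
    pufa_g = X @ catalog.nutrient_vector("pufa_g")
    zero_energy = energy <= 0
    if np.any(zero_energy & ((trans_g > 0) | (pufa_g > 0))):
        raise UndefinedEnergyError(
            "percent-of-energy components are undefined: zero energy intake "
            "with non-zero fat intake"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        trans_pct = np.where(
            zero_energy, 0.0, 100.0 * KCAL_PER_G_FAT * trans_g / energy
        )
        pufa_pct = np.where(
            zero_energy, 0.0, 100.0 * KCAL_PER_G_FAT * pufa_g / energy
        )
    return {
        "vegetables": X @ catalog.membership_vector("vegetables"),
        "fruit": X @ catalog.membership_vector("fruit"),
        "whole_grains_g": X @ catalog.membership_vector("whole_grains_g"),
        "ssb_juice": X @ catalog.membership_vector("ssb_juice"),
        "nuts_legumes": X @ catalog.membership_vector("nuts_legumes"),
        "red_processed_meat": X @ catalog.membership_vector("red_processed_meat"),
        "trans_fat_pct_energy": trans_pct,
        "epa_dha_mg": X @ catalog.nutrient_vector("epa_dha_mg"),
        "pufa_pct_energy": pufa_pct,
        "sodium_mg": X @ catalog.nutrient_vector("sodium_mg"),
        "alcohol_drinks": X @ catalog.nutrient_vector("alcohol_drinks"),
        "energy_kcal": energy,
    }


# ---------------------------------------------------------------------------
# Cohort tables


def intake_matrix(cohort: pd.DataFrame, catalog: ItemCatalog) -> np.ndarray:
    """Extract the (n, n_items) servings/day matrix in catalog item order."""
    missing = [i for i in catalog.item_ids if i not in cohort.columns]
    if missing:
        raise CohortError(f"cohort is missing intake column(s): {missing}")
    X = cohort.loc[:, list(catalog.item_ids)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise CohortError("cohort intakes contain missing values")
    if (X < 0).any():
        raise CohortError("cohort intakes contain negative values")
    return X


def cohort_component_intakes(
    cohort: pd.DataFrame, catalog: ItemCatalog
) -> pd.DataFrame:
    """Per-respondent component amounts for a whole cohort table."""
    table = _component_table(intake_matrix(cohort, catalog), catalog)
    return pd.DataFrame(table, index=cohort.index)


def cohort_group_intakes(
    cohort: pd.DataFrame, catalog: ItemCatalog
) -> pd.DataFrame:
    X = intake_matrix(cohort, catalog)
    idx = {item_id: j for j, item_id in enumerate(catalog.item_ids)}
    data = {
        gid: X[:, [idx[m] for m in members]].sum(axis=1)
        for gid, members in catalog.groups.items()
    }
    return pd.DataFrame(data, index=cohort.index)


def load_cohort(path: str | Path, catalog: ItemCatalog) -> pd.DataFrame:
    """Read a cohort CSV (one row per respondent).

    Expected columns: ``respondent_id, sex, age, height_cm, weight_kg`` then
    one column per catalog item id. Missing intake cells are set to 0 with a
    logged warning; unknown intake columns are an error.
    """
    df = pd.read_csv(path)
    missing_demo = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing_demo:
        raise CohortError(f"{path}: missing required column(s): {missing_demo}")
    unknown = [
        c
        for c in df.columns
        if c not in DEMOGRAPHIC_COLUMNS and c not in catalog.item_ids
    ]
    if unknown:
        raise CohortError(f"{path}: unknown intake column(s): {unknown}")
    item_cols = [c for c in df.columns if c in catalog.item_ids]
    n_missing = int(df[item_cols].isna().sum().sum())
    if n_missing:
        logger.warning(
            "%s: %d missing intake cell(s) set to 0", path, n_missing
        )
        df[item_cols] = df[item_cols].fillna(0.0)
    absent = [i for i in catalog.item_ids if i not in df.columns]
    if absent:
        logger.warning(
            "%s: item column(s) absent, assumed 0: %s", path, absent
        )
        for col in absent:
            df[col] = 0.0
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise CohortError(f"{path}: invalid sex value(s): {sorted(bad_sex)}")
    return df


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def respondent_from_row(row: Mapping, catalog: ItemCatalog) -> Respondent:
    """Build a :class:`Respondent` from one cohort-table row."""
    return Respondent(
        respondent_id=str(row["respondent_id"]),
        sex=row["sex"],
        age=float(row["age"]),
        height_cm=float(row["height_cm"]),
        weight_kg=float(row["weight_kg"]),
        intakes={i: float(row[i]) for i in catalog.item_ids if i in row},
    )
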