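"""Energy-reporting plausibility screening (Goldberg cutoff).

Reported energy intake (rEI, from the FFQ) is compared with basal metabolic
rate estimated by the Mifflin-St Jeor equation (eBMR). Respondents with
rEI:eBMR >= 1.2 and < 2.4 are plausible reporters; those below the band are
under-reporters and those at or above 2.4 are over-reporters. Development
analyses filter to plausible reporters; external validation keeps everyone
and only annotates status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ffq import ItemCatalog, SEXES, cohort_component_intakes

#: Goldberg band: lower bound inclusive, upper bound exclusive.
GOLDBERG_LOW = 1.2
GOLDBERG_HIGH = 2.4

STATUS_PLAUSIBLE = "plausible"
STATUS_UNDER = "under_reporter"
STATUS_OVER = "over_reporter"


@dataclass(frozen=True)
class PlausibilityResult:
    rEI: float  # kcal/day
    eBMR: float  # kcal/day
    ratio: float
    status: str


def mifflin_st_jeor(sex, weight_kg, height_cm, age_years):
    """Estimated basal metabolic rate in kcal/day.

    men:   10*weight + 6.25*height - 5*age + 5
    women: 10*weight + 6.25*height - 5*age - 161

    Accepts scalars or aligned arrays; ``sex`` holds "female"/"male".
    """
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0) or np.any(age <= 0):
        raise ValueError("weight, height and age must all be positive")
    sex_arr = np.asarray(sex)
    bad = ~np.isin(sex_arr, SEXES)
    if np.any(bad):
        raise ValueError(f"invalid sex value(s): {np.unique(sex_arr[bad])}")
    const = np.where(sex_arr == "male", 5.0, -161.0)
    bmr = 10.0 * weight + 6.25 * height - 5.0 * age + const
    return float(bmr) if np.isscalar(sex) else bmr


def plausibility_status(rEI: float, eBMR: float) -> PlausibilityResult:
    """Classify one reporter against the Goldberg band."""
    if eBMR <= 0:
        raise ValueError("eBMR must be positive")
    if rEI < 0:
        raise ValueError("rEI must be non-negative")
    ratio = rEI / eBMR
    if ratio < GOLDBERG_LOW:
        status = STATUS_UNDER
    elif ratio < GOLDBERG_HIGH:
        status = STATUS_PLAUSIBLE
    else:
        status = STATUS_OVER
    return PlausibilityResult(rEI=rEI, eBMR=eBMR, ratio=ratio, status=status)


def annotate_cohort(cohort: pd.DataFrame, catalog: ItemCatalog) -> pd.DataFrame:
    """Per-respondent rEI, eBMR, ratio and status for a cohort table."""
    if len(cohort) == 0:
        return pd.DataFrame(
            columns=["respondent_id", "rEI", "eBMR", "ratio", "status"]
        )
    rei = cohort_component_intakes(cohort, catalog)["energy_kcal"].to_numpy()
    ebmr = mifflin_st_jeor(
        cohort["sex"].to_numpy(),
        cohort["weight_kg"].to_numpy(),
        cohort["height_cm"].to_numpy(),
        cohort["age"].to_numpy(),
    )
    ratio = rei / ebmr
    status = np.where(
        ratio < GOLDBERG_LOW,
        STATUS_UNDER,
        np.where(ratio < GOLDBERG_HIGH, STATUS_PLAUSIBLE, STATUS_OVER),
    )
    return pd.DataFrame(
        {
            "respondent_id": cohort["respondent_id"].to_numpy(),
            "rEI": rei,
            "eBMR": ebmr,
            "ratio": ratio,
            "status": status,
        },
        index=cohort.index,
    )


def filter_plausible(
    cohort: pd.DataFrame, catalog: ItemCatalog, apply: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply (or merely annotate) the Goldberg filter.

    Returns ``(retained cohort, exclusion log)``. With ``apply=True`` only
    plausible reporters are retained (development mode); with ``apply=False``
    all rows are retained and the log annotates every status
    (external-validation mode).
    """
    log = annotate_cohort(cohort, catalog)
    if not apply:
        return cohort.copy(), log
    keep = (log["status"] == STATUS_PLAUSIBLE).to_numpy() if len(log) else []
    retained = cohort.loc[keep].copy() if len(cohort) else cohort.copy()
    excluded = log.loc[log["status"] != STATUS_PLAUSIBLE] if len(log) else log
    return retained, excluded
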