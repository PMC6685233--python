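import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietscreen import cart, ffq, synth
from dietscreen.ahei import score_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_catalog():
    return ffq.load_demo_catalog()


@pytest.fixture(scope="session")
def small_cohort(demo_catalog):
    """A small development-style synthetic cohort (n=250, fixed seed)."""
    spec = dataclasses.replace(synth.presets()["development"], n=250, seed=42)
    return synth.generate_cohort(spec, demo_catalog)


@pytest.fixture(scope="session")
def fitted_tree(demo_catalog, small_cohort):
    """A tree fitted to the small cohort with MC cross-validation."""
    scores = score_cohort(small_cohort.cohort, demo_catalog)
    predictors = cart.build_predictor_matrix(small_cohort.cohort, demo_catalog)
    return cart.fit_classification_tree(
        predictors, scores["quality_class"].to_numpy(), seed=7
    )


def random_cohort_rows(catalog, n, rng):
    """Arbitrary valid respondent rows (uniform random intakes)."""
    import pandas as pd

    data = {
        "respondent_id": [f"R{i}" for i in range(n)],
        "sex": rng.choice(["female", "male"], n),
        "age": rng.uniform(18, 80, n),
        "height_cm": rng.uniform(150, 195, n),
        "weight_kg": rng.uniform(45, 120, n),
    }
    for item_id in catalog.item_ids:
        data[item_id] = rng.uniform(0, 3, n) * rng.integers(0, 2, n)
    return pd.DataFrame(data)
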