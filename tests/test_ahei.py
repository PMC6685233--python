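import numpy as np
import pytest
from hypothesis import given, strategies as st

from dietscreen import ahei
from dietscreen.ffq import ComponentIntakes


def _ctx(values=None):
    if values is None:
        values = np.linspace(1000, 5000, 100)
    return ahei.sodium_decile_context(values)


@pytest.mark.parametrize(
    "component, amount, sex, expected",
    [
        ("vegetables", 0.0, "female", 0.0),
        ("vegetables", 5.0, "female", 10.0),
        ("vegetables", 2.5, "female", 5.0),  # linear proration
        ("fruit", 0.0, "male", 0.0),
        ("fruit", 4.0, "male", 10.0),
        ("whole_grains", 75.0, "female", 10.0),
        ("whole_grains", 75.0, "male", 75.0 / 90.0 * 10.0),
        ("whole_grains", 90.0, "male", 10.0),
        ("ssb_juice", 0.0, "female", 10.0),
        ("ssb_juice", 1.0, "female", 0.0),
        ("nuts_legumes", 1.0, "female", 10.0),
        ("red_processed_meat", 0.0, "female", 10.0),
        ("red_processed_meat", 1.5, "female", 0.0),
        ("red_processed_meat", 3.0, "female", 0.0),  # beyond the criterion
        ("trans_fat", 0.5, "female", 10.0),
        ("trans_fat", 4.0, "female", 0.0),
        ("epa_dha", 250.0, "female", 10.0),
        ("epa_dha", 125.0, "female", 5.0),
        ("pufa", 2.0, "female", 0.0),
        ("pufa", 10.0, "female", 10.0),
        ("alcohol", 0.0, "female", 2.5),  # non-drinker rule
        ("alcohol", 0.0, "male", 2.5),
        ("alcohol", 1.0, "female", 10.0),  # moderate band
        ("alcohol", 2.0, "male", 10.0),
        ("alcohol", 2.5, "female", 0.0),  # heavy cutoff
        ("alcohol", 3.5, "male", 0.0),
        ("alcohol", 2.0, "female", 5.0),  # halfway from band edge to heavy
    ],
)
def test_component_scoring_criteria(component, amount, sex, expected):
    assert ahei.score_component(component, amount, sex, _ctx()) == pytest.approx(
        expected
    )


def test_negative_amount_rejected():
    with pytest.raises(ahei.ScoringError):
        ahei.score_component("vegetables", -0.1, "female")


def test_sodium_requires_context():
    with pytest.raises(ahei.ScoringError, match="[Cc]ontext"):
        ahei.score_component("sodium", 2000.0, "female", None)


def test_sodium_decile_extremes():
    ctx = _ctx(np.linspace(1000, 5000, 200))
    assert ahei.score_component("sodium", 500.0, ctx=ctx) == 10.0
    assert ahei.score_component("sodium", 6000.0, ctx=ctx) == 0.0


def test_sodium_identical_reference_population():
    ctx = ahei.sodium_decile_context([2000.0] * 50)
    # ties share the lower decile: everyone scores 10
    assert ahei.score_component("sodium", 2000.0, ctx=ctx) == 10.0


def test_sodium_ten_distinct_values_fill_deciles():
    values = np.arange(1, 11, dtype=float) * 100
    ctx = ahei.sodium_decile_context(values)
    ranks = sorted(int(ctx.decile(v)) for v in values)
    assert ranks == list(range(1, 11))


def test_sodium_permutation_invariance():
    rng = np.random.default_rng(0)
    values = rng.uniform(1500, 4500, 60)
    ctx1 = ahei.sodium_decile_context(values)
    ctx2 = ahei.sodium_decile_context(rng.permutation(values))
    assert ctx1.decile_boundaries == ctx2.decile_boundaries


def test_sodium_context_needs_ten_values():
    with pytest.raises(ahei.ScoringError):
        ahei.sodium_decile_context([1.0] * 9)


def _intakes(**kw):
    base = dict(
        vegetables=0.0,
        fruit=0.0,
        whole_grains_g=0.0,
        ssb_juice=0.0,
        nuts_legumes=0.0,
        red_processed_meat=0.0,
        trans_fat_pct_energy=0.0,
        epa_dha_mg=0.0,
        pufa_pct_energy=0.0,
        sodium_mg=0.0,
        alcohol_drinks=0.0,
        energy_kcal=2000.0,
    )
    base.update(kw)
    return ComponentIntakes(**base)


def _all_max(sex):
    return _intakes(
        vegetables=5,
        fruit=4,
        whole_grains_g=75 if sex == "female" else 90,
        ssb_juice=0,
        nuts_legumes=1,
        red_processed_meat=0,
        trans_fat_pct_energy=0.5,
        epa_dha_mg=250,
        pufa_pct_energy=10,
        sodium_mg=500,  # below the lowest decile boundary
        alcohol_drinks=1.0,
    )


def _all_min(sex):
    return _intakes(
        ssb_juice=1,
        red_processed_meat=1.5,
        trans_fat_pct_energy=4,
        pufa_pct_energy=2,
        sodium_mg=9000,  # above the highest decile boundary
        alcohol_drinks=5.0,
    )


@pytest.mark.parametrize("sex", ["female", "male"])
def test_total_bounds(sex):
    ctx = _ctx()
    top = ahei.score_ahei(_all_max(sex), sex, ctx)
    assert top.total == pytest.approx(110.0)
    assert top.quality_class == "high"
    bottom = ahei.score_ahei(_all_min(sex), sex, ctx)
    assert bottom.total == pytest.approx(0.0)
    assert bottom.quality_class == "low"


def test_threshold_comparison_is_inclusive():
    """A total exactly at the threshold classifies high; any total strictly
    below it classifies low (unrounded comparison)."""
    ctx = _ctx()
    ci = _intakes(vegetables=2.5, fruit=2.0)
    total = ahei.score_ahei(ci, "female", ctx).total
    at = ahei.score_ahei(ci, "female", ctx, threshold=total)
    assert at.quality_class == "high"  # >= threshold, inclusive
    above = ahei.score_ahei(ci, "female", ctx, threshold=np.nextafter(total, np.inf))
    assert above.quality_class == "low"


def test_sex_specific_components_differ_between_criteria():
    ctx = _ctx()
    ci = _intakes(whole_grains_g=80.0, alcohol_drinks=1.8)
    f = ahei.score_ahei(ci, "female", ctx)
    m = ahei.score_ahei(ci, "male", ctx)
    assert f.component_scores["whole_grains"] == 10.0
    assert m.component_scores["whole_grains"] < 10.0
    assert m.component_scores["alcohol"] == 10.0
    assert f.component_scores["alcohol"] < 10.0


@given(
    lo=st.floats(0, 20),
    hi=st.floats(0, 20),
    sex=st.sampled_from(["female", "male"]),
    component=st.sampled_from(
        ["vegetables", "fruit", "whole_grains", "nuts_legumes", "epa_dha", "pufa"]
    ),
)
def test_adequacy_monotone_nondecreasing(lo, hi, sex, component):
    if lo > hi:
        lo, hi = hi, lo
    scale = 25.0 if component == "epa_dha" else (9.0 if component == "whole_grains" else 1.0)
    s_lo = ahei.score_component(component, lo * scale, sex)
    s_hi = ahei.score_component(component, hi * scale, sex)
    assert s_lo <= s_hi + 1e-12


@given(
    lo=st.floats(0, 6),
    hi=st.floats(0, 6),
    component=st.sampled_from(["ssb_juice", "red_processed_meat", "trans_fat"]),
)
def test_moderation_monotone_nonincreasing(lo, hi, component):
    if lo > hi:
        lo, hi = hi, lo
    assert ahei.score_component(component, lo, "female") >= (
        ahei.score_component(component, hi, "female") - 1e-12
    )


@given(st.integers(0, 2**32 - 1))
def test_total_is_bounded_sum_of_components(seed):
    rng = np.random.default_rng(seed)
    ci = _intakes(
        vegetables=rng.uniform(0, 8),
        fruit=rng.uniform(0, 6),
        whole_grains_g=rng.uniform(0, 150),
        ssb_juice=rng.uniform(0, 3),
        nuts_legumes=rng.uniform(0, 3),
        red_processed_meat=rng.uniform(0, 3),
        trans_fat_pct_energy=rng.uniform(0, 6),
        epa_dha_mg=rng.uniform(0, 400),
        pufa_pct_energy=rng.uniform(0, 15),
        sodium_mg=rng.uniform(500, 6000),
        alcohol_drinks=rng.uniform(0, 5),
    )
    score = ahei.score_ahei(ci, "male", _ctx())
    assert score.total == pytest.approx(sum(score.component_scores.values()))
    assert 0.0 <= score.total <= 110.0
    assert all(0.0 <= v <= 10.0 for v in score.component_scores.values())


def test_score_cohort_matches_per_respondent(demo_catalog, small_cohort):
    """The vectorized cohort scorer agrees with single-diet scoring."""
    from dietscreen.ffq import cohort_component_intakes, respondent_from_row, component_intakes

    cohort = small_cohort.cohort.head(20)
    comp = cohort_component_intakes(small_cohort.cohort, demo_catalog)
    ctx = ahei.sodium_decile_context(comp["sodium_mg"])
    table = ahei.score_cohort(small_cohort.cohort, demo_catalog, ctx=ctx)
    for idx, row in cohort.iterrows():
        ci = component_intakes(respondent_from_row(row, demo_catalog), demo_catalog)
        single = ahei.score_ahei(ci, row["sex"], ctx)
        assert table.loc[idx, "ahei_total"] == pytest.approx(single.total)
        assert table.loc[idx, "quality_class"] == single.quality_class
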