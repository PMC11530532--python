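"""Unit and property tests for the eight domain scorers and expertise coder."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elitesport import (
    DegenerateGroupWarning,
    ValidationError,
    build_score_table,
    classify_elite,
    code_expertise,
)
from elitesport.schemes import DOMAINS, SNP_PANELS, PolygenicScheme, ScoringScheme
from elitesport.scoring import (
    grouped_z,
    reactive_strength_index,
    relative_strength,
    score_basic_cognitive_function,
    score_blood_micronutrients_record,
    score_lower_body_dynamics,
    score_mental_health,
    score_muscle_power_genetics,
    score_muscular_strength,
    score_social_support,
    score_training_conditions,
)


def _frame(**columns) -> pd.DataFrame:
    frame = pd.DataFrame(columns)
    if "athlete_id" not in frame:
        frame["athlete_id"] = [f"a{i}" for i in range(len(frame))]
    return frame


def _items(frame, prefix, n, values):
    for i in range(1, n + 1):
        frame[f"{prefix}_{i}"] = values
    return frame


# ---------------------------------------------------------------------------
# muscular strength


def test_relative_strength_is_grip_over_mass():
    frame = _frame(grip_strength=[500.0], body_mass=[50.0])
    assert relative_strength(frame).iloc[0] == pytest.approx(10.0)


def test_strength_z_matches_hand_computed_sample_sd():
    # relative strengths {8, 10, 12, 14} in one group
    frame = _frame(
        grip_strength=[8 * 70.0, 10 * 70.0, 12 * 70.0, 14 * 70.0],
        body_mass=[70.0] * 4,
        sex=["male"] * 4, squad_level=["junior"] * 4, sport=["volleyball"] * 4,
    )
    z = score_muscular_strength(frame)
    assert np.allclose(z, [-1.162, -0.387, 0.387, 1.162], atol=5e-4)


def test_zero_variance_group_warns_and_zeroes():
    frame = _frame(
        grip_strength=[600.0, 600.0], body_mass=[60.0, 60.0],
        sex=["male"] * 2, squad_level=["junior"] * 2, sport=["volleyball"] * 2,
    )
    with pytest.warns(DegenerateGroupWarning):
        z = score_muscular_strength(frame)
    assert (z == 0).all()


def test_nonpositive_body_mass_rejected():
    frame = _frame(
        grip_strength=[500.0], body_mass=[0.0],
        sex=["male"], squad_level=["junior"], sport=["volleyball"],
    )
    with pytest.raises(ValidationError, match="body_mass"):
        score_muscular_strength(frame)


def test_grouped_z_mean_zero_sd_one_within_groups():
    rng = np.random.default_rng(3)
    values = pd.Series(rng.normal(5, 2, 60))
    groups = pd.DataFrame({"g": np.repeat(["x", "y", "z"], 20)})
    z = grouped_z(values, groups)
    for key in ("x", "y", "z"):
        sub = z[groups["g"] == key]
        assert abs(sub.mean()) < 1e-9
        assert abs(sub.std(ddof=1) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# lower-body dynamics


def _dynamics_frame(sport, speed, power, n=None):
    n = n or len(speed)
    frame = _frame(
        sport=[sport] * n, sex=["male"] * n, squad_level=["junior"] * n,
        tapping=[np.nan] * n, sprint_10m=[np.nan] * n,
        cmj_height=[np.nan] * n, drop_jump_rsi=[np.nan] * n,
        sergeant_height=[np.nan] * n,
    )
    scheme = ScoringScheme()
    speed_col, power_col = scheme.sport_components[sport]
    frame[speed_col] = speed
    frame[power_col] = power
    return frame


def test_rsi_is_height_over_contact_time():
    assert reactive_strength_index(30.0, 0.20) == pytest.approx(150.0)
    with pytest.raises(ValidationError):
        reactive_strength_index(30.0, 0.0)


def test_fastest_sprinter_highest_jumper_maximal_in_group():
    # ice hockey: 10 m sprint (lower is better) + CMJ
    frame = _dynamics_frame(
        "ice_hockey", speed=[1.70, 1.85, 1.95], power=[48.0, 40.0, 36.0]
    )
    score = score_lower_body_dynamics(frame)
    assert score.idxmax() == 0
    assert score.iloc[0] > score.iloc[1] > score.iloc[2]


@pytest.mark.parametrize("sport", ["volleyball", "table_tennis",
                                   "modern_pentathlon", "ice_hockey"])
def test_composite_monotone_in_both_components(sport):
    # exhaustive over component orderings for a two-athlete group
    better_speed = (11.0, 10.0) if sport != "ice_hockey" else (1.70, 1.90)
    better_power = (45.0, 35.0) if sport != "table_tennis" else (160.0, 120.0)
    for speed in (better_speed, better_speed[::-1]):
        for power in (better_power, better_power[::-1]):
            frame = _dynamics_frame(sport, speed=list(speed), power=list(power))
            score = score_lower_body_dynamics(frame)
            x_better_speed = (speed[0] < speed[1]) if sport == "ice_hockey" \
                else (speed[0] > speed[1])
            x_better_power = power[0] > power[1]
            if x_better_speed and x_better_power:
                assert score.iloc[0] > score.iloc[1]
            elif not x_better_speed and not x_better_power:
                assert score.iloc[0] < score.iloc[1]


def test_unknown_sport_rejected_by_name():
    frame = _dynamics_frame("volleyball", speed=[10.0, 11.0], power=[40.0, 42.0])
    frame.loc[0, "sport"] = "curling"
    with pytest.raises(ValidationError, match="curling"):
        score_lower_body_dynamics(frame)


def test_missing_component_gives_missing_score():
    frame = _dynamics_frame("volleyball", speed=[10.0, 11.0, 10.5],
                            power=[40.0, 42.0, np.nan])
    score = score_lower_body_dynamics(frame)
    assert score.iloc[:2].notna().all()
    assert np.isnan(score.iloc[2])


# ---------------------------------------------------------------------------
# muscle-power genetics


def _genetics_frame(sexes, genotypes):
    frame = _frame(sex=sexes)
    for snp in ("rs699", "rs6942022", "rs1544410", "rs1815739",
                "rs7247312", "rs1801394", "rs660339"):
        frame[f"geno_{snp}"] = [g.get(snp, np.nan) for g in genotypes]
    return frame


def test_male_all_effect_alleles_scores_highest():
    male = lambda a, b, c: {"rs699": a, "rs6942022": b, "rs1544410": c}
    frame = _genetics_frame(
        ["male"] * 4,
        [male(2, 2, 2), male(0, 0, 0), male(1, 1, 1), male(2, 1, 0)],
    )
    z = score_muscle_power_genetics(frame)
    assert z.idxmax() == 0 and z.idxmin() == 1


def test_doubling_weights_leaves_z_unchanged():
    rng = np.random.default_rng(5)
    frame = _genetics_frame(
        ["male"] * 10,
        [{"rs699": rng.integers(3), "rs6942022": rng.integers(3),
          "rs1544410": rng.integers(3)} for _ in range(10)],
    )
    base = score_muscle_power_genetics(frame)
    doubled = ScoringScheme(polygenic=PolygenicScheme(weights={
        sex: {snp: 2.0 for snp in panel} for sex, panel in SNP_PANELS.items()
    }))
    assert np.allclose(base, score_muscle_power_genetics(frame, doubled))


def test_invalid_genotype_rejected_and_missing_snp_gives_nan():
    frame = _genetics_frame(
        ["male"] * 2,
        [{"rs699": 3, "rs6942022": 0, "rs1544410": 0},
         {"rs699": 1, "rs6942022": 1, "rs1544410": 1}],
    )
    with pytest.raises(ValidationError, match="rs699"):
        score_muscle_power_genetics(frame)
    frame2 = _genetics_frame(
        ["male"] * 3,
        [{"rs6942022": 0, "rs1544410": 0},          # rs699 missing
         {"rs699": 1, "rs6942022": 1, "rs1544410": 1},
         {"rs699": 0, "rs6942022": 2, "rs1544410": 1}],
    )
    z = score_muscle_power_genetics(frame2)
    assert np.isnan(z.iloc[0]) and z.iloc[1:].notna().all()


# ---------------------------------------------------------------------------
# blood micronutrients


def _record(sex="male", age=19.0, **conc):
    return {"sex": sex, "age": age,
            "vitamin_b12": conc.get("b12", np.nan),
            "vitamin_d": conc.get("vitd", np.nan),
            "folic_acid": conc.get("folate", np.nan),
            "ferritin": conc.get("ferritin", np.nan)}


def test_optimal_panel_scores_100():
    assert score_blood_micronutrients_record(
        _record(b12=400, vitd=35, folate=7.0, ferritin=30)
    ) == pytest.approx(100.0)


def test_substandard_panel_scores_0():
    assert score_blood_micronutrients_record(
        _record(sex="female", age=20, b12=150, vitd=10, folate=2.0, ferritin=5)
    ) == pytest.approx(0.0)


def test_missing_folate_three_nutrient_case():
    # codes {1, 1, 2} over 3 available nutrients -> 100 * 4 / 6
    score = score_blood_micronutrients_record(
        _record(sex="female", age=20, b12=300, vitd=25, ferritin=12)
    )
    assert score == pytest.approx(100 * 4 / 6)


@pytest.mark.parametrize("kwargs, expected", [
    (dict(b12=350), 100.0),      # lower bound of the standard tier -> code 2
    (dict(b12=211), 50.0),       # lower bound of the suboptimal tier -> code 1
    (dict(b12=210.99), 0.0),
    (dict(vitd=30), 100.0),
    (dict(vitd=20), 50.0),
    (dict(folate=6.8), 100.0),
    (dict(folate=3.15), 50.0),
    (dict(ferritin=20), 100.0),  # male adult threshold, boundary inclusive
    (dict(ferritin=19.99), 0.0),
])
def test_tier_boundaries_upper_inclusive(kwargs, expected):
    assert score_blood_micronutrients_record(
        _record(sex="male", age=19, **kwargs)
    ) == pytest.approx(expected)


def test_ferritin_thresholds_depend_on_sex_and_age():
    # 12 ng/ml: below the under-18 female threshold (13), above adult (10)
    assert score_blood_micronutrients_record(
        _record(sex="female", age=17, ferritin=12.0)) == 0.0
    assert score_blood_micronutrients_record(
        _record(sex="female", age=20, ferritin=12.0)) == 100.0


def test_all_missing_is_missing_and_negative_rejected():
    assert np.isnan(score_blood_micronutrients_record(_record()))
    with pytest.raises(ValidationError, match="negative"):
        score_blood_micronutrients_record(_record(b12=-1.0))


@settings(max_examples=60, deadline=None)
@given(
    b12=st.floats(0, 800), vitd=st.floats(0, 80), folate=st.floats(0, 15),
    ferritin=st.floats(0, 60), delta=st.floats(0, 100),
    nutrient=st.sampled_from(["vitamin_b12", "vitamin_d", "folic_acid",
                              "ferritin"]),
)
def test_micronutrient_score_monotone_in_each_concentration(
    b12, vitd, folate, ferritin, delta, nutrient
):
    record = _record(b12=b12, vitd=vitd, folate=folate, ferritin=ferritin)
    bumped = dict(record)
    bumped[nutrient] = record[nutrient] + delta
    low = score_blood_micronutrients_record(record)
    high = score_blood_micronutrients_record(bumped)
    assert high >= low
    assert 0.0 <= low <= 100.0


# ---------------------------------------------------------------------------
# cognition, psychosocial, training


def _cognition_frame(zvt, correct, wrong):
    return _frame(zvt_mean=zvt, d2r_correct=correct, d2r_wrong=wrong)


def test_cognition_composite_and_translation_invariance():
    frame = _cognition_frame([80.0, 90.0, 100.0], [100.0, 120.0, 140.0],
                             [10.0, 15.0, 20.0])
    base = score_basic_cognitive_function(frame)
    shifted = _cognition_frame([85.0, 95.0, 105.0], [100.0, 120.0, 140.0],
                               [10.0, 15.0, 20.0])
    assert np.allclose(base, score_basic_cognitive_function(shifted))
    # athlete exactly at the mean of both variables -> composite 0
    assert base.iloc[1] == pytest.approx(0.0, abs=1e-12)


def test_cognition_implausible_counts_rejected():
    frame = _cognition_frame([90.0, 90.0], [900.0, 100.0], [10.0, 10.0])
    with pytest.raises(ValidationError, match="implausible"):
        score_basic_cognitive_function(frame)


def test_mental_health_higher_symptoms_lower_score():
    frame = _frame(dummy=[0, 0])
    frame = _items(frame, "phq4", 4, [1.0, 3.0])
    frame = _items(frame, "pss4", 4, [2.0, 2.0])
    z = score_mental_health(frame)
    assert z.iloc[0] > z.iloc[1]


def test_mental_health_item_out_of_range_named():
    frame = _frame(dummy=[0, 0])
    frame = _items(frame, "phq4", 4, [1.0, 5.0])
    frame = _items(frame, "pss4", 4, [2.0, 2.0])
    with pytest.raises(ValidationError, match="phq4"):
        score_mental_health(frame)


def test_social_support_matches_mean_of_scale_means():
    frame = _frame(dummy=[0, 0, 0])
    frame = _items(frame, "passq", 16, [3.0, 5.0, 1.0])
    frame = _items(frame, "mspss", 12, [5.0, 5.0, 1.0])
    z = score_social_support(frame)
    # combined raws: (3+5)/2=4, (5+5)/2=5, (1+1)/2=1
    raw = pd.Series([4.0, 5.0, 1.0])
    expected = (raw - raw.mean()) / raw.std(ddof=1)
    assert np.allclose(z, expected)
    assert z.idxmax() == 1 and z.idxmin() == 2


def test_training_conditions_mean_and_symmetry():
    frame = _frame(train_cond_1=[10.0, 4.0, 2.0], train_cond_2=[10.0, 6.0, 8.0])
    swapped = _frame(train_cond_1=[10.0, 6.0, 8.0], train_cond_2=[10.0, 4.0, 2.0])
    z = score_training_conditions(frame)
    assert np.allclose(z, score_training_conditions(swapped))
    raw = pd.Series([10.0, 5.0, 5.0])
    expected = (raw - raw.mean()) / raw.std(ddof=1)
    assert np.allclose(z, expected)


# ---------------------------------------------------------------------------
# expertise taxonomy


@pytest.mark.parametrize("a, b, yh, ys, expected", [
    (4, 4, 10, 12, 16),     # top of the printed 2-16 range
    (1, 0, 0, 0, 2),        # bottom of the range
    (3, 2, 3, 1, 8),        # 3 years at highest -> C=2; 1 senior year -> D=1
    (2, 1, 8, 3, 2 + 1 + 4 + 2),   # shared boundaries take the higher code
    (1, 0, 20, 10, 1 + 0 + 4 + 3), # clamp beyond top C bracket; 10 is not >10
    (1, 0, 0, 10.5, 1 + 0 + 1 + 4),
])
def test_expertise_coding_examples(a, b, yh, ys, expected):
    assert code_expertise(a, b, yh, ys) == expected


def test_expertise_invalid_codes_rejected():
    with pytest.raises(ValidationError):
        code_expertise(0, 0, 1, 1)
    with pytest.raises(ValidationError):
        code_expertise(1, 5, 1, 1)
    with pytest.raises(ValueError):
        code_expertise(1, 1, -1, 1)


@pytest.mark.parametrize("value, expected", [(13, True), (12, False),
                                             (16, True), (2, False)])
def test_classify_elite_threshold(value, expected):
    assert classify_elite(value) is expected


def test_classify_elite_out_of_range_rejected():
    with pytest.raises(ValidationError):
        classify_elite(17)


@settings(max_examples=100, deadline=None)
@given(a=st.integers(1, 4), b=st.integers(0, 4),
       yh=st.floats(0, 30), ys=st.floats(0, 30))
def test_expertise_always_within_2_16(a, b, yh, ys):
    assert 2 <= code_expertise(a, b, yh, ys) <= 16


# ---------------------------------------------------------------------------
# score table


def test_score_table_shape_and_zero_means(default_table):
    frame = default_table.frame
    assert len(frame) == 296
    assert list(DOMAINS) == [c for c in frame.columns if c in DOMAINS]
    for domain in ("muscle_power_genetics", "blood_micronutrients",
                   "mental_health", "social_support", "training_conditions"):
        assert abs(frame[domain].mean()) < 1e-9
    # composites of grouped z-scores: overall mean approximately zero
    assert abs(frame["lower_body_dynamics"].mean()) < 0.05
    assert frame["athlete_id"].is_unique
    assert ((frame["expertise"] >= 2) & (frame["expertise"] <= 16)).all()
    assert (frame["elite"] == (frame["expertise"] >= 13)).all()


def test_score_table_order_invariance(default_synthetic):
    cohort = default_synthetic.cohort
    shuffled = cohort.sample(frac=1.0, random_state=11).reset_index(drop=True)
    a = build_score_table(cohort).frame.set_index("athlete_id").sort_index()
    b = build_score_table(shuffled).frame.set_index("athlete_id").sort_index()
    pd.testing.assert_frame_equal(a, b)


def test_empty_cohort_rejected():
    with pytest.raises(ValidationError, match="empty"):
        build_score_table(pd.DataFrame())


def test_packaged_scheme_yaml_matches_builtin_defaults():
    from elitesport.schemes import default_scheme_path, load_scheme
    scheme = load_scheme(default_scheme_path())
    default = ScoringScheme()
    assert scheme.micronutrients == default.micronutrients
    assert scheme.expertise == default.expertise
    assert scheme.polygenic.weights == default.polygenic.weights
    assert scheme.sport_components == default.sport_components
    assert scheme.pss4_reverse_items == default.pss4_reverse_items
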