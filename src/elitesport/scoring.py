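"""Domain scoring: raw athlete records -> eight standardized domain scores.

Each scorer transforms one block of raw measurements into a single
superiority-oriented score (larger = better), z-standardized within the
group structure appropriate to that block:

* muscular strength: relative grip strength [N/kg], z within
  sex x squad_level x sport;
* lower-body dynamics: the discipline-specific speed and power components,
  each z within sex x squad_level, sprint z negated, then summed;
* muscle-power genetics: sex-specific additive polygenic score, z over the
  whole cohort;
* blood micronutrients: 0-100 supply score from medically coded
  concentrations, z over the whole cohort;
* basic cognitive function: processing-speed (ZVT) and concentration
  (d2-R correct minus wrong) scores, each z over the cohort, summed;
* mental health: PHQ-4 and PSS-4 item means rescaled to a common range,
  averaged, sign-inverted (higher = better), z over the cohort;
* social support: PASS-Q and MSPSS item means averaged, z over the cohort;
* training conditions: mean of the two satisfaction items, z over the cohort.

Alongside the eight domains, the expertise taxonomy (A + B + C + D, range
2-16) is coded from competition history and dichotomized into elite
(>= 13) vs semi-elite.

Zero-variance or singleton standardization groups yield z = 0 with a
:class:`~elitesport.errors.DegenerateGroupWarning` rather than an error, so
small cohorts stay usable.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGroupWarning, ValidationError
from .schemes import (
    DOMAINS,
    LOWER_IS_BETTER,
    MICRONUTRIENTS,
    SNP_PANELS,
    SPORTS,
    ScoringScheme,
)

#: Objects presented in the d2-R test (14 pages x 60 objects).
D2R_TOTAL_OBJECTS = 840

STRENGTH_GROUPS = ["sex", "squad_level", "sport"]
DYNAMICS_GROUPS = ["sex", "squad_level"]


def grouped_z(values: pd.Series, groups: pd.DataFrame | None = None) -> pd.Series:
    """z-standardize ``values`` within groups (sample SD, n-1 denominator).

    Missing values are excluded from the group statistics and stay missing.
    Groups of size 1 or with zero variance get z = 0 and raise a
    DegenerateGroupWarning.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    if groups is None:
        frames = [(None, values.index)]
    else:
        frames = list(groups.groupby(list(groups.columns), sort=False).groups.items())
    for key, idx in frames:
        vals = values.loc[idx]
        ok = vals.notna()
        if ok.sum() == 0:
            continue
        sub = vals[ok]
        if len(sub) < 2 or sub.std(ddof=1) == 0:
            warnings.warn(
                f"degenerate standardization group {key!r} "
                f"(n={len(sub)}); z set to 0",
                DegenerateGroupWarning,
                stacklevel=2,
            )
            out.loc[sub.index] = 0.0
        else:
            out.loc[sub.index] = (sub - sub.mean()) / sub.std(ddof=1)
    return out


def group_census(cohort: pd.DataFrame, by: list[str]) -> dict:
    """Sizes of every standardization group defined by the columns ``by``."""
    sizes = cohort.groupby(by, sort=True).size()
    return {
        "/".join(k) if isinstance(k, tuple) else str(k): int(v)
        for k, v in sizes.items()
    }


# ---------------------------------------------------------------------------
# physical performance domains


def reactive_strength_index(jump_height: float, contact_time: float) -> float:
    """Drop-jump Reactive Strength Index = jump height / ground contact time."""
    if contact_time <= 0:
        raise ValidationError(f"contact time must be > 0, got {contact_time}")
    return jump_height / contact_time


def relative_strength(cohort: pd.DataFrame) -> pd.Series:
    """Relative grip strength [N/kg] = absolute grip strength / body mass."""
    mass = cohort["body_mass"]
    if (mass.dropna() <= 0).any():
        bad = cohort.loc[mass.notna() & (mass <= 0), "athlete_id"].tolist()
        raise ValidationError(f"nonpositive body_mass for athletes {bad}")
    return cohort["grip_strength"] / mass


def score_muscular_strength(cohort: pd.DataFrame) -> pd.Series:
    """z of relative grip strength within sex x squad_level x sport."""
    return grouped_z(relative_strength(cohort), cohort[STRENGTH_GROUPS])


def score_lower_body_dynamics(
    cohort: pd.DataFrame, scheme: ScoringScheme | None = None
) -> pd.Series:
    """Sport-specific speed + power composite, components z within sex x squad.

    Each component variable (tapping, 10 m sprint, CMJ, drop-jump RSI,
    sergeant jump) is standardized separately over *all* athletes measured
    on it within a sex x squad_level group; the sprint z is negated so a
    faster time scores higher; the athlete's two sport-appropriate
    component z-scores are summed.
    """
    scheme = scheme or ScoringScheme()
    unknown = set(cohort["sport"]) - set(scheme.sport_components)
    if unknown:
        raise ValidationError(f"unknown sport(s): {sorted(unknown)}")
    components = sorted({c for pair in scheme.sport_components.values() for c in pair})
    comp_z = {}
    for comp in components:
        uses = cohort["sport"].map(lambda s: comp in scheme.sport_components[s])
        vals = cohort[comp].where(uses)
        z = grouped_z(vals, cohort[DYNAMICS_GROUPS])
        if comp in LOWER_IS_BETTER:
            z = -z
        comp_z[comp] = z
    score = pd.Series(np.nan, index=cohort.index, dtype=float)
    for sport, (speed, power) in scheme.sport_components.items():
        rows = cohort.index[cohort["sport"] == sport]
        score.loc[rows] = comp_z[speed].loc[rows] + comp_z[power].loc[rows]
    return score


def score_muscle_power_genetics(
    cohort: pd.DataFrame, scheme: ScoringScheme | None = None
) -> pd.Series:
    """Sex-specific polygenic score (weighted effect-allele counts), z over cohort."""
    scheme = scheme or ScoringScheme()
    raw = pd.Series(np.nan, index=cohort.index, dtype=float)
    for sex in SNP_PANELS:
        weights = scheme.polygenic.panel(sex)
        rows = cohort.index[cohort["sex"] == sex]
        total = pd.Series(0.0, index=rows)
        missing = pd.Series(False, index=rows)
        for snp, w in weights.items():
            counts = cohort.loc[rows, f"geno_{snp}"].astype(float)
            valid = counts.dropna()
            if not valid.isin([0, 1, 2]).all():
                bad = valid[~valid.isin([0, 1, 2])]
                raise ValidationError(
                    f"genotype outside {{0,1,2}} at {snp}: "
                    f"{bad.head().to_dict()}"
                )
            missing |= counts.isna()
            total = total + w * counts.fillna(0.0)
        raw.loc[rows] = total.where(~missing)
    return grouped_z(raw)


# ---------------------------------------------------------------------------
# blood micronutrients


def _code_three_tier(value: float, bounds: tuple[float, float]) -> int:
    low, high = bounds
    if value < low:
        return 0
    if value >= high:
        return 2
    return 1


def score_blood_micronutrients_record(
    record, scheme: ScoringScheme | None = None
) -> float:
    """0-100 supply score for one athlete record (mapping or Series).

    Each available nutrient is coded 0 (substandard), 1 (suboptimal) or
    2 (within the standard); ferritin is coded 0/2 with sex- and
    age-dependent thresholds. The score is 100 x sum(codes) /
    (2 x number of available nutrients); missing nutrients drop out of both
    numerator and denominator. Returns NaN if all four are missing.
    """
    scheme = scheme or ScoringScheme()
    mn = scheme.micronutrients
    codes = []
    for nutrient in MICRONUTRIENTS:
        value = record.get(nutrient) if hasattr(record, "get") else record[nutrient]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        value = float(value)
        if value < 0:
            raise ValidationError(f"negative concentration for {nutrient}: {value}")
        if nutrient == "ferritin":
            thr = mn.ferritin_threshold(record["sex"], float(record["age"]))
            codes.append(2 if value >= thr else 0)
        else:
            codes.append(_code_three_tier(value, getattr(mn, nutrient)))
    if not codes:
        return float("nan")
    return 100.0 * sum(codes) / (2 * len(codes))


def micronutrient_raw_scores(
    cohort: pd.DataFrame, scheme: ScoringScheme | None = None
) -> pd.Series:
    """Per-athlete 0-100 micronutrient supply scores."""
    scheme = scheme or ScoringScheme()
    return pd.Series(
        [score_blood_micronutrients_record(row, scheme) for _, row in cohort.iterrows()],
        index=cohort.index,
        dtype=float,
    )


def score_blood_micronutrients(
    cohort: pd.DataFrame, scheme: ScoringScheme | None = None
) -> pd.Series:
    """z over the whole cohort of the 0-100 micronutrient supply scores."""
    return grouped_z(micronutrient_raw_scores(cohort, scheme))


# ---------------------------------------------------------------------------
# cognition and psychosocial domains


def score_basic_cognitive_function(cohort: pd.DataFrame) -> pd.Series:
    """ZVT mean + d2-R concentration (correct - wrong), each z'd, summed."""
    correct, wrong = cohort["d2r_correct"], cohort["d2r_wrong"]
    implausible = (
        (wrong > D2R_TOTAL_OBJECTS)
        | (correct > D2R_TOTAL_OBJECTS)
        | (correct + wrong > D2R_TOTAL_OBJECTS)
        | (correct < 0)
        | (wrong < 0)
    )
    if implausible.fillna(False).any():
        bad = cohort.loc[implausible.fillna(False), "athlete_id"].tolist()
        raise ValidationError(
            f"implausible d2-R counts (total objects {D2R_TOTAL_OBJECTS}) "
            f"for athletes {bad}"
        )
    concentration = correct - wrong
    return grouped_z(cohort["zvt_mean"]) + grouped_z(concentration)


def _item_block(cohort: pd.DataFrame, prefix: str, n: int,
                lo: float, hi: float) -> pd.DataFrame:
    cols = [f"{prefix}_{i}" for i in range(1, n + 1)]
    block = cohort[cols].astype(float)
    out_of_range = (block < lo) | (block > hi)
    if out_of_range.any().any():
        col = out_of_range.any()[out_of_range.any()].index[0]
        row = out_of_range[col][out_of_range[col]].index[0]
        raise ValidationError(
            f"questionnaire item {col} out of range [{lo}, {hi}]: "
            f"value {block.loc[row, col]}"
        )
    return block


def score_mental_health(
    cohort: pd.DataFrame, scheme: ScoringScheme | None = None
) -> pd.Series:
    """PHQ-4 and PSS-4 composites on a common range, inverted, z over cohort.

    The PHQ-4 (4 items, 1-4) and PSS-4 (4 items, 1-5; positively worded
    items reverse-coded) item means are min-max rescaled to [0, 1],
    averaged, and sign-inverted so that higher = better mental health.
    """
    scheme = scheme or ScoringScheme()
    phq = _item_block(cohort, "phq4", 4, 1, 4)
    pss = _item_block(cohort, "pss4", 4, 1, 5).copy()
    for item in scheme.pss4_reverse_items:
        pss[f"pss4_{item}"] = 6 - pss[f"pss4_{item}"]
    phq_rescaled = (phq.mean(axis=1) - 1) / 3
    pss_rescaled = (pss.mean(axis=1) - 1) / 4
    raw = -(phq_rescaled + pss_rescaled) / 2
    return grouped_z(raw)


def mental_health_raw(cohort: pd.DataFrame,
                      scheme: ScoringScheme | None = None) -> pd.Series:
    """The pre-standardization mental-health composite (higher = better)."""
    scheme = scheme or ScoringScheme()
    phq = _item_block(cohort, "phq4", 4, 1, 4)
    pss = _item_block(cohort, "pss4", 4, 1, 5).copy()
    for item in scheme.pss4_reverse_items:
        pss[f"pss4_{item}"] = 6 - pss[f"pss4_{item}"]
    return -(((phq.mean(axis=1) - 1) / 3) + ((pss.mean(axis=1) - 1) / 4)) / 2


def score_social_support(cohort: pd.DataFrame) -> pd.Series:
    """PASS-Q and MSPSS item means averaged (both 1-5), z over cohort."""
    passq = _item_block(cohort, "passq", 16, 1, 5)
    mspss = _item_block(cohort, "mspss", 12, 1, 5)
    raw = (passq.mean(axis=1) + mspss.mean(axis=1)) / 2
    return grouped_z(raw)


def score_training_conditions(cohort: pd.DataFrame) -> pd.Series:
    """Mean of the two 1-10 satisfaction items, z over cohort."""
    items = _item_block(cohort, "train_cond", 2, 1, 10)
    return grouped_z(items.mean(axis=1))


# ---------------------------------------------------------------------------
# expertise taxonomy


def code_expertise(
    level_code: int,
    success_code: int,
    years_highest: float,
    years_international_senior: float,
    scheme: ScoringScheme | None = None,
) -> int:
    """Expertise value = A + B + C + D on the 2-16 taxonomy scale.

    A (1-4) and B (0-4) are taken as coded; C (1-4) and D (0-4) are derived
    from year counts with upper-inclusive shared boundaries (8 years at the
    highest level codes C = 4; 3 years of senior international ranking
    codes D = 2) and clamping beyond the top bracket.
    """
    scheme = scheme or ScoringScheme()
    a, b = int(level_code), int(success_code)
    if not 1 <= a <= 4:
        raise ValidationError(f"level_code (category A) must be in [1, 4], got {a}")
    if not 0 <= b <= 4:
        raise ValidationError(f"success_code (category B) must be in [0, 4], got {b}")
    c = scheme.expertise.code_years_highest(float(years_highest))
    d = scheme.expertise.code_years_senior(float(years_international_senior))
    return a + b + c + d


def classify_elite(expertise: int, threshold: int | None = None,
                   scheme: ScoringScheme | None = None) -> bool:
    """True iff expertise >= the elite threshold (default 13)."""
    scheme = scheme or ScoringScheme()
    if not 2 <= int(expertise) <= 16:
        raise ValidationError(f"expertise must be in [2, 16], got {expertise}")
    thr = scheme.expertise.elite_threshold if threshold is None else threshold
    return int(expertise) >= thr


# ---------------------------------------------------------------------------
# score table


@dataclass
class ScoreTable:
    """Cohort matrix of the eight domain scores plus expertise and elite flag.

    ``frame`` has one row per athlete with columns: athlete_id, sex, age,
    sport, squad_level, the eight domain scores, micronutrient_raw,
    expertise, elite. ``census`` records the size of every standardization
    group used; ``flagged`` lists athlete_ids with at least one missing
    domain score (they are retained, and dropped listwise by the models).
    """

    frame: pd.DataFrame
    census: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)

    @property
    def domains(self) -> tuple[str, ...]:
        return DOMAINS

    def elites(self) -> pd.DataFrame:
        return self.frame[self.frame["elite"]]

    def semi_elites(self) -> pd.DataFrame:
        return self.frame[~self.frame["elite"]]


def build_score_table(
    cohort: pd.DataFrame, scheme: ScoringScheme | None = None
) -> ScoreTable:
    """Apply every scorer plus the expertise coder to a raw cohort."""
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    scheme = scheme or ScoringScheme()
    cohort = cohort.reset_index(drop=True)
    if cohort["athlete_id"].duplicated().any():
        dupes = cohort.loc[cohort["athlete_id"].duplicated(), "athlete_id"].tolist()
        raise ValidationError(f"duplicate athlete_id(s): {dupes}")

    scores = pd.DataFrame({
        "athlete_id": cohort["athlete_id"],
        "sex": cohort["sex"],
        "age": cohort["age"].astype(float),
        "sport": cohort["sport"],
        "squad_level": cohort["squad_level"],
        "muscular_strength": score_muscular_strength(cohort),
        "lower_body_dynamics": score_lower_body_dynamics(cohort, scheme),
        "muscle_power_genetics": score_muscle_power_genetics(cohort, scheme),
        "blood_micronutrients": score_blood_micronutrients(cohort, scheme),
        "basic_cognitive_function": score_basic_cognitive_function(cohort),
        "mental_health": score_mental_health(cohort, scheme),
        "social_support": score_social_support(cohort),
        "training_conditions": score_training_conditions(cohort),
        "micronutrient_raw": micronutrient_raw_scores(cohort, scheme),
    })
    expertise = [
        code_expertise(
            row["level_code"], row["success_code"],
            row["years_highest"], row["years_international_senior"], scheme,
        )
        for _, row in cohort.iterrows()
    ]
    scores["expertise"] = pd.Series(expertise, index=cohort.index, dtype=int)
    scores["elite"] = scores["expertise"] >= scheme.expertise.elite_threshold

    census = {
        "muscular_strength": group_census(cohort, STRENGTH_GROUPS),
        "lower_body_dynamics": group_census(cohort, DYNAMICS_GROUPS),
        "cohort": {"all": len(cohort)},
    }
    flagged = scores.loc[
        scores[list(DOMAINS)].isna().any(axis=1), "athlete_id"
    ].tolist()
    return ScoreTable(frame=scores, census=census, flagged=flagged)
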