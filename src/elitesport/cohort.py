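"""Synthetic athlete-cohort generator.

The generator works latent-first: an 8-dimensional latent domain vector is
drawn per athlete from a multivariate normal with a configurable
correlation matrix, an expertise value (2-16) is derived from age plus a
weighted combination of latent domains plus noise, elite athletes
(expertise >= 13) receive configurable mean shifts and within-group scale
factors on their latents, and finally each domain's scoring map is
*inverted* through a norm table to produce raw measurements in native
units (N/kg, Hz, s, cm, pg/ml, questionnaire points, ...).

Because the inversion standardizes the latents within exactly the groups
the scorers use before mapping them to raw units, scoring a generated
cohort reproduces the generator's expected score table to machine
precision for the continuous domains; the polygenic and micronutrient
domains pass through a documented discretization (allele counts, supply
tiers) and are exact with respect to the discretized expected scores.

The default configuration emulates the study cohort: 296 athletes across
8 sports x 2 sexes with the printed per-sport counts and age means/SDs,
the printed inter-domain correlations (e.g., strength-dynamics r = .282),
and elite superiority (+0.9 SD) with reduced elite spread in basic
cognitive function and blood micronutrients.

The default norm table is a clearly-labeled *fictional* set of plausible
physiological values; no real group norms are published.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormCoverageError, ValidationError
from .schemes import (
    DOMAINS,
    MICRONUTRIENTS,
    SNP_PANELS,
    SPORT_COMPONENTS,
    ScoringScheme,
)
from .scoring import (
    DYNAMICS_GROUPS,
    STRENGTH_GROUPS,
    grouped_z,
    score_blood_micronutrients_record,
)

# Printed per-(sport, sex) cohort composition (n = 296).
SPORT_SEX_COUNTS: dict[tuple[str, str], int] = {
    ("basketball_3x3", "female"): 20, ("basketball_3x3", "male"): 15,
    ("ice_hockey", "female"): 20, ("ice_hockey", "male"): 34,
    ("volleyball", "female"): 33, ("volleyball", "male"): 65,
    ("artistic_gymnastics", "female"): 17,
    ("trampoline_gymnastics", "female"): 13, ("trampoline_gymnastics", "male"): 13,
    ("rhythmic_gymnastics", "female"): 25,
    ("table_tennis", "female"): 6, ("table_tennis", "male"): 8,
    ("modern_pentathlon", "female"): 13, ("modern_pentathlon", "male"): 14,
}

# Printed age means +/- SD in years per (sex, squad_level).
AGE_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("female", "junior"): (16.55, 1.70),
    ("male", "junior"): (17.27, 1.56),
    ("female", "senior"): (22.86, 5.69),
    ("male", "senior"): (24.38, 4.36),
}

#: Fraction of each (sport, sex) cell assigned to the senior squad; the
#: remainder is junior. 1/3 approximates the printed squad margins.
SENIOR_FRACTION = 1 / 3

# Representative concentrations per supply tier used by the inversion.
_TIER_CONCENTRATIONS = {
    "vitamin_b12": (150.0, 280.0, 450.0),   # pg/ml
    "vitamin_d": (14.0, 25.0, 40.0),        # ng/ml
    "folic_acid": (2.2, 5.0, 9.0),          # ng/ml
}
# Ferritin representative values as multiples of the sex/age threshold.
_FERRITIN_BELOW, _FERRITIN_ABOVE = 0.6, 1.8
# Population tier split for the supply coding: P(substandard), P(<=suboptimal).
_TIER_QUANTILES = (0.15, 0.5)


def default_counts() -> dict[tuple[str, str, str], int]:
    """Per-(sport, sex, squad_level) counts approximating the study cohort."""
    counts: dict[tuple[str, str, str], int] = {}
    for (sport, sex), n in SPORT_SEX_COUNTS.items():
        n_senior = int(round(n * SENIOR_FRACTION))
        counts[(sport, sex, "senior")] = n_senior
        counts[(sport, sex, "junior")] = n - n_senior
    return counts


def default_latent_correlation() -> np.ndarray:
    """Identity plus the study's printed inter-domain correlations."""
    r = np.eye(len(DOMAINS))
    idx = {d: i for i, d in enumerate(DOMAINS)}
    planted = [
        ("muscular_strength", "lower_body_dynamics", 0.282),
        ("muscle_power_genetics", "lower_body_dynamics", 0.186),
        ("mental_health", "social_support", 0.277),
        ("training_conditions", "mental_health", 0.305),
        ("training_conditions", "social_support", 0.386),
        ("basic_cognitive_function", "lower_body_dynamics", 0.116),
        ("muscle_power_genetics", "social_support", -0.138),
    ]
    for a, b, value in planted:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = value
    return r


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``expertise_weights`` maps 'age' and domain names to weights on the
    standardized expertise propensity; ``expertise_noise_sd`` defaults to
    the value that keeps the propensity at unit variance. The propensity is
    mapped to the 2-16 scale via round(center + slope * t).
    """

    counts: dict = field(default_factory=default_counts)
    age_params: dict = field(default_factory=lambda: dict(AGE_PARAMS))
    latent_correlation: np.ndarray = field(default_factory=default_latent_correlation)
    elite_effect: dict = field(default_factory=lambda: {
        "basic_cognitive_function": 0.6, "blood_micronutrients": 0.6,
    })
    elite_scale: dict = field(default_factory=lambda: {
        "basic_cognitive_function": 0.7, "blood_micronutrients": 0.7,
        "social_support": 1.3,
    })
    expertise_weights: dict = field(default_factory=lambda: {
        "age": 0.75, "lower_body_dynamics": 0.25,
    })
    expertise_noise_sd: float | None = None
    expertise_center: float = 7.5
    expertise_slope: float = 3.5
    missing_rate: dict = field(default_factory=dict)   # nutrient -> fraction
    nutrient_noise: float = 0.5
    elite_threshold: int = 13
    seed: int = 0

    def noise_sd(self) -> float:
        if self.expertise_noise_sd is not None:
            return self.expertise_noise_sd
        total = sum(w ** 2 for w in self.expertise_weights.values())
        return float(np.sqrt(max(0.05, 1.0 - total)))

    def validate(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for cell {key}: {n}")
        total = sum(self.counts.values())
        if 0 < total <= len(DOMAINS):
            raise ValidationError(
                f"cohort size {total} must exceed the number of domains "
                f"({len(DOMAINS)}) or be zero"
            )
        r = np.asarray(self.latent_correlation, dtype=float)
        if r.shape != (len(DOMAINS), len(DOMAINS)):
            raise ValidationError(f"latent_correlation must be 8x8, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValidationError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValidationError("latent_correlation must have unit diagonal")
        min_eig = float(np.linalg.eigvalsh(r).min())
        if min_eig < -1e-10:
            raise ValidationError(
                f"latent_correlation is not positive semi-definite: "
                f"smallest eigenvalue {min_eig:.6g}"
            )
        for nutrient, rate in self.missing_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(
                    f"missing_rate[{nutrient}] must be in [0, 1], got {rate}"
                )
        for key, (mean, sd) in self.age_params.items():
            if sd <= 0:
                raise ValidationError(f"age SD for {key} must be > 0, got {sd}")


@dataclass
class GroupNorms:
    """Measurement norms (mean + SD in native units) with group wildcards.

    ``frame`` columns: measurement, sex, squad_level, sport, mean, sd; a
    '*' in a group column matches any group. Lookups prefer the most
    specific matching row. The packaged defaults are FICTIONAL plausible
    physiological values (no real norms are published) and exist only to
    give the synthetic cohort realistic native units.
    """

    frame: pd.DataFrame

    def validate(self) -> None:
        if (self.frame["sd"] <= 0).any():
            bad = self.frame[self.frame["sd"] <= 0]
            raise ValidationError(
                f"norm SD must be > 0; offending rows:\n{bad}"
            )

    def lookup(self, measurement: str, sex: str, squad_level: str,
               sport: str) -> tuple[float, float]:
        f = self.frame
        rows = f[f["measurement"] == measurement]
        best, best_score = None, -1
        for _, row in rows.iterrows():
            score = 0
            ok = True
            for col, val in (("sex", sex), ("squad_level", squad_level),
                             ("sport", sport)):
                if row[col] == "*":
                    continue
                if row[col] != val:
                    ok = False
                    break
                score += 1
            if ok and score > best_score:
                best, best_score = row, score
        if best is None:
            raise NormCoverageError(
                f"no norm for measurement {measurement!r} in group "
                f"(sex={sex}, squad_level={squad_level}, sport={sport})"
            )
        return float(best["mean"]), float(best["sd"])


def default_norms() -> GroupNorms:
    """Fictional (synthetic) measurement norms; see GroupNorms docstring."""
    rows = [
        # measurement, sex, squad, sport, mean, sd
        ("rel_strength", "female", "*", "*", 5.6, 0.9),    # N/kg
        ("rel_strength", "male", "*", "*", 7.2, 1.0),
        ("body_mass", "female", "*", "*", 62.0, 7.0),      # kg
        ("body_mass", "male", "*", "*", 78.0, 9.0),
        ("tapping", "female", "*", "*", 10.8, 0.9),        # Hz
        ("tapping", "male", "*", "*", 11.4, 0.9),
        ("sprint_10m", "female", "*", "*", 1.95, 0.10),    # s
        ("sprint_10m", "male", "*", "*", 1.80, 0.10),
        ("cmj_height", "female", "*", "*", 32.0, 4.5),     # cm
        ("cmj_height", "male", "*", "*", 42.0, 5.5),
        ("drop_jump_rsi", "female", "*", "*", 130.0, 25.0),
        ("drop_jump_rsi", "male", "*", "*", 160.0, 30.0),
        ("sergeant_height", "female", "*", "*", 38.0, 5.0),
        ("sergeant_height", "male", "*", "*", 46.0, 6.0),
        ("zvt_mean", "*", "*", "*", 88.0, 12.0),           # numbers/page
        ("d2r_concentration", "*", "*", "*", 120.0, 25.0),
        ("d2r_wrong", "*", "*", "*", 15.0, 5.0),
    ]
    frame = pd.DataFrame(
        rows, columns=["measurement", "sex", "squad_level", "sport", "mean", "sd"]
    )
    return GroupNorms(frame=frame)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its expected (planted) score table.

    ``cohort`` holds the raw records; ``scores`` holds, per athlete, the
    domain scores the scoring pipeline will reproduce, alongside the
    expertise value and elite flag. Scoring ``cohort`` with zero
    missingness recovers ``scores`` to machine precision.
    """

    cohort: pd.DataFrame
    scores: pd.DataFrame
    config: CohortConfig


def _decompose_expertise(e: int) -> tuple[int, int, float, float]:
    """Split an expertise value into (A, B, years_highest, years_senior)."""
    a, b, c, d = 1, 0, 1, 0
    rem = e - 2
    add = min(rem, 3); a += add; rem -= add
    add = min(rem, 4); b += add; rem -= add
    add = min(rem, 3); c += add; rem -= add
    d += rem
    years_highest = {1: 1.0, 2: 3.0, 3: 5.0, 4: 9.0}[c]
    years_senior = {0: 0.0, 1: 2.0, 2: 4.0, 3: 8.0, 4: 12.0}[d]
    return a, b, years_highest, years_senior


def _empty_cohort_frame() -> pd.DataFrame:
    from .io import COHORT_COLUMNS
    return pd.DataFrame(columns=COHORT_COLUMNS)


def generate_cohort(
    config: CohortConfig | None = None,
    norms: GroupNorms | None = None,
    scheme: ScoringScheme | None = None,
) -> SyntheticCohort:
    """Generate raw athlete records with the configured planted structure."""
    config = config or CohortConfig()
    norms = norms or default_norms()
    scheme = scheme or ScoringScheme()
    config.validate()
    norms.validate()
    rng = np.random.default_rng(config.seed)
    n = sum(config.counts.values())
    if n == 0:
        return SyntheticCohort(
            cohort=_empty_cohort_frame(), scores=pd.DataFrame(), config=config
        )

    # -- demographics ------------------------------------------------------
    records = []
    for (sport, sex, squad), count in sorted(config.counts.items()):
        for _ in range(count):
            records.append({"sport": sport, "sex": sex, "squad_level": squad})
    base = pd.DataFrame(records)
    base["athlete_id"] = [f"ath_{i + 1:04d}" for i in range(n)]
    age = np.empty(n)
    for (sex, squad), (mean, sd) in config.age_params.items():
        mask = ((base["sex"] == sex) & (base["squad_level"] == squad)).to_numpy()
        age[mask] = rng.normal(mean, sd, mask.sum())
    base["age"] = np.clip(age, 10.0, None)

    # verify norm coverage for every group present
    for sport, sex, squad in {tuple(r) for r in
                              base[["sport", "sex", "squad_level"]].to_numpy()}:
        for meas in ("rel_strength", "body_mass", "zvt_mean",
                     "d2r_concentration", "d2r_wrong",
                     *scheme.sport_components[sport]):
            norms.lookup(meas, sex, squad, sport)

    # -- latent domain vectors --------------------------------------------
    r = np.asarray(config.latent_correlation, dtype=float)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(len(DOMAINS)))
    latent = rng.standard_normal((n, len(DOMAINS))) @ chol.T
    lat = pd.DataFrame(latent, columns=DOMAINS, index=base.index)

    # -- expertise and elite flag -----------------------------------------
    z_age = (base["age"] - base["age"].mean()) / base["age"].std(ddof=1)
    t = np.zeros(n)
    for key, w in config.expertise_weights.items():
        t += w * (z_age.to_numpy() if key == "age" else lat[key].to_numpy())
    t += rng.normal(0.0, config.noise_sd(), n)
    expertise = np.clip(
        np.round(config.expertise_center + config.expertise_slope * t), 2, 16
    ).astype(int)
    elite = expertise >= config.elite_threshold
    codes = [_decompose_expertise(int(e)) for e in expertise]
    base["level_code"] = pd.array([c[0] for c in codes], dtype="Int64")
    base["success_code"] = pd.array([c[1] for c in codes], dtype="Int64")
    base["years_highest"] = [c[2] for c in codes]
    base["years_international_senior"] = [c[3] for c in codes]

    # planted elite superiority: mean shift + within-group scale
    for domain in DOMAINS:
        shift = config.elite_effect.get(domain, 0.0)
        scale = config.elite_scale.get(domain, 1.0)
        lat.loc[elite, domain] = shift + scale * lat.loc[elite, domain]

    groups_strength = base[STRENGTH_GROUPS]
    groups_dynamics = base[DYNAMICS_GROUPS]
    expected = pd.DataFrame({
        "athlete_id": base["athlete_id"], "sex": base["sex"],
        "age": base["age"], "sport": base["sport"],
        "squad_level": base["squad_level"],
    })

    with warnings.catch_warnings():
        # degenerate singleton cells in small configs are expected here
        warnings.simplefilter("ignore")

        # -- muscular strength (invert through rel. strength and mass) ----
        e_str = grouped_z(lat["muscular_strength"], groups_strength)
        rel = np.empty(n)
        mass = np.empty(n)
        for key, idx in groups_strength.groupby(STRENGTH_GROUPS,
                                                sort=False).groups.items():
            sex, squad, sport = key
            m_rel, s_rel = norms.lookup("rel_strength", sex, squad, sport)
            m_mass, s_mass = norms.lookup("body_mass", sex, squad, sport)
            pos = base.index.get_indexer(idx)
            rel[pos] = m_rel + s_rel * e_str.loc[idx].to_numpy()
            mass[pos] = np.clip(
                m_mass + s_mass * rng.standard_normal(len(idx)), 35.0, None
            )
        rel = np.clip(rel, 0.5, None)
        base["body_mass"] = mass
        base["grip_strength"] = rel * mass
        expected["muscular_strength"] = e_str

        # -- lower-body dynamics (two sport-specific components) ----------
        all_components = sorted(
            {c for pair in scheme.sport_components.values() for c in pair}
        )
        comp_e = {}
        for comp in all_components:
            uses = base["sport"].map(
                lambda s: comp in scheme.sport_components[s]
            )
            vals = lat["lower_body_dynamics"].where(uses)
            comp_e[comp] = grouped_z(vals, groups_dynamics)
            raw = pd.Series(np.nan, index=base.index, dtype=float)
            for key, idx in groups_dynamics[uses].groupby(
                    DYNAMICS_GROUPS, sort=False).groups.items():
                sex, squad = key
                m, s = norms.lookup(comp, sex, squad, "*")
                sign = -1.0 if comp == "sprint_10m" else 1.0
                raw.loc[idx] = m + sign * s * comp_e[comp].loc[idx]
            base[comp] = raw
        dyn = pd.Series(np.nan, index=base.index, dtype=float)
        for sport, (speed, power) in scheme.sport_components.items():
            rows = base.index[base["sport"] == sport]
            dyn.loc[rows] = comp_e[speed].loc[rows] + comp_e[power].loc[rows]
        expected["lower_body_dynamics"] = dyn

        # -- muscle-power genetics (allele counts via binomial quantiles) -
        u = np.clip(stats.norm.cdf(lat["muscle_power_genetics"]), 1e-9, 1 - 1e-9)
        for snp in sorted({s for panel in SNP_PANELS.values() for s in panel}):
            base[f"geno_{snp}"] = pd.array([pd.NA] * n, dtype="Int64")
        polygenic = np.zeros(n)
        for sex, panel in SNP_PANELS.items():
            mask = (base["sex"] == sex).to_numpy()
            total = stats.binom.ppf(u[mask], 2 * len(panel), 0.5).astype(int)
            remaining = total.copy()
            for snp in panel:
                count = np.minimum(remaining, 2)
                remaining = remaining - count
                col = base[f"geno_{snp}"].to_numpy(dtype=object)
                col[mask] = count
                base[f"geno_{snp}"] = pd.array(col, dtype="Int64")
            polygenic[mask] = total
        expected["muscle_power_genetics"] = grouped_z(
            pd.Series(polygenic, index=base.index)
        )

        # -- blood micronutrients (supply tiers -> concentrations) --------
        tau = config.nutrient_noise
        denom = np.sqrt(1.0 + tau ** 2)
        q0, q1 = _TIER_QUANTILES
        mn = scheme.micronutrients
        for nutrient in MICRONUTRIENTS:
            propensity = (
                lat["blood_micronutrients"].to_numpy()
                + tau * rng.standard_normal(n)
            ) / denom
            p = stats.norm.cdf(propensity)
            if nutrient == "ferritin":
                thr = np.array([
                    mn.ferritin_threshold(s, a)
                    for s, a in zip(base["sex"], base["age"])
                ])
                conc = np.where(p < q0, _FERRITIN_BELOW * thr,
                                _FERRITIN_ABOVE * thr)
            else:
                reps = _TIER_CONCENTRATIONS[nutrient]
                conc = np.select([p < q0, p < q1], [reps[0], reps[1]], reps[2])
            rate = config.missing_rate.get(nutrient, 0.0)
            if rate > 0:
                conc = np.where(rng.random(n) < rate, np.nan, conc)
            base[nutrient] = conc
        raw_scores = pd.Series(
            [score_blood_micronutrients_record(row, scheme)
             for _, row in base.iterrows()],
            index=base.index,
        )
        expected["blood_micronutrients"] = grouped_z(raw_scores)
        expected["micronutrient_raw"] = raw_scores

        # -- basic cognitive function (ZVT + d2-R) ------------------------
        e_cog = grouped_z(lat["basic_cognitive_function"])
        m_zvt, s_zvt = norms.lookup("zvt_mean", "*", "*", "*")
        m_con, s_con = norms.lookup("d2r_concentration", "*", "*", "*")
        m_wr, s_wr = norms.lookup("d2r_wrong", "*", "*", "*")
        base["zvt_mean"] = m_zvt + s_zvt * e_cog
        wrong = np.clip(m_wr + s_wr * rng.standard_normal(n), 0.0, None)
        concentration = m_con + s_con * e_cog
        base["d2r_wrong"] = wrong
        base["d2r_correct"] = concentration + wrong
        expected["basic_cognitive_function"] = 2.0 * e_cog

        # -- mental health (PHQ-4 + PSS-4 items) --------------------------
        phq_mean = np.clip(2.5 - 0.3 * lat["mental_health"], 1.0, 4.0)
        pss_mean = np.clip(3.0 - 0.4 * lat["mental_health"], 1.0, 5.0)
        for i in range(1, 5):
            base[f"phq4_{i}"] = phq_mean
        for i in range(1, 5):
            # scoring reverse-codes the positively worded items
            base[f"pss4_{i}"] = (
                6 - pss_mean if i in scheme.pss4_reverse_items else pss_mean
            )
        mh_raw = -(((phq_mean - 1) / 3) + ((pss_mean - 1) / 4)) / 2
        expected["mental_health"] = grouped_z(pd.Series(mh_raw, index=base.index))

        # -- social support (PASS-Q + MSPSS items) -------------------------
        pass_mean = np.clip(3.3 + 0.3 * lat["social_support"], 1.0, 5.0)
        mspss_mean = np.clip(3.5 + 0.3 * lat["social_support"], 1.0, 5.0)
        for i in range(1, 17):
            base[f"passq_{i}"] = pass_mean
        for i in range(1, 13):
            base[f"mspss_{i}"] = mspss_mean
        ss_raw = (pass_mean + mspss_mean) / 2
        expected["social_support"] = grouped_z(pd.Series(ss_raw, index=base.index))

        # -- training conditions (two 1-10 satisfaction items) -------------
        t_mean = np.clip(6.0 + 0.7 * lat["training_conditions"], 1.0, 10.0)
        base["train_cond_1"] = t_mean
        base["train_cond_2"] = t_mean
        expected["training_conditions"] = grouped_z(
            pd.Series(t_mean, index=base.index)
        )

    expected["expertise"] = expertise
    expected["elite"] = elite
    expected = expected[
        ["athlete_id", "sex", "age", "sport", "squad_level", *DOMAINS,
         "micronutrient_raw", "expertise", "elite"]
    ]

    from .io import COHORT_COLUMNS
    base = base[list(COHORT_COLUMNS)]
    return SyntheticCohort(cohort=base, scores=expected, config=config)


def write_fixture(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (one row per athlete, stable column order)."""
    from .io import write_cohort
    if len(cohort) == 0:
        raise ValidationError("refusing to write an empty cohort fixture")
    write_cohort(cohort, path)
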