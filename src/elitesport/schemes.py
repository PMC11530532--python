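"""Coding schemes and domain constants.

Everything an analyst may legitimately want to re-configure lives here as
plain data: the eight performance domains, the eight sport disciplines and
their speed/power component pairing, the sex-specific SNP panels for the
polygenic muscle-power score, the medical micronutrient cut-offs, and the
four-category expertise taxonomy. Each scheme can be overridden from a
YAML/JSON mapping with the same structure as the defaults.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# The eight standardized predictor domains, in canonical order.
DOMAINS: tuple[str, ...] = (
    "muscular_strength",
    "lower_body_dynamics",
    "muscle_power_genetics",
    "blood_micronutrients",
    "basic_cognitive_function",
    "mental_health",
    "social_support",
    "training_conditions",
)

SPORTS: tuple[str, ...] = (
    "basketball_3x3",
    "ice_hockey",
    "volleyball",
    "artistic_gymnastics",
    "trampoline_gymnastics",
    "rhythmic_gymnastics",
    "table_tennis",
    "modern_pentathlon",
)

SEXES: tuple[str, ...] = ("female", "male")
SQUAD_LEVELS: tuple[str, ...] = ("junior", "senior")

# Lower-body dynamics: discipline-specific (speed component, power component).
# Speed is tapping frequency [Hz] or a 10 m sprint [s]; power is a jump
# measure (countermovement jump height [cm], drop-jump reactive strength
# index, or sergeant jump height [cm]).
SPORT_COMPONENTS: dict[str, tuple[str, str]] = {
    "basketball_3x3": ("tapping", "cmj_height"),
    "volleyball": ("tapping", "cmj_height"),
    "artistic_gymnastics": ("tapping", "cmj_height"),
    "trampoline_gymnastics": ("tapping", "cmj_height"),
    "rhythmic_gymnastics": ("tapping", "drop_jump_rsi"),
    "table_tennis": ("tapping", "drop_jump_rsi"),
    "ice_hockey": ("sprint_10m", "cmj_height"),
    "modern_pentathlon": ("tapping", "sergeant_height"),
}

# Components where a *smaller* raw value means better performance.
LOWER_IS_BETTER: frozenset[str] = frozenset({"sprint_10m"})

# Sex-specific SNP panels for the additive polygenic muscle-power score.
SNP_PANELS: dict[str, tuple[str, ...]] = {
    "male": ("rs699", "rs6942022", "rs1544410"),          # AGT, IP6K3, VDR
    "female": ("rs1815739", "rs699", "rs7247312",          # ACTN3, AGT, HSD17B14
               "rs1801394", "rs660339"),                   # MTRR, UCP2
}
ALL_SNPS: tuple[str, ...] = (
    "rs699", "rs6942022", "rs1544410",
    "rs1815739", "rs7247312", "rs1801394", "rs660339",
)

MICRONUTRIENTS: tuple[str, ...] = ("vitamin_b12", "vitamin_d", "folic_acid", "ferritin")


@dataclass(frozen=True)
class MicronutrientScheme:
    """Medical cut-offs for the 0/1/2 supply coding.

    Three-tier nutrients carry (substandard_below, standard_at_or_above):
    concentrations below the first bound code 0, at or above the second
    code 2, in between code 1. A value equal to a printed lower bound of a
    tier belongs to that tier. Ferritin is binary (0 or 2) with sex- and
    age-dependent thresholds; the adult threshold applies from age 18.
    """

    vitamin_b12: tuple[float, float] = (211.0, 350.0)   # pg/ml
    vitamin_d: tuple[float, float] = (20.0, 30.0)       # ng/ml
    folic_acid: tuple[float, float] = (3.15, 6.8)       # ng/ml
    ferritin_thresholds: dict = field(default_factory=lambda: {
        ("male", "under_18"): 14.0,   # ng/ml
        ("male", "adult"): 20.0,
        ("female", "under_18"): 13.0,
        ("female", "adult"): 10.0,
    })
    adult_age: float = 18.0

    def ferritin_threshold(self, sex: str, age: float) -> float:
        band = "adult" if age >= self.adult_age else "under_18"
        return self.ferritin_thresholds[(sex, band)]


@dataclass(frozen=True)
class ExpertiseScheme:
    """Four-category sport-expertise taxonomy.

    A: highest competition level (1-4), B: success at that level (0-4),
    C: years of experience at the highest level coded 1-4,
    D: years with international senior top rankings coded 0-4.
    The printed year brackets share boundaries; a year count on a shared
    boundary takes the higher code, and years beyond the top bracket clamp
    to 4. Expertise = A + B + C + D, in [2, 16]; athletes at or above
    ``elite_threshold`` are classified elite.
    """

    # (lower bound in years, code), evaluated top-down; first match wins.
    years_highest_brackets: tuple[tuple[float, int], ...] = (
        (8.0, 4), (5.0, 3), (3.0, 2), (0.0, 1),
    )
    years_senior_brackets: tuple[tuple[float, int], ...] = (
        (7.0, 3), (3.0, 2), (0.0, 1),
    )
    # the top senior bracket is "> 10 years", strictly exclusive at 10
    years_senior_top: float = 10.0
    elite_threshold: int = 13

    def code_years_highest(self, years: float) -> int:
        if years < 0:
            raise ValueError(f"years_highest must be >= 0, got {years}")
        for bound, code in self.years_highest_brackets:
            if years >= bound:
                return code
        return self.years_highest_brackets[-1][1]

    def code_years_senior(self, years: float) -> int:
        if years < 0:
            raise ValueError(f"years_international_senior must be >= 0, got {years}")
        if years == 0:
            return 0
        if years > self.years_senior_top:
            return 4
        for bound, code in self.years_senior_brackets:
            if years >= bound:
                return code
        return 1  # any nonzero experience below 3 years


@dataclass(frozen=True)
class PolygenicScheme:
    """Per-SNP effect-allele weights for the polygenic score, by sex.

    Defaults are unit weights on effect-allele counts (the source study's
    weights are not published alongside the panel definition).
    """

    weights: dict = field(default_factory=lambda: {
        sex: {snp: 1.0 for snp in panel} for sex, panel in SNP_PANELS.items()
    })

    def panel(self, sex: str) -> dict[str, float]:
        return self.weights[sex]


@dataclass(frozen=True)
class ScoringScheme:
    """Bundle of every configurable coding scheme used by the scorers."""

    micronutrients: MicronutrientScheme = field(default_factory=MicronutrientScheme)
    expertise: ExpertiseScheme = field(default_factory=ExpertiseScheme)
    polygenic: PolygenicScheme = field(default_factory=PolygenicScheme)
    sport_components: dict = field(default_factory=lambda: dict(SPORT_COMPONENTS))
    # PSS-4 positively worded items (1-based) reverse-coded before averaging;
    # set to () to disable.
    pss4_reverse_items: tuple[int, ...] = (2, 3)
    # Whether cognition / psychosocial z-standardization is grouped; the
    # default is whole-cohort standardization.
    cohort_level_groups: bool = True


def default_scheme_path() -> Path:
    """Path of the editable YAML copy of the package's default schemes."""
    return Path(__file__).parent / "data" / "default_scheme.yaml"


def load_scheme(path: str | Path) -> ScoringScheme:
    """Load a ScoringScheme from a YAML or JSON mapping of overrides."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    kwargs = {}
    if "micronutrients" in data:
        mn = dict(data["micronutrients"])
        if "ferritin_thresholds" in mn:
            mn["ferritin_thresholds"] = {
                (k.split("/")[0], k.split("/")[1]): float(v)
                for k, v in mn["ferritin_thresholds"].items()
            }
        for key in ("vitamin_b12", "vitamin_d", "folic_acid"):
            if key in mn:
                mn[key] = tuple(mn[key])
        kwargs["micronutrients"] = MicronutrientScheme(**mn)
    if "expertise" in data:
        ex = dict(data["expertise"])
        for key in ("years_highest_brackets", "years_senior_brackets"):
            if key in ex:
                ex[key] = tuple((float(a), int(b)) for a, b in ex[key])
        kwargs["expertise"] = ExpertiseScheme(**ex)
    if "polygenic" in data:
        kwargs["polygenic"] = PolygenicScheme(weights=data["polygenic"])
    if "sport_components" in data:
        kwargs["sport_components"] = {
            k: tuple(v) for k, v in data["sport_components"].items()
        }
    if "pss4_reverse_items" in data:
        kwargs["pss4_reverse_items"] = tuple(data["pss4_reverse_items"])
    return ScoringScheme(**kwargs)
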