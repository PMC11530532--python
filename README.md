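# elitesport

Multifactorial profiling of elite vs. semi-elite squad athletes.

Sports-expertise research is fragmented across subdisciplines: strength
diagnostics, motor performance, genetics, nutrition status, cognition, and
psychosocial factors are usually studied in isolation. `elitesport`
implements a complete cross-domain analysis pipeline for cohorts of
national-squad athletes (here: eight Olympic sports, two squad levels) in
which every athlete is described by **eight standardized domain scores**:

| domain | raw inputs | standardization |
|---|---|---|
| muscular strength | grip strength / body mass [N/kg] | z within sex × squad × sport |
| lower-body dynamics | sport-specific speed (tapping Hz or 10 m sprint s) + power (CMJ, drop-jump RSI, or sergeant jump) | each component z within sex × squad, sprint negated, summed |
| muscle-power genetics | sex-specific polygenic score (males: *AGT* rs699, *IP6K3* rs6942022, *VDR* rs1544410; females: *ACTN3* rs1815739, *AGT* rs699, *HSD17B14* rs7247312, *MTRR* rs1801394, *UCP2* rs660339) | z over cohort |
| blood micronutrients | B12, 25-OH-vitamin D, folic acid, ferritin coded 0/1/2 by medical cut-offs; score = 100·Σcodes/(2·n) | z over cohort |
| basic cognitive function | ZVT pages/min + d2-R (correct − wrong) | each z over cohort, summed |
| mental health | PHQ-4 and PSS-4 item means, common range, inverted | z over cohort |
| social support | PASS-Q and MSPSS item means averaged | z over cohort |
| training conditions | two 1–10 satisfaction items averaged | z over cohort |

The outcome is a **sport-expertise value** on a 2–16 taxonomy
(A: highest competition level 1–4, B: success at that level 0–4,
C: years at the highest level 1–4, D: years internationally ranked as a
senior 0–4); athletes with expertise ≥ 13 are *elite*, the rest
*semi-elite*.

On top of the scores the package provides:

* **group_regression** — four logistic models of elite status and four
  linear models of the continuous expertise value on the eight domains
  (± sex, age), with Wald tests, odds-ratio CIs, Nagelkerke's R², percent
  correctly classified, heteroscedasticity-aware standard errors
  (Breusch–Pagan → HC3; plus Shapiro–Wilk non-normality → HC4), and a
  diagnostic battery (Durbin–Watson, Breusch–Pagan, VIF, Cook's D,
  leverage, Studentized residuals, Box–Tidwell);
* **association_variance** — one-sided Pearson correlations between
  domains, a domain network (node size ∝ |β|, edges where r > .15), and a
  resampling variance null: 1,000 draws of elite-sized (22) semi-elite
  subsets position each domain's elite variance below / within / above the
  resampled range;
* **individual_profiles** — per-elite z-profiles with outlier flags
  (|z| > 1), sum scores, and an *ergodicity* label: whether an individual
  reproduces the group-level pattern (superior in cognition + dynamics +
  micronutrients for the linear pattern; cognition + micronutrients for
  the logistic one);
* **synthetic_cohort** — a seeded generator that draws latent domain
  vectors from a configurable correlation model (defaults plant the
  study's printed correlations, e.g. strength–dynamics r = .282), derives
  expertise from age + latent domains + noise, applies elite mean
  shifts/scales, and inverts the whole scoring pipeline to raw
  measurements so that scoring a generated cohort reproduces the planted
  scores to machine precision. The packaged norm table is fictional
  (plausible physiological values); real athlete data are confidential.

## Worked example

```python
import elitesport as es

syn = es.generate_cohort(es.CohortConfig(seed=1))      # 296 athletes
table = es.build_score_table(syn.cohort)               # eight z-scores each
fit = es.fit_logistic(table)                           # elite ~ 8 domains
print(fit.terms.set_index("term")[["B", "SE", "p"]].round(3))
print(f"Nagelkerke R2 = {fit.nagelkerke_r2:.3f}, "
      f"correctly classified = {fit.pct_correct:.1f}%")
```

prints (seed 1):

```
                              B     SE      p
const                    -3.648  0.524  0.000
muscular_strength         0.075  0.254  0.767
lower_body_dynamics      -0.034  0.129  0.792
muscle_power_genetics    -0.612  0.283  0.031
blood_micronutrients      1.828  0.608  0.003
basic_cognitive_function  0.368  0.132  0.005
mental_health             0.288  0.269  0.284
social_support           -0.209  0.241  0.387
training_conditions      -0.056  0.262  0.831
Nagelkerke R2 = 0.249, correctly classified = 92.2%
```

The two domains in which the generator planted elite superiority — blood
micronutrients (B = 1.83, p = .003) and basic cognitive function
(B = 0.37, p = .005) — are clearly significant; the remaining terms
fluctuate around zero (at this seed, genetics picks up a marginal
negative partial effect through its planted correlation with the
dynamics domain). Continuing,

```python
var = es.resample_semielite_variances(table, seed=1)
print(var.frame[["domain", "elite_var", "resampled_min",
                 "resampled_max", "position"]].round(3))
```

shows `blood_micronutrients` **below** the resampled semi-elite variance
range (elite athletes are more alike there) and `social_support` above it,
mirroring the planted within-group scales.

The same pipeline is scriptable from a shell:

```bash
elitesport report --seed 1 --out run1      # simulate → score → models →
                                           # correlations → variance →
                                           # network → profiles
elitesport score --cohort my_cohort.csv --out scored
```

Every run directory contains `provenance.json` (resolved config, hash,
seed, package version); identical configs reproduce identical artifacts
byte for byte.

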