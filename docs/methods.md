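# Methods

## The analysis model

Each athlete in a cohort of national-squad members is reduced to eight
superiority-oriented domain scores (larger = better) plus an integer
expertise value on a 2–16 taxonomy. The analysis then runs at three
levels:

1. **Group models.** Elite status (expertise ≥ 13, coded 1) is regressed
   on the eight domain scores by maximum-likelihood logistic regression,
   in four variants: no covariates, + sex (female = 1), + age, + sex and
   age. The continuous expertise value is regressed on the same designs by
   OLS. Because every predictor is a (composite of) z-score(s), the
   coefficients are directly comparable across domains.
2. **Structure.** Pairwise Pearson correlations between the eight scores
   (one-sided toward positive association, the direction implied by the
   superiority orientation; a negative observed r is reported with the
   attained one-sided p in its own direction and flagged), and a variance
   comparison between the 22-ish elite athletes and repeatedly resampled
   elite-sized semi-elite subsets.
3. **Individuals.** Per-elite z-profiles, answering whether any single
   athlete actually exhibits the pattern the group models suggest
   (ergodicity).

## Scoring details and conventions

* All z-standardization uses the sample SD (n − 1), matching the defaults
  of the statistics environments this style of analysis is usually run in.
* Standardization groups: relative grip strength within
  sex × squad × sport; the five lower-body components within sex × squad
  pooled over the sports that use the component; everything else over the
  whole cohort. A singleton or zero-variance group yields z = 0 plus a
  `DegenerateGroupWarning` rather than an error, so small cohorts remain
  usable; the emitted group census makes such cells auditable.
* The 10 m sprint z is negated before the lower-body composite is summed,
  so that the composite is superiority-oriented like every other domain.
* Two-variable composites (lower-body dynamics, basic cognitive function)
  are the *sum* of two component z-scores and therefore have SD ≈ 2, not
  1. They are deliberately not re-standardized; coefficients on these
  domains are per component-z-sum unit.
* Mental health: PHQ-4 (1–4) and PSS-4 (1–5) item means are min–max
  rescaled to [0, 1] (the simplest map to "an identical range"), averaged,
  and sign-inverted so that higher = better mental health. PSS-4 items 2
  and 3 are reverse-coded per the instrument's standard key; this is
  configurable off because some administrations pre-reverse them.
* Micronutrient coding: the printed "≥" tiers take the upper code, i.e.
  tier boundaries are upper-inclusive (B12 = 350 pg/ml codes 2; the
  suboptimal band is [211, 350)). Ferritin's binary threshold switches
  from the under-18 to the adult value at age 18. Missing nutrients drop
  out of both the numerator and denominator of
  100·Σcodes/(2·n_available); the score is missing only when all four are.
* Expertise year brackets overlap in print; shared boundaries resolve to
  the higher code (8 years at the highest level → C = 4; 3 senior years →
  D = 2), years beyond the top C bracket clamp to 4, and the top D bracket
  is strictly "> 10 years" (10.0 → D = 3). This resolution is
  deterministic and favors the athlete. The elite threshold (13) is a
  named configuration constant.
* Polygenic weights default to +1 per effect allele (the source weights
  are not published); a weight table per sex is configurable. Note that
  the polygenic raw score is z-standardized over the *whole* cohort even
  though the male and female panels have different ranges (3 vs 5 SNPs),
  so the genetics score absorbs a sex contrast; this follows the scored
  procedure as described rather than what one might consider cleaner
  (within-sex standardization), and it attenuates cross-domain
  correlations involving genetics by a predictable factor.

## Regression battery

* Logistic fits report per-term B, SE, Wald = (B/SE)², χ²(1) p, and 95%
  odds-ratio CIs exp(B ± 1.96·SE). Model fit: likelihood-ratio χ²,
  Nagelkerke R² = [1 − (L₀/L₁)^(2/n)] / [1 − L₀^(2/n)], and percent
  correctly classified at a 0.5 probability cut. Complete separation is
  detected (failed/singular fits, or |B| > 15 on a standardized predictor)
  and rejected naming the separating term; no penalized fallback is
  attempted.
* Linear fits use OLS coefficients with an SE policy: Breusch–Pagan
  p < .05 selects HC3; if the residuals additionally fail Shapiro–Wilk at
  α = .05, HC4. HC3 comes from statsmodels; HC4 is implemented directly as
  (XᵀX)⁻¹Xᵀ diag(eᵢ²/(1−hᵢᵢ)^δᵢ) X(XᵀX)⁻¹ with δᵢ = min(4, n·hᵢᵢ/p) and is
  cross-checked in the test suite against R's `sandwich::vcovHC(type="HC4")`.
* Diagnostics are report-only (no case exclusion): Durbin–Watson flagged
  outside [1.5, 2.5], Breusch–Pagan, VIF flagged > 10, |Studentized
  residual| > 3, leverage > 0.2, Cook's D ≥ 1. The Box–Tidwell linearity
  check shifts each z-scored predictor by (1 − min) to be strictly
  positive before adding x·ln(x) terms, since ln requires positivity and
  z-scores are negative half the time.
* Missing predictor values are handled by listwise deletion, keeping a
  single n across the model battery.

## Variance resampling and network

Each iteration draws `group_size` (default 22) semi-elite athletes without
replacement and records each domain's sample variance; mean, min, and max
over the (default 1,000) iterations form the reference range. The reading
"one variance per variable per iteration, summarized across iterations" is
the only one consistent with reporting a *range* of sampled variances.
The elite variance is computed once on all elites and labeled
below/within/above the range; no inferential variance test is attempted.
Resampling is unstratified (no sport/sex stratification), configurable.
Network edges require r > .15 strictly, per the reporting convention for
the correlation network; node size is |β| from the no-covariate linear
model.

## Individual profiles and ergodicity

Superiority means z > 0, i.e. above the whole-cohort mean — the cohort is
the reference population; the elite-group mean comparison is computed and
reported separately but does not drive the label. Outliers use strict
|z| > 1. An athlete is *ergodic-linear* if simultaneously superior in
basic cognitive function, lower-body dynamics, and blood micronutrients
(the domains the linear model flags), and *ergodic-logistic* if superior
in basic cognitive function and blood micronutrients; the first condition
set is a superset of the second, so ergodic-linear implies
ergodic-logistic, which the code asserts. Profile tables anonymize
athletes as "Athlete 01, 02, …" in order of descending sum score.

## The synthetic cohort

The generator works latent-first: an 8-vector per athlete from
MVN(0, R) with a configurable correlation matrix R (validated symmetric,
unit-diagonal, PSD; rejection names the offending eigenvalue). The default
R plants the study-level correlations: strength–dynamics .282,
genetics–dynamics .186, mental-health–support .277,
conditions–mental-health .305, conditions–support .386,
cognition–dynamics .116, genetics–support −.138.

**Expertise** is round(7.5 + 3.5·t) clipped to [2, 16], where t is a
unit-variance combination of standardized age (weight 0.75), latent
lower-body dynamics (0.25), and noise. This yields a strong age–expertise
dependence (seniors dominate the elite group) and about 22/296 elites in
expectation. The expertise value is decomposed into taxonomy inputs
(A, B, and representative year counts) that re-code to exactly the same
value, so the competition-history fields in the raw records are coherent
with the planted expertise.

**Elite superiority** is planted after elite determination: elites'
latents receive per-domain mean shifts (default +0.6 SD in basic cognitive
function and blood micronutrients) and within-group scale factors
(default 0.7 in those two domains — elites more alike — and 1.3 in social
support — elites more heterogeneous). The +0.6 default was chosen to
reproduce the qualitative profile structure of such cohorts: roughly
two-thirds to three-quarters of elites superior in each flagged domain and
only a minority jointly superior in all three linear-pattern domains,
while still making the two planted domains (and only those) detectable by
the logistic battery. Sharper contrasts (e.g. +0.9) are used explicitly in
the parameter-recovery simulations.

**Inversion.** For each domain, the latents are first standardized within
exactly the groups the scorers use, then mapped to native units through a
norm table (mean + SD per measurement with group wildcards). Because the
scorers re-standardize within the same groups, scoring a generated cohort
reproduces the planted scores to machine precision for the continuous
domains. Two domains pass through an explicit discretization: the
polygenic score maps the latent's normal quantile to an allele-count total
via a binomial(2k, ½) quantile (then fills individual SNPs), and the
micronutrient score maps per-nutrient propensities (latent plus noise,
τ = 0.5) to supply tiers at the 15% / 50% population quantiles, with
tier-representative concentrations. For these two, the generator stores
the post-discretization expected score, and scoring recovers *that*
exactly. Missingness (default zero) applies only to micronutrient
concentrations, the one score with an explicit missing-data rule.

**The norm table is fictional.** It contains plausible physiological
means/SDs (e.g. relative grip strength 5.6 ± 0.9 N/kg for female
athletes, 10 m sprint 1.80 ± 0.10 s for male athletes) chosen for
realistic native units only; no real group norms are published, and the
inversion construction makes the analysis results independent of these
values. Questionnaire items are set uniformly to their scale mean per
athlete (reverse-coded items mirrored), so within-scale item variance is
zero — a simplification that leaves every downstream statistic untouched
because only scale means enter the scores.

What the generator does *not* emulate: measurement error on top of the
latent structure (components of a composite are perfectly coupled by
default), non-normal latent distributions, item-level response styles,
missingness outside micronutrients, and any real athlete's data. Passing
tests therefore demonstrate correctness of the pipeline and the stated
statistical behavior under a known model — not empirical claims about real
cohorts. Cohort composition defaults to the printed per-sport/sex counts
(n = 296); the printed squad-level margins are inconsistent with the
per-sport table, so each (sport, sex) cell is split junior : senior ≈ 2 : 1,
approximating them.

## Numerical choices and test design

* Single `numpy.random.default_rng(seed)` stream per generation; the
  resampler takes its own seed. Identical config + seed ⇒ byte-identical
  artifacts.
* Sample variance/SD uses n − 1 throughout.
* Logistic classification cut: predicted probability ≥ 0.5.
* The odds-ratio CIs are the conventional exp(Wald interval). Published
  tables in this literature sometimes print CI columns that cannot be
  reproduced as exp(B ± 1.96·SE); this package makes no attempt to match
  such transformations.
* Simulation-based tests are derandomized with fixed seeds and sized to
  their purpose: 100 replicates at n = 296 for parameter recovery
  (power ≥ 80% planted vs ~5% elsewhere), 30 seeds for variance-range
  positioning, 1,000 replicates for null calibration. The t-test
  calibration check uses a continuous normal outcome, where the nominal
  level is exact; with the integer 2–16 outcome the tests run ~0.5
  percentage points hot, a genuine small-sample property of the
  heavy-tailed outcome, and the logistic Wald rates at 22 events are
  checked pooled across terms with binomial-width per-term bounds.

## Known limitations

* With ~22 elites and 8 predictors (events per variable < 3), logistic
  estimates are small-sample; separation is rejected rather than
  penalized.
* Pairwise-complete correlation matrices need not be exactly PSD under
  missingness (they are on complete data).
* The expertise decomposition returns one representative
  competition-history realization per expertise value, not the full
  variety of real careers.
* The supplementary discipline-specific competition-level coding table is
  represented only structurally (category A is taken as coded); its
  sport-specific content is configuration, not code.
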