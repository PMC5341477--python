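# Methods

## The substitution experiment

The unit of analysis is the person-day of a 24-h dietary recall.  Each
food record carries a respondent-designated eating occasion (meal, snack,
or beverage addition), a beverage flag, a snack-category label, an energy
value, a nutrient vector (total/saturated/mono/polyunsaturated fat,
alpha-linolenic acid, protein, carbohydrate, fiber, sodium, potassium,
magnesium) and a food-pattern component vector (FPED-style cup/oz/tsp
equivalents plus solid fats and oils in grams).  Occasion labels are taken
as given in the input; the package never re-derives them.

A substitution model removes the *eligible* records of a person-day and
adds a single composite-nut record of exactly the removed energy, with
nutrients and components scaled linearly from the composite's per-100-kcal
profile.  Eligibility: solid food, snack occasion, not itself a tree nut;
Model 2 additionally exempts whole-fruit categories, non-starchy-vegetable
categories (a configurable list; the packaged snack vocabulary has no
vegetable category, so it defaults to empty), and records whose grain
content is more than 50% whole grain.  Beverages and beverage additions
are never replaced.  A person whose solid snacks are exclusively tree
nuts (evaluated across both recall days; snack beverages disregarded) is
exempt person-wide.  Persons with no snacks are not flagged exempt — the
distinction is observationally irrelevant, since there is nothing to
replace either way.  The composite record is emitted with occasion =
snack and a tree-nut flag, which makes substitution idempotent: re-running
a model on modified data changes nothing.

Energy conservation is exact by construction (the composite record's
energy is the eligible sum), which is the defining isocaloric contract:
the experiment isolates diet composition from energy intake.

## The composite nut

Each nut item contributes weight w_i = f_i / Σf_j, where f_i is its
(survey-weighted) frequency of consumption; the composite profile per
100 kcal is Σ w_i · profile_i, a convex combination, and its energy
density is the harmonic mean 100 / Σ(w_i · 100/d_i) so that mass
conversions remain consistent.  The almond-only variant restricts to
almond items before normalizing, so its weights are proportional to the
tree-nut weights on that subset.  The packaged item table
(`data/nut_items.csv`) is a synthetic fixture: frequencies are chosen to
reproduce the published seven largest composite weights with an almond
share of ~45%, and per-100-kcal profiles are transcribed from standard
food-composition values (salted and unsalted variants are distinct
items).  Users can supply their own table.

## Usual-intake model

Recall amounts Y_ij (person i, day j) are modeled on the Box-Cox scale
g(y; λ) = (y^λ − 1)/λ (natural log at λ = 0):

    g(Y_ij) = x_ij'β + u_i + ε_ij,  u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²)

with covariates intercept, weekend indicator, and recall-sequence
indicator (second recall; this also absorbs interview-mode effects as a
single indicator).  Fitting is maximum likelihood with survey weights
entering as frequency-type weights normalized to mean 1 (an approximation
that mirrors common practice).  β is profiled out by weighted GLS and the
compound-symmetric person blocks are inverted in closed form
(Sherman–Morrison), so each evaluation is O(n); (σ_u², σ_e²) are
optimized on the log scale by L-BFGS-B.  λ is selected by profile
likelihood over the grid {0, 0.05, …, 1}, with the Jacobian term
(λ − 1)Σw log y making likelihoods comparable across exponents.  At least
some persons must have two recalls or σ_u is unidentifiable (an error).

A person's usual intake is the within-person expectation of the
back-transform at reference covariates — weekdays weighted 5/7, weekends
2/7, first recall — computed by 9-point Gauss–Hermite quadrature over ε
(9 vs 21 points agree to <0.1% in all tested configurations).
Back-transform arguments outside the domain (1 + λz ≤ 0) truncate to 0
with a logged count; the truncated probability mass is negligible for
realistic parameters but makes the λ=1 "closed form" exact only to ~1e-4.
The population distribution is Monte Carlo over u ~ N(0, σ_u²);
percentiles 1–99 and percent above/below thresholds (sodium 2,300 mg/d,
fiber 25 g/d by default) are read from the draws.

Episodically consumed items (both zero and positive days) get a two-part
model: a mixed logistic for daily consumption probability (person random
intercept; marginal likelihood by 21-point Gauss–Hermite, Nelder–Mead
over the four parameters) and the amount model above on consumption days.
The parts are fitted independently — no cross-part random-effect
correlation; correlation is left as an extension point.  Usual intake is
usual probability × usual amount with independent random effects.  The
per-nutrient mode is user-configurable; suggested defaults treat fiber,
sodium, magnesium and the fats as ubiquitous and whole grains / ALA as
episodic when zero-inflated.

The pipeline reports population means and their BRR standard errors using
the survey-weighted mean of person-mean daily intakes (an unbiased,
cheap estimator of the usual-intake population mean); the fitted
measurement-error model supplies the distributions and
threshold-attainment percentages on full-sample weights.  Refitting the
mixed model under every replicate weight is supported in principle but
not done by default.

## HEI-2010

Scored by the population ratio method on first-recall records only: each
component density is (Σ w_i amount_i)/(Σ w_i energy_i) scaled to its
basis — per 1,000 kcal for most components, the (MUFA+PUFA)/SFA ratio for
fatty acids, and percent of energy for empty calories, computed as solid
fats × 9 kcal/g + added sugars × 16 kcal/tsp.  Adequacy components score
linearly from a lower anchor (0, except 1.2 for the fatty-acid ratio) to
the standard for maximum points; moderation components score linearly
from the standard for maximum points down to zero at the lower standard.
The numeric standards ship in `data/hei2010_standards.yaml` (per-1,000-kcal
anchors, e.g. sodium max at ≤1.1 g and zero at ≥2.0 g).  Persons with zero
day-1 energy are excluded with a logged count.  Legume-allocation rules
between the vegetable and protein components are not implemented; the
generator does not produce foods that would exercise them.

## Survey inference

Replicate weights follow Fay's balanced repeated replication for
two-PSU-per-stratum designs: strata are assigned to columns of a Hadamard
matrix (order = number of replicates, default 32, which must be a power
of two and at least the number of strata), and replicate r multiplies a
stratum's first PSU by (2 − ρ) or ρ according to the sign pattern, with
ρ = 0.7 by default.  ρ is implemented as the weight-perturbation factor
(the WesVar convention).  The variance of an estimator is
Σ_r(θ_r − θ)² / (R(1 − ρ)²); for a linear statistic this is algebraically
identical to the stratified two-PSU variance formula, which the tests
verify.  ρ = 1 degenerates to zero variance, handled exactly.

Modeled-vs-observed comparisons use t = (m₁ − m₀)/√(se₀² + se₁²) against
a standard normal reference (BRR degrees of freedom are unstated in
practice and large; a Student-t reference with user df is available).
The paired structure — the same persons underlie both datasets — is
deliberately ignored, which is conservative.  Relative changes are
classified, when p < 0.05, as marginal (|Δ| < 5%), modest/moderate
(5% ≤ |Δ| < 10%) or strong/dramatic (|Δ| ≥ 10%); exactly 5% is modest and
exactly 10% is strong, matching "10% is the cut-off for strong".

## Synthetic generator

The generator emulates the statistical structure the analysis relies on,
not any particular survey's microdata:

- Persons draw an age band (default: approximate US population shares over
  eight bands), a lognormal survey weight, a stratum/PSU assignment
  (round-robin over 16 strata × 2 PSUs), and one or two recall days
  (P(two) = 0.85).
- 76.9% of persons are snack consumers; a consumer's daily snack energy is
  lognormal with median 293 and mean 394 kcal/d (μ = ln 293,
  σ = √(2 ln(394/293))), multiplied by an age-band factor (children and
  younger adults snack more; factors normalized to population mean 1) and
  a lognormal day factor.  About 17% of snack energy is beverages
  (sugar-sweetened profile), which the substitution never touches.  Solid
  snack energy is split over 1 + Poisson-thinned snack events whose
  categories follow the published solid-snack calorie shares; each food's
  nutrients and components are category density profiles × energy
  (`data/snack_categories.csv`, a synthetic fixture of category-typical
  densities).  3% of persons snack exclusively on tree nuts.
- Background diet comes from three meal-profile archetypes (typical /
  prudent / convenience) with person- and day-level lognormal energy
  factors — i.e., day-to-day variation is log-scale normal, the λ = 0
  Box-Cox case.  A single weekend indicator per recall day is Bernoulli
  (2/7), the calendar frequency.
- For parameter-recovery work, `simulate_intakes` draws day-level intakes
  *directly* from a configured Box-Cox-normal truth (with optional
  two-part probability structure), and `truth_summary` integrates that
  truth analytically (Gauss–Hermite over the random effects; threshold
  crossings by root-finding on the monotone usual-amount curve), so
  recovery tests compare estimates to exact ground truth.

What the generator does *not* emulate: survey nonresponse and weight
calibration, correlations between snack category and person
characteristics beyond age, seasonal or secular trends, food-level
portion-size distributions, and within-category nutrient heterogeneity.
Passing tests therefore demonstrate that the algorithms are correct under
the declared statistical structure, not that the package reproduces any
particular survey's point estimates — those depend on the real microdata.

## Problem sizes and numerical choices

Test and acceptance runs use 300–4,000 synthetic persons (2,000 for
usual-intake recovery, 500 simulated populations for the type-I-error
check, 100 toy populations for the BRR-vs-closed-form check), sizes at
which the Monte-Carlo tolerances asserted in the tests are comfortably
identifiable.  The acceptance script runs the pipeline at 1,500 persons.
Other numerical choices: λ grid step 0.05; Gauss–Hermite 9 points for ε
(21 for the logistic marginal likelihood and 41 for analytic truth);
usual-intake Monte Carlo 50,000 draws (200,000 in the tighter tests);
variance components bounded at e^-30 below; ties at moderation anchors
score by the linear segment's closure (max at ≤ upper anchor, 0 at ≥
lower anchor).

## Known limitations

- Survey weights as frequency weights in the ML fit is an approximation;
  design-consistent pseudo-likelihood with replicate-weight refitting
  would be the fully rigorous route.
- The episodic model omits cross-part correlation, and ratio-type usual
  intakes (nutrient densities) and bivariate models are out of scope.
- HEI is population-level only; person-level HEI distributions are not
  computed (the population ratio method does not support them).
- The category-level exemption mapping (whole fruit, non-starchy
  vegetables) is a configuration choice; real food-code-level data would
  map more finely.
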