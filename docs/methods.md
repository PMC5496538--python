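# Methods

## The analysis model

The scientific question is whether a nursery-pollinating moth distributes its
eggs over female (F) and hermaphrodite (H) plants of a gynodioecious host in
proportion to the sex ratio, which traits drive any departure, and what egg
receipt costs the plant. The package implements the analysis at three
observation levels, matching three field designs:

* **stems** — multi-population transect records (sex, open flowers, egg and
  caterpillar counts, leaf/flower damage flags);
* **plants** — single-site whole-plant monitoring over four egg censuses
  with trait measurements, floral-part damage at two assessments, and
  end-of-season expanded/damaged fruit counts; a plant "received eggs" if
  any census was positive;
* **flower pairs** — age-matched egg/control flowers on the same plant with
  floral measurements, seed counts and fruit mass.

### Sex-bias tests

The proportional-receipt null says the expected female share of eggs equals
the female share of flowers (e.g. 30 female among 300 flowers → 10 % of
eggs). Departures are tested two ways:

1. **Binomial GLM**: egg receipt ~ sex (+ population + sex×population where
   several populations are surveyed), fitted by IRLS; the term of interest
   is judged by comparing two models that differ only in that term.
   Likelihood-ratio χ² (deviance difference) is the default for binomial
   responses; quasi-likelihood *F* — the deviance difference per df scaled
   by the Pearson dispersion of the fuller model, referred to
   F(Δdf, df_resid) — is used whenever a quasi family is requested. Both
   report shapes occur in practice in this literature, so both are exposed
   (`test_kind`), and the choice is recorded in each report.
2. **Stratified permutation**: the per-flower egg indicator is reshuffled
   uniformly within each population (B = 10,000 by default); the statistic
   is the number of hermaphrodite flowers bearing eggs summed over
   populations. Within a population the null law of the per-population
   count is hypergeometric, so the full null is available exactly as a
   convolution of hypergeometrics (`exact=True`); Monte-Carlo sampling
   remains the default because it is the procedure as practised.

Oviposition analyses use only populations where eggs were observed; damage
analyses use all surveyed populations.

### Two-tailed permutation p-values

p = 2 × (null mass more extreme than the observed statistic, in the
direction of its departure from the null mean), capped at 1. "More extreme"
**includes ties** by default (`extremity="inclusive"`). The strict variant
(ties excluded) is available and recorded in every result, but it is
anticonservative on discrete statistics: excluding the point mass at the
observed value removes up to a full pmf bin from each tail, and in
simulation at n = 200 flowers the strict rule rejected ~6 % of global-null
datasets versus ~4 % for the inclusive rule. Including ties is the standard
convention for permutation p-values and is what keeps the test at or below
its nominal level. The Monte-Carlo denominator is count/B (the doubled
empirical tail); the conservative (count+1)/(B+1) variant is available as
`denominator="plus_one"`.

For pairs, each of the n pairs swaps its egg/control labels with
probability ½ and the statistic is the mean within-pair difference; for
n ≤ 20 all 2ⁿ sign assignments are enumerated instead of sampled.

### Trait association and model selection

Backward elimination on egg receipt ~ {open flowers, stems, height,
projected area, flower depth, flower width, sex}: at each step the
removable term (interactions before their main effects) with the largest
p-value above α = 0.05 is dropped. After convergence each dropped term is
re-tested by adding it alone back to the final model, and each retained
term against the final model lacking it — so the reported table contains a
test for every candidate term against a common final model. The same
protocol with quasi-Poisson *F* tests produces the fruit-production table,
whose coefficients are also reported exponentiated (a one-unit increase in
a predictor multiplies expected fruit number by exp(β)).

### Numerical choices

* IRLS: mean-response initialization, convergence when the relative
  deviance change is < 1e-8, at most 100 iterations; weighted least-squares
  steps solved by `lstsq` for rank stability.
* Treatment contrasts, reference = first sorted level, so sex F/H yields an
  "if hermaphrodite" coefficient.
* Quasi dispersion φ̂ = Pearson χ²/df_resid; exactly 1 for plain binomial
  and Poisson.
* Rank deficiency is reported with the first offending term;
  non-convergence and apparent quasi-complete separation (|β| > 15 on the
  logit scale) are flagged in the fit and emitted as warnings, never
  silently returned.
* Degenerate inputs are flagged rather than guessed at: zero eggs overall
  (permutation p = 1), zero-variance paired differences (t undefined →
  error), one sex absent from an egg-receiving subset (error), pairs with
  a missing arm (dropped with a count).
* Clopper–Pearson endpoints use the beta-quantile form, which equals
  binomial tail inversion to machine precision and is exact at x = 0 and
  x = n.

## The synthetic generator

The generator exists so that every stage — including type-I error and
recovery behaviour of the *whole pipeline* — is checkable without field
data. It emulates:

* a two-sex population (`female_freq`, default 0.5; monitored plants are
  balanced by design);
* sexually dimorphic flower depth (F 16.0 mm, H 18.0 mm, SD 1.5 — a
  standardized difference ≈ 1.3) and deliberately non-dimorphic stem
  number; most other trait SDs are **assumed**, not field-derived, since
  only a few dispersions are reported in this literature;
* oviposition log-odds increasing in flower depth (0.40 per mm) and stem
  number (0.08 per stem) with a zero direct sex term, so that the realized
  hermaphrodite bias is entirely trait-mediated. These slopes are chosen by
  power analysis so that the central inference pattern (depth and stems
  retained, sex dropped) is recovered in ≳ 90 % of 160-plant replicates;
  the intercepts put stem-level receipt at ~18–33 % and season-long plant
  receipt near 30 %;
* mostly single-egg clutches: 71 % of egg-bearing stems carry exactly one
  egg (`single_egg_prob`);
* fruit production log-linear in traits (slopes 0.029/flower, 0.020/stem,
  0.029/cm height, −0.14/mm depth, 0.00011/cm² area) with
  negative-binomial noise, marginal mean anchored at 30.75 fruits;
* fruit predation means 3.85 (egg-receiving) vs 1.84 (non-receiving)
  fruits lost, strongly overdispersed;
* pair-level calyx-width offset of +0.50 mm for egg-receiving flowers
  (arm means ≈ 8.16 vs 7.66 mm with the default centre of 7.9 mm) and
  zero-seed probabilities 0.61 (egg) vs 0.39 (control).

**Flower-level oviposition.** Survey oviposition is resolved per flower:
each open flower independently receives an oviposition event with the
logistic probability implied by its stem's latent traits, and stem egg
counts are totals over flowers. This makes the per-flower egg indicators
exchangeable within a population under the global null — exactly the null
the stratified permutation test conditions on — so the permutation test is
calibrated by construction. Clutch sizes (how many eggs one event
deposits) never touch the indicators, which leaves them free to calibrate
the stem-level single-egg fraction exactly: the probability that a
single-event stem carries one egg is inverted from the realized share of
single-event stems. A stem-level Bernoulli formulation was rejected
because any deterministic expansion of stem egg counts onto flowers either
clusters eggs on same-sex flowers (anticonservative permutation test,
measured type-I ≈ 0.08) or under-disperses them (conservative, ≈ 0.02).

`survey_to_flowers` still expands stem-only tables when no flower table
exists, and the report marks such flower-level results as derived from an
approximation.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: spatial/transect autocorrelation, repeat
visits by individual moths (egg events are independent given traits),
within-plant trait correlation beyond the shared plant mean, multi-year
survival, caterpillar movement between plants, and observation error in
trait measurement. Calibration results certify the *tests*, not the
field-sampling process.

## Design choices that were genuinely open

* **Family for the eggs-given-receipt count test**: Poisson log-link on the
  egg-receiving subset; a documented choice, since count-model families are
  often unstated in this literature.
* **Stem-level response**: Bernoulli "received ≥ 1 egg" rather than the
  count, since the egg-count comparison is performed separately on the
  receiving subset.
* **Permutation statistic with multi-egg flowers**: flowers-with-eggs, not
  eggs; in generated data a flower's indicator is 1 regardless of clutch
  size.
* **Multiple testing**: none, matching field practice of reporting each test
  at raw α = 0.05; every report carries a footnote with the number of tests
  it contains.
* **Fruit-predation sensitivity**: the model is refit without the single
  largest fruits-lost value and the report flags any term whose
  significance at α flips — small overdispersed samples can hinge on one
  plant.
* **2015-style flower-level sex-bias analysis is refused** for monitoring
  data: plant records carry no flower-level egg mapping, so the pipeline
  simply has no such block rather than fabricating one.

## Problem sizes

Defaults mirror the study scale: 6 survey populations × 50 stems, 160
monitored plants, 36 flower pairs, B = 10,000 permutation replicates, 4
censuses. Simulation-based checks in the test suite use 2,000 replicates at
n = 200 (calibration) and 500 replicates at n = 160 (selection recovery);
moment checks use 50,000-unit datasets.

## Known limitations

* Quasi-likelihood F tests rely on the Pearson dispersion estimate; with
  very small residual df the dispersion itself is noisy.
* The permutation p-value convention (inclusive ties, count/B) is slightly
  conservative on coarse discrete nulls; exact enumeration is preferred
  whenever feasible and is the default for ≤ 20 pairs.
* Backward selection inherits the usual caveats of stepwise procedures
  (post-selection inference is not corrected); the protocol is implemented
  because it is the analysis being reproduced, not because it is optimal.
* No mixed models: population enters as a fixed factor and plant identity
  only through pairing, matching the reproduced analysis.
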