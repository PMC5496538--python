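# ovibias

Statistical analysis of **sex-biased oviposition by a nursery pollinator on a
gynodioecious host plant**, plus a synthetic-data generator that emulates the
underlying field designs so every stage of the analysis can be verified
end-to-end.

In a gynodioecious population, female (male-sterile) and hermaphrodite plants
coexist. A nursery-pollinating moth pollinates flowers but lays eggs whose
larvae eat fruits, so *which sex* receives the eggs matters for the relative
fitness of females and hermaphrodites — and thereby for the stability of the
breeding system. The package answers three questions on tabular survey data:

1. **Is egg receipt (or floral damage) sex-biased?** The null hypothesis is
   that eggs fall on the sexes *in proportion to the sex ratio*: in a
   population with female flower frequency *f*, females should receive a
   fraction *f* of eggs. Tested with binomial GLMs (likelihood-ratio χ² or
   quasi-likelihood *F*) and with a population-stratified permutation test
   that reshuffles the per-flower egg indicator within each population and
   counts hermaphrodite egg-bearing flowers.
2. **Which traits predict oviposition?** A binomial GLM of egg receipt on
   plant traits (open flowers, stems, height, projected area, flower depth,
   flower width) and sex, reduced by backward elimination at α = 0.05. If
   traits stay but sex drops, trait dimorphism explains the sex bias.
3. **What does oviposition cost?** Quasi-Poisson models of fruit production
   and fruit predation, paired *t* and within-pair sign-flip permutation
   tests of seed counts and fruit mass in age-matched egg/control flower
   pairs, and exact (Clopper–Pearson) binomial CIs on every reported
   proportion.

## Statistical core

* **Exact binomial CIs** — Clopper–Pearson via the beta-quantile form:
  `lower = B⁻¹(α/2; x, n−x+1)`, `upper = B⁻¹(1−α/2; x+1, n−x)`.
* **GLMs from scratch** — IRLS for binomial/quasibinomial (logit),
  Poisson/quasi-Poisson (log) and Gaussian families; LR χ² tests
  (`Δdeviance ~ χ²`) and quasi-likelihood *F* tests
  (`(Δdev/Δdf)/φ̂ ~ F`, with φ̂ the Pearson dispersion); backward selection
  that re-tests every dropped term against the final model.
* **Bespoke permutation constructions** — the stratified flower-level
  reshuffle (exact null available as a convolution of per-population
  hypergeometrics) and the within-pair label swap (exhaustive 2ⁿ sign-flip
  enumeration up to 20 pairs). Two-tailed p-values are twice the null mass
  at least as extreme as the observed statistic, capped at 1.
* **Synthetic generator** — a two-sex population with configurable female
  frequency, hermaphrodite-deeper flowers, oviposition log-odds increasing
  in flower depth and stem number (no direct sex effect by default), mostly
  single-egg clutches, trait-linked fruit production, egg-conditional fruit
  predation, and arm-specific zero-seed rates in flower pairs. A global-null
  configuration (`SimulationConfig.null()`) switches every effect off for
  calibration studies.

## Worked example

```sh
ovibias simulate --out data --seed 7
ovibias all --data-dir data --out results --seed 3
```

or in Python:

```python
import ovibias as ov

cfg = ov.SimulationConfig()                      # study-like defaults
survey, flowers = ov.generate_survey(cfg, with_flowers=True)
plants = ov.generate_monitoring(cfg)

report = ov.analyze_survey(survey, ov.AnalysisSettings(seed=1), flowers=flowers)
print(report["stem_level"]["sex"])
# {'kind': 'chisq', 'statistic': 8.4945..., 'df1': 1, 'df2': None,
#  'p_value': 0.003562..., 'term_tested': 'sex'}
print(report["flower_level"]["permutation"]["p_two_tailed"])
# 0.002
report_m = ov.analyze_monitoring(plants, ov.AnalysisSettings(seed=1))
print(report_m["trait_selection"]["retained"], report_m["trait_selection"]["dropped"])
# ['flower_depth', 'stems'] ['flower_width', 'height', 'open_flowers', 'projected_area', 'sex']
```

Read: stem-level egg receipt is hermaphrodite-biased (LR χ²₁ = 8.49,
p = .0036; the flower-level permutation agrees, p = .002), and among plant
traits only
flower depth and stem number predict oviposition while sex itself drops out —
the sexual dimorphism in flower depth, not sex per se, explains the bias.
Egg-receipt proportions in the report carry exact binomial CIs, e.g.
hermaphrodites 0.333 [0.259, 0.415] vs females 0.173 [0.116, 0.244] at
these settings.

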