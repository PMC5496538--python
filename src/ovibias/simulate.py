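"""Synthetic data generators emulating the three field designs.

Each generator is deterministic given ``config.rng_seed`` and returns a
dataframe conforming to the matching schema in :mod:`ovibias.datasets`.

The statistical structure is:

* sex drawn with probability ``female_freq`` (survey) or balanced by design
  (monitoring, mirroring equal numbers of monitored females and
  hermaphrodites);
* traits drawn per sex from :class:`~ovibias.config.TraitDistribution`
  (truncated normals for lengths, negative binomials for counts);
* egg receipt from a logistic model on the unit's traits plus an optional
  direct sex term;
* egg counts mostly 1 per oviposition event (``single_egg_prob``), else 2+;
* fruit production log-linear in plant traits with negative-binomial noise,
  fruit predation with means conditional on egg receipt;
* egg-receiving flowers in matched pairs get a calyx-width offset and a
  higher zero-seed probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig, TraitDistribution
from .datasets import validate_dataset

__all__ = [
    "generate_survey",
    "survey_to_flowers",
    "generate_monitoring",
    "generate_pairs",
    "marginal_receipt_probability",
]


def _draw_lengths(rng, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Normal draws truncated at zero (redraw negatives)."""
    x = rng.normal(mean, sd)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            break
        x[bad] = rng.normal(mean[bad], sd[bad])
    return np.maximum(x, 1e-6)


def _draw_counts(rng, mean: np.ndarray, sd: np.ndarray, minimum: float) -> np.ndarray:
    """Negative-binomial (or Poisson) draws with a lower truncation bound."""
    var = sd**2
    out = np.empty(mean.shape, dtype=np.int64)
    over = var > mean + 1e-12
    if over.any():
        m = mean[over]
        r = m**2 / (var[over] - m)
        p = r / (r + m)
        out[over] = rng.negative_binomial(r, p)
    if (~over).any():
        out[~over] = rng.poisson(mean[~over])
    for _ in range(1000):
        bad = out < minimum
        if not bad.any():
            break
        # redraw truncated values from the same per-element distribution
        if over.any():
            redo = bad & over
            if redo.any():
                m = mean[redo]
                r = m**2 / (var[redo] - m)
                out[redo] = rng.negative_binomial(r, r / (r + m))
        redo = bad & ~over
        if redo.any():
            out[redo] = rng.poisson(mean[redo])
    return np.maximum(out, int(minimum))


def _draw_trait(rng, trait: TraitDistribution, sex: np.ndarray) -> np.ndarray:
    is_f = sex == "F"
    mean = np.where(is_f, trait.female_mean, trait.herm_mean)
    sd = np.where(is_f, trait.female_sd, trait.herm_sd)
    if trait.kind == "count":
        return _draw_counts(rng, mean.astype(float), sd.astype(float), trait.minimum)
    return _draw_lengths(rng, mean, sd)


def _egg_counts(rng, receipt: np.ndarray, single_egg_prob: float) -> np.ndarray:
    """Egg counts given a Bernoulli receipt vector: 1 w.p. p, else 2+."""
    n = receipt.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    hit = receipt.astype(bool)
    single = rng.random(n) < single_egg_prob
    counts[hit & single] = 1
    multi = hit & ~single
    if multi.any():
        counts[multi] = 1 + rng.geometric(0.7, size=int(multi.sum()))
    return counts


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# --------------------------------------------------------------------- #
#                               survey                                  #
# --------------------------------------------------------------------- #

def generate_survey(
    config: SimulationConfig, with_flowers: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Stem-level transect survey across ``n_populations`` populations.

    Each stem carries a latent flower depth (drawn from its sex's
    distribution) that drives the oviposition logit; depth itself is not a
    survey field, matching a design where stem surveys record sex, open
    flowers, egg/caterpillar counts and damage flags only.

    Oviposition is resolved at the flower level: every open flower on a
    stem independently receives an oviposition event with the logistic
    probability implied by the stem's latent traits, and an event deposits
    one egg with probability ``single_egg_prob``, else 2+.  Stem egg counts
    are the totals over flowers.  Under the global-null configuration the
    per-flower egg indicators are therefore exchangeable within a
    population, which is exactly the null the stratified flower-level
    permutation test conditions on.

    With ``with_flowers=True`` also returns the flower-level table holding
    the true per-flower egg indicators.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_units * config.n_populations
    population = np.repeat(
        [f"P{i + 1}" for i in range(config.n_populations)], config.n_units
    )
    sex = np.where(rng.random(n) < config.female_freq, "F", "H").astype(object)
    open_flowers = _draw_trait(rng, config.trait_params["stem_open_flowers"], sex)
    depth = _draw_trait(rng, config.trait_params["flower_depth"], sex)

    c = config.ovi_coefs
    logit = (
        c["intercept_survey"]
        + c.get("flower_depth", 0.0) * depth
        + c.get("open_flowers", 0.0) * open_flowers
        + c.get("sex", 0.0) * (sex == "H")
    )
    k = open_flowers.astype(np.int64)
    stem_of_flower = np.repeat(np.arange(n), k)
    event = rng.random(stem_of_flower.size) < _sigmoid(logit)[stem_of_flower]
    events_per_stem = np.bincount(stem_of_flower, weights=event, minlength=n).astype(np.int64)
    # Clutch sizes leave the flower egg *indicators* untouched, so they are
    # free to calibrate the stem-level single-egg fraction: stems with one
    # oviposition event carry one egg with probability s (else a multi-egg
    # clutch in that flower), where s is inverted from the realized share of
    # single-event stems so that P(exactly 1 egg | stem egged) hits
    # single_egg_prob.
    n_one = int((events_per_stem == 1).sum())
    n_any = int((events_per_stem >= 1).sum())
    s = 1.0 if n_one == 0 else min(1.0, config.single_egg_prob * n_any / n_one)
    eggs = events_per_stem.copy()
    multi = (events_per_stem == 1) & (rng.random(n) >= s)
    eggs[multi] += rng.geometric(0.7, size=n)[multi]
    # extra clutch eggs sit in the stem's (unique) event flower
    extra = np.where(multi, eggs - 1, 0)
    flower_eggs = event.astype(np.int64) * (1 + extra[stem_of_flower])

    caterpillars = rng.poisson(config.caterpillar_rate, size=n)
    leaf_p = np.where(sex == "F", config.damage_probs["leaf"]["F"], config.damage_probs["leaf"]["H"])
    flower_p = np.where(sex == "F", config.damage_probs["flower"]["F"], config.damage_probs["flower"]["H"])
    df = pd.DataFrame(
        {
            "population": population,
            "sex": sex,
            "open_flowers": open_flowers,
            "eggs": eggs,
            "caterpillars": caterpillars,
            "leaf_damage": (rng.random(n) < leaf_p).astype(np.int64),
            "flower_damage": (rng.random(n) < flower_p).astype(np.int64),
        }
    )
    survey = validate_dataset(df, "survey")
    if not with_flowers:
        return survey
    flowers = pd.DataFrame(
        {
            "population": population[stem_of_flower],
            "stem_id": np.char.add("S", (stem_of_flower + 1).astype(str)).astype(object),
            "sex": sex[stem_of_flower],
            "egg": (flower_eggs >= 1).astype(np.int64),
        }
    )
    return survey, validate_dataset(flowers, "flowers")


def survey_to_flowers(survey: pd.DataFrame) -> pd.DataFrame:
    """Approximate a flower table from stem records alone.

    Within a stem, ``min(eggs, open_flowers)`` flowers are marked as egg
    bearing (a stem with more eggs than flowers yields all-egg flowers).
    Use this only when no true flower-level table exists: when several eggs
    on a stem came from one multi-egg clutch this expansion overstates the
    number of egged flowers and clusters them on one sex, so flower-level
    tests on the expansion are approximate.  Generated datasets carry the
    true per-flower indicators (``generate_survey(..., with_flowers=True)``).
    """
    survey = validate_dataset(survey, "survey")
    k = survey["open_flowers"].to_numpy(dtype=np.int64)
    e = np.minimum(survey["eggs"].to_numpy(dtype=np.int64), k)
    idx = np.repeat(np.arange(len(survey)), k)
    # first e_i flowers of each stem carry the eggs
    pos = np.arange(idx.size) - np.repeat(np.concatenate(([0], np.cumsum(k)[:-1])), k)
    flowers = pd.DataFrame(
        {
            "population": survey["population"].to_numpy()[idx],
            "stem_id": np.char.add("S", (idx + 1).astype(str)).astype(object),
            "sex": survey["sex"].to_numpy()[idx],
            "egg": (pos < e[idx]).astype(np.int64),
        }
    )
    return validate_dataset(flowers, "flowers")


# --------------------------------------------------------------------- #
#                             monitoring                                #
# --------------------------------------------------------------------- #

def generate_monitoring(config: SimulationConfig) -> pd.DataFrame:
    """Whole-plant monitoring records with censuses, damage and fruit counts.

    Sexes are balanced by design (``round(n_plants * female_freq)`` females).
    Egg receipt is drawn independently per census from the logistic model on
    plant traits; a plant "ever received eggs" if any census is positive.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)
    n = config.n_plants
    n_f = int(round(n * config.female_freq))
    sex = np.array(["F"] * n_f + ["H"] * (n - n_f), dtype=object)

    traits = {
        name: _draw_trait(rng, config.trait_params[name], sex)
        for name in (
            "stems", "height", "projected_area", "open_flowers",
            "flower_depth", "flower_width",
        )
    }

    c = config.ovi_coefs
    logit = c["intercept_census"] + c.get("sex", 0.0) * (sex == "H")
    for name, x in traits.items():
        logit = logit + c.get(name, 0.0) * x
    p_census = _sigmoid(logit)

    egg_by_census = rng.random((config.n_censuses, n)) < p_census
    eggs_total = np.zeros(n, dtype=np.int64)
    for j in range(config.n_censuses):
        eggs_total += _egg_counts(rng, egg_by_census[j], config.single_egg_prob)
    ever = egg_by_census.any(axis=0)

    pp = config.predation_params
    lost_mean = np.where(ever, pp["lost_mean_egg"], pp["lost_mean_noegg"])
    r_lost = pp["lost_dispersion"]
    fruits_damaged = rng.negative_binomial(r_lost, r_lost / (r_lost + np.maximum(lost_mean, 1e-9)))

    fc = config.fruit_coefs
    log_mu = np.zeros(n)
    for name, x in traits.items():
        log_mu += fc.get(name, 0.0) * x
    log_mu += fc.get("sex", 0.0) * (sex == "H") + fc.get("oviposition", 0.0) * ever
    # intercept anchors the marginal mean at total_mean: scale out the
    # sample mean of the multiplicative trait term (handles the Jensen gap
    # between exp(E[.]) and E[exp(.)] without distributional assumptions)
    rel = np.exp(log_mu - log_mu.mean())
    mu = pp["total_mean"] * rel / rel.mean()
    r_tot = pp["total_dispersion"]
    fruits_expanded = rng.negative_binomial(r_tot, r_tot / (r_tot + mu))

    data = {
        "plant_id": np.char.add("MSH", (np.arange(n) + 1).astype(str)).astype(object),
        "sex": sex,
        "stems": traits["stems"],
        "height": traits["height"],
        "projected_area": traits["projected_area"],
        "open_flowers": traits["open_flowers"],
        "flower_depth": traits["flower_depth"],
        "flower_width": traits["flower_width"],
    }
    for j in range(config.n_censuses):
        data[f"egg_c{j + 1}"] = egg_by_census[j].astype(np.int64)
    data["ever_egg"] = ever.astype(np.int64)
    data["eggs_total"] = eggs_total
    for dmg in ("bud", "calyx", "petal", "ovary"):
        p = np.where(sex == "F", config.damage_probs[dmg]["F"], config.damage_probs[dmg]["H"])
        for a in (1, 2):
            data[f"{dmg}_damage_a{a}"] = (rng.random(n) < p).astype(np.int64)
    data["fruits_expanded"] = fruits_expanded
    data["fruits_damaged"] = fruits_damaged
    return validate_dataset(pd.DataFrame(data), "plants")


# --------------------------------------------------------------------- #
#                                pairs                                  #
# --------------------------------------------------------------------- #

_PAIR_TRAITS = {
    "floral_face_width": "flower_width",
    "flower_length": "flower_length",
    "calyx_width": "calyx_width",
    "calyx_length": "calyx_length",
    "tube_opening": "tube_opening",
}


def generate_pairs(config: SimulationConfig, n_pairs: int | None = None) -> pd.DataFrame:
    """Age-matched egg/control flower pairs on individual plants (long form).

    Flower traits combine a plant-level value (between-plant SD from
    ``trait_params``) with within-plant noise; the egg-receiving arm's calyx
    width gets ``pair_params['calyx_offset']`` added.  Seed counts are zero
    with arm-specific probability, otherwise truncated-normal counts; fruit
    mass is recorded only for flowers that set seed.
    """
    config.validate()
    if n_pairs is None:
        n_pairs = config.n_pairs
    if n_pairs < 1:
        raise ConfigError(f"n_pairs must be >= 1, got {n_pairs}")
    rng = np.random.default_rng(config.rng_seed + 2)
    sex = np.where(rng.random(n_pairs) < config.female_freq, "F", "H").astype(object)
    frac = config.pair_params["within_sd_frac"]

    rows: dict[str, np.ndarray] = {}
    for col, trait_name in _PAIR_TRAITS.items():
        trait = config.trait_params[trait_name]
        plant_val = _draw_trait(rng, trait, sex)
        within_sd = (
            config.pair_params["calyx_within_sd"]
            if col == "calyx_width"
            else frac * 0.5 * (trait.female_sd + trait.herm_sd)
        )
        egg_val = plant_val + rng.normal(0.0, within_sd, n_pairs)
        ctl_val = plant_val + rng.normal(0.0, within_sd, n_pairs)
        if col == "calyx_width":
            egg_val = egg_val + config.pair_params["calyx_offset"]
        rows[col] = (np.maximum(egg_val, 1e-6), np.maximum(ctl_val, 1e-6))

    def _seeds(p_zero: float) -> np.ndarray:
        zero = rng.random(n_pairs) < p_zero
        raw = rng.normal(config.seed_count_params["mean"], config.seed_count_params["sd"], n_pairs)
        counts = np.maximum(np.round(raw), 1).astype(np.int64)
        return np.where(zero, 0, counts)

    def _mass(seeds: np.ndarray) -> np.ndarray:
        raw = rng.normal(config.fruit_mass_params["mean"], config.fruit_mass_params["sd"], n_pairs)
        mass = np.maximum(raw, 1e-3)
        return np.where(seeds > 0, mass, np.nan)

    seeds_egg = _seeds(config.zero_seed_probs["egg"])
    seeds_ctl = _seeds(config.zero_seed_probs["control"])
    mass_egg = _mass(seeds_egg)
    mass_ctl = _mass(seeds_ctl)

    def _arm(is_egg: bool) -> pd.DataFrame:
        i = 0 if is_egg else 1
        d = {
            "pair_id": np.char.add("PR", (np.arange(n_pairs) + 1).astype(str)).astype(object),
            "plant_id": np.char.add("MSH", (np.arange(n_pairs) + 1).astype(str)).astype(object),
            "population": np.repeat("MSH", n_pairs).astype(object),
            "sex": sex,
            "egg": np.full(n_pairs, 1 if is_egg else 0, dtype=np.int64),
        }
        for col in _PAIR_TRAITS:
            d[col] = rows[col][i]
        d["seeds"] = seeds_egg if is_egg else seeds_ctl
        d["fruit_mass"] = mass_egg if is_egg else mass_ctl
        return pd.DataFrame(d)

    out = (
        pd.concat([_arm(True), _arm(False)], ignore_index=True)
        .sort_values(["pair_id", "egg"], ascending=[True, False], kind="stable")
        .reset_index(drop=True)
    )
    return validate_dataset(out, "pairs")


# --------------------------------------------------------------------- #
#                    closed-form generator diagnostics                  #
# --------------------------------------------------------------------- #

def _count_pmf(trait: TraitDistribution, sex: str) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the (truncated) count distribution up to a far tail."""
    from scipy import stats

    m, s = trait.mean(sex), trait.sd(sex)
    ks = np.arange(int(trait.minimum), int(m + 12 * s) + 2)
    var = s**2
    if var > m:
        r = m**2 / (var - m)
        pmf = stats.nbinom.pmf(ks, r, r / (r + m))
    else:
        pmf = stats.poisson.pmf(ks, m)
    return ks, pmf / pmf.sum()


def marginal_receipt_probability(
    config: SimulationConfig, sex: str, level: str = "stem", n_quad: int = 80
) -> float:
    """Marginal egg-receipt probability for one sex in the survey design.

    ``level="flower"``: the per-flower oviposition-event probability
    integrated over the latent flower-depth normal (Gauss-Hermite).
    ``level="stem"``: the probability a stem bears any egg, additionally
    integrating 1 - (1 - q)^k over the open-flower count distribution.
    Serves as an independent closed-form check on the Monte-Carlo generator.
    """
    if sex not in ("F", "H"):
        raise ConfigError(f"sex must be 'F' or 'H', got {sex!r}")
    if level not in ("stem", "flower"):
        raise ConfigError(f"level must be 'stem' or 'flower', got {level!r}")
    depth = config.trait_params["flower_depth"]
    m, s = depth.mean(sex), depth.sd(sex)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    d = m + s * nodes
    c = config.ovi_coefs

    flowers = config.trait_params["stem_open_flowers"]
    fw_slope = c.get("open_flowers", 0.0)
    ks, k_pmf = _count_pmf(flowers, sex)
    base = c["intercept_survey"] + c.get("sex", 0.0) * (sex == "H")
    total = 0.0
    for k, w_k in zip(ks, k_pmf):
        q = _sigmoid(base + fw_slope * k + c.get("flower_depth", 0.0) * d)
        if level == "flower":
            # flower-level probability weighted by flowers per stem
            total += w_k * k * float(np.sum(weights * q))
        else:
            total += w_k * float(np.sum(weights * (1.0 - (1.0 - q) ** k)))
    if level == "flower":
        total /= float(np.sum(ks * k_pmf))
    return total
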