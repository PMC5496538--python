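"""Full analysis pipeline: sex-bias, trait-association and outcome tests.

The pipeline mirrors a three-part field study of nursery-pollinator
oviposition on a gynodioecious host:

* ``analyze_survey``      — stem- and flower-level sex-bias tests across
  populations (binomial GLMs, stratified permutation), egg-count test among
  receiving stems, leaf/flower damage-bias tests, proportions with exact
  binomial CIs;
* ``analyze_monitoring``  — plant-level sex bias, backward selection of
  traits predicting oviposition, per-trait sexual-dimorphism tests,
  quasi-Poisson fruit-production and fruit-predation models (the latter
  with a leave-one-out sensitivity flag for a single extreme value),
  per-census egg-receipt proportions;
* ``analyze_pairs``       — per-trait paired t-tests and within-pair
  permutation tests of seed count and fruit mass, zero-seed proportions.

Oviposition analyses use only populations where eggs were observed; damage
analyses use all populations.  Reports are plain JSON-serializable dicts in
which every proportion carries its CI and every stochastic result its seed.
"""

from __future__ import annotations

import dataclasses
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binomial import clopper_pearson, proportion_table
from .datasets import validate_dataset
from .glm import (
    GLMError,
    ModelSpec,
    backward_select,
    eggs_given_receipt_test,
    exponentiate_report,
    fit_glm,
    lr_test,
)
from .permutation import (
    ResamplingError,
    flower_sexbias_permutation,
    paired_swap_permutation,
    paired_t,
)
from .simulate import survey_to_flowers

__all__ = [
    "AnalysisSettings",
    "expected_null_share",
    "analyze_survey",
    "analyze_monitoring",
    "analyze_pairs",
    "run_all",
    "to_jsonable",
]

_MONITOR_TRAITS = (
    "open_flowers",
    "stems",
    "height",
    "projected_area",
    "flower_depth",
    "flower_width",
)
_PAIR_TRAITS = (
    "floral_face_width",
    "flower_length",
    "calyx_width",
    "calyx_length",
    "tube_opening",
)
_SMALL_PAIR_N = 15  # below this the permutation test is the reported one


@dataclass
class AnalysisSettings:
    """Shared analysis options; recorded verbatim in every report."""

    alpha: float = 0.05
    B: int = 10_000
    seed: int | None = None
    test_kind: str = "chisq"      # for binomial LR tests; quasi families use F
    extremity: str = "inclusive"
    denominator: str = "plain"
    ci_level: float = 0.95
    permutation_exact: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def to_jsonable(obj):
    """Recursively convert results (dataclasses, numpy, frames) to JSON types."""
    if hasattr(obj, "to_dict") and not isinstance(obj, pd.DataFrame):
        return to_jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return [to_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    return str(obj)


def expected_null_share(n_female_flowers: int, n_herm_flowers: int, n_eggs: int) -> dict:
    """Expected per-sex egg counts when eggs fall in proportion to sex ratio.

    The no-bias null: a population that is 10% female should receive 10% of
    the eggs on females.  Returns shares and expected egg counts per sex.
    """
    n_f, n_h, e = int(n_female_flowers), int(n_herm_flowers), int(n_eggs)
    if n_f < 0 or n_h < 0 or e < 0:
        raise ValueError("counts must be nonnegative")
    total = n_f + n_h
    if total < 1:
        raise ValueError("need at least one flower")
    share_f = n_f / total
    return {
        "female_share": share_f,
        "herm_share": 1.0 - share_f,
        "expected_female_eggs": share_f * e,
        "expected_herm_eggs": (1.0 - share_f) * e,
        "n_eggs": e,
    }


# --------------------------------------------------------------------- #
#                               helpers                                 #
# --------------------------------------------------------------------- #

def _term_test(data, response, family, base_terms, term, kind):
    """Type-II style test of one term given the others."""
    others = tuple(t for t in base_terms if t != term)
    full = fit_glm(ModelSpec(response, others + (term,), family), data)
    reduced = fit_glm(ModelSpec(response, others, family), data)
    return lr_test(reduced, full, kind), full


def _selection_table(sel, data: pd.DataFrame) -> list[dict]:
    """Per-term rows (coefficient, exponentiated coefficient, test) from a
    backward-selection result, dropped terms refit alongside the final model."""
    rows = []
    link = sel.final.spec.link
    exp_ok = link in ("log", "logit")

    def coef_entries(fit, term):
        prefix = term
        out = {
            k: v
            for k, v in fit.coefficients.items()
            if k == prefix or k.startswith(f"{prefix}[")
        }
        return out

    for term, test in sel.retained.items():
        coefs = coef_entries(sel.final, term)
        rows.append(
            {
                "term": term,
                "status": "retained",
                "coefficients": coefs,
                "exp_coefficients": {k: float(np.exp(v)) for k, v in coefs.items()} if exp_ok else None,
                "test": test.to_dict(),
            }
        )
    for term, test in sel.dropped.items():
        aug_fit = fit_glm(sel.final.spec.add(term), data)
        coefs = coef_entries(aug_fit, term)
        rows.append(
            {
                "term": term,
                "status": "dropped",
                "coefficients": coefs,
                "exp_coefficients": {k: float(np.exp(v)) for k, v in coefs.items()} if exp_ok else None,
                "test": test.to_dict(),
            }
        )
    return rows


def _catch(fn, *args, **kwargs):
    """Run a test, returning either its result or a recorded error."""
    try:
        return {"result": fn(*args, **kwargs), "error": None}
    except (GLMError, ResamplingError, ValueError) as e:
        return {"result": None, "error": str(e)}


# --------------------------------------------------------------------- #
#                             survey analysis                           #
# --------------------------------------------------------------------- #

def analyze_survey(
    survey: pd.DataFrame,
    settings: AnalysisSettings | None = None,
    flowers: pd.DataFrame | None = None,
) -> dict:
    """Stem- and flower-level sex-bias analysis of a multi-population survey.

    When a true flower-level table is available pass it as ``flowers``;
    otherwise the stem records are expanded with
    :func:`~ovibias.simulate.survey_to_flowers` (approximate for multi-egg
    stems, and noted as such in the report).
    """
    settings = settings or AnalysisSettings()
    survey = validate_dataset(survey, "survey")
    if len(survey) == 0:
        raise GLMError("empty survey dataset")
    survey = survey.copy()
    survey["stem_egg"] = (survey["eggs"].astype(np.int64) >= 1).astype(np.int64)

    egg_pops = sorted(
        survey.loc[survey["stem_egg"] == 1, "population"].unique()
    )
    ovi = survey[survey["population"].isin(egg_pops)].reset_index(drop=True)
    kind = settings.test_kind
    report: dict = {
        "analysis": "survey",
        "n_stems": int(len(survey)),
        "populations": sorted(survey["population"].unique()),
        "egg_bearing_populations": list(map(str, egg_pops)),
        "settings": settings.to_dict(),
    }

    # ---- stem-level sex bias ---------------------------------------- #
    multi_pop = len(egg_pops) >= 2
    base = ("sex", "population") if multi_pop else ("sex",)
    stem_block: dict = {"response": "stem_egg", "family": "binomial", "kind": kind}
    sex_test, _ = _term_test(ovi, "stem_egg", "binomial", base, "sex", kind)
    stem_block["sex"] = sex_test.to_dict()
    if multi_pop:
        pop_test, _ = _term_test(ovi, "stem_egg", "binomial", base, "population", kind)
        stem_block["population"] = pop_test.to_dict()
        both_sexes = ovi.groupby("population")["sex"].nunique()
        if (both_sexes < 2).any():
            stem_block["interaction"] = None
            stem_block["interaction_note"] = (
                "interaction dropped: single-sex population(s) "
                f"{sorted(both_sexes.index[both_sexes < 2])}"
            )
            _warnings.warn(stem_block["interaction_note"], stacklevel=2)
        else:
            full = fit_glm(
                ModelSpec("stem_egg", ("sex", "population", "sex:population"), "binomial"), ovi
            )
            mains = fit_glm(ModelSpec("stem_egg", ("sex", "population"), "binomial"), ovi)
            stem_block["interaction"] = lr_test(mains, full, kind).to_dict()
    report["stem_level"] = stem_block

    # ---- flower-level sex bias -------------------------------------- #
    if flowers is None:
        flowers = survey_to_flowers(ovi)
        flower_source = "expanded_from_stems"
    else:
        flowers = validate_dataset(flowers, "flowers")
        flowers = flowers[flowers["population"].isin(egg_pops)].reset_index(drop=True)
        flower_source = "observed"
    fl_block: dict = {"n_flowers": int(len(flowers)), "source": flower_source}
    fl_base = ("sex", "population") if multi_pop else ("sex",)
    fl_sex, _ = _term_test(flowers, "egg", "binomial", fl_base, "sex", kind)
    fl_block["glm_sex"] = fl_sex.to_dict()
    perm = flower_sexbias_permutation(
        flowers,
        B=settings.B,
        seed=None if settings.seed is None else settings.seed + 11,
        extremity=settings.extremity,
        denominator=settings.denominator,
        exact=settings.permutation_exact,
    )
    fl_block["permutation"] = perm.to_dict()
    n_f = int((flowers["sex"] == "F").sum())
    n_h = int((flowers["sex"] == "H").sum())
    fl_block["null_share"] = expected_null_share(n_f, n_h, int(flowers["egg"].sum()))
    report["flower_level"] = fl_block

    # ---- egg counts among receiving stems --------------------------- #
    report["eggs_given_receipt"] = _catch(eggs_given_receipt_test, ovi, "eggs", "sex")
    if report["eggs_given_receipt"]["result"] is not None:
        report["eggs_given_receipt"]["result"] = report["eggs_given_receipt"]["result"].to_dict()
    egged = survey[survey["stem_egg"] == 1]
    n_single = int((egged["eggs"] == 1).sum())
    if len(egged):
        report["single_egg"] = clopper_pearson(n_single, len(egged), settings.ci_level).to_dict()

    # ---- proportions with CIs --------------------------------------- #
    report["proportions"] = {
        "egg_receipt_by_pop_sex": to_jsonable(
            proportion_table(ovi, "stem_egg", ["population", "sex"], settings.ci_level)
        ),
        "egg_receipt_by_sex": to_jsonable(
            proportion_table(ovi, "stem_egg", "sex", settings.ci_level)
        ),
    }

    # ---- damage bias (all populations) ------------------------------ #
    damage: dict = {}
    dmg_base = ("sex", "population") if survey["population"].nunique() >= 2 else ("sex",)
    for col in ("leaf_damage", "flower_damage"):
        block = {}
        t, _ = _term_test(survey, col, "binomial", dmg_base, "sex", kind)
        block["sex"] = t.to_dict()
        if len(dmg_base) == 2:
            t, _ = _term_test(survey, col, "binomial", dmg_base, "population", kind)
            block["population"] = t.to_dict()
        block["by_sex"] = to_jsonable(proportion_table(survey, col, "sex", settings.ci_level))
        damage[col] = block
    report["damage"] = damage
    return report


# --------------------------------------------------------------------- #
#                          monitoring analysis                          #
# --------------------------------------------------------------------- #

def analyze_monitoring(plants: pd.DataFrame, settings: AnalysisSettings | None = None) -> dict:
    """Plant-level sex bias, trait selection, fruit production and predation."""
    settings = settings or AnalysisSettings()
    plants = validate_dataset(plants, "plants")
    if len(plants) == 0:
        raise GLMError("empty plant dataset")
    plants = plants.copy()
    for col in ("stems", "open_flowers", "eggs_total", "fruits_expanded", "fruits_damaged"):
        plants[col] = plants[col].astype(np.int64)
    kind = settings.test_kind
    report: dict = {
        "analysis": "monitoring",
        "n_plants": int(len(plants)),
        "settings": settings.to_dict(),
    }

    # (a) sex bias in ever receiving an egg
    sex_test, _ = _term_test(plants, "ever_egg", "binomial", ("sex",), "sex", kind)
    report["sex_bias"] = sex_test.to_dict()

    # (b) backward selection over traits + sex for oviposition
    sel = backward_select(
        ModelSpec("ever_egg", _MONITOR_TRAITS + ("sex",), "binomial"),
        plants,
        alpha=settings.alpha,
        kind=kind,
    )
    report["trait_selection"] = {
        "retained": sorted(sel.retained),
        "dropped": sorted(sel.dropped),
        "table": to_jsonable(_selection_table(sel, plants)),
        "history": sel.history,
    }

    # (c) sexual dimorphism per trait (gaussian LR F)
    dimorphism = {}
    for trait in _MONITOR_TRAITS:
        t, full = _term_test(plants, trait, "gaussian", ("sex",), "sex", "f")
        means = plants.groupby("sex")[trait].mean()
        dimorphism[trait] = {
            "test": t.to_dict(),
            "mean_female": float(means.get("F", np.nan)),
            "mean_herm": float(means.get("H", np.nan)),
        }
    report["dimorphism"] = dimorphism

    # (d) fruit production: quasi-Poisson with backward selection (F tests)
    fruit_sel = backward_select(
        ModelSpec("fruits_expanded", _MONITOR_TRAITS + ("sex", "ever_egg"), "quasipoisson"),
        plants,
        alpha=settings.alpha,
        kind="f",
    )
    report["fruit_production"] = {
        "retained": sorted(fruit_sel.retained),
        "dropped": sorted(fruit_sel.dropped),
        "table": to_jsonable(_selection_table(fruit_sel, plants)),
        "dispersion": fruit_sel.final.dispersion,
        "exponentiated": to_jsonable(exponentiate_report(fruit_sel.final)),
        "mean_fruits": float(plants["fruits_expanded"].mean()),
    }

    # (e) fruit predation: fruits lost ~ oviposition + sex with LOO sensitivity
    def predation_tests(df):
        out = {}
        for term in ("ever_egg", "sex"):
            t, _ = _term_test(df, "fruits_damaged", "quasipoisson", ("ever_egg", "sex"), term, "f")
            out[term] = t.to_dict()
        return out

    pred: dict = {"tests": predation_tests(plants)}
    means = plants.groupby("ever_egg")["fruits_damaged"].mean()
    pred["mean_lost_egg"] = float(means.get(1, np.nan))
    pred["mean_lost_noegg"] = float(means.get(0, np.nan))
    idx_extreme = int(plants["fruits_damaged"].idxmax())
    loo = plants.drop(index=idx_extreme).reset_index(drop=True)
    pred_loo = predation_tests(loo)
    flips = [
        term
        for term in ("ever_egg", "sex")
        if (pred["tests"][term]["p_value"] < settings.alpha)
        != (pred_loo[term]["p_value"] < settings.alpha)
    ]
    pred["sensitivity"] = {
        "excluded_max_fruits_damaged": int(plants.loc[idx_extreme, "fruits_damaged"]),
        "tests_without_extreme": pred_loo,
        "significance_flips": flips,
        "flagged": bool(flips),
    }
    report["fruit_predation"] = pred

    # (f) per-census egg-receipt proportions
    census_cols = [c for c in plants.columns if c.startswith("egg_c")]
    report["proportions"] = {
        "ever_egg_by_sex": to_jsonable(proportion_table(plants, "ever_egg", "sex", settings.ci_level)),
        "by_census": {
            c: to_jsonable(proportion_table(plants, c, "sex", settings.ci_level))
            for c in census_cols
        },
    }

    # egg counts among receiving plants
    report["eggs_given_receipt"] = _catch(eggs_given_receipt_test, plants, "eggs_total", "sex")
    if report["eggs_given_receipt"]["result"] is not None:
        report["eggs_given_receipt"]["result"] = report["eggs_given_receipt"]["result"].to_dict()

    # damage bias at each assessment
    damage = {}
    for dmg in ("bud", "calyx", "petal", "ovary"):
        for a in (1, 2):
            col = f"{dmg}_damage_a{a}"
            t = _catch(lambda c=col: _term_test(plants, c, "binomial", ("sex",), "sex", kind)[0])
            damage[col] = {
                "test": t["result"].to_dict() if t["result"] is not None else None,
                "error": t["error"],
                "by_sex": to_jsonable(proportion_table(plants, col, "sex", settings.ci_level)),
            }
    report["floral_damage"] = damage
    return report


# --------------------------------------------------------------------- #
#                             pair analysis                             #
# --------------------------------------------------------------------- #

def analyze_pairs(
    pairs: pd.DataFrame,
    settings: AnalysisSettings | None = None,
    egg_removed: bool = False,
) -> dict:
    """Paired-flower outcome analysis (traits, seeds, fruit mass)."""
    settings = settings or AnalysisSettings()
    pairs = validate_dataset(pairs, "pairs")
    n_pairs = int(pairs["pair_id"].nunique())
    if n_pairs < 2:
        raise ResamplingError("need at least 2 flower pairs")
    report: dict = {
        "analysis": "pairs",
        "n_pairs": n_pairs,
        "egg_removed": bool(egg_removed),
        "settings": settings.to_dict(),
    }

    trait_tests = {}
    for trait in _PAIR_TRAITS:
        res = _catch(paired_t, pairs, trait)
        trait_tests[trait] = {
            "t": res["result"].to_dict() if res["result"] is not None else None,
            "error": res["error"],
        }
    report["trait_tests"] = trait_tests

    outcomes = {}
    for i, value in enumerate(("seeds", "fruit_mass")):
        t_res = _catch(paired_t, pairs, value)
        perm_res = _catch(
            paired_swap_permutation,
            pairs,
            value,
            B=settings.B,
            seed=None if settings.seed is None else settings.seed + 23 + i,
            extremity=settings.extremity,
            denominator=settings.denominator,
        )
        n_complete = (
            perm_res["result"].n_used if perm_res["result"] is not None else 0
        )
        primary = (
            "permutation" if (egg_removed or n_complete < _SMALL_PAIR_N) else "t"
        )
        outcomes[value] = {
            "t": t_res["result"].to_dict() if t_res["result"] is not None else None,
            "t_error": t_res["error"],
            "permutation": perm_res["result"].to_dict() if perm_res["result"] is not None else None,
            "permutation_error": perm_res["error"],
            "n_complete_pairs": n_complete,
            "primary_test": primary,
        }
    report["outcome_tests"] = outcomes

    # zero-seed proportions per arm
    zero_seed = {}
    for arm, label in ((1, "egg"), (0, "control")):
        sub = pairs[(pairs["egg"] == arm) & pairs["seeds"].notna()]
        if len(sub):
            x = int((sub["seeds"] == 0).sum())
            zero_seed[label] = clopper_pearson(x, len(sub), settings.ci_level).to_dict()
    report["zero_seed"] = zero_seed

    wide = pairs.pivot_table(index="pair_id", columns="egg", values="seeds", aggfunc="first", observed=True)
    complete = wide.dropna()
    if len(complete):
        both_zero = int(((complete[1] == 0) & (complete[0] == 0)).sum())
        both_seed = int(((complete[1] > 0) & (complete[0] > 0)).sum())
        report["pair_outcomes"] = {
            "n_complete": int(len(complete)),
            "both_zero": clopper_pearson(both_zero, len(complete), settings.ci_level).to_dict(),
            "both_seeds": clopper_pearson(both_seed, len(complete), settings.ci_level).to_dict(),
        }
    return report


# --------------------------------------------------------------------- #
#                               run all                                 #
# --------------------------------------------------------------------- #

def run_all(
    survey: pd.DataFrame,
    plants: pd.DataFrame,
    pairs: pd.DataFrame,
    settings: AnalysisSettings | None = None,
    flowers: pd.DataFrame | None = None,
    egg_removed_pairs: bool = False,
) -> dict:
    """Run every analysis block and assemble one report."""
    settings = settings or AnalysisSettings()
    report = {
        "survey": analyze_survey(survey, settings, flowers=flowers),
        "monitoring": analyze_monitoring(plants, settings),
        "pairs": analyze_pairs(pairs, settings, egg_removed=egg_removed_pairs),
        "settings": settings.to_dict(),
    }
    n_tests = _count_tests(report)
    report["multiple_testing_note"] = (
        f"{n_tests} hypothesis tests reported at raw alpha = {settings.alpha}; "
        "no multiplicity correction applied."
    )
    return report


def _count_tests(obj) -> int:
    if isinstance(obj, dict):
        hit = 1 if ("p_value" in obj or "p_two_tailed" in obj) else 0
        return hit + sum(_count_tests(v) for v in obj.values())
    if isinstance(obj, (list, tuple)):
        return sum(_count_tests(v) for v in obj)
    return 0


def collect_proportions(report: dict) -> pd.DataFrame:
    """Flatten every CI-bearing proportion in a report into one table."""
    rows: list[dict] = []

    def walk(obj, path):
        if isinstance(obj, dict):
            if {"successes", "trials", "lower", "upper"} <= set(obj):
                row = {"block": path}
                for k in ("population", "sex", "successes", "trials", "proportion", "lower", "upper"):
                    if k in obj:
                        row[k] = obj[k]
                rows.append(row)
            else:
                for k, v in obj.items():
                    walk(v, f"{path}/{k}" if path else str(k))
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                walk(v, path)

    walk(report, "")
    return pd.DataFrame(rows)
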