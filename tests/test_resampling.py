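"""Permutation tests: enumeration oracles, stratification, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovibias import (
    ResamplingError,
    flower_sexbias_permutation,
    paired_swap_permutation,
    paired_t,
)
from ovibias.permutation import exact_sexbias_null

from conftest import make_flowers, make_pairs


def enumerate_placements(n, n_herm, n_eggs):
    """Brute-force null pmf of the herm-egg count over all C(n, e) placements."""
    counts = {}
    herm = set(range(n_herm))
    total = 0
    for placement in itertools.combinations(range(n), n_eggs):
        k = len(herm.intersection(placement))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    ks = np.arange(max(counts) + 1)
    pmf = np.array([counts.get(int(k), 0) / total for k in ks])
    return ks, pmf


def oracle_p(obs, ks, pmf, extremity="inclusive"):
    mean = float(np.sum(ks * pmf))
    if obs == mean:
        return 1.0
    if obs > mean:
        mask = ks >= obs if extremity == "inclusive" else ks > obs
    else:
        mask = ks <= obs if extremity == "inclusive" else ks < obs
    return min(1.0, 2.0 * float(pmf[mask].sum()))


# -------------------- stratified flower permutation ------------------- #

def test_enumeration_matches_hypergeometric_closed_form():
    """The brute-force placement enumeration equals the hypergeometric pmf
    for single-population instances, and the package's exact null equals both."""
    for n, h, e in [(6, 3, 2), (8, 5, 3), (10, 4, 3), (7, 7, 2)]:
        ks, pmf = enumerate_placements(n, h, e)
        hg = stats.hypergeom.pmf(ks, n, h, e)
        np.testing.assert_allclose(pmf, hg, atol=1e-12)
        fl = make_flowers(n, h, e, obs_herm_eggs=min(e, h))
        support, pkg_pmf = exact_sexbias_null(fl)
        np.testing.assert_allclose(pkg_pmf[: len(pmf)], pmf, atol=1e-12)


def test_monte_carlo_close_to_enumeration():
    """MC p at B = 10,000 within 3 binomial SEs of the exhaustive p for all
    single-population instances with <= 10 flowers and <= 3 eggs."""
    checked = 0
    exceed_3se = 0
    for n in range(2, 11):
        for e in range(1, min(3, n) + 1):
            for h in range(0, n + 1):
                lo, hi = max(0, e - (n - h)), min(e, h)
                for obs in range(lo, hi + 1):
                    fl = make_flowers(n, h, e, obs)
                    ks, pmf = enumerate_placements(n, h, e)
                    p_ex = oracle_p(obs, ks, pmf)
                    res = flower_sexbias_permutation(fl, B=10_000, seed=1000 + checked)
                    tail = p_ex / 2.0
                    se = 2.0 * np.sqrt(max(tail * (1 - tail), 1e-12) / 10_000)
                    err = abs(res.p_two_tailed - p_ex)
                    # hard bound well beyond MC noise; count 3-SE exceedances
                    # separately since ~0.3% of instances exceed 3 SE by chance
                    assert err <= 5 * se + 1e-9, (n, h, e, obs)
                    exceed_3se += err > 3 * se + 1e-9
                    checked += 1
    assert checked > 100
    # with ~150 comparisons the expected number of 3-SE exceedances is ~0.4
    assert exceed_3se <= 3


def test_exact_flag_and_p_match_oracle():
    fl = make_flowers(9, 5, 3, 3)
    res = flower_sexbias_permutation(fl, exact=True)
    ks, pmf = enumerate_placements(9, 5, 3)
    assert res.exact
    assert res.p_two_tailed == pytest.approx(oracle_p(3.0, ks, pmf), abs=1e-12)


def test_stratification_preserves_population_egg_totals():
    """Multi-population exact null equals the convolution of per-population
    hypergeometrics — each population keeps its own egg total."""
    f1 = make_flowers(6, 4, 2, 2, population="P1")
    f2 = make_flowers(5, 2, 1, 0, population="P2")
    fl = pd.concat([f1, f2], ignore_index=True)
    support, pmf = exact_sexbias_null(fl)
    k1, p1 = enumerate_placements(6, 4, 2)
    k2, p2 = enumerate_placements(5, 2, 1)
    np.testing.assert_allclose(pmf, np.convolve(p1, p2), atol=1e-12)
    # Monte-Carlo statistic never exceeds per-population maxima summed
    res = flower_sexbias_permutation(fl, B=3000, seed=5)
    assert res.null_stats.max() <= min(2, 4) + min(1, 2)
    assert res.null_stats.min() >= 0


def test_all_herm_degenerate():
    """Every flower hermaphrodite: the statistic is constant, p = 1."""
    fl = make_flowers(6, 6, 2, 2)
    res = flower_sexbias_permutation(fl, B=500, seed=0)
    assert (res.null_stats == res.observed_stat).all()
    assert res.p_two_tailed == 1.0


def test_zero_eggs_degenerate():
    fl = make_flowers(5, 3, 0, 0)
    with pytest.warns(UserWarning, match="zero eggs"):
        res = flower_sexbias_permutation(fl, B=100, seed=0)
    assert res.p_two_tailed == 1.0


def test_permutation_determinism():
    fl = make_flowers(40, 22, 9, 8)
    a = flower_sexbias_permutation(fl, B=2000, seed=77)
    b = flower_sexbias_permutation(fl, B=2000, seed=77)
    np.testing.assert_array_equal(a.null_stats, b.null_stats)
    assert a.p_two_tailed == b.p_two_tailed


def test_hermaphrodite_bias_detected():
    """With strongly hermaphrodite-biased eggs the test rejects."""
    fl = make_flowers(300, 150, 40, 36)
    res = flower_sexbias_permutation(fl, B=10_000, seed=3)
    assert res.p_two_tailed < 0.01


# ------------------------ within-pair label swap ---------------------- #

def test_pair_swap_exact_matches_signflip_oracle():
    """Exact path equals the independent 2^n sign-flip enumeration, and the
    MC path is within 3 SEs of it, for n <= 12 pairs."""
    rng = np.random.default_rng(21)
    for n in (2, 5, 10, 12):
        d = np.round(rng.normal(3, 8, size=n))
        pr = make_pairs(d)
        res = paired_swap_permutation(pr, "seeds")
        assert res.exact and res.B == 2**n
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
        null = signs @ d / n
        obs = d.mean()
        mean = null.mean()
        if obs == mean:
            p_or = 1.0
        else:
            mask = null >= obs if obs > mean else null <= obs
            p_or = min(1.0, 2.0 * mask.mean())
        assert res.p_two_tailed == pytest.approx(p_or, abs=1e-12)
        mc = paired_swap_permutation(pr, "seeds", B=10_000, seed=int(n), exact=False)
        tail = p_or / 2
        se = 2 * np.sqrt(max(tail * (1 - tail), 1e-12) / 10_000)
        assert abs(mc.p_two_tailed - p_or) <= 3 * se + 1e-9


def test_identical_arms_give_p_one():
    pr = make_pairs(np.zeros(8))
    res = paired_swap_permutation(pr, "seeds")
    assert res.observed_stat == 0.0 and res.p_two_tailed == 1.0


def test_missing_arm_dropped_with_warning():
    pr = make_pairs(np.array([2.0, -1.0, 4.0, 3.0, 1.0]))
    pr.loc[(pr.pair_id == "PR2") & (pr.egg == 0), "fruit_mass"] = np.nan
    with pytest.warns(UserWarning, match="dropped 1 pair"):
        res = paired_swap_permutation(pr, "fruit_mass")
    assert res.n_used == 4


def test_too_few_pairs_rejected():
    pr = make_pairs(np.array([1.0]))
    with pytest.raises(ResamplingError, match="2 complete pairs"):
        paired_swap_permutation(pr, "seeds")


def test_swap_type_one_error_nominal():
    """Zero true difference: rejection rate ~5% (exact path, 10 pairs)."""
    rng = np.random.default_rng(31)
    rej = 0
    reps = 500
    for _ in range(reps):
        d = np.round(rng.normal(0, 10, size=10))
        res = paired_swap_permutation(make_pairs(d), "seeds")
        rej += res.p_two_tailed < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rej / reps - 0.05) < 3.5 * se + 0.01


# ------------------------------ paired t ------------------------------ #

def test_paired_t_matches_scipy_and_df():
    rng = np.random.default_rng(41)
    d = rng.normal(0.5, 1.0, size=36)
    pr = make_pairs(np.round(d * 10))
    res = paired_t(pr, "seeds")
    assert res.df == 35
    diffs = np.round(d * 10)
    ref = stats.ttest_1samp(diffs, 0.0)
    assert res.t_stat == pytest.approx(float(ref.statistic), abs=1e-9)
    assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_paired_t_zero_variance_flagged():
    pr = make_pairs(np.full(6, 3.0))
    with pytest.raises(ResamplingError, match="zero variance"):
        paired_t(pr, "seeds")


def test_paired_t_null_p_uniform():
    """Symmetric zero-mean differences give uniform p-values (KS check)."""
    rng = np.random.default_rng(51)
    ps = []
    for _ in range(300):
        d = rng.normal(0, 5, size=15)
        pr = make_pairs(np.round(d))
        if np.var(np.round(d)) == 0:
            continue
        ps.append(paired_t(pr, "seeds").p_value)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01
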