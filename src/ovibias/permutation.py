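"""Permutation tests and paired t-tests for the flower-level analyses.

Two bespoke constructions:

* a population-stratified reshuffle of the per-flower egg indicator, with
  the number of hermaphrodite egg-bearing flowers (summed over populations)
  as the statistic — the null keeps each population's egg total fixed, so
  under a single population the null law of the statistic is exactly
  hypergeometric, and the multi-population exact null is a convolution of
  hypergeometrics;
* a within-pair label swap for age-matched egg/control flower pairs, with
  the mean within-pair difference as the statistic; for up to 20 pairs the
  2^n sign assignments are enumerated exactly instead of sampled.

Two-tailed p-values follow the doubled-tail rule: twice the null mass more
extreme than the observed statistic in the direction of its departure from
the null mean, capped at 1.  ``extremity="inclusive"`` counts ties as
extreme (the default: on the discrete statistics used here the strict rule
is anticonservative), ``"strict"`` does not.  The Monte-Carlo denominator
is ``count / B`` by default, with the ``(count + 1) / (B + 1)`` variant
available as ``denominator="plus_one"``.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "PairedTestResult",
    "flower_sexbias_permutation",
    "paired_swap_permutation",
    "paired_t",
    "ResamplingError",
]

_EXACT_PAIR_LIMIT = 20  # enumerate sign flips when 2^n <= 2^20


class ResamplingError(ValueError):
    """Raised for degenerate or invalid resampling inputs."""


@dataclass
class PermutationResult:
    """Observed statistic, null distribution and doubled-tail p-value."""

    observed_stat: float
    null_stats: np.ndarray
    null_probs: np.ndarray | None
    B: int
    p_two_tailed: float
    extremity_rule: str
    denominator: str
    rng_seed: int | None
    exact: bool
    n_used: int
    warnings: list[str] = field(default_factory=list)

    @property
    def null_mean(self) -> float:
        if self.null_probs is not None:
            return float(np.sum(self.null_stats * self.null_probs))
        return float(np.mean(self.null_stats))

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "B": self.B,
            "p_two_tailed": self.p_two_tailed,
            "extremity_rule": self.extremity_rule,
            "denominator": self.denominator,
            "rng_seed": self.rng_seed,
            "exact": self.exact,
            "null_mean": self.null_mean,
            "n_used": self.n_used,
            "warnings": list(self.warnings),
        }


@dataclass
class PairedTestResult:
    """Classical paired t-test on within-pair differences."""

    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "mean_diff": self.mean_diff,
            "n_pairs": self.n_pairs,
        }


def _doubled_tail_p(
    obs: float,
    null_stats: np.ndarray,
    null_probs: np.ndarray | None,
    extremity: str,
    denominator: str,
) -> float:
    """Twice the null mass more extreme than ``obs`` (direction of departure
    from the null mean), capped at 1."""
    if extremity not in ("strict", "inclusive"):
        raise ResamplingError(f"extremity must be 'strict' or 'inclusive', got {extremity!r}")
    if denominator not in ("plain", "plus_one"):
        raise ResamplingError(f"denominator must be 'plain' or 'plus_one', got {denominator!r}")
    if null_probs is not None:
        mean = float(np.sum(null_stats * null_probs))
        if obs == mean:
            return 1.0
        if obs > mean:
            mask = null_stats >= obs if extremity == "inclusive" else null_stats > obs
        else:
            mask = null_stats <= obs if extremity == "inclusive" else null_stats < obs
        tail = float(np.sum(null_probs[mask]))
        return min(1.0, 2.0 * tail)
    B = null_stats.shape[0]
    mean = float(np.mean(null_stats))
    if obs == mean:
        return 1.0
    if obs > mean:
        count = int(np.sum(null_stats >= obs)) if extremity == "inclusive" else int(np.sum(null_stats > obs))
    else:
        count = int(np.sum(null_stats <= obs)) if extremity == "inclusive" else int(np.sum(null_stats < obs))
    if denominator == "plus_one":
        return min(1.0, 2.0 * (count + 1) / (B + 1))
    return min(1.0, 2.0 * count / B)


# --------------------------------------------------------------------- #
#               stratified flower-level sex-bias permutation            #
# --------------------------------------------------------------------- #

def _strata(flowers: pd.DataFrame) -> list[tuple[str, int, int, int]]:
    """Per population: (name, n flowers, n hermaphrodite flowers, n eggs)."""
    out = []
    for pop, grp in flowers.groupby("population", sort=True):
        n_i = len(grp)
        h_i = int((grp["sex"] == "H").sum())
        e_i = int(pd.to_numeric(grp["egg"]).sum())
        out.append((str(pop), n_i, h_i, e_i))
    return out


def exact_sexbias_null(flowers: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the hermaphrodite-egg-flower count.

    Within each population the count of hermaphrodite flowers among the
    reshuffled egg positions is hypergeometric; populations are independent,
    so the total's law is the convolution of the per-population
    hypergeometric pmfs.  Returns (support, probabilities).
    """
    pmf = np.array([1.0])
    for _pop, n_i, h_i, e_i in _strata(flowers):
        if e_i == 0:
            continue
        ks = np.arange(0, e_i + 1)
        p_i = stats.hypergeom.pmf(ks, n_i, h_i, e_i)
        pmf = np.convolve(pmf, p_i)
    support = np.arange(pmf.size)
    return support, pmf / pmf.sum()


def flower_sexbias_permutation(
    flowers: pd.DataFrame,
    B: int = 10_000,
    seed: int | None = None,
    extremity: str = "inclusive",
    denominator: str = "plain",
    exact: bool = False,
) -> PermutationResult:
    """Stratified permutation test for sex-biased egg receipt.

    Per replicate the per-flower egg indicator is reshuffled uniformly
    within each population independently; the statistic is the number of
    hermaphrodite flowers bearing eggs summed over populations.  With
    ``exact=True`` the full null law (hypergeometric convolution) replaces
    Monte-Carlo sampling.
    """
    required = {"population", "sex", "egg"}
    if not required <= set(flowers.columns):
        raise ResamplingError(f"flower table needs columns {sorted(required)}")
    if len(flowers) < 2:
        raise ResamplingError("need at least 2 flowers")
    egg = pd.to_numeric(flowers["egg"]).to_numpy(dtype=np.int64)
    if not np.isin(egg, (0, 1)).all():
        raise ResamplingError("egg must be a 0/1 indicator at the flower level")
    warn: list[str] = []
    strata = _strata(flowers)
    total_eggs = sum(e for *_x, e in strata)
    observed = float(((flowers["sex"] == "H") & (egg == 1)).sum())
    if total_eggs == 0:
        warn.append("zero eggs overall: degenerate null, p = 1")
        _warnings.warn(warn[-1], stacklevel=2)
        return PermutationResult(
            observed, np.zeros(1), np.ones(1), 0, 1.0, extremity, denominator,
            seed, True, len(flowers), warn,
        )
    for pop, n_i, _h, e_i in strata:
        if n_i == 0:
            warn.append(f"population {pop!r} has no flowers; skipped")
            _warnings.warn(warn[-1], stacklevel=2)

    if exact:
        support, pmf = exact_sexbias_null(flowers)
        p = _doubled_tail_p(observed, support.astype(float), pmf, extremity, denominator)
        return PermutationResult(
            observed, support.astype(float), pmf, int(support.size), p,
            extremity, denominator, seed, True, len(flowers), warn,
        )

    if B < 1:
        raise ResamplingError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    null = np.zeros(B, dtype=np.int64)
    for pop, grp in flowers.groupby("population", sort=True):
        e_i = int(pd.to_numeric(grp["egg"]).sum())
        if e_i == 0:
            continue
        herm = (grp["sex"] == "H").to_numpy(dtype=np.int8)
        ind = np.zeros(len(grp), dtype=np.int8)
        ind[:e_i] = 1
        perms = rng.permuted(np.broadcast_to(ind, (B, ind.size)).copy(), axis=1)
        null += perms @ herm.astype(np.int64)
    p = _doubled_tail_p(observed, null.astype(float), None, extremity, denominator)
    return PermutationResult(
        observed, null.astype(float), None, B, p, extremity, denominator,
        seed, False, len(flowers), warn,
    )


# --------------------------------------------------------------------- #
#                       within-pair label swap                          #
# --------------------------------------------------------------------- #

def _pair_differences(pairs: pd.DataFrame, value: str) -> tuple[np.ndarray, int]:
    """(egg - control) differences for complete pairs; count of dropped pairs."""
    for col in ("pair_id", "egg", value):
        if col not in pairs.columns:
            raise ResamplingError(f"pair table needs column {col!r}")
    wide = pairs.pivot_table(
        index="pair_id", columns="egg", values=value, aggfunc="first", observed=True
    )
    if 0 not in wide.columns or 1 not in wide.columns:
        raise ResamplingError("pair table needs both egg=1 and egg=0 arms")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    d = (
        pd.to_numeric(complete[1]).to_numpy(dtype=float)
        - pd.to_numeric(complete[0]).to_numpy(dtype=float)
    )
    return d, dropped


def _enumerate_signed_means(d: np.ndarray) -> np.ndarray:
    """All 2^n values of mean(s * d) over sign vectors s in {-1, +1}^n."""
    sums = np.zeros(1)
    for di in d:
        sums = np.concatenate([sums - di, sums + di])
    return sums / d.size


def paired_swap_permutation(
    pairs: pd.DataFrame,
    value: str = "seeds",
    B: int = 10_000,
    seed: int | None = None,
    extremity: str = "inclusive",
    denominator: str = "plain",
    exact: bool | None = None,
) -> PermutationResult:
    """Within-pair label-swap test of the egg-vs-control difference.

    Per replicate each pair independently swaps its egg/control labels with
    probability 1/2; the statistic is the mean within-pair difference.
    When ``2^n_pairs <= 2^20`` (and ``exact`` is not False) the sign
    assignments are enumerated exhaustively.  Pairs with a missing arm are
    dropped and counted in the result's warnings.
    """
    d, dropped = _pair_differences(pairs, value)
    warn: list[str] = []
    if dropped:
        warn.append(f"dropped {dropped} pair(s) with a missing {value!r} arm")
        _warnings.warn(warn[-1], stacklevel=2)
    n = d.size
    if n < 2:
        raise ResamplingError(f"need >= 2 complete pairs with {value!r} in both arms, have {n}")
    observed = float(np.mean(d))
    if exact is None:
        exact = n <= _EXACT_PAIR_LIMIT
    if exact and n > _EXACT_PAIR_LIMIT:
        raise ResamplingError(f"exact enumeration limited to {_EXACT_PAIR_LIMIT} pairs, have {n}")
    if exact:
        null = _enumerate_signed_means(d)
        p = _doubled_tail_p(observed, null, None, extremity, "plain")
        return PermutationResult(
            observed, null, None, int(null.size), p, extremity, "plain",
            seed, True, n, warn,
        )
    if B < 1:
        raise ResamplingError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(B, n)) * 2 - 1
    null = signs @ d / n
    p = _doubled_tail_p(observed, null, None, extremity, denominator)
    return PermutationResult(
        observed, null, None, B, p, extremity, denominator, seed, False, n, warn,
    )


def paired_t(pairs: pd.DataFrame, value: str) -> PairedTestResult:
    """Classical paired t-test of egg-vs-control differences in ``value``."""
    d, dropped = _pair_differences(pairs, value)
    if dropped:
        _warnings.warn(f"dropped {dropped} pair(s) with a missing {value!r} arm", stacklevel=2)
    n = d.size
    if n < 2:
        raise ResamplingError(f"need >= 2 complete pairs with {value!r} in both arms, have {n}")
    if float(np.var(d)) == 0.0:
        raise ResamplingError("within-pair differences have zero variance; t is undefined")
    res = stats.ttest_1samp(d, 0.0)
    return PairedTestResult(
        t_stat=float(res.statistic),
        df=n - 1,
        p_value=float(res.pvalue),
        mean_diff=float(np.mean(d)),
        n_pairs=n,
    )
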