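"""Exact (Clopper-Pearson) binomial confidence intervals.

Used for every reported proportion.  The interval inverts binomial tail
probabilities; the implementation uses the equivalent beta-quantile form,
which is numerically stable for all ``0 <= x <= n``:

    lower = BetaInv((1 - level)/2; x, n - x + 1)        (0 when x = 0)
    upper = BetaInv(1 - (1 - level)/2; x + 1, n - x)    (1 when x = n)

Exact intervals are asymmetric about x/n, so error bars built from them are
unequal above and below the observed proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["BinomialCI", "clopper_pearson", "proportion_table"]


@dataclass(frozen=True)
class BinomialCI:
    """An exact binomial confidence interval for x successes of n trials."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials

    def to_dict(self) -> dict:
        return {
            "successes": self.successes,
            "trials": self.trials,
            "proportion": self.proportion,
            "level": self.level,
            "lower": self.lower,
            "upper": self.upper,
        }


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Exact two-sided binomial confidence interval.

    Parameters
    ----------
    successes, trials
        Observed count and sample size, ``0 <= successes <= trials``,
        ``trials >= 1``.
    level
        Confidence level in (0, 1); default 0.95.
    """
    x, n = int(successes), int(trials)
    if n < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not 0 <= x <= n:
        raise ValueError(f"successes must be in [0, trials], got {successes} of {trials}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialCI(x, n, level, lower, upper)


def proportion_table(
    data: pd.DataFrame,
    response: str,
    by: list[str] | str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group proportions of a binary response with exact CIs.

    Returns a dataframe with the grouping columns plus ``successes``,
    ``trials``, ``proportion``, ``lower`` and ``upper`` — the table behind
    bar-with-CI figures of egg receipt or damage frequency.
    """
    if isinstance(by, str):
        by = [by]
    rows = []
    for keys, grp in data.groupby(by, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        x = int(pd.to_numeric(grp[response]).sum())
        n = int(len(grp))
        ci = clopper_pearson(x, n, level)
        rows.append(dict(zip(by, keys)) | {
            "successes": x,
            "trials": n,
            "proportion": ci.proportion,
            "lower": ci.lower,
            "upper": ci.upper,
        })
    return pd.DataFrame(rows)
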