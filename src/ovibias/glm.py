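"""Generalized linear models fit by IRLS, with nested-model tests.

Families: binomial and quasibinomial (logit link), poisson and quasipoisson
(log link), and gaussian (identity link, used for trait-dimorphism tests).
Coefficients maximize the (quasi-)likelihood via iteratively reweighted
least squares.  Nested models are compared by likelihood-ratio chi-square
tests (deviance difference) or by quasi-likelihood F tests (deviance
difference scaled by the Pearson dispersion of the fuller model).

Categorical predictors use treatment contrasts with the first sorted level
as reference; sex coded F/H therefore yields an "if hermaphrodite"
coefficient.  Interactions are written ``"a:b"`` and require their main
effects.

The backward-selection protocol drops the least-significant removable term
(interactions before their main effects) while its p-value exceeds alpha,
then re-tests every dropped term by adding it alone back to the final
model.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GLMError",
    "ModelSpec",
    "GLMFit",
    "LRTestResult",
    "BackwardSelectionResult",
    "fit_glm",
    "lr_test",
    "backward_select",
    "exponentiate_report",
    "eggs_given_receipt_test",
]

_MAX_ITER = 100
_DEV_TOL = 1e-8
_SEPARATION_BOUND = 15.0

_FAMILIES = {
    "binomial": {"link": "logit", "quasi": False},
    "quasibinomial": {"link": "logit", "quasi": True},
    "poisson": {"link": "log", "quasi": False},
    "quasipoisson": {"link": "log", "quasi": True},
    "gaussian": {"link": "identity", "quasi": True},
}


class GLMError(ValueError):
    """Raised for invalid model specifications or data."""


@dataclass(frozen=True)
class ModelSpec:
    """A model formula as an ordered term list.

    ``predictors`` holds main effects (column names) and interactions
    (``"a:b"``).  An empty tuple is the intercept-only model.
    """

    response: str
    predictors: tuple[str, ...] = ()
    family: str = "binomial"

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise GLMError(f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}")
        preds = tuple(self.predictors)
        object.__setattr__(self, "predictors", preds)
        present = set(preds)
        for term in preds:
            for part in term.split(":"):
                if ":" in term and part not in present:
                    raise GLMError(
                        f"interaction {term!r} requires main effect {part!r} in the model"
                    )

    @property
    def link(self) -> str:
        return _FAMILIES[self.family]["link"]

    def drop(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, tuple(t for t in self.predictors if t != term), self.family)

    def add(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, self.predictors + (term,), self.family)


@dataclass
class GLMFit:
    """A fitted GLM: coefficients on the link scale plus fit diagnostics."""

    spec: ModelSpec
    coefficients: dict[str, float]
    deviance: float
    df_residual: int
    dispersion: float
    pearson_chi2: float
    converged: bool
    iterations: int
    n_obs: int
    warnings: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    _y: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "predictors": list(self.spec.predictors),
            "family": self.spec.family,
            "coefficients": self.coefficients,
            "deviance": self.deviance,
            "df_residual": self.df_residual,
            "dispersion": self.dispersion,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_obs": self.n_obs,
            "warnings": list(self.warnings),
        }


@dataclass
class LRTestResult:
    """A nested-model comparison: LR chi-square or quasi-likelihood F."""

    kind: str
    statistic: float
    df1: int
    df2: int | None
    p_value: float
    term_tested: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": self.statistic,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "term_tested": self.term_tested,
        }


@dataclass
class BackwardSelectionResult:
    """Final model plus per-term tests from the backward-selection protocol.

    ``retained`` maps each kept term to its test against the final model
    lacking that term; ``dropped`` maps each removed term to its test of the
    final model against the final model plus that term alone.
    """

    final: GLMFit
    retained: dict[str, LRTestResult]
    dropped: dict[str, LRTestResult]
    history: list[dict]

    def to_dict(self) -> dict:
        return {
            "final": self.final.to_dict(),
            "retained": {t: r.to_dict() for t, r in self.retained.items()},
            "dropped": {t: r.to_dict() for t, r in self.dropped.items()},
            "history": self.history,
        }


# --------------------------------------------------------------------- #
#                            design matrix                              #
# --------------------------------------------------------------------- #

def _is_categorical(col: pd.Series) -> bool:
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or pd.api.types.is_string_dtype(col)


def _encode_main(data: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    if name not in data.columns:
        raise GLMError(f"predictor {name!r} not found in data")
    col = data[name]
    if _is_categorical(col):
        levels = sorted(pd.unique(col.dropna()))
        if len(levels) < 2:
            return np.empty((len(data), 0)), []
        cols = np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])
        return cols, [f"{name}[{lv}]" for lv in levels[1:]]
    return pd.to_numeric(col).to_numpy(float).reshape(-1, 1), [name]


def build_design(data: pd.DataFrame, predictors: tuple[str, ...]) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix with intercept, treatment contrasts and interactions.

    Returns the matrix, column names, and a map from term to its column
    indices (used by nested-model bookkeeping).
    """
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {}
    main_cache: dict[str, tuple[np.ndarray, list[str]]] = {}
    for term in predictors:
        parts = term.split(":")
        for p in parts:
            if p not in main_cache:
                main_cache[p] = _encode_main(data, p)
        block, blocknames = main_cache[parts[0]]
        for p in parts[1:]:
            nxt, nxtnames = main_cache[p]
            block = np.einsum("ni,nj->nij", block, nxt).reshape(n, -1)
            blocknames = [f"{a}:{b}" for a in blocknames for b in nxtnames]
        start = sum(b.shape[1] for b in blocks)
        term_cols[term] = list(range(start, start + block.shape[1]))
        blocks.append(block)
        names.extend(blocknames)
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cum = 1
        for term in predictors:
            k = len(term_cols[term])
            sub = X[:, : cum + k]
            if np.linalg.matrix_rank(sub) < cum + k:
                raise GLMError(
                    f"design matrix is rank deficient at term {term!r} "
                    "(aliased with earlier terms)"
                )
            cum += k
        raise GLMError("design matrix is rank deficient")
    return X, names, term_cols


# --------------------------------------------------------------------- #
#                                IRLS                                   #
# --------------------------------------------------------------------- #

def _check_response(y: np.ndarray, family: str, response: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise GLMError(f"response {response!r} contains missing values")
    if family in ("binomial", "quasibinomial"):
        if not np.isin(y, (0.0, 1.0)).all():
            raise GLMError(f"response {response!r} must be binary 0/1 for family {family}")
    elif family in ("poisson", "quasipoisson"):
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise GLMError(f"response {response!r} must be nonnegative integer for family {family}")
    return y


def _deviance(y: np.ndarray, mu: np.ndarray, link: str) -> float:
    if link == "logit":
        return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))
    if link == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))
    return float(np.sum((y - mu) ** 2))


def _variance(mu: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        return mu * (1.0 - mu)
    if link == "log":
        return mu
    return np.ones_like(mu)


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> GLMFit:
    """Fit a GLM by IRLS.

    Convergence: relative deviance change below 1e-8, at most 100
    iterations.  Quasi-family dispersion is Pearson chi-square over residual
    df.  Non-convergence and apparent quasi-complete separation (a logit
    coefficient beyond +-15) are flagged in ``GLMFit.warnings`` and emitted
    as Python warnings, never silently dropped.
    """
    if len(data) == 0:
        raise GLMError("empty dataset")
    if spec.response not in data.columns:
        raise GLMError(f"response {spec.response!r} not found in data")
    y = _check_response(pd.to_numeric(data[spec.response]).to_numpy(), spec.family, spec.response)
    X, names, term_cols = build_design(data, spec.predictors)
    n, p = X.shape
    if n <= p:
        raise GLMError(f"model has {p} coefficients but only {n} observations")
    link = spec.link

    if link == "logit":
        mu = (y + 0.5) / 2.0
        eta = np.log(mu / (1.0 - mu))
    elif link == "log":
        mu = y + 0.1
        eta = np.log(mu)
    else:
        mu = np.full_like(y, float(np.mean(y)))
        eta = mu

    beta = np.zeros(p)
    if link == "logit":
        dev = _deviance(y, np.clip(mu, 1e-10, 1 - 1e-10), link)
    elif link == "log":
        dev = _deviance(y, np.clip(mu, 1e-10, None), link)
    else:
        dev = _deviance(y, mu, link)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        if link == "logit":
            mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
            dmu = mu * (1.0 - mu)
        elif link == "log":
            mu = np.clip(mu, 1e-10, None)
            dmu = mu
        else:
            dmu = np.ones_like(mu)
        V = _variance(mu, link)
        w = dmu**2 / np.clip(V, 1e-12, None)
        z = eta + (y - mu) / np.clip(dmu, 1e-12, None)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        if link == "logit":
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
        elif link == "log":
            mu = np.exp(np.clip(eta, -700, 700))
            mu = np.clip(mu, 1e-10, None)
        else:
            mu = eta
        new_dev = _deviance(y, mu, link)
        if abs(new_dev - dev) / (abs(new_dev) + 0.1) < _DEV_TOL:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    warn: list[str] = []
    if not converged:
        warn.append(f"IRLS did not converge in {_MAX_ITER} iterations")
    if link == "logit" and np.any(np.abs(beta) > _SEPARATION_BOUND):
        warn.append(
            "possible quasi-complete separation: a coefficient exceeds "
            f"{_SEPARATION_BOUND} on the logit scale"
        )
    for w_msg in warn:
        _warnings.warn(w_msg, stacklevel=2)

    df_resid = n - p
    pearson = float(np.sum((y - mu) ** 2 / np.clip(_variance(mu, link), 1e-12, None)))
    quasi = _FAMILIES[spec.family]["quasi"]
    if spec.family == "gaussian":
        dispersion = dev / df_resid if df_resid > 0 else np.nan
    elif quasi:
        dispersion = pearson / df_resid if df_resid > 0 else np.nan
    else:
        dispersion = 1.0
    return GLMFit(
        spec=spec,
        coefficients=dict(zip(names, (float(b) for b in beta))),
        deviance=dev,
        df_residual=df_resid,
        dispersion=float(dispersion),
        pearson_chi2=pearson,
        converged=converged,
        iterations=it,
        n_obs=n,
        warnings=warn,
        fitted=mu,
        _y=y,
    )


# --------------------------------------------------------------------- #
#                           nested-model tests                          #
# --------------------------------------------------------------------- #

def lr_test(fit_reduced: GLMFit, fit_full: GLMFit, kind: str = "chisq") -> LRTestResult:
    """Likelihood-ratio test between two nested fits on the same data.

    ``kind="chisq"``: statistic is the deviance difference, referred to a
    chi-square with df equal to the difference in model df.
    ``kind="f"``: statistic is (deviance difference / df difference) divided
    by the fuller model's dispersion, referred to F(df1, df_residual(full)).
    """
    if kind not in ("chisq", "f"):
        raise GLMError(f"kind must be 'chisq' or 'f', got {kind!r}")
    if fit_reduced.n_obs != fit_full.n_obs or not np.array_equal(fit_reduced._y, fit_full._y):
        raise GLMError("nested-model test requires both fits on the same data")
    r_terms, f_terms = set(fit_reduced.spec.predictors), set(fit_full.spec.predictors)
    if not r_terms <= f_terms:
        raise GLMError(
            f"models are not nested: {sorted(r_terms - f_terms)} only in the reduced model"
        )
    if fit_reduced.spec.family != fit_full.spec.family:
        raise GLMError("nested-model test requires the same family")
    df1 = fit_reduced.df_residual - fit_full.df_residual
    term = "+".join(sorted(f_terms - r_terms))
    ddev = max(fit_reduced.deviance - fit_full.deviance, 0.0)
    if df1 == 0:
        return LRTestResult(kind, 0.0, 0, fit_full.df_residual if kind == "f" else None, 1.0, term)
    if df1 < 0:
        raise GLMError("reduced model has fewer residual df than the full model")
    if kind == "chisq":
        stat = ddev
        p = float(stats.chi2.sf(stat, df1))
        return LRTestResult("chisq", float(stat), df1, None, p, term)
    df2 = fit_full.df_residual
    disp = fit_full.dispersion
    if not np.isfinite(disp) or disp <= 0:
        raise GLMError("F test needs a positive finite dispersion in the full model")
    stat = (ddev / df1) / disp
    p = float(stats.f.sf(stat, df1, df2))
    return LRTestResult("f", float(stat), df1, df2, p, term)


def _removable(terms: list[str]) -> list[str]:
    """Terms droppable now: not a component of any remaining interaction."""
    out = []
    for t in terms:
        t_parts = set(t.split(":"))
        locked = any(
            o != t and t_parts < set(o.split(":")) for o in terms
        )
        if not locked:
            out.append(t)
    return out


def backward_select(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    kind: str = "chisq",
) -> BackwardSelectionResult:
    """Backward elimination by nested-model tests at level ``alpha``.

    At each step the removable term with the largest p-value above alpha is
    dropped (interaction terms become removable before their main effects by
    construction).  After convergence each dropped term is re-tested by
    comparing the final model against the final model plus that term alone,
    and each retained term against the final model lacking it.
    """
    if not 0.0 < alpha < 1.0:
        raise GLMError(f"alpha must be in (0, 1), got {alpha}")
    current = spec
    try:
        current_fit = fit_glm(current, data)
    except GLMError as e:
        raise GLMError(f"backward selection failed fitting the full model: {e}") from e
    history: list[dict] = []
    order_dropped: list[str] = []
    while current.predictors:
        pvals: dict[str, float] = {}
        for t in _removable(list(current.predictors)):
            try:
                reduced_fit = fit_glm(current.drop(t), data)
            except GLMError as e:
                raise GLMError(f"backward selection failed while testing term {t!r}: {e}") from e
            pvals[t] = lr_test(reduced_fit, current_fit, kind).p_value
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] <= alpha:
            break
        history.append({"dropped": worst, "p_value": pvals[worst]})
        order_dropped.append(worst)
        current = current.drop(worst)
        current_fit = fit_glm(current, data)

    final_fit = current_fit
    dropped: dict[str, LRTestResult] = {}
    for t in order_dropped:
        try:
            aug = current.add(t)
        except GLMError:
            # an interaction whose main effect was also dropped: re-add both
            parts = [p for p in t.split(":") if p not in current.predictors]
            aug = current
            for p in parts:
                aug = aug.add(p)
            if t not in aug.predictors:
                aug = aug.add(t)
        dropped[t] = lr_test(final_fit, fit_glm(aug, data), kind)
    retained: dict[str, LRTestResult] = {}
    for t in _removable(list(current.predictors)):
        retained[t] = lr_test(fit_glm(current.drop(t), data), final_fit, kind)
    return BackwardSelectionResult(final_fit, retained, dropped, history)


def exponentiate_report(fit: GLMFit) -> pd.DataFrame:
    """Per-term multiplicative effects for log- or logit-link models.

    A one-unit increase in a predictor multiplies the mean response (log
    link) or the odds (logit link) by the exponentiated coefficient.
    """
    if fit.spec.link not in ("log", "logit"):
        raise GLMError("exponentiated effects require a log or logit link")
    terms = list(fit.coefficients)
    coefs = np.array([fit.coefficients[t] for t in terms])
    return pd.DataFrame(
        {"term": terms, "coefficient": coefs, "exp_coefficient": np.exp(coefs)}
    )


def eggs_given_receipt_test(
    data: pd.DataFrame, response: str = "eggs", group: str = "sex"
) -> LRTestResult:
    """Sex effect on egg counts among units that received at least one egg.

    Poisson log-link count model on the egg-receiving subset, LR chi-square
    for the sex term.  A subset with one sex absent is an error; a
    zero-variance response (e.g. every unit got exactly one egg) is flagged
    with a warning and yields the trivial p = 1 comparison.
    """
    sub = data[pd.to_numeric(data[response]) >= 1]
    present = set(sub[group].unique())
    if present != {"F", "H"}:
        raise GLMError(
            f"degenerate egg-receiving subset: sexes present = {sorted(present)}"
        )
    y = pd.to_numeric(sub[response])
    if float(y.var(ddof=0)) == 0.0:
        _warnings.warn("zero-variance egg counts among receiving units", stacklevel=2)
    full = fit_glm(ModelSpec(response, (group,), "poisson"), sub)
    reduced = fit_glm(ModelSpec(response, (), "poisson"), sub)
    return lr_test(reduced, full, "chisq")
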