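"""Quadratic response-surface models: fit, reduce, assess, predict, optimize.

Ordinary least squares (via statsmodels) on the natural, pump-rounded factor
settings.  Terms are named after the factors, e.g. ``frr``, ``tfr``,
``frr^2``, ``tfr^2``, ``frr:tfr``; the intercept ``1`` is always present.

Model reduction is iterative backward elimination on coefficient t-test
p-values (equivalent to partial F tests for a single term), respecting
hierarchy: a main effect is never dropped while its square or an interaction
containing it is still in the model.

Goodness of fit reports the familiar trio R^2, adjusted R^2 and the
PRESS-based predicted R^2 (leave-one-out residuals e_i / (1 - h_ii)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SingularDesignError",
    "full_quadratic_terms",
    "SurfaceModel",
    "AnovaReport",
    "PredictionResult",
    "OptimumResult",
    "fit_quadratic",
    "reduce_model",
    "goodness_of_fit",
    "predict",
    "optimize_response",
]

INTERCEPT = "1"


class SingularDesignError(ValueError):
    """Raised when the model matrix is rank deficient."""


def full_quadratic_terms(factors: Sequence[str]) -> list[str]:
    """Full second-order term set: intercept, linear, square, interaction."""
    terms = [INTERCEPT] + list(factors)
    terms += [f"{f}^2" for f in factors]
    for i, a in enumerate(factors):
        for b in factors[i + 1 :]:
            terms.append(f"{a}:{b}")
    return terms


def _term_column(term: str, data: pd.DataFrame) -> np.ndarray:
    if term == INTERCEPT:
        return np.ones(len(data))
    if term.endswith("^2"):
        return data[term[:-2]].to_numpy(dtype=float) ** 2
    if ":" in term:
        a, b = term.split(":")
        return data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
    return data[term].to_numpy(dtype=float)


def _term_parents(term: str) -> set[str]:
    """Main effects that must stay in the model while ``term`` is present."""
    if term.endswith("^2"):
        return {term[:-2]}
    if ":" in term:
        return set(term.split(":"))
    return set()


def design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    return np.column_stack([_term_column(t, data) for t in terms])


@dataclass
class SurfaceModel:
    """A fitted polynomial response surface.

    Coefficients are in natural units; ``cov`` is sigma-hat^2 (X'X)^-1.
    """

    response: str
    terms: list[str]
    factors: tuple[str, ...]
    coefficients: np.ndarray
    cov: np.ndarray
    df_resid: int
    residuals: np.ndarray
    leverage: np.ndarray
    fitted: np.ndarray
    y: np.ndarray
    significant: bool = True
    n_dropped_missing: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def design_row(self, point: Mapping[str, float]) -> np.ndarray:
        row = pd.DataFrame({k: [float(v)] for k, v in point.items()})
        return design_matrix(row, self.terms)[0]

    def __call__(self, point: Mapping[str, float]) -> float:
        return float(self.design_row(point) @ self.coefficients)

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        t = np.divide(self.coefficients, se, out=np.full_like(se, np.inf),
                      where=se > 0)
        p = 2 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {"term": self.terms, "coef": self.coefficients, "se": se,
             "t": t, "p": p}
        )


@dataclass
class PredictionResult:
    mean: float
    se_fit: float
    ci95: tuple[float, float]
    pi95: tuple[float, float]


@dataclass
class AnovaReport:
    """Term-wise partial tests plus model-level statistics.

    R^2 values are stored as fractions; reports print them in percent.
    ``r2_pred`` may be negative when PRESS exceeds SST (reported floored
    at zero by :meth:`to_text`).
    """

    response: str
    terms: pd.DataFrame  # term, coef, se, t, p, partial_ss
    ssr: float
    sse: float
    sst: float
    f_model: float
    p_model: float
    r2: float
    r2_adj: float
    press: float
    r2_pred: float
    n_obs: int
    n_params: int

    def to_text(self) -> str:
        lines = [f"response: {self.response}",
                 f"n = {self.n_obs}, parameters = {self.n_params}"]
        for _, row in self.terms.iterrows():
            lines.append(
                f"  {row['term']:>8s}  coef={row['coef']: .6g}  "
                f"se={row['se']:.4g}  t={row['t']: .3f}  p={row['p']:.4g}"
            )
        lines += [
            f"model F = {self.f_model:.2f}, p = {self.p_model:.3g}",
            f"R2 = {100 * self.r2:.2f}%",
            f"R2(adj) = {100 * self.r2_adj:.2f}%",
            f"R2(pred) = {100 * max(self.r2_pred, 0.0):.2f}%",
        ]
        return "\n".join(lines)


@dataclass
class OptimumResult:
    settings: dict[str, float]
    predicted: float
    se_fit: float
    ci95: tuple[float, float]
    at_boundary: dict[str, bool]
    sense: str


def _prepare(runs: pd.DataFrame, response: str,
             factors: Sequence[str]) -> tuple[pd.DataFrame, int]:
    cols = list(factors) + [response]
    sub = runs[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    dropped = n0 - len(sub)
    if dropped:
        logger.info("dropped %d rows with missing %s", dropped, response)
    return sub, dropped


def fit_quadratic(
    runs: pd.DataFrame,
    response: str,
    terms: Sequence[str] | None = None,
    factors: Sequence[str] = ("frr", "tfr"),
) -> SurfaceModel:
    """OLS fit of ``response`` on the given polynomial terms.

    ``terms=None`` fits the full quadratic.  Rows with a missing response
    are skipped (count logged and recorded on the model).
    """
    factors = tuple(factors)
    if terms is None:
        terms = full_quadratic_terms(factors)
    terms = list(terms)
    if INTERCEPT not in terms:
        terms = [INTERCEPT] + terms
    data, dropped = _prepare(runs, response, factors)
    X = design_matrix(data, terms)
    if len(data) < len(terms) + 1:
        raise ValueError(
            f"need at least {len(terms) + 1} complete runs, have {len(data)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix for terms {terms} is rank deficient"
        )
    y = data[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    infl_hat = res.get_influence().hat_matrix_diag
    return SurfaceModel(
        response=response,
        terms=terms,
        factors=factors,
        coefficients=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        df_resid=int(res.df_resid),
        residuals=np.asarray(res.resid, dtype=float),
        leverage=np.asarray(infl_hat, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        y=y,
        n_dropped_missing=dropped,
    )


def goodness_of_fit(model: SurfaceModel) -> AnovaReport:
    """R^2 trio, PRESS and the model F test for a fitted surface."""
    y, fitted, resid = model.y, model.fitted, model.residuals
    n, p = model.n_obs, len(model.terms)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    ssr = sst - sse
    if np.any(model.leverage >= 1.0 - 1e-12):
        raise ValueError("a leverage of 1 makes PRESS undefined")
    press = float(np.sum((resid / (1.0 - model.leverage)) ** 2))
    mse = sse / (n - p) if n > p else np.nan
    if p > 1 and n > p and sse > 0:
        f_model = (ssr / (p - 1)) / mse
        p_model = float(stats.f.sf(f_model, p - 1, n - p))
    else:
        f_model, p_model = np.nan, np.nan
    tf = model.summary_frame()
    tf["partial_ss"] = tf["t"] ** 2 * mse
    return AnovaReport(
        response=model.response,
        terms=tf,
        ssr=ssr,
        sse=sse,
        sst=sst,
        f_model=float(f_model),
        p_model=p_model,
        r2=1.0 - sse / sst if sst > 0 else np.nan,
        r2_adj=1.0 - (sse / (n - p)) / (sst / (n - 1)) if sst > 0 else np.nan,
        press=press,
        r2_pred=1.0 - press / sst if sst > 0 else np.nan,
        n_obs=n,
        n_params=p,
    )


def reduce_model(
    runs: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
    remove_alpha: float = 0.10,
    factors: Sequence[str] = ("frr", "tfr"),
    start_terms: Sequence[str] | None = None,
) -> tuple[SurfaceModel, AnovaReport]:
    """Backward-eliminate non-significant terms from the full quadratic.

    Repeatedly drops the eligible non-intercept term with the largest
    p > ``remove_alpha`` and refits, until every remaining term clears the
    removal threshold or only the intercept remains.  ``remove_alpha``
    defaults to 0.10, the customary alpha-to-remove of stepwise backward
    elimination; ``alpha`` is the stricter level used when *reporting* term
    significance.  Hierarchy: main effects shielded by a surviving square or
    interaction are not eligible for removal.  A model reduced to the bare
    intercept is flagged ``significant=False``.
    """
    terms = list(start_terms) if start_terms is not None else full_quadratic_terms(tuple(factors))
    model = fit_quadratic(runs, response, terms, factors)
    while True:
        tf = model.summary_frame()
        shielded: set[str] = set()
        for t in model.terms:
            shielded |= _term_parents(t)
        candidates = tf[(tf.term != INTERCEPT) & (~tf.term.isin(shielded))]
        worst = candidates[candidates.p > remove_alpha]
        if worst.empty:
            break
        drop = worst.loc[worst.p.idxmax(), "term"]
        terms = [t for t in model.terms if t != drop]
        logger.info("%s: dropping %s (p=%.3g)", response, drop,
                    worst.p.max())
        model = fit_quadratic(runs, response, terms, model.factors)
        if len(model.terms) == 1:
            break
    model.significant = len(model.terms) > 1
    return model, goodness_of_fit(model)


def predict(model: SurfaceModel, point: Mapping[str, float]) -> PredictionResult:
    """Point prediction with SE of the mean, 95% CI and prediction interval."""
    x = model.design_row(point)
    mean = float(x @ model.coefficients)
    se_fit = float(np.sqrt(x @ model.cov @ x))
    tcrit = stats.t.ppf(0.975, model.df_resid)
    mse = float(np.sum(model.residuals**2)) / model.df_resid
    se_pred = float(np.sqrt(se_fit**2 + mse))
    return PredictionResult(
        mean=mean,
        se_fit=se_fit,
        ci95=(mean - tcrit * se_fit, mean + tcrit * se_fit),
        pi95=(mean - tcrit * se_pred, mean + tcrit * se_pred),
    )


def optimize_response(
    model: SurfaceModel,
    bounds: Mapping[str, tuple[float, float]],
    sense: str = "min",
) -> OptimumResult:
    """Optimize a fitted quadratic surface over a rectangular region.

    The quadratic is optimized by multi-start L-BFGS-B (all corners plus a
    coarse interior lattice as starts), which for a quadratic with at most
    one interior stationary point recovers the closed-form optimum; factors
    that enter only linearly land on the bound favoured by the sense.
    """
    if sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")
    names = [f for f in model.factors if f in bounds]
    if set(names) != set(model.factors):
        raise ValueError("bounds must cover every model factor")
    lo = np.array([bounds[f][0] for f in names], dtype=float)
    hi = np.array([bounds[f][1] for f in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    sign = 1.0 if sense == "min" else -1.0

    def obj(x: np.ndarray) -> float:
        return sign * model(dict(zip(names, x)))

    from scipy.optimize import minimize

    starts = [lo, hi]
    grid = np.meshgrid(*[np.linspace(l, h, 4) for l, h in zip(lo, hi)])
    starts += list(np.stack([g.ravel() for g in grid], axis=1))
    best_x, best_v = None, np.inf
    for x0 in starts:
        r = minimize(obj, x0, method="L-BFGS-B",
                     bounds=list(zip(lo, hi)))
        if r.fun < best_v - 1e-12:
            best_v, best_x = r.fun, r.x
    settings = dict(zip(names, map(float, best_x)))
    pred = predict(model, settings)
    span = hi - lo
    at_boundary = {
        f: bool(min(best_x[i] - lo[i], hi[i] - best_x[i]) < 1e-6 * span[i])
        for i, f in enumerate(names)
    }
    return OptimumResult(
        settings=settings,
        predicted=pred.mean,
        se_fit=pred.se_fit,
        ci95=pred.ci95,
        at_boundary=at_boundary,
        sense=sense,
    )
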