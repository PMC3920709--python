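"""Descriptor-based QSAR regression.

Ordinary least squares with an intercept links surface-ESP descriptors (and
the LUMO energy) to activity (IC50, mmol/dm^3, untransformed).  Three entry
points cover the usual workflows:

* :func:`fit_ols` — a single model on named predictor columns;
* :func:`stepwise_forward` — SPSS-style forward selection with backward
  elimination, driven by partial-F probabilities (enter p<0.05, remove
  p>0.10 by default);
* :func:`nested_model_trace` — the prefix models of a fixed predictor
  order, i.e. a "model summary" table for a known entry sequence.

statsmodels performs the fits; this module wraps them in a stable result
type and adds the selection logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, DegreesOfFreedomError, SchemaError

__all__ = [
    "QsarModel",
    "StepwiseStep",
    "StepwiseTrace",
    "fit_ols",
    "predict",
    "stepwise_forward",
    "nested_model_trace",
    "published_pyrazine_model",
    "PUBLISHED_COEFFICIENTS",
    "PUBLISHED_INTERCEPT",
]

#: Published five-descriptor QSAR model for the pyrazine-2-carboxamide
#: series: IC50 = intercept + sum(coef * descriptor).  Units: response in
#: mmol/dm^3, reciprocals in mol/kcal, means in kcal/mol, LUMO as printed.
PUBLISHED_INTERCEPT: float = -2.467
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "inv_vs_min": 82.101,
    "lumo": -34.882,
    "vs_mean": -0.132,
    "vs_plus_mean": 0.139,
    "inv_vs_max": 5.569,
}


@dataclass
class QsarModel:
    """An OLS fit: coefficients, their standard errors and fit statistics.

    ``se`` is the residual standard error sqrt(SSres/(n-p-1)); ``r`` is the
    (positive) square root of ``r2``.
    """

    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    coef_std_errors: np.ndarray
    intercept_std_error: float
    n: int
    r: float
    r2: float
    r2_adj: float
    se: float
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def p(self) -> int:
        return len(self.predictor_names)

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictor_names),
            "intercept": self.intercept,
            "coefficients": dict(zip(self.predictor_names, map(float, self.coefficients))),
            "coef_std_errors": dict(zip(self.predictor_names, map(float, self.coef_std_errors))),
            "intercept_std_error": self.intercept_std_error,
            "n": self.n,
            "r": self.r,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "se": self.se,
        }


@dataclass
class StepwiseStep:
    action: str  # "add" or "remove"
    predictor: str
    model: QsarModel


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    @property
    def final(self) -> QsarModel | None:
        return self.steps[-1].model if self.steps else None

    def summary_frame(self) -> pd.DataFrame:
        """Model-summary table: one row per step (R, R^2, adjusted R^2, SE)."""
        rows = []
        included: list[str] = []
        for s in self.steps:
            if s.action == "add":
                included.append(s.predictor)
            else:
                included.remove(s.predictor)
            rows.append(
                {
                    "model": ", ".join(included),
                    "r": s.model.r,
                    "r2": s.model.r2,
                    "r2_adj": s.model.r2_adj,
                    "se": s.model.se,
                }
            )
        return pd.DataFrame(rows)


def _design(table: pd.DataFrame, predictors: list[str], response: str) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in [*predictors, response] if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing columns: {missing}")
    X = table[list(predictors)].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    return X, y


def fit_ols(table: pd.DataFrame, predictors: list[str], response: str = "activity") -> QsarModel:
    """Fit OLS with intercept; response regressed on the named columns."""
    X, y = _design(table, list(predictors), response)
    n, p = X.shape
    if n <= p + 1:
        raise DegreesOfFreedomError(f"n={n} rows cannot support {p} predictors plus intercept")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < p + 1:
        dependent = _dependent_columns(Xc, predictors)
        raise CollinearityError(f"design matrix is rank deficient; dependent columns: {dependent}")
    res = sm.OLS(y, Xc).fit()
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    r2 = float(res.rsquared)
    return QsarModel(
        predictor_names=list(predictors),
        coefficients=params[1:],
        intercept=float(params[0]),
        coef_std_errors=bse[1:],
        intercept_std_error=float(bse[0]),
        n=n,
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        r2_adj=float(res.rsquared_adj),
        se=float(np.sqrt(res.mse_resid)) if n > p + 1 else 0.0,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def _dependent_columns(Xc: np.ndarray, predictors: list[str]) -> list[str]:
    """Name the predictor columns involved in the rank deficiency."""
    names = ["const", *predictors]
    bad = []
    rank_full = np.linalg.matrix_rank(Xc)
    for j in range(Xc.shape[1]):
        sub = np.delete(Xc, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank_full:
            bad.append(names[j])
    return [b for b in bad if b != "const"] or predictors


def predict(model: QsarModel, table: pd.DataFrame) -> np.ndarray:
    """Apply the linear model row-wise: intercept + sum(coef * column)."""
    missing = [c for c in model.predictor_names if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing model predictors: {missing}")
    X = table[model.predictor_names].to_numpy(dtype=float)
    return model.intercept + X @ model.coefficients


def published_pyrazine_model() -> QsarModel:
    """The published five-descriptor pyrazine-amide equation as a QsarModel.

    Only the coefficients are meaningful; the fit statistics are NaN
    because the model was not fit here.
    """
    names = list(PUBLISHED_COEFFICIENTS)
    nan = float("nan")
    return QsarModel(
        predictor_names=names,
        coefficients=np.array([PUBLISHED_COEFFICIENTS[k] for k in names]),
        intercept=PUBLISHED_INTERCEPT,
        coef_std_errors=np.full(len(names), nan),
        intercept_std_error=nan,
        n=15,
        r=nan,
        r2=nan,
        r2_adj=nan,
        se=nan,
        fitted=np.empty(0),
        residuals=np.empty(0),
    )


def _partial_f_pvalue(table: pd.DataFrame, included: list[str], candidate: str, response: str) -> float:
    """p-value of the candidate's coefficient in the augmented model.

    The squared t statistic of a single added column equals the partial F
    for that addition, so the two-sided t probability is the partial-F
    probability.
    """
    X, y = _design(table, [*included, candidate], response)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        return 1.0
    res = sm.OLS(y, Xc).fit()
    return float(res.pvalues[-1])


def stepwise_forward(
    table: pd.DataFrame,
    candidates: list[str],
    response: str = "activity",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseTrace:
    """Forward stepwise selection with backward elimination.

    At each step the not-yet-included candidate with the smallest
    partial-F probability enters if it is below ``p_enter``; after each
    entry, any included predictor whose probability has risen above
    ``p_remove`` leaves (largest first).  Ties break by candidate input
    order.  Terminates when no entry or removal occurs.
    """
    if not (0 < p_enter <= p_remove <= 1):
        raise ValueError("require 0 < p_enter <= p_remove <= 1")
    trace = StepwiseTrace()
    included: list[str] = []
    remaining = list(candidates)
    if not remaining:
        return trace
    n = len(table)
    # p_enter <= p_remove prevents immediate re-entry cycles; the cap guards
    # the pathological multi-predictor cycles classic stepwise can fall into
    max_steps = 4 * len(candidates) + 4
    while len(trace.steps) < max_steps:
        moved = False
        # entry: need residual dof for the augmented model
        if remaining and n > len(included) + 2:
            pvals = [_partial_f_pvalue(table, included, c, response) for c in remaining]
            best = int(np.argmin(pvals))
            if pvals[best] < p_enter:
                entering = remaining.pop(best)
                included.append(entering)
                trace.steps.append(
                    StepwiseStep("add", entering, fit_ols(table, included, response))
                )
                moved = True
        # removal
        while len(included) > 1:
            model = fit_ols(table, included, response)
            tvals = model.coefficients / model.coef_std_errors
            from scipy import stats

            pv = 2 * stats.t.sf(np.abs(tvals), df=model.n - model.p - 1)
            worst = int(np.argmax(pv))
            if pv[worst] > p_remove:
                leaving = included.pop(worst)
                remaining.append(leaving)
                trace.steps.append(
                    StepwiseStep("remove", leaving, fit_ols(table, included, response))
                )
                moved = True
            else:
                break
        if not moved:
            break
    return trace


def nested_model_trace(
    table: pd.DataFrame, ordered_predictors: list[str], response: str = "activity"
) -> StepwiseTrace:
    """Fit the k-predictor prefix models of a fixed entry order, k = 1..len."""
    trace = StepwiseTrace()
    for k in range(1, len(ordered_predictors) + 1):
        prefix = list(ordered_predictors[:k])
        trace.steps.append(
            StepwiseStep("add", prefix[-1], fit_ols(table, prefix, response))
        )
    return trace
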