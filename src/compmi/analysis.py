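"""Substantive analysis models and the method dispatcher.

Two estimands are supported for a binary composite y and randomized binary
treatment x:

* ``logit``    — the treatment log odds ratio beta_x from
  logit P(y=1|x) = beta_0 + beta_x x (the simulation-study estimand);
* ``riskdiff`` — the difference in event proportions p1 - p0, the estimand
  of an identity-link binomial GLM on treatment alone, whose MLE and
  model-based standard error reduce to the closed forms
  p1_hat - p0_hat and sqrt(p1(1-p1)/n1 + p0(1-p0)/n0).

``analyze_with_method`` applies one of eight missing-data strategies before
fitting: full data, complete records, the derived endpoint, or one of the
five multiple-imputation strategies (pooled by Rubin's rules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import fit_logistic
from .composite import CompositeDefinition, complete_records, derive_endpoint
from .errors import DomainError, EmptyAnalysisSetError, SeparationError
from .mi import (
    COMPONENT_STRATEGIES,
    COMPOSITE_STRATEGIES,
    ImputationSpec,
    impute_components_mice,
    impute_composite,
    pool_rubin,
)

__all__ = [
    "AnalysisResult",
    "fit_logit_y_on_x",
    "fit_risk_difference",
    "analyze_with_method",
    "METHODS",
]

METHODS = ("Full", "CRA", "Deriv") + COMPOSITE_STRATEGIES + COMPONENT_STRATEGIES


@dataclass(frozen=True)
class AnalysisResult:
    """A treatment-effect estimate with its Wald-type interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_analyzed: int
    level: float
    model: str
    method: str | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    #: Monte Carlo error of a pooled MI estimate, sqrt(B/M); None for
    #: single-fit methods.
    mc_error: float | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise DomainError("standard error must be nonnegative")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise DomainError("confidence interval must contain the estimate")


def _extract_xy(data: pd.DataFrame, ycol: str) -> tuple[np.ndarray, np.ndarray]:
    sub = data[["x", ycol]].dropna()
    if len(sub) == 0:
        raise EmptyAnalysisSetError("no rows with both x and y observed")
    x = sub["x"].to_numpy(dtype=float)
    y = sub[ycol].to_numpy(dtype=float)
    if not (np.any(x == 0) and np.any(x == 1)):
        raise EmptyAnalysisSetError("both treatment arms must be represented")
    return x, y


def fit_logit_y_on_x(
    data: pd.DataFrame,
    confidence_level: float = 0.95,
    ycol: str = "y",
) -> AnalysisResult:
    """Logistic MLE of the composite on treatment with Wald intervals.

    A treatment arm with constant y makes the log odds ratio infinite and
    raises :class:`SeparationError` (analysis models are never augmented)."""
    x, y = _extract_xy(data, ycol)
    for arm in (0, 1):
        ya = y[x == arm]
        if ya.min() == ya.max():
            raise SeparationError(
                f"outcome is constant ({ya[0]:g}) in arm x={arm}: "
                "the log odds ratio is not estimable"
            )
    fit = fit_logistic(np.column_stack([np.ones_like(x), x]), y)
    beta0, betax = fit.params
    se0, sex = np.sqrt(np.diag(fit.cov))
    zcrit = stats.norm.ppf(0.5 + confidence_level / 2)
    return AnalysisResult(
        estimate=float(betax),
        se=float(sex),
        ci_low=float(betax - zcrit * sex),
        ci_high=float(betax + zcrit * sex),
        n_analyzed=int(len(x)),
        level=confidence_level,
        model="logit",
        intercept=float(beta0),
        intercept_se=float(se0),
    )


def fit_risk_difference(
    data: pd.DataFrame,
    confidence_level: float = 0.90,
    ycol: str = "y",
) -> AnalysisResult:
    """Difference in proportions with the binomial closed-form SE.

    Algebraically identical to an identity-link binomial GLM on the single
    binary covariate x, but immune to its convergence failures."""
    x, y = _extract_xy(data, ycol)
    p1, p0 = y[x == 1].mean(), y[x == 0].mean()
    n1, n0 = int((x == 1).sum()), int((x == 0).sum())
    if p1 in (0.0, 1.0) or p0 in (0.0, 1.0):
        warnings.warn(
            "an arm has a degenerate event proportion (0 or 1); its variance "
            "contribution is zero and the CI collapses on that side",
            stacklevel=2,
        )
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    zcrit = stats.norm.ppf(0.5 + confidence_level / 2)
    diff = float(p1 - p0)
    return AnalysisResult(
        estimate=diff,
        se=se,
        ci_low=diff - zcrit * se,
        ci_high=diff + zcrit * se,
        n_analyzed=n1 + n0,
        level=confidence_level,
        model="riskdiff",
    )


_MODEL_FITTERS = {"logit": fit_logit_y_on_x, "riskdiff": fit_risk_difference}


def _pool_fits(fits, confidence_level, model, method) -> AnalysisResult:
    pooled = pool_rubin(
        [f.estimate for f in fits],
        [f.se**2 for f in fits],
        confidence_level=confidence_level,
    )
    return AnalysisResult(
        estimate=pooled.estimate,
        se=float(np.sqrt(pooled.total)),
        ci_low=pooled.ci_low,
        ci_high=pooled.ci_high,
        n_analyzed=fits[0].n_analyzed,
        level=confidence_level,
        model=model,
        method=method,
        mc_error=float(np.sqrt(pooled.between / pooled.m)),
    )


def analyze_with_method(
    data: pd.DataFrame,
    definition: CompositeDefinition,
    method: str,
    model: str = "logit",
    spec: ImputationSpec | None = None,
    confidence_level: float = 0.95,
) -> AnalysisResult:
    """Apply one missing-data handling method, then fit the analysis model.

    ``Full`` requires a complete true-y column; ``CRA`` keeps rows with all
    components observed; ``Deriv`` keeps rows whose endpoint is derivable;
    the MI methods fit the model on each completed dataset and pool with
    Rubin's rules.
    """
    if model not in _MODEL_FITTERS:
        raise DomainError(f"unknown analysis model {model!r}")
    fitter = _MODEL_FITTERS[model]
    try:
        if method == "Full":
            if "y" not in data.columns or data["y"].isna().any():
                raise DomainError("Full-data analysis requires a complete y column")
            return _tag(fitter(data, confidence_level), method)
        if method == "CRA":
            return _tag(fitter(complete_records(data, definition), confidence_level), method)
        if method == "Deriv":
            derived = derive_endpoint(data, definition)
            kept = derived.loc[derived["r_y_deriv"] == 1]
            if len(kept) == 0:
                raise EmptyAnalysisSetError("no rows with a derivable endpoint")
            return _tag(fitter(kept, confidence_level, ycol="y_deriv"), method)
        if method in COMPOSITE_STRATEGIES or method in COMPONENT_STRATEGIES:
            if spec is None:
                spec = ImputationSpec()
            if method in COMPOSITE_STRATEGIES:
                completed = impute_composite(data, definition, method, spec)
            else:
                completed = impute_components_mice(data, definition, method, spec)
            fits = [fitter(frame, confidence_level) for frame in completed]
            return _pool_fits(fits, confidence_level, model, method)
        raise DomainError(f"unknown method {method!r}; expected one of {METHODS}")
    except Exception as exc:
        if not getattr(exc, "_method_tagged", False):
            exc.args = (f"[{method}] {exc}",) + exc.args[1:]
            exc._method_tagged = True
        raise


def _tag(result: AnalysisResult, method: str) -> AnalysisResult:
    return AnalysisResult(**{**result.__dict__, "method": method})
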