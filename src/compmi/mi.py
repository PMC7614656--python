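"""Multiple imputation for composite endpoints, at composite or component level.

Composite-level strategies impute the endpoint itself with a univariate
logistic model on randomized treatment:

* ``MI-CRA``   — y is treated as missing for every row with any missing
  component (the imputation analogue of complete-record analysis);
* ``MI-Deriv`` — y is first derived from observed components where possible
  and only the underivable rows are imputed (inherits the derived endpoint's
  bias).

Component-level strategies run chained equations (MICE) over the incomplete
components z2 and z3 with logistic conditional models, then passively
compute y from the completed components:

* ``MIC-main``  — x, z1 and the other component as main effects;
* ``MIC-x``    — z1 and the other component, fit separately within treatment
  strata (equivalent to a model with all two-way treatment interactions);
* ``MIC-x-z1`` — the other component only, fit within (x, z1) strata
  (equivalent to the saturated interaction model; never mis-specified but
  most exposed to perfect prediction in small strata).

All imputation is *proper*: each imputed value uses a coefficient vector
drawn from the asymptotic normal distribution of the fitted conditional
model, so between-imputation variance reflects parameter uncertainty.
Perfect prediction raises a typed error unless pseudo-observation
augmentation is enabled.  Estimates from the M completed datasets are
combined by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._logit import LogitFit, augmented_design, fit_logistic
from .composite import CompositeDefinition, derive_endpoint
from .errors import (
    DegenerateStratumError,
    DomainError,
    EmptyAnalysisSetError,
    PoolingError,
)

__all__ = [
    "ImputationSpec",
    "PooledEstimate",
    "impute_logistic_univariate",
    "impute_composite",
    "impute_components_mice",
    "augment_fit",
    "pool_rubin",
    "COMPOSITE_STRATEGIES",
    "COMPONENT_STRATEGIES",
]

COMPOSITE_STRATEGIES = ("MI-CRA", "MI-Deriv")
COMPONENT_STRATEGIES = ("MIC-main", "MIC-x", "MIC-x-z1")


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class ImputationSpec:
    """How many imputations to draw and how to draw them.

    ``m`` completed datasets; ``burnin`` chained-equation cycles per
    imputation (component level only); ``augment`` enables pseudo-observation
    augmentation with per-observation weight ``augment_weight``.
    """

    m: int = 25
    burnin: int = 20
    augment: bool = False
    augment_weight: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise DomainError(f"m = {self.m} imputations; at least 2 required")
        if self.burnin < 1:
            raise DomainError(f"burnin = {self.burnin}; at least 1 cycle required")
        if self.augment_weight <= 0:
            raise DomainError("augment_weight must be positive")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of M point estimates and variances."""

    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    level: float
    m: int


def augment_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    augment_weight: float = 0.01,
) -> LogitFit:
    """Weighted logistic fit with pseudo-observation augmentation.

    Always returns finite coefficients, even under perfect prediction; with
    no separation and small weight the fit matches the plain MLE closely
    (the 2p added rows carry total weight 2p*augment_weight).
    """
    Xa, ya, wa = augmented_design(X, y, weights, augment_weight)
    return fit_logistic(Xa, ya, weights=wa, divergence_bound=np.inf)


def _fit_imputation_model(
    X: np.ndarray,
    y: np.ndarray,
    spec: ImputationSpec,
    context: str,
) -> LogitFit:
    try:
        if spec.augment:
            return augment_fit(X, y, augment_weight=spec.augment_weight)
        return fit_logistic(X, y)
    except DegenerateStratumError:
        raise
    except Exception as exc:
        raise type(exc)(f"{context}: {exc}") from exc


def impute_logistic_univariate(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    rng: np.random.Generator,
    augment: bool = False,
    augment_weight: float = 0.01,
) -> pd.Series:
    """One proper imputation of a binary outcome from a logistic model.

    Fits on rows with the outcome observed, draws a coefficient vector from
    the asymptotic normal at the MLE, and fills the missing rows with
    Bernoulli draws at the drawn coefficients.
    """
    for col in predictors:
        if data[col].isna().any():
            raise DomainError(f"predictor {col!r} contains missing values")
    y = data[outcome].to_numpy(dtype="float64", na_value=np.nan)
    obs = ~np.isnan(y)
    if (~obs).sum() == 0:
        return data[outcome].copy()
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype="float64") for c in predictors]
    )
    fit = (
        augment_fit(X[obs], y[obs], augment_weight=augment_weight)
        if augment
        else fit_logistic(X[obs], y[obs])
    )
    beta = fit.draw_params(rng)
    p = expit(X[~obs] @ beta)
    completed = y.copy()
    completed[~obs] = (rng.random(p.shape) < p).astype(float)
    return pd.Series(
        pd.array(completed.astype(np.int8), dtype="Int8"),
        index=data.index,
        name=outcome,
    )


def impute_composite(
    data: pd.DataFrame,
    definition: CompositeDefinition,
    mode: str,
    spec: ImputationSpec,
) -> list[pd.DataFrame]:
    """Composite-level MI: M completed datasets with y imputed from x.

    ``MI-CRA`` discards all partially derived information: y counts as
    missing for any row with any missing component.  ``MI-Deriv`` keeps
    derived values and imputes only the underivable rows.
    """
    if mode not in COMPOSITE_STRATEGIES:
        raise DomainError(f"unknown composite-level mode {mode!r}")
    if data["x"].isna().any():
        raise DomainError("treatment column x must be complete")
    derived = derive_endpoint(data, definition)
    component_complete = np.ones(len(data), dtype=bool)
    for name in definition.components:
        component_complete &= data[name].notna().to_numpy()
    if mode == "MI-CRA":
        y_start = derived["y_deriv"].copy()
        y_start[~component_complete] = pd.NA
    else:
        y_start = derived["y_deriv"].copy()
    if y_start.notna().sum() == 0:
        raise EmptyAnalysisSetError(f"{mode}: no observed endpoint values to fit on")
    base = data.copy()
    base["y"] = y_start
    streams = _seed_seq(spec.seed).spawn(spec.m)
    completed = []
    for child in streams:
        rng = np.random.default_rng(child)
        copy = base.copy()
        copy["y"] = impute_logistic_univariate(
            copy, "y", ["x"], rng, augment=spec.augment, augment_weight=spec.augment_weight
        )
        completed.append(copy)
    return completed


# strategy -> (stratification columns, main-effect predictors given other component)
_STRATEGY_LAYOUT = {
    "MIC-main": ((), ("x", "z1", "other")),
    "MIC-x": (("x",), ("z1", "other")),
    "MIC-x-z1": (("x", "z1"), ("other",)),
}


def impute_components_mice(
    data: pd.DataFrame,
    definition: CompositeDefinition,
    strategy: str,
    spec: ImputationSpec,
) -> list[pd.DataFrame]:
    """Component-level chained-equations MI with passive composite imputation.

    Missing z2/z3 values are initialized by draws from the observed marginal
    of each column, then updated for ``spec.burnin`` cycles visiting z2 then
    z3 (fixed visit sequence).  Each update fits the strategy's conditional
    logistic model on the rows where the target was originally observed,
    draws coefficients, and redraws the originally missing values.  After the
    final cycle y is computed from the completed components.
    """
    if strategy not in _STRATEGY_LAYOUT:
        raise DomainError(f"unknown component-level strategy {strategy!r}")
    for col in ("x", "z1"):
        if data[col].isna().any():
            raise DomainError(f"column {col!r} must be complete")
    strata_cols, predictor_roles = _STRATEGY_LAYOUT[strategy]
    x = data["x"].to_numpy(dtype="float64")
    z1 = data["z1"].to_numpy(dtype="float64")
    z = {
        c: data[c].to_numpy(dtype="float64", na_value=np.nan) for c in ("z2", "z3")
    }
    obs = {c: ~np.isnan(z[c]) for c in ("z2", "z3")}
    for c in ("z2", "z3"):
        if obs[c].sum() == 0:
            raise EmptyAnalysisSetError(f"component {c} has no observed values")

    strata_arrays = {"x": x, "z1": z1}
    strata_values = [
        tuple(combo)
        for combo in (np.array(np.meshgrid(*[[0.0, 1.0]] * len(strata_cols))).T.reshape(-1, len(strata_cols)) if strata_cols else [()])
    ]

    completed_frames: list[pd.DataFrame] = []
    for child in _seed_seq(spec.seed).spawn(spec.m):
        rng = np.random.default_rng(child)
        cur = {c: z[c].copy() for c in ("z2", "z3")}
        for c in ("z2", "z3"):
            p0 = cur[c][obs[c]].mean()
            miss = ~obs[c]
            cur[c][miss] = (rng.random(miss.sum()) < p0).astype(float)
        for _ in range(spec.burnin):
            for target, other in (("z2", "z3"), ("z3", "z2")):
                _mice_update(
                    cur, target, other, obs[target], strata_cols, strata_values,
                    strata_arrays, predictor_roles, spec, rng, strategy,
                )
        out = data.copy()
        for c in ("z2", "z3"):
            out[c] = pd.array(cur[c].astype(np.int8), dtype="Int8")
        tri = definition.evaluate_frame(out)
        out["y"] = pd.array(tri, dtype="Int8")  # components complete => no -1
        completed_frames.append(out)
    return completed_frames


def _mice_update(
    cur, target, other, target_obs, strata_cols, strata_values, strata_arrays,
    predictor_roles, spec, rng, strategy,
):
    predictor_arrays = []
    for role in predictor_roles:
        predictor_arrays.append(cur[other] if role == "other" else strata_arrays[role])
    n = len(cur[target])
    X = np.column_stack([np.ones(n)] + predictor_arrays)
    y = cur[target]
    for combo in strata_values:
        if strata_cols:
            in_stratum = np.ones(n, dtype=bool)
            for col, val in zip(strata_cols, combo):
                in_stratum &= strata_arrays[col] == val
        else:
            in_stratum = np.ones(n, dtype=bool)
        fit_rows = in_stratum & target_obs
        fill_rows = in_stratum & ~target_obs
        if fill_rows.sum() == 0:
            continue
        label = (
            f"{strategy} imputing {target}"
            + (f" in stratum {dict(zip(strata_cols, combo))}" if strata_cols else "")
        )
        if fit_rows.sum() == 0:
            raise DegenerateStratumError(f"{label}: no rows to fit on")
        yfit = y[fit_rows]
        if not spec.augment and (yfit.min() == yfit.max()):
            raise DegenerateStratumError(
                f"{label}: outcome is constant in the fitting set "
                "(perfect prediction); enable augmentation"
            )
        fit = _fit_imputation_model(X[fit_rows], yfit, spec, label)
        beta = fit.draw_params(rng)
        p = expit(X[fill_rows] @ beta)
        y[fill_rows] = (rng.random(p.shape) < p).astype(float)


def pool_rubin(
    estimates,
    variances,
    confidence_level: float = 0.95,
) -> PooledEstimate:
    """Combine M complete-data estimates by Rubin's rules.

    Point estimate: mean.  Total variance T = W + (1 + 1/M) B with W the mean
    within-imputation variance and B the between-imputation sample variance.
    Degrees of freedom (M-1) * [1 + W / ((1+1/M) B)]^2, infinite when B = 0.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m < 2:
        raise PoolingError(f"pooling requires at least 2 estimates, got {m}")
    if np.any(var <= 0):
        raise PoolingError("all within-imputation variances must be positive")
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1 + 1 / m) * between
    if between > 0:
        df = (m - 1) * (1 + within / ((1 + 1 / m) * between)) ** 2
        tcrit = stats.t.ppf(0.5 + confidence_level / 2, df)
    else:
        df = np.inf
        tcrit = stats.norm.ppf(0.5 + confidence_level / 2)
    half = float(tcrit * np.sqrt(total))
    return PooledEstimate(
        estimate=point,
        within=within,
        between=between,
        total=total,
        df=float(df),
        ci_low=point - half,
        ci_high=point + half,
        level=confidence_level,
        m=m,
    )
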