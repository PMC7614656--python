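"""Saturated log-linear generator for three correlated binary components.

Each trial arm draws a component triple (z1, z2, z3) from the eight-cell
distribution

    p_c = exp(LP_c) / sum_c exp(LP_c),
    LP_c = l1*z1 + l2*z2 + l3*z3 + l12*z1*z2 + l23*z2*z3 + l13*z1*z3
           + l123*z1*z2*z3,

the linear predictor of a saturated log-linear model for the cell counts
(reference cell (0,0,0) has LP = 0).  The pairwise coefficients are log odds
ratios between two components when the third is 0; l123 is the three-way
interaction.  Two composite endpoints are read off each triple:

* ``simple``:  1 if any component is 1 (cells c = 2..8);
* ``complex``: 1 if z1 = 1 and (z2 = 1 or z3 = 1) (cells c = 6..8).

Arm-specific coefficients are calibrated so that the composite event
probability hits a target per arm — by default expit(0.3) ~ 0.574 in the
control arm and expit(0.3 + 1.35) ~ 0.839 under treatment, which makes the
treatment log odds ratio on the composite exactly 1.35.  Calibration uses
exchangeable main effects (l1 = l2 = l3 = m) with the interaction
coefficients held fixed, solving for m by bracketed root finding; the
composite event probability is strictly increasing in m, so the root is
unique when bracketed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import CalibrationError, DomainError

__all__ = [
    "LogLinearParams",
    "COMBINATIONS",
    "linear_predictor",
    "combination_table",
    "combination_probs",
    "composite_event_prob",
    "calibrate_lambdas",
    "case_interactions",
    "case_params",
    "simulate_trial",
    "DEFAULT_ARM_TARGETS",
]

#: The 8 component combinations in canonical order (c = 1..8 maps to rows
#: 0..7): z1 = 1 for c > 4; z2 = 1 for c in {3,4,7,8}; z3 = 1 for c in
#: {2,4,6,8}.
COMBINATIONS = np.array(
    [
        (0, 0, 0),
        (0, 0, 1),
        (0, 1, 0),
        (0, 1, 1),
        (1, 0, 0),
        (1, 0, 1),
        (1, 1, 0),
        (1, 1, 1),
    ],
    dtype=np.int8,
)

#: Default composite event-rate targets per arm: control expit(0.3),
#: treatment expit(0.3 + 1.35).
DEFAULT_ARM_TARGETS = (float(expit(0.3)), float(expit(0.3 + 1.35)))


@dataclass(frozen=True)
class LogLinearParams:
    """Log-linear coefficients for one arm's component distribution.

    ``mu0`` is the count-model intercept; it normalizes expected cell counts
    to the sample size and cancels out of the cell probabilities, so it
    defaults to 0 and never affects sampling.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0
    lambda12: float = 0.0
    lambda13: float = 0.0
    lambda23: float = 0.0
    lambda123: float = 0.0
    mu0: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "lambda1",
            "lambda2",
            "lambda3",
            "lambda12",
            "lambda13",
            "lambda23",
            "lambda123",
            "mu0",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"{name} = {v!r} is not finite")


def linear_predictor(params: LogLinearParams, triple) -> float:
    """LP for one component triple; the reference triple (0,0,0) gives 0."""
    z1, z2, z3 = triple
    if any(z not in (0, 1) for z in (z1, z2, z3)):
        raise DomainError(f"component triple {triple!r} is not binary")
    return (
        params.lambda1 * z1
        + params.lambda2 * z2
        + params.lambda3 * z3
        + params.lambda12 * z1 * z2
        + params.lambda23 * z2 * z3
        + params.lambda13 * z1 * z3
        + params.lambda123 * z1 * z2 * z3
    )


def _linear_predictors(params: LogLinearParams) -> np.ndarray:
    z1, z2, z3 = COMBINATIONS.T.astype(float)
    return (
        params.lambda1 * z1
        + params.lambda2 * z2
        + params.lambda3 * z3
        + params.lambda12 * z1 * z2
        + params.lambda23 * z2 * z3
        + params.lambda13 * z1 * z3
        + params.lambda123 * z1 * z2 * z3
    )


def combination_probs(params: LogLinearParams) -> np.ndarray:
    """The eight cell probabilities p_c (softmax of the linear predictors).

    The maximum LP is subtracted before exponentiation, so finite
    coefficients never overflow to NaN.
    """
    lp = _linear_predictors(params)
    shifted = np.exp(lp - lp.max())
    return shifted / shifted.sum()


def combination_table(params: LogLinearParams) -> pd.DataFrame:
    """The full combination table: triples, composite values, LP_c and p_c."""
    z1, z2, z3 = COMBINATIONS.T
    lp = _linear_predictors(params)
    return pd.DataFrame(
        {
            "c": np.arange(1, 9),
            "z1": z1,
            "z2": z2,
            "z3": z3,
            "y_simple": (COMBINATIONS.max(axis=1) == 1).astype(np.int8),
            "y_complex": ((z1 == 1) & ((z2 == 1) | (z3 == 1))).astype(np.int8),
            "lp": lp,
            "p": combination_probs(params),
        }
    )


def _composite_cells(definition: str) -> np.ndarray:
    if definition == "simple":
        return np.arange(1, 8)  # rows for c = 2..8
    if definition == "complex":
        return np.arange(5, 8)  # rows for c = 6..8
    raise DomainError(f"unknown composite definition {definition!r}")


def composite_event_prob(params: LogLinearParams, definition: str) -> float:
    """Model-implied P(y = 1) for the given composite definition."""
    return float(combination_probs(params)[_composite_cells(definition)].sum())


def calibrate_lambdas(
    target_event_prob: float,
    fixed: LogLinearParams | None = None,
    definition: str = "simple",
    bracket: tuple[float, float] = (-20.0, 20.0),
) -> LogLinearParams:
    """Solve for exchangeable main effects hitting a composite event rate.

    Sets l1 = l2 = l3 = m, keeps the interaction coefficients of ``fixed``,
    and solves composite_event_prob(params) = target to 1e-10 by Brent's
    method on the given bracket.  Raises :class:`CalibrationError`, reporting
    the achievable range, if the target is outside the bracketed range.
    """
    if not (0.0 < target_event_prob < 1.0):
        raise DomainError(f"target event probability {target_event_prob!r} not in (0,1)")
    base = fixed if fixed is not None else LogLinearParams()

    def with_main(m: float) -> LogLinearParams:
        return replace(base, lambda1=m, lambda2=m, lambda3=m)

    def objective(m: float) -> float:
        return composite_event_prob(with_main(m), definition) - target_event_prob

    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target {target_event_prob} not bracketed: achievable range is "
            f"[{f_lo + target_event_prob:.6g}, {f_hi + target_event_prob:.6g}] "
            f"for main effects in [{lo}, {hi}]"
        )
    m = brentq(objective, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return with_main(m)


#: Default exchangeable pairwise interactions per arm (control, treatment).
#: They differ by arm so that the component-component association depends on
#: treatment: the true conditional model for one component then carries
#: component-by-treatment interactions, and an imputation model with only
#: main effects of treatment is genuinely mis-specified in every case.
DEFAULT_PAIRWISE = (1.0, 0.2)


def case_interactions(
    case: str, pairwise: tuple[float, float] = DEFAULT_PAIRWISE
) -> tuple[LogLinearParams, LogLinearParams]:
    """Interaction settings (control, treatment) for the three study cases.

    Exchangeable two-way interactions take arm-specific values ``pairwise``
    (control, treatment).  The three-way interaction distinguishes the
    cases: case I has l123 = 0 in both arms (stratifying imputation by
    treatment alone is then sufficient); case II has l123 = 0 under
    treatment but 0.5 in control; case III has arm-specific nonzero values
    0.3 (treatment) and 0.6 (control), so only imputation stratified by both
    treatment and z1 is correctly specified.
    """
    three_way = {"I": (0.0, 0.0), "II": (0.5, 0.0), "III": (0.6, 0.3)}
    if case not in three_way:
        raise DomainError(f"unknown case {case!r}; expected 'I', 'II' or 'III'")
    l123_ctrl, l123_trt = three_way[case]
    make = lambda pw, l123: LogLinearParams(
        lambda12=pw, lambda13=pw, lambda23=pw, lambda123=l123
    )
    return make(pairwise[0], l123_ctrl), make(pairwise[1], l123_trt)


def case_params(
    case: str,
    definition: str = "simple",
    targets: tuple[float, float] = DEFAULT_ARM_TARGETS,
    pairwise: tuple[float, float] = DEFAULT_PAIRWISE,
) -> tuple[LogLinearParams, LogLinearParams]:
    """Fully calibrated (control, treatment) parameters for a study case."""
    ctrl_fix, trt_fix = case_interactions(case, pairwise=pairwise)
    ctrl = calibrate_lambdas(targets[0], ctrl_fix, definition)
    trt = calibrate_lambdas(targets[1], trt_fix, definition)
    return ctrl, trt


def components_from_combination(c: np.ndarray) -> np.ndarray:
    """Map combination indices c in 1..8 to component triples (bijection)."""
    c = np.asarray(c)
    if np.any((c < 1) | (c > 8)):
        raise DomainError("combination index outside 1..8")
    return COMBINATIONS[c - 1]


def simulate_trial(
    n: int,
    p_x: float,
    params_ctrl: LogLinearParams,
    params_trt: LogLinearParams,
    definition: str = "simple",
    seed=None,
) -> pd.DataFrame:
    """Simulate a fully observed trial dataset.

    Treatment is assigned by simple randomization, x ~ Bernoulli(p_x)
    independently per participant (arm sizes are random, not forced equal).
    Component triples are drawn from each arm's combination distribution and
    the composite y is computed from the definition.  Columns x, z1, z2, z3
    use the nullable Int8 dtype so that later masking can store missing
    values; y is complete here.
    """
    if n < 1:
        raise DomainError(f"n = {n} must be >= 1")
    if not (0.0 <= p_x <= 1.0):
        raise DomainError(f"p_x = {p_x!r} is not a probability")
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_x).astype(np.int8)
    cells = _composite_cells(definition)
    z = np.empty((n, 3), dtype=np.int8)
    y = np.empty(n, dtype=np.int8)
    for arm, params in ((0, params_ctrl), (1, params_trt)):
        idx = np.flatnonzero(x == arm)
        probs = combination_probs(params)
        draws = rng.choice(8, size=idx.size, p=probs)  # 0-based cell index
        z[idx] = COMBINATIONS[draws]
        y[idx] = np.isin(draws, cells).astype(np.int8)
    frame = pd.DataFrame(
        {
            "x": pd.array(x, dtype="Int8"),
            "z1": pd.array(z[:, 0], dtype="Int8"),
            "z2": pd.array(z[:, 1], dtype="Int8"),
            "z3": pd.array(z[:, 2], dtype="Int8"),
            "y": pd.array(y, dtype="Int8"),
        }
    )
    return frame
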