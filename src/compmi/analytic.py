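"""Closed-form bias analysis for a two-component binary composite endpoint.

Setting: a composite ``y = 1 if z1 = 1 or z2 = 1`` built from two binary
components, where ``z1`` is always observed and ``z2`` is missing completely
at random (MCAR) with observation probability ``alpha``.  The "derived
endpoint" strategy reads ``y`` off the observed component where possible
(``z1 = 1`` determines ``y = 1`` on its own) and treats the rest as missing.

Although ``z2`` is MCAR, the derived endpoint's own missingness depends on
the unobserved outcome value, i.e. the derived endpoint can be missing not
at random.  This module provides the exact distribution of that induced
missingness, the odds ratios estimated from full data and from the derived
endpoint, and the multiplicative bias

    OR_deriv / OR_full = [1 - (1 - alpha) * sigma] / [1 - (1 - alpha) * tau],

where ``sigma`` and ``tau`` are the per-arm fractions
``p01 / (p01 + p10 + p11)`` — the share of composite events that are carried
by ``z2`` alone.  The bias factor always lies in ``[alpha, 1/alpha]``.
Complete-record analysis (dropping every row with ``z2`` missing) is exempt:
under MCAR its outcome distribution equals the full-data one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateOddsError, DomainError, UndefinedConditionalError

__all__ = [
    "TwoComponentJoint",
    "BiasDecomposition",
    "derived_missingness_probs",
    "outcome_dist_by_derivability",
    "odds_ratio_full",
    "odds_ratio_derived",
    "bias_ratio",
    "cra_outcome_dist",
    "event_share_z2_only",
]

_SUM_TOL = 1e-12


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"{name} = {value!r} is not a probability in [0, 1]")


@dataclass(frozen=True)
class TwoComponentJoint:
    """Joint distribution of two binary components within one arm.

    ``pjk`` is P(z1 = j, z2 = k).  The four cells must be nonnegative and sum
    to 1 (tolerance 1e-12).
    """

    p00: float
    p01: float
    p10: float
    p11: float

    def __post_init__(self) -> None:
        for name in ("p00", "p01", "p10", "p11"):
            _check_prob(name, getattr(self, name))
        total = self.p00 + self.p01 + self.p10 + self.p11
        if abs(total - 1.0) > _SUM_TOL:
            raise DomainError(f"cell probabilities sum to {total!r}, not 1")

    @classmethod
    def from_marginals(cls, p1: float, p2: float) -> "TwoComponentJoint":
        """Joint for independent components with P(z1=1)=p1, P(z2=1)=p2."""
        _check_prob("p1", p1)
        _check_prob("p2", p2)
        return cls(
            p00=(1 - p1) * (1 - p2),
            p01=(1 - p1) * p2,
            p10=p1 * (1 - p2),
            p11=p1 * p2,
        )

    @property
    def event_prob(self) -> float:
        """P(y = 1) = p01 + p10 + p11 for the OR-composite."""
        return self.p01 + self.p10 + self.p11


@dataclass(frozen=True)
class BiasDecomposition:
    """Odds ratios and the sigma/tau decomposition of the derived-endpoint bias.

    ``sigma`` is the event share attached to the numerator arm of the odds
    ratio and ``tau`` to the denominator arm; ``ratio = or_deriv / or_full``.
    """

    or_full: float
    or_deriv: float
    ratio: float
    sigma: float
    tau: float
    alpha: float

    def __post_init__(self) -> None:
        if abs(self.ratio - self.or_deriv / self.or_full) > 1e-10:
            raise DomainError("ratio inconsistent with or_deriv / or_full")
        _check_prob("sigma", self.sigma)
        _check_prob("tau", self.tau)
        if not (0.0 < self.alpha <= 1.0):
            raise DomainError(f"alpha = {self.alpha!r} not in (0, 1]")
        lo, hi = self.alpha, 1.0 / self.alpha
        if not (lo - 1e-10 <= self.ratio <= hi + 1e-10):
            raise DomainError("bias ratio violates the factor-alpha bound")


def derived_missingness_probs(
    joint: TwoComponentJoint, alpha: float
) -> tuple[float, float]:
    """Distribution of the derived endpoint's response indicator.

    Returns ``(P(r_deriv = 0), P(r_deriv = 1))``: the endpoint is underivable
    exactly when z2 is unobserved and z1 = 0.
    """
    _check_prob("alpha", alpha)
    p_missing = (1 - alpha) * (joint.p00 + joint.p01)
    return p_missing, 1.0 - p_missing


def outcome_dist_by_derivability(
    joint: TwoComponentJoint, alpha: float
) -> tuple[float, float]:
    """``(P(y=1 | r_deriv=0), P(y=1 | r_deriv=1))``.

    The first conditional exists only if underivable rows occur (alpha < 1 and
    p00 + p01 > 0); the two generally differ, which is the MNAR phenomenon.
    """
    _check_prob("alpha", alpha)
    p_nonderiv = joint.p00 + joint.p01
    if alpha >= 1.0 or p_nonderiv <= 0.0:
        raise UndefinedConditionalError(
            "P(y | r_deriv = 0) is undefined: no underivable rows "
            f"(alpha={alpha}, p00+p01={p_nonderiv})"
        )
    among_missing = joint.p01 / p_nonderiv
    denom = alpha + (1 - alpha) * (joint.p10 + joint.p11)
    among_derivable = (alpha * joint.p01 + joint.p10 + joint.p11) / denom
    return among_missing, among_derivable


def _odds_cells(arm: TwoComponentJoint, label: str) -> tuple[float, float]:
    event = arm.event_prob
    if arm.p00 <= 0.0 or event <= 0.0:
        raise DegenerateOddsError(
            f"{label} arm has degenerate odds: P(y=1)={event}, P(y=0)={arm.p00}"
        )
    return event, arm.p00


def odds_ratio_full(trt: TwoComponentJoint, ctrl: TwoComponentJoint) -> float:
    """Full-data odds ratio of the composite, treatment vs control."""
    s_event, s00 = _odds_cells(trt, "treatment")
    t_event, t00 = _odds_cells(ctrl, "control")
    return (s_event * t00) / (t_event * s00)


def odds_ratio_derived(
    trt: TwoComponentJoint, ctrl: TwoComponentJoint, alpha: float
) -> float:
    """Odds ratio estimated from the derived endpoint among derivable rows.

    Equals ``odds_ratio_full`` at alpha = 1 (no missingness).
    """
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha = {alpha!r} not in (0, 1]")
    _, s00 = _odds_cells(trt, "treatment")
    _, t00 = _odds_cells(ctrl, "control")
    num = (alpha * trt.p01 + trt.p10 + trt.p11) * t00
    den = (alpha * ctrl.p01 + ctrl.p10 + ctrl.p11) * s00
    return num / den


def event_share_z2_only(arm: TwoComponentJoint) -> float:
    """Fraction of an arm's composite events carried by z2 alone:
    p01 / (p01 + p10 + p11)."""
    event = arm.event_prob
    if event <= 0.0:
        raise DegenerateOddsError("arm has zero composite event probability")
    return arm.p01 / event


def bias_ratio(
    trt: TwoComponentJoint, ctrl: TwoComponentJoint, alpha: float
) -> BiasDecomposition:
    """Multiplicative bias of the derived-endpoint odds ratio.

    ``sigma`` is the event share of the treatment (numerator) arm and ``tau``
    that of the control (denominator) arm; the returned ratio satisfies
    ``ratio = [1-(1-alpha)*sigma] / [1-(1-alpha)*tau] = or_deriv / or_full``
    and lies within the factor-alpha bound ``[alpha, 1/alpha]``.  With the
    arms swapped the ratio inverts, so an x% underestimate in one labelling
    is the reciprocal overestimate in the other.
    """
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha = {alpha!r} not in (0, 1]")
    sigma = event_share_z2_only(trt)
    tau = event_share_z2_only(ctrl)
    or_full = odds_ratio_full(trt, ctrl)
    or_deriv = odds_ratio_derived(trt, ctrl, alpha)
    ratio = (1 - (1 - alpha) * sigma) / (1 - (1 - alpha) * tau)
    return BiasDecomposition(
        or_full=or_full,
        or_deriv=or_deriv,
        ratio=ratio,
        sigma=sigma,
        tau=tau,
        alpha=alpha,
    )


def cra_outcome_dist(arm_joint: TwoComponentJoint, alpha: float) -> float:
    """P(y = 1 | z2 observed) under MCAR — equal to the full-data P(y = 1).

    This is the complete-record validity result: restricting to rows with z2
    observed does not change the outcome distribution, whatever alpha > 0.
    """
    if alpha <= 0.0:
        raise UndefinedConditionalError(
            "conditioning on z2 observed is undefined when alpha = 0"
        )
    _check_prob("alpha", alpha)
    return arm_joint.event_prob
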