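"""Closed-form engine vs exhaustive enumeration over (z1, z2, r_z2)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compmi.analytic import (
    BiasDecomposition,
    TwoComponentJoint,
    bias_ratio,
    cra_outcome_dist,
    derived_missingness_probs,
    event_share_z2_only,
    odds_ratio_derived,
    odds_ratio_full,
    outcome_dist_by_derivability,
)
from compmi.errors import DegenerateOddsError, DomainError, UndefinedConditionalError

from conftest import random_joint


def enumerate_outcomes(joint, alpha):
    """Independent oracle: the 8 atoms (z1, z2, r2) with their probabilities.

    r2 is independent of everything (MCAR); y = z1 or z2; the endpoint is
    derivable unless r2 = 0 and z1 = 0.
    """
    cells = {(0, 0): joint.p00, (0, 1): joint.p01, (1, 0): joint.p10, (1, 1): joint.p11}
    atoms = []
    for (z1, z2), p in cells.items():
        for r2, pr in ((1, alpha), (0, 1 - alpha)):
            y = int(z1 == 1 or z2 == 1)
            derivable = int(r2 == 1 or z1 == 1)
            atoms.append(dict(z1=z1, z2=z2, r2=r2, y=y, derivable=derivable, p=p * pr))
    return atoms


def oracle_probs(joint, alpha):
    atoms = enumerate_outcomes(joint, alpha)
    p_nonderiv = sum(a["p"] for a in atoms if not a["derivable"])
    p_deriv = 1 - p_nonderiv
    y_given_nonderiv = (
        sum(a["p"] for a in atoms if not a["derivable"] and a["y"]) / p_nonderiv
        if p_nonderiv > 0
        else None
    )
    y_given_deriv = sum(a["p"] for a in atoms if a["derivable"] and a["y"]) / p_deriv
    y_given_complete = sum(a["p"] for a in atoms if a["r2"] and a["y"]) / sum(
        a["p"] for a in atoms if a["r2"]
    )
    return p_nonderiv, p_deriv, y_given_nonderiv, y_given_deriv, y_given_complete


class TestDerivedMissingness:
    def test_no_missingness_means_always_derivable(self, rng):
        joint = random_joint(rng)
        assert derived_missingness_probs(joint, 1.0) == (0.0, 1.0)

    def test_uniform_joint_alpha_zero(self):
        joint = TwoComponentJoint(0.25, 0.25, 0.25, 0.25)
        p0, p1 = derived_missingness_probs(joint, 0.0)
        assert p0 == pytest.approx(0.5, abs=1e-15)
        assert p1 == pytest.approx(0.5, abs=1e-15)

    def test_derived_example(self):
        joint = TwoComponentJoint(0.1, 0.2, 0.3, 0.4)
        p0, p1 = derived_missingness_probs(joint, 0.3)
        # frozen from the enumeration oracle: (1-0.3)*(0.1+0.2) = 0.21
        assert p0 == pytest.approx(0.21, abs=1e-15)
        assert p1 == pytest.approx(0.79, abs=1e-15)

    def test_invalid_alpha_rejected(self, rng):
        with pytest.raises(DomainError, match="alpha"):
            derived_missingness_probs(random_joint(rng), 1.5)


class TestOutcomeByDerivability:
    def test_no_events_among_nonderivable_when_p01_zero(self):
        joint = TwoComponentJoint(0.5, 0.0, 0.3, 0.2)
        among_missing, _ = outcome_dist_by_derivability(joint, 0.5)
        assert among_missing == 0.0

    def test_alpha_near_one_recovers_marginal_event_prob(self):
        joint = TwoComponentJoint(0.1, 0.2, 0.3, 0.4)
        _, among_derivable = outcome_dist_by_derivability(joint, 1 - 1e-9)
        assert among_derivable == pytest.approx(joint.event_prob, abs=1e-8)

    def test_undefined_conditional_is_an_error(self):
        joint = TwoComponentJoint(0.0, 0.0, 0.5, 0.5)  # p00+p01 = 0
        with pytest.raises(UndefinedConditionalError):
            outcome_dist_by_derivability(joint, 0.5)

    def test_mnar_strict_inequality_on_worked_example(self, worked_example_joints):
        # the derived endpoint's value distribution differs between derivable
        # and underivable rows: missingness depends on the outcome (MNAR)
        for joint in worked_example_joints:
            among_missing, among_derivable = outcome_dist_by_derivability(joint, 0.3)
            assert among_missing != pytest.approx(among_derivable, abs=1e-6)


class TestOddsRatios:
    def test_null_effect_gives_unit_or(self, rng):
        joint = random_joint(rng)
        assert odds_ratio_full(joint, joint) == pytest.approx(1.0, abs=1e-12)
        assert odds_ratio_derived(joint, joint, 0.4) == pytest.approx(1.0, abs=1e-12)

    def test_full_or_matches_direct_arithmetic(self, worked_example_joints):
        ctrl, trt = worked_example_joints  # P=0.7 arm, P=0.2 arm
        # events: 1-0.8^2=0.36 (trt), 1-0.3^2=0.91 (ctrl)
        expected = (0.36 / 0.64) / (0.91 / 0.09)
        assert odds_ratio_full(trt, ctrl) == pytest.approx(expected, rel=1e-12)

    def test_swapping_arms_inverts(self, rng):
        a, b = random_joint(rng), random_joint(rng)
        assert odds_ratio_full(a, b) == pytest.approx(1 / odds_ratio_full(b, a), rel=1e-12)

    def test_alpha_one_is_identity(self, rng):
        a, b = random_joint(rng), random_joint(rng)
        assert odds_ratio_derived(a, b, 1.0) == pytest.approx(
            odds_ratio_full(a, b), rel=1e-12
        )

    def test_degenerate_cells_raise(self):
        degenerate = TwoComponentJoint(0.0, 0.5, 0.25, 0.25)
        other = TwoComponentJoint(0.25, 0.25, 0.25, 0.25)
        with pytest.raises(DegenerateOddsError):
            odds_ratio_full(degenerate, other)


class TestBiasRatio:
    def test_equal_event_shares_mean_no_bias(self):
        # different joints engineered to share p01/(p01+p10+p11)
        a = TwoComponentJoint(0.4, 0.12, 0.24, 0.24)
        b = TwoComponentJoint(0.2, 0.16, 0.32, 0.32)
        assert event_share_z2_only(a) == pytest.approx(event_share_z2_only(b))
        assert bias_ratio(a, b, 0.3).ratio == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_shares_and_inflation(self, worked_example_joints):
        arm_07, arm_02 = worked_example_joints
        assert round(event_share_z2_only(arm_07), 2) == 0.23
        assert round(event_share_z2_only(arm_02), 2) == 0.44
        # with the 0.7 arm in the numerator the derived OR is inflated 22%
        dec = bias_ratio(arm_07, arm_02, alpha=0.3)
        assert round(100 * (dec.ratio - 1)) == 22
        # the opposite labelling gives the reciprocal (an 18% deflation)
        assert bias_ratio(arm_02, arm_07, 0.3).ratio == pytest.approx(
            1 / dec.ratio, rel=1e-12
        )

    def test_ratio_consistent_and_bounded_over_random_inputs(self, rng):
        for _ in range(1000):
            trt, ctrl = random_joint(rng), random_joint(rng)
            alpha = rng.uniform(0.05, 1.0)
            dec = bias_ratio(trt, ctrl, alpha)
            assert dec.ratio == pytest.approx(dec.or_deriv / dec.or_full, abs=1e-10)
            assert alpha - 1e-12 <= dec.ratio <= 1 / alpha + 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=8, max_size=8),
        st.floats(0.05, 1.0),
    )
    def test_factor_alpha_bound_property(self, raw, alpha):
        """For every valid pair of arms the derived/full OR ratio lies in
        [alpha, 1/alpha], and matches the sigma/tau closed form."""
        t = np.array(raw[:4]) / sum(raw[:4])
        c = np.array(raw[4:]) / sum(raw[4:])
        dec = bias_ratio(TwoComponentJoint(*t), TwoComponentJoint(*c), alpha)
        assert alpha - 1e-9 <= dec.ratio <= 1 / alpha + 1e-9
        expected = (1 - (1 - alpha) * dec.sigma) / (1 - (1 - alpha) * dec.tau)
        assert dec.ratio == pytest.approx(expected, rel=1e-12)

    def test_zero_event_arm_raises(self):
        dead = TwoComponentJoint(1.0, 0.0, 0.0, 0.0)
        live = TwoComponentJoint(0.25, 0.25, 0.25, 0.25)
        with pytest.raises(DegenerateOddsError):
            bias_ratio(dead, live, 0.5)


class TestEnumerationEquivalence:
    def test_closed_forms_match_oracle(self, rng):
        for _ in range(300):
            joint = random_joint(rng)
            alpha = rng.uniform(0.05, 0.95)
            p_nd, p_d, y_nd, y_d, y_cr = oracle_probs(joint, alpha)
            got_nd, got_d = derived_missingness_probs(joint, alpha)
            assert got_nd == pytest.approx(p_nd, abs=1e-12)
            assert got_d == pytest.approx(p_d, abs=1e-12)
            m, d = outcome_dist_by_derivability(joint, alpha)
            assert m == pytest.approx(y_nd, abs=1e-12)
            assert d == pytest.approx(y_d, abs=1e-12)
            assert cra_outcome_dist(joint, alpha) == pytest.approx(y_cr, abs=1e-12)

    def test_derived_or_matches_two_arm_enumeration(self, rng):
        for _ in range(200):
            trt, ctrl = random_joint(rng), random_joint(rng)
            alpha = rng.uniform(0.05, 0.95)
            _, _, _, yd_trt, _ = oracle_probs(trt, alpha)
            _, _, _, yd_ctrl, _ = oracle_probs(ctrl, alpha)
            oracle_or = (yd_trt / (1 - yd_trt)) / (yd_ctrl / (1 - yd_ctrl))
            assert odds_ratio_derived(trt, ctrl, alpha) == pytest.approx(
                oracle_or, rel=1e-10
            )


class TestCompleteRecordValidity:
    def test_invariant_in_alpha(self, rng):
        joint = random_joint(rng)
        assert cra_outcome_dist(joint, 0.1) == cra_outcome_dist(joint, 0.9)

    def test_no_events(self):
        assert cra_outcome_dist(TwoComponentJoint(1.0, 0.0, 0.0, 0.0), 0.5) == 0.0

    def test_alpha_zero_is_undefined(self, rng):
        with pytest.raises(UndefinedConditionalError):
            cra_outcome_dist(random_joint(rng), 0.0)


class TestJointValidation:
    def test_negative_cell_named(self):
        with pytest.raises(DomainError, match="p01"):
            TwoComponentJoint(0.5, -0.1, 0.3, 0.3)

    def test_cells_must_sum_to_one(self):
        with pytest.raises(DomainError, match="sum"):
            TwoComponentJoint(0.3, 0.3, 0.3, 0.3)

    def test_decomposition_invariants_enforced(self):
        with pytest.raises(DomainError):
            BiasDecomposition(
                or_full=1.0, or_deriv=2.0, ratio=1.5, sigma=0.2, tau=0.4, alpha=0.5
            )
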