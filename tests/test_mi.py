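"""Imputation engine: properness, passivity, strategy layouts, pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from compmi._logit import fit_logistic
from compmi.composite import simple_composite
from compmi.dgm import case_params, simulate_trial
from compmi.errors import DegenerateStratumError, DomainError, PoolingError
from compmi.mi import (
    ImputationSpec,
    impute_components_mice,
    impute_composite,
    impute_logistic_univariate,
    pool_rubin,
)
from compmi.missingness import PRESETS, apply_missingness


@pytest.fixture(scope="module")
def masked_trial():
    ctrl, trt = case_params("I")
    full = simulate_trial(3000, 0.5, ctrl, trt, seed=202)
    return full, apply_missingness(full, PRESETS["MCAR"], PRESETS["MCAR"], seed=203)


class TestPoolRubin:
    def test_hand_arithmetic_example(self):
        pooled = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert pooled.estimate == 2.0
        assert pooled.within == 1.0
        assert pooled.between == 2.0
        assert pooled.total == pytest.approx(1.0 + 1.5 * 2.0)

    def test_identical_estimates_collapse_to_wald(self):
        pooled = pool_rubin([0.5] * 5, [0.04] * 5, confidence_level=0.95)
        assert pooled.between == 0.0
        assert pooled.total == pooled.within
        assert pooled.df == np.inf
        half = 1.959963984540054 * np.sqrt(0.04)
        assert pooled.ci_low == pytest.approx(0.5 - half)
        assert pooled.ci_high == pytest.approx(0.5 + half)

    def test_total_variance_never_below_within(self, rng):
        for _ in range(20):
            est = rng.normal(size=8)
            var = rng.uniform(0.01, 1.0, size=8)
            pooled = pool_rubin(est, var)
            assert pooled.total >= pooled.within
            assert pooled.ci_low <= pooled.estimate <= pooled.ci_high

    def test_single_estimate_rejected(self):
        with pytest.raises(PoolingError):
            pool_rubin([1.0], [1.0])


class TestUnivariateImputation:
    def test_no_missing_is_identity(self, rng):
        data = pd.DataFrame(
            {
                "x": pd.array(rng.integers(0, 2, 200), dtype="Int8"),
                "y": pd.array(rng.integers(0, 2, 200), dtype="Int8"),
            }
        )
        out = impute_logistic_univariate(data, "y", ["x"], rng)
        assert (out == data["y"]).all()

    def test_imputed_rate_tracks_observed_rate(self, rng):
        n = 40_000
        y = pd.array((rng.random(n) < 0.35).astype("int8"), dtype="Int8")
        y[rng.random(n) < 0.4] = pd.NA
        data = pd.DataFrame({"x": pd.array(rng.integers(0, 2, n), dtype="Int8"), "y": y})
        observed_rate = data["y"].dropna().astype(float).mean()
        out = impute_logistic_univariate(data, "y", ["x"], rng)
        imputed = out[data["y"].isna()].astype(float)
        se = np.sqrt(0.35 * 0.65 / len(imputed))
        assert abs(imputed.mean() - observed_rate) < 5 * se

    def test_different_streams_differ(self, rng):
        n = 500
        y = pd.array((rng.random(n) < 0.5).astype("int8"), dtype="Int8")
        y[rng.random(n) < 0.5] = pd.NA
        data = pd.DataFrame({"x": pd.array(rng.integers(0, 2, n), dtype="Int8"), "y": y})
        a = impute_logistic_univariate(data, "y", ["x"], np.random.default_rng(1))
        b = impute_logistic_univariate(data, "y", ["x"], np.random.default_rng(2))
        assert (a != b).any()


class TestCompositeLevelMI:
    def test_fully_observed_returns_identical_copies(self, masked_trial):
        full, _ = masked_trial
        spec = ImputationSpec(m=3, burnin=1, seed=1)
        defn = simple_composite()
        for mode in ("MI-CRA", "MI-Deriv"):
            for frame in impute_composite(full, defn, mode, spec):
                assert (frame["y"] == full["y"]).all()

    def test_micra_discards_derived_information(self, masked_trial):
        _, masked = masked_trial
        defn = simple_composite()
        spec = ImputationSpec(m=2, burnin=1, seed=2)
        derivable = (
            (masked["z1"] == 1)
            | (masked[["z1", "z2", "z3"]].notna().all(axis=1))
            | (masked["z2"] == 1)
            | (masked["z3"] == 1)
        )
        incomplete = masked[["z1", "z2", "z3"]].isna().any(axis=1)
        completed = impute_composite(masked, defn, "MI-CRA", spec)[0]
        completed2 = impute_composite(masked, defn, "MI-Deriv", spec)[0]
        # MI-Deriv keeps every derivable value fixed across imputations
        keep = derivable & incomplete
        copies = impute_composite(masked, defn, "MI-Deriv", ImputationSpec(m=3, seed=3))
        fixed = np.column_stack([c.loc[keep, "y"].to_numpy(dtype=float) for c in copies])
        assert (fixed.std(axis=1) == 0).all()
        assert completed["y"].notna().all() and completed2["y"].notna().all()

    def test_properness_between_variance_positive(self, masked_trial):
        _, masked = masked_trial
        spec = ImputationSpec(m=5, burnin=1, seed=4)
        copies = impute_composite(masked, simple_composite(), "MI-CRA", spec)
        rates = [c["y"].astype(float).mean() for c in copies]
        assert np.std(rates) > 0


class TestComponentLevelMICE:
    def test_complete_data_identity(self, masked_trial):
        full, _ = masked_trial
        spec = ImputationSpec(m=2, burnin=2, seed=5)
        for strategy in ("MIC-main", "MIC-x", "MIC-x-z1"):
            for frame in impute_components_mice(
                full, simple_composite(), strategy, spec
            ):
                pd.testing.assert_series_equal(frame["z2"], full["z2"])
                pd.testing.assert_series_equal(frame["z3"], full["z3"])

    def test_passive_composite_consistency(self, masked_trial):
        _, masked = masked_trial
        spec = ImputationSpec(m=3, burnin=3, seed=6)
        for definition in (simple_composite(),):
            for strategy in ("MIC-main", "MIC-x", "MIC-x-z1"):
                for frame in impute_components_mice(masked, definition, strategy, spec):
                    tri = definition.evaluate_frame(frame)
                    assert (frame["y"].to_numpy(dtype=int) == tri).all()

    def test_properness(self, masked_trial):
        _, masked = masked_trial
        spec = ImputationSpec(m=4, burnin=3, seed=7)
        copies = impute_components_mice(masked, simple_composite(), "MIC-x", spec)
        miss = masked["z2"].isna()
        stacked = np.column_stack(
            [c.loc[miss, "z2"].to_numpy(dtype=float) for c in copies]
        )
        assert (stacked.std(axis=1) > 0).any()

    def test_degenerate_stratum_raises_without_augment(self):
        # z2 observed only as 1 inside the (x=1, z1=1) stratum
        n = 80
        rngl = np.random.default_rng(8)
        x = pd.array(np.repeat([0, 1], n // 2), dtype="Int8")
        z1 = pd.array(rngl.integers(0, 2, n), dtype="Int8")
        z2 = pd.Series(pd.array(np.ones(n, dtype="int8"), dtype="Int8"))
        z2[(np.asarray(x) == 1) & (np.asarray(z1) == 1) & (rngl.random(n) < 0.5)] = pd.NA
        z2[:10] = pd.array([0, 1] * 5, dtype="Int8")  # avoid global invariance
        z3 = pd.array(rngl.integers(0, 2, n), dtype="Int8")
        data = pd.DataFrame({"x": x, "z1": z1, "z2": z2, "z3": z3})
        if not data["z2"].isna().any():  # pragma: no cover - guard
            pytest.skip("mask draw left nothing missing")
        spec = ImputationSpec(m=2, burnin=1, augment=False, seed=9)
        with pytest.raises(DegenerateStratumError, match="stratum"):
            impute_components_mice(data, simple_composite(), "MIC-x-z1", spec)
        # augmentation turns the same configuration into a finite fit
        spec_aug = ImputationSpec(m=2, burnin=1, augment=True, seed=9)
        frames = impute_components_mice(data, simple_composite(), "MIC-x-z1", spec_aug)
        assert all(f["z2"].notna().all() for f in frames)

    def test_stratified_equals_explicit_interaction_model(self, masked_trial):
        """MIC-x's stratified fits describe the same model as the explicit
        treatment-interaction parameterization: mapping the two stratum
        coefficient vectors into (base, difference) form reproduces the
        interaction-model predictions exactly."""
        _, masked = masked_trial
        sub = masked.dropna(subset=["z2", "z3"])
        x = sub["x"].to_numpy(dtype=float)
        z1 = sub["z1"].to_numpy(dtype=float)
        z3 = sub["z3"].to_numpy(dtype=float)
        y = sub["z2"].to_numpy(dtype=float)
        stratum_fits = {}
        for xv in (0.0, 1.0):
            mask = x == xv
            X = np.column_stack([np.ones(mask.sum()), z1[mask], z3[mask]])
            stratum_fits[xv] = fit_logistic(X, y[mask]).params
        b0, b1 = stratum_fits[0.0], stratum_fits[1.0]
        # interaction model: base coefficients b0, x-interactions b1 - b0
        Xint = np.column_stack([np.ones(len(y)), z1, z3, x, x * z1, x * z3])
        beta_int = np.concatenate([b0, b1 - b0])
        pred_interaction = expit(Xint @ beta_int)
        pred_stratified = np.where(
            x == 0,
            expit(np.column_stack([np.ones(len(y)), z1, z3]) @ b0),
            expit(np.column_stack([np.ones(len(y)), z1, z3]) @ b1),
        )
        assert pred_interaction == pytest.approx(pred_stratified, abs=1e-10)

    def test_spec_validation(self):
        with pytest.raises(DomainError):
            ImputationSpec(m=1)
        with pytest.raises(DomainError):
            ImputationSpec(m=5, burnin=0)
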