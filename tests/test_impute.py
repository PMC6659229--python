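import numpy as np
import pytest

from respondermi import (
    DropoutSpec,
    ImputationModelSpec,
    PROFILES,
    apply_dropout,
    classify_responders,
    fcs_impute,
    fill_in_start,
    impute_binary_draw,
    impute_continuous_draw,
    mask_dataset,
    nri_impute,
    run_strategy,
    simulate_trial,
)
from respondermi.impute import VariableSpec
from respondermi.pooling import diff_proportions


class TestNriImpute:
    def test_no_missing_is_identity(self, complete_trial):
        r = classify_responders(complete_trial)
        assert np.array_equal(nri_impute(r), r)

    def test_all_missing_all_non_responders(self, complete_trial):
        r = np.full(complete_trial.n, np.nan)
        filled = nri_impute(r)
        assert np.all(filled == 0.0)
        est = diff_proportions(filled, complete_trial.arm)
        assert est.p_A == est.p_B == 0.0

    def test_observed_untouched_and_missing_zeroed(self):
        r = np.array([1.0, np.nan, 0.0, np.nan])
        assert np.array_equal(nri_impute(r), [1.0, 0.0, 0.0, 0.0])


class TestContinuousDraw:
    def test_posterior_concentrates_on_noise_free_relation(self, rng):
        n = 5_000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 * x
        xm = rng.normal(size=50)
        Xm = np.column_stack([np.ones(50), xm])
        imp, _ = impute_continuous_draw(X, y, Xm, rng)
        assert np.allclose(imp, 2.0 * xm, atol=1e-3)

    def test_intercept_only_matches_closed_form(self, rng):
        # imputations ~ N(ybar, s^2) for large n
        n = 20_000
        y = rng.normal(10.0, 3.0, n)
        X = np.ones((n, 1))
        Xm = np.ones((5_000, 1))
        imp, _ = impute_continuous_draw(X, y, Xm, rng)
        assert imp.mean() == pytest.approx(y.mean(), abs=0.2)
        assert imp.std(ddof=1) == pytest.approx(y.std(ddof=1), rel=0.05)

    def test_same_seed_identical(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        y = np.arange(50.0) * 1.5 + 2.0
        Xm = X[:10]
        a, _ = impute_continuous_draw(X, y, Xm, rng1)
        b, _ = impute_continuous_draw(X, y, Xm, rng2)
        assert np.array_equal(a, b)

    def test_too_few_rows_rejected(self, rng):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="observed rows"):
            impute_continuous_draw(X, np.zeros(3), X, rng)

    def test_rank_deficient_design_falls_back(self, rng):
        # duplicated column: ridge jitter engages instead of crashing
        n = 100
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, x])
        y = x + rng.normal(0, 0.1, n)
        imp, jittered = impute_continuous_draw(X, y, X[:10], rng)
        assert np.all(np.isfinite(imp))
        assert jittered


class TestBinaryDraw:
    def test_separated_predictor_reproduces_rule(self, rng):
        n = 400
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = (x >= 0.3).astype(float)
        xm = rng.normal(size=2_000)
        Xm = np.column_stack([np.ones(2_000), xm])
        hits = []
        for _ in range(20):
            imp, fallback = impute_binary_draw(X, y, Xm, rng)
            assert fallback  # separation must be flagged
            hits.append(np.mean(imp == (xm >= 0.3)))
        assert np.mean(hits) > 0.9

    def test_intercept_only_prevalence(self, rng):
        n = 10_000
        y = (rng.random(n) < 0.3).astype(float)
        X = np.ones((n, 1))
        Xm = np.ones((10_000, 1))
        imp, _ = impute_binary_draw(X, y, Xm, rng)
        assert imp.mean() == pytest.approx(y.mean(), abs=0.03)

    def test_one_class_degenerate_fill(self, rng):
        X = np.ones((20, 1))
        y = np.ones(20)
        imp, fallback = impute_binary_draw(X, y, np.ones((7, 1)), rng)
        assert np.all(imp == 1.0) and fallback

    def test_same_seed_identical(self):
        X = np.column_stack([np.ones(100), np.linspace(-2, 2, 100)])
        y = (np.linspace(-2, 2, 100) + 0.5 * np.sin(np.arange(100)) > 0).astype(float)
        a, _ = impute_binary_draw(X, y, X, np.random.default_rng(9))
        b, _ = impute_binary_draw(X, y, X, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestFillInStart:
    def test_no_missing_unchanged(self, rng):
        cols = {"a": np.arange(5.0), "b": np.ones(5)}
        variables = [VariableSpec("a", "continuous"), VariableSpec("b", "continuous")]
        out = fill_in_start(cols, variables, rng)
        assert np.array_equal(out["a"], cols["a"])
        assert np.array_equal(out["b"], cols["b"])

    def test_constant_predictors_fill_with_mean(self, rng):
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        cols = {"c": np.ones(5), "y": y}
        variables = [VariableSpec("c", "continuous", imputed=False), VariableSpec("y", "continuous")]
        out = fill_in_start(cols, variables, rng)
        assert out["y"][4] == pytest.approx(2.5, rel=1e-3)  # ridge jitter on constant design

    def test_one_class_binary_fill(self, rng):
        r = np.array([1.0, 1.0, 1.0, np.nan, np.nan])
        cols = {"x": np.arange(5.0), "r": r}
        variables = [VariableSpec("x", "continuous", imputed=False), VariableSpec("r", "binary")]
        out = fill_in_start(cols, variables, rng)
        assert np.all(out["r"][3:] == 1.0)

    def test_all_missing_variable_rejected(self, rng):
        cols = {"x": np.arange(5.0), "y": np.full(5, np.nan)}
        variables = [VariableSpec("x", "continuous", imputed=False), VariableSpec("y", "continuous")]
        with pytest.raises(ValueError, match="no observed"):
            fill_in_start(cols, variables, rng)


class TestFcsImpute:
    def test_zero_missing_returns_identical_copies(self, rng):
        cols = {"x": rng.normal(size=30), "y": rng.normal(size=30)}
        variables = [VariableSpec("x", "continuous"), VariableSpec("y", "continuous")]
        completed, fallbacks = fcs_impute(cols, variables, M=4, cycles=3, seed=1)
        assert fallbacks == 0
        for cur in completed:
            assert np.array_equal(cur["x"], cols["x"])
            assert np.array_equal(cur["y"], cols["y"])

    def test_observed_cells_never_altered(self, masked_trial):
        masked, _ = masked_trial
        res = run_strategy(masked, "IBD", spec=ImputationModelSpec(M=3, cycles=2), seed=5)
        determined = ~np.isnan(classify_responders(masked))
        observed_status = classify_responders(masked)[determined]
        for m in range(res.M):
            assert np.array_equal(res.completed_responders[m, determined], observed_status)

    def test_mcar_recovers_full_data_proportion(self):
        # MCAR missingness on Y4 only: pooled arm-A proportion tracks the
        # full-data proportion over replicates
        deltas = []
        rng = np.random.default_rng(77)
        for _ in range(60):
            data = simulate_trial(PROFILES["linear"], n=200, seed=rng)
            full_p = classify_responders(data)[data.arm == 1].mean()
            masked = data.copy()
            drop = rng.random(200) < 0.3
            masked.Y[drop, 3] = np.nan
            res = run_strategy(masked, "IBD", spec=ImputationModelSpec(M=10, cycles=3), seed=rng)
            pooled_p = np.mean([e.p_A for e in res.per_imputation])
            deltas.append(pooled_p - full_p)
        assert abs(np.mean(deltas)) < 0.02

    def test_reproducible_under_seed(self, masked_trial):
        masked, _ = masked_trial
        a = run_strategy(masked, "IBD", spec=ImputationModelSpec(M=3, cycles=2), seed=123)
        b = run_strategy(masked, "IBD", spec=ImputationModelSpec(M=3, cycles=2), seed=123)
        assert np.array_equal(a.completed_responders, b.completed_responders)


class TestStackCompleted:
    def test_long_format_with_imputation_index(self, rng):
        from respondermi import stack_completed

        x = np.arange(10.0)
        x[7] = np.nan
        cols = {"x": x, "y": np.linspace(0, 1, 10)}
        variables = [VariableSpec("x", "continuous"), VariableSpec("y", "continuous", imputed=False)]
        completed, _ = fcs_impute(cols, variables, M=3, cycles=1, seed=4)
        frame = stack_completed(completed)
        assert list(frame.columns) == ["imputation", "x", "y"]
        assert len(frame) == 30
        assert sorted(frame["imputation"].unique()) == [1, 2, 3]
        assert not frame["x"].isna().any()


class TestRunStrategy:
    def test_nri_single_estimate(self, masked_trial):
        masked, _ = masked_trial
        res = run_strategy(masked, "NRI")
        assert len(res.per_imputation) == 1
        assert res.M == 1

    def test_unknown_strategy_rejected(self, masked_trial):
        masked, _ = masked_trial
        with pytest.raises(ValueError, match="strategy"):
            run_strategy(masked, "LOCF")

    def test_ibd_dti_identical_without_missing(self, complete_trial):
        spec = ImputationModelSpec(M=3, cycles=2)
        a = run_strategy(complete_trial, "IBD", spec=spec, seed=1)
        b = run_strategy(complete_trial, "DTI", spec=spec, seed=1)
        assert np.array_equal(a.completed_responders, b.completed_responders)
        assert a.per_imputation[0].p_A == b.per_imputation[0].p_A

    def test_nri_proportions_bounded_by_full_data(self):
        rng = np.random.default_rng(55)
        spec = DropoutSpec(model_id=1, target_rate=0.30)
        for i in range(20):
            data = simulate_trial(PROFILES["linear"], n=200, seed=rng)
            mask = apply_dropout(data, spec, seed=rng, cutoff=0.55)
            masked = mask_dataset(data, mask)
            full = classify_responders(data)
            nri = run_strategy(masked, "NRI").per_imputation[0]
            assert nri.p_A <= full[data.arm == 1].mean() + 1e-12
            assert nri.p_B <= full[data.arm == 0].mean() + 1e-12

    def test_include_cv_requires_column(self, masked_trial):
        masked, _ = masked_trial
        masked = masked.copy()
        masked.cv = None
        with pytest.raises(ValueError, match="CV"):
            run_strategy(masked, "IBD", spec=ImputationModelSpec(include_cv=True, M=2))

    def test_dti_exclude_endpoint_flag(self, masked_trial):
        masked, _ = masked_trial
        spec = ImputationModelSpec(M=3, cycles=2, dti_exclude_endpoint=True)
        res = run_strategy(masked, "DTI", spec=spec, seed=2)
        assert np.all(np.isfinite(res.completed_responders))

    def test_m_copies_shape(self, masked_trial):
        masked, _ = masked_trial
        res = run_strategy(masked, "IBD", spec=ImputationModelSpec(M=5, cycles=2), seed=3)
        assert res.completed_responders.shape == (5, masked.n)
        assert set(np.unique(res.completed_responders)) <= {0.0, 1.0}
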