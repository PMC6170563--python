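"""Transforms, OLS, AICc, all-subsets selection, confidence set, averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from econetres import (
    TransformSpec,
    aicc,
    all_subsets,
    confidence_set,
    fit_ols,
    model_average,
    transform,
)
from econetres.model_selection import ModelFit, _aicc_value, _rank_models


def make_fit(terms, coefs, ses, aicc_value, weight_placeholder=0.0, n=50):
    names = ["(Intercept)"] + list(terms)
    return ModelFit(
        terms=tuple(terms),
        coefficients=dict(zip(names, [0.0] + list(coefs))),
        std_errors=dict(zip(names, [0.1] + list(ses))),
        t_values={},
        p_values={},
        r_squared=0.5,
        log_likelihood=-(aicc_value / 2),
        n=n,
        k=len(terms) + 2,
        aicc=aicc_value,
    )


class TestTransform:
    def test_log_columns(self):
        df = pd.DataFrame({"richness": [1.0, np.e, np.e**2], "x": [1.0, 2.0, 3.0]})
        out = transform(df, TransformSpec(log_vars=("richness",), sqrt_vars=(), standardize=False))
        assert np.allclose(out["richness"], [0, 1, 2])

    def test_sqrt_before_scaling(self):
        df = pd.DataFrame({"p_ann": [4.0, 9.0, 16.0]})
        out = transform(df, TransformSpec(log_vars=(), sqrt_vars=("p_ann",), standardize=False))
        assert np.allclose(out["p_ann"], [2, 3, 4])

    def test_standardization_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"x": rng.uniform(1, 10, 30)})
        out = transform(df, TransformSpec(log_vars=(), sqrt_vars=(), standardize=True))
        assert abs(out["x"].mean()) < 1e-12
        assert out["x"].std(ddof=1) == pytest.approx(1.0)

    def test_non_positive_log_input_names_variable_and_site(self):
        df = pd.DataFrame({"t_velocity": [1.0, 0.0]}, index=["S1", "S2"])
        with pytest.raises(ValueError, match="t_velocity.*S2"):
            transform(df, TransformSpec(log_vars=("t_velocity",), sqrt_vars=()))

    def test_missing_variable_rejected(self):
        with pytest.raises(KeyError):
            transform(pd.DataFrame({"x": [1.0]}), TransformSpec(log_vars=("y",), sqrt_vars=()))


class TestFitOls:
    def test_exact_linear_relation(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(30), "b": rng.standard_normal(30)})
        y = 2.0 + 1.5 * X["a"] - 0.5 * X["b"]
        fit = fit_ols(y, X)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients["a"] == pytest.approx(1.5)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_intercept_only_is_mean(self, rng):
        y = rng.standard_normal(25)
        fit = fit_ols(y, None)
        assert fit.coefficients["(Intercept)"] == pytest.approx(y.mean())

    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(5):
            n = 40
            X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
            y = rng.standard_normal(n)
            fit = fit_ols(y, X)
            ref = sm.OLS(y, sm.add_constant(X)).fit()
            assert fit.coefficients["a"] == pytest.approx(ref.params["a"], abs=1e-10)
            assert fit.std_errors["b"] == pytest.approx(ref.bse["b"], abs=1e-10)
            assert fit.p_values["c"] == pytest.approx(ref.pvalues["c"], abs=1e-10)
            assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
            assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_collinear_terms_rejected(self, rng):
        a = rng.standard_normal(20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank"):
            fit_ols(rng.standard_normal(20), X)

    def test_filter_columns_counted_in_k(self, rng):
        n = 30
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        basis = np.linalg.qr(rng.standard_normal((n, 2)))[0]
        fit = fit_ols(rng.standard_normal(n), X, basis)
        # intercept + a + 2 filter cols + error variance
        assert fit.k == 5
        assert "_sevm2" in fit.coefficients


class TestAicc:
    def test_arithmetic(self):
        # -2logLik + 2k = 100 at n=10, k=3 -> AICc = 100 + 24/6 = 104
        assert _aicc_value(log_lik=-(100 - 6) / 2, n=10, k=3) == pytest.approx(104.0)

    def test_approaches_aic_for_large_n(self):
        ll = -500.0
        aic = -2 * ll + 2 * 3
        assert _aicc_value(ll, n=10**6, k=3) == pytest.approx(aic, abs=1e-3)

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            _aicc_value(-10.0, n=4, k=3)

    def test_accessor_matches_stored(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20)})
        fit = fit_ols(rng.standard_normal(20), X)
        assert aicc(fit) == pytest.approx(fit.aicc)


class TestAllSubsets:
    def test_enumerates_all_subsets(self, rng):
        n = 80
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        ms = all_subsets(rng.standard_normal(n), X)
        assert len(ms.fits) == 32

    def test_nine_candidates_give_512_models(self, rng):
        n = 60
        X = pd.DataFrame(rng.standard_normal((n, 9)), columns=[f"v{i}" for i in range(9)])
        ms = all_subsets(rng.standard_normal(n), X)
        assert len(ms.fits) == 512

    def test_weights_sum_to_one_and_sorted(self, rng):
        n = 60
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        ms = all_subsets(rng.standard_normal(n), X)
        assert sum(ms.akaike_weights) == pytest.approx(1.0)
        assert list(ms.delta_aicc) == sorted(ms.delta_aicc)
        assert ms.delta_aicc[0] == 0.0

    def test_strong_signal_term_selected(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 200
            X = pd.DataFrame(r.standard_normal((n, 4)), columns=list("abcd"))
            y = 0.8 * X["a"] + 0.3 * r.standard_normal(n)
            ms = all_subsets(y, X)
            hits += "a" in ms.best.terms
        assert hits >= 18

    def test_subset_fit_matches_fit_ols(self, rng):
        n = 50
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = rng.standard_normal(n)
        ms = all_subsets(y, X)
        for fit in ms.fits:
            direct = fit_ols(y, X[list(fit.terms)] if fit.terms else None)
            assert fit.aicc == pytest.approx(direct.aicc, abs=1e-8)
            for t in fit.terms:
                assert fit.coefficients[t] == pytest.approx(direct.coefficients[t], abs=1e-8)
                assert fit.std_errors[t] == pytest.approx(direct.std_errors[t], abs=1e-8)

    def test_best_model_aicc_never_exceeds_full(self, rng):
        n = 70
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        y = X["a"] + rng.standard_normal(n)
        ms = all_subsets(y, X)
        full = [f for f in ms.fits if len(f.terms) == 5][0]
        assert ms.best.aicc <= full.aicc

    def test_fixed_filter_in_every_model(self, rng):
        n = 50
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        basis = np.linalg.qr(rng.standard_normal((n, 2)))[0]
        ms = all_subsets(rng.standard_normal(n), X, filter_basis=basis)
        assert all("_sevm2" in f.coefficients for f in ms.fits)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(-50, 50))
    def test_weights_invariant_to_aicc_shift(self, shift):
        fits = [make_fit((), [], [], a) for a in (100.0, 101.0, 103.5)]
        shifted = [make_fit((), [], [], a + shift) for a in (100.0, 101.0, 103.5)]
        w1 = _rank_models(fits).akaike_weights
        w2 = _rank_models(shifted).akaike_weights
        assert np.allclose(w1, w2, atol=1e-12)

    def test_delta_two_weight_ratio(self):
        ms = _rank_models([make_fit((), [], [], 100.0), make_fit(("a",), [1.0], [0.1], 102.0)])
        assert ms.akaike_weights[0] == pytest.approx(0.731, abs=1e-3)
        assert ms.akaike_weights[1] == pytest.approx(0.269, abs=1e-3)


class TestConfidenceSet:
    def test_prefix_rule(self):
        fits = [make_fit((c,), [1.0], [0.1], 100.0 + d) for c, d in
                zip("abcd", [0.0, 1.3862943611, 4.0295, 6.8024])]
        ms = _rank_models(fits)
        assert np.allclose(ms.akaike_weights, [0.6, 0.3, 0.08, 0.02], atol=1e-3)
        cs = confidence_set(ms, 0.95)
        assert len(cs.fits) == 3
        assert sum(cs.akaike_weights) == pytest.approx(1.0)

    def test_single_model_set(self):
        ms = _rank_models([make_fit((), [], [], 10.0)])
        assert len(confidence_set(ms).fits) == 1

    def test_uniform_weights_keep_95_of_100(self):
        fits = [make_fit((f"v{i}",), [1.0], [0.1], 50.0) for i in range(100)]
        ms = _rank_models(fits)
        assert len(confidence_set(ms, 0.95).fits) == 95


class TestModelAverage:
    def test_degenerate_average_is_identity(self):
        fits = [make_fit(("a",), [2.0], [0.5], 100.0), make_fit(("a",), [2.0], [0.5], 101.0)]
        avg = model_average(_rank_models(fits))
        assert avg.coefficients["a"] == pytest.approx(2.0)
        assert avg.unconditional_se["a"] == pytest.approx(0.5)

    def test_zero_substitution_halves_coefficient(self):
        fits = [make_fit(("a",), [1.0], [0.3], 100.0), make_fit((), [], [], 100.0)]
        avg = model_average(_rank_models(fits))
        assert avg.coefficients["a"] == pytest.approx(0.5)
        assert avg.relative_importance["a"] == pytest.approx(0.5)

    def test_matches_weighted_sum_oracle(self, rng):
        for _ in range(5):
            terms = ["a", "b"]
            fits = []
            for subset in [(), ("a",), ("a", "b")]:
                coefs = rng.standard_normal(len(subset))
                ses = rng.uniform(0.1, 1.0, len(subset))
                fits.append(make_fit(subset, coefs, ses, float(rng.uniform(90, 100))))
            ms = _rank_models(fits)
            avg = model_average(ms)
            w = np.array(ms.akaike_weights)
            for t in terms:
                b = np.array([f.coefficients.get(t, 0.0) for f in ms.fits])
                v = np.array([f.std_errors.get(t, 0.0) ** 2 for f in ms.fits])
                bbar = w @ b
                assert avg.coefficients[t] == pytest.approx(bbar, abs=1e-12)
                assert avg.unconditional_se[t] == pytest.approx(
                    w @ np.sqrt(v + (b - bbar) ** 2), abs=1e-12
                )

    def test_averaged_magnitude_bounded_by_max(self, rng):
        fits = [
            make_fit(("a",), [1.0], [0.2], 100.0),
            make_fit(("a",), [3.0], [0.2], 100.5),
            make_fit((), [], [], 101.0),
        ]
        avg = model_average(_rank_models(fits))
        assert abs(avg.coefficients["a"]) <= 3.0
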