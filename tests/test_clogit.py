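"""Conditional-logit engine: closed forms, oracles, invariances, reference."""

import numpy as np
import pytest
from scipy import optimize

import stepselect as ss
from stepselect.errors import DesignError, SeparationError

from conftest import softmax_design


def _design(X, y, strata, terms=None):
    X = np.asarray(X, dtype=float)
    terms = terms or [f"x{j}" for j in range(X.shape[1])]
    return ss.DesignMatrix(X=np.asarray(X, float), y=np.asarray(y), strata=np.asarray(strata), terms=terms)


class TestPartialLoglik:
    def test_uniform_choice_closed_form(self):
        rng = np.random.default_rng(0)
        S = 5
        d = _design(rng.standard_normal((S * 11, 2)), np.tile([1] + [0] * 10, S),
                    np.repeat(np.arange(S), 11))
        assert ss.partial_loglik(np.zeros(2), d) == pytest.approx(-S * np.log(11))
        one = _design(rng.standard_normal((11, 1)), [1] + [0] * 10, np.zeros(11))
        assert ss.partial_loglik(np.zeros(1), one) == pytest.approx(-2.3978952728)

    def test_two_candidate_closed_form(self):
        d = _design([[1.0], [0.0]], [1, 0], [0, 0])
        assert ss.partial_loglik(np.array([np.log(3.0)]), d) == pytest.approx(
            np.log(3.0 / 4.0)
        )

    def test_matches_explicit_softmax(self):
        rng = np.random.default_rng(1)
        d = softmax_design(rng, 12, 4, [0.3, -0.6])
        beta = rng.standard_normal(2)
        expected = 0.0
        for s in np.unique(d.strata):
            rows = d.strata == s
            eta = d.X[rows] @ beta
            expected += eta[d.y[rows] == 1][0] - np.log(np.exp(eta).sum())
        assert ss.partial_loglik(beta, d) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self):
        d = _design([[1.0], [0.0]], [1, 0], [0, 0])
        with pytest.raises(DesignError):
            ss.partial_loglik(np.zeros(3), d)


class TestFitClogit:
    def test_tiny_instance_matches_direct_optimizer(self):
        """MLE within 1e-4 of an independent Nelder-Mead maximiser of ℓ."""
        rng = np.random.default_rng(2)
        d = softmax_design(rng, 3, 3, [0.8, -0.4])
        fit = ss.fit_clogit(d)
        res = optimize.minimize(
            lambda b: -ss.partial_loglik(b, d), np.zeros(2),
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert np.abs(fit.beta - res.x).max() < 1e-4

    def test_agrees_with_statsmodels_reference(self):
        """|Δβ| < 1e-5 vs statsmodels ConditionalLogit on 20 random designs."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(3)
        for _ in range(20):
            d = softmax_design(rng, 40, 6, rng.uniform(-1, 1, 3))
            fit = ss.fit_clogit(d)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = ConditionalLogit(d.y, d.X, groups=d.strata).fit(
                    method="newton", disp=0
                )
            assert np.abs(fit.beta - ref.params).max() < 1e-5

    def test_coefficient_recovery_two_se(self):
        """True β=(0.5,−1) inside β̂ ± 2·SE in ≈95% of replicates (quick
        smoke version; the full 200-replicate check lives in the acceptance
        suite)."""
        rng = np.random.default_rng(4)
        truth = np.array([0.5, -1.0])
        hits = np.zeros(2)
        n_rep = 60
        for _ in range(n_rep):
            d = softmax_design(rng, 500, 11, truth)
            fit = ss.fit_clogit(d)
            hits += np.abs(fit.beta - truth) <= 2 * fit.se
        for j in range(2):
            assert hits[j] / n_rep >= 0.85, f"coverage {hits[j] / n_rep} for term {j}"

    def test_degenerate_design_raises(self):
        X = np.tile(np.array([[1.0, 2.0]]), (22, 1))  # constant within strata
        y = np.tile([1] + [0] * 10, 2)
        with pytest.raises(DesignError):
            ss.fit_clogit(_design(X, y, np.repeat([0, 1], 11)))

    def test_separation_raises_named_error(self):
        # case always has the strictly largest covariate: likelihood unbounded
        S = 30
        X = np.zeros((S * 3, 1))
        y = np.tile([1, 0, 0], S)
        X[y == 1, 0] = 1.0
        with pytest.raises(SeparationError):
            ss.fit_clogit(_design(X, y, np.repeat(np.arange(S), 3), ["sep_term"]))

    def test_constant_column_dropped_without_changing_others(self):
        rng = np.random.default_rng(5)
        d = softmax_design(rng, 30, 5, [0.7, -0.2])
        fit0 = ss.fit_clogit(d)
        lag = np.repeat(rng.standard_normal(30), 5)  # constant within stratum
        X2 = np.column_stack([d.X, lag])
        d2 = _design(X2, d.y, d.strata, ["x0", "x1", "lag"])
        with pytest.warns(UserWarning, match="lag"):
            fit2 = ss.fit_clogit(d2)
        assert fit2.dropped_terms == ["lag"]
        assert np.allclose(fit2.beta, fit0.beta, atol=1e-10)
        assert fit2.loglik == pytest.approx(fit0.loglik)

    def test_rescaling_invariance(self):
        """Scaling a covariate by c scales β̂ by 1/c; ℓ̂, AIC, c-index unchanged."""
        rng = np.random.default_rng(6)
        d = softmax_design(rng, 40, 5, [0.5, -0.5])
        fit = ss.fit_clogit(d)
        X2 = d.X.copy()
        X2[:, 0] *= 10.0
        fit2 = ss.fit_clogit(_design(X2, d.y, d.strata))
        assert fit2.beta[0] == pytest.approx(fit.beta[0] / 10.0, abs=1e-8)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)
        assert fit2.aic == pytest.approx(fit.aic, abs=1e-8)
        assert fit2.concordance == pytest.approx(fit.concordance, abs=1e-12)

    def test_concave_multistart_agreement(self):
        rng = np.random.default_rng(7)
        d = softmax_design(rng, 50, 6, [0.4, 0.9])
        solutions = [
            ss.fit_clogit(d, start=rng.uniform(-2, 2, 2)).beta for _ in range(5)
        ]
        for b in solutions[1:]:
            assert np.abs(b - solutions[0]).max() < 1e-6

    def test_aic_identity_and_wald(self):
        rng = np.random.default_rng(8)
        d = softmax_design(rng, 60, 4, [1.0, 0.0])
        fit = ss.fit_clogit(d)
        assert fit.aic == pytest.approx(2 * len(fit.terms) - 2 * fit.loglik)
        assert np.all((fit.p >= 0) & (fit.p <= 1))
        assert np.all(fit.se > 0)


class TestConcordance:
    def test_perfect_and_null(self):
        rng = np.random.default_rng(9)
        S, size = 20, 5
        X = rng.standard_normal((S * size, 1))
        y = np.zeros(S * size, int)
        strata = np.repeat(np.arange(S), size)
        for s in range(S):
            block = slice(s * size, (s + 1) * size)
            X[block][0, 0] = X[block].max() + 1.0  # case strictly highest
            y[s * size] = 1
        d = _design(X, y, strata, ["x"])
        perfect = ss.FitResult(
            terms=["x"], beta=np.array([1.0]), se=np.array([1.0]),
            z=np.array([1.0]), p=np.array([0.5]), loglik=0.0, aic=0.0,
            concordance=0.0,
        )
        assert ss.concordance(perfect, d) == 1.0
        null = ss.FitResult(
            terms=["x"], beta=np.array([0.0]), se=np.array([1.0]),
            z=np.array([0.0]), p=np.array([1.0]), loglik=0.0, aic=0.0,
            concordance=0.0,
        )
        assert ss.concordance(null, d) == 0.5

    def test_matches_double_loop(self):
        rng = np.random.default_rng(10)
        d = softmax_design(rng, 15, 6, [0.6])
        fit = ss.fit_clogit(d)
        eta = d.X @ fit.beta
        num = den = 0.0
        for s in np.unique(d.strata):
            rows = np.nonzero(d.strata == s)[0]
            case = rows[d.y[rows] == 1][0]
            for r in rows:
                if r == case:
                    continue
                den += 1
                if eta[case] > eta[r]:
                    num += 1
                elif eta[case] == eta[r]:
                    num += 0.5
        assert ss.concordance(fit, d) == pytest.approx(num / den, rel=1e-12)


def test_fitresult_json_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    fit = ss.fit_clogit(softmax_design(rng, 25, 4, [0.5, -0.5]))
    fit.to_json(tmp_path / "fit.json")
    back = ss.FitResult.from_json(tmp_path / "fit.json")
    assert back.terms == fit.terms
    assert np.allclose(back.beta, fit.beta)
    assert back.aic == pytest.approx(fit.aic)
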