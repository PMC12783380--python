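"""Weighted mean, weighted logistic GLM, log-logistic AFT, plugin adapter."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from ipcwjack import (
    AFTFit,
    ConfigError,
    DataError,
    DichotomizedLabels,
    FitError,
    GLMFit,
    IPCWeightSet,
    SurvivalData,
    WeightedClassifierSpec,
    aft_model_se,
    aft_predict_survival,
    compute_ipc_weights,
    dichotomize,
    fit_loglogistic_aft,
    fit_weighted_logit,
    glm_model_se,
    glm_predict,
    refit_with_weights,
    weighted_log_loss,
    weighted_mean_predict,
)
from ipcwjack.simulation import ScenarioConfig, simulate_dataset

B_TRUE = (1.0, -0.5, 0.5)
TAU = 5.0


def _labels(y, tau=1.0):
    return DichotomizedLabels(y=np.asarray(y), tau=tau)


def _weights(raw):
    return IPCWeightSet.from_raw(np.asarray(raw, dtype=float))


def _sim(n, lam, seed, **kw):
    cfg = ScenarioConfig(n=n, lambda_cens=lam, nsim=1, seed=0, **kw)
    data = simulate_dataset(cfg, seed)
    labels = dichotomize(data, TAU)
    weights = compute_ipc_weights(data, TAU)
    return data, labels, weights


class TestWeightedMean:
    def test_hand_arithmetic(self):
        assert weighted_mean_predict(_labels([1, 0, 1]), _weights([0.5, 0.3, 0.2])) == pytest.approx(0.7)

    def test_all_ones(self):
        assert weighted_mean_predict(_labels([1, 1, 1]), _weights([1, 2, 3])) == pytest.approx(1.0)

    def test_unknown_with_positive_weight_rejected(self):
        w = IPCWeightSet(raw=np.array([1.0, 1.0]), normalized=np.array([0.5, 0.5]),
                         zero_mask=np.array([False, False]))
        with pytest.raises(DataError):
            weighted_mean_predict(_labels([1, -1]), w)


class TestWeightedLogLoss:
    def test_single_record_half(self):
        assert weighted_log_loss([0.5], _labels([1]), _weights([1.0])) == pytest.approx(np.log(2))

    def test_three_record_hand_case(self):
        # -[0.5 ln .8 + 0.3 ln(1-.6) + 0.2 ln .5]
        expected = -(0.5 * np.log(0.8) + 0.3 * np.log(0.4) + 0.2 * np.log(0.5))
        got = weighted_log_loss([0.8, 0.6, 0.5], _labels([1, 0, 1]), _weights([0.5, 0.3, 0.2]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_perfect_prediction_limit(self):
        eps = 1e-8
        loss = weighted_log_loss([1 - eps, eps], _labels([1, 0]), _weights([0.5, 0.5]))
        assert 0 <= loss < 2 * eps

    def test_discordant_degenerate_probability_rejected(self):
        with pytest.raises(DataError):
            weighted_log_loss([0.0], _labels([1]), _weights([1.0]))


class TestWeightedLogit:
    def test_intercept_recovers_logit_of_weighted_mean(self):
        data = SurvivalData(x=np.zeros((4, 1)), time=np.full(4, 2.0), status=np.ones(4))
        fit = fit_weighted_logit(data, _labels([1, 1, 0, 0]), _weights(np.ones(4)), offset=0.0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_derivative_free_optimizer(self):
        # fixed 8-row uncensored dataset with both classes present
        data = SurvivalData(
            x=np.array([[1, 1], [1, 0], [-1, 1], [-1, 0], [1, 1], [-1, 0], [1, 0], [-1, 1]], dtype=float),
            time=np.array([6.0, 2.0, 7.0, 1.0, 3.0, 8.0, 9.0, 2.0]),
            status=np.ones(8),
        )
        labels = dichotomize(data, TAU)
        weights = compute_ipc_weights(data, TAU)
        offset = -np.log(TAU)
        fit = fit_weighted_logit(data, labels, weights, offset=offset)

        X = np.hstack([np.ones((data.n, 1)), data.x])
        y = labels.y.astype(float)
        w = weights.normalized

        def loss(beta):
            eta = offset + X @ beta
            return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

        res = minimize(loss, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000})
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-6)

    def test_matches_statsmodels_weighted_glm(self):
        import statsmodels.api as sm

        data, labels, weights = _sim(300, 0.10, seed=7)
        known = labels.known_mask
        offset = -np.log(TAU)
        fit = fit_weighted_logit(data, labels, weights, offset=offset)
        X = sm.add_constant(data.x[known])
        model = sm.GLM(
            labels.y[known].astype(float),
            X,
            family=sm.families.Binomial(),
            freq_weights=weights.raw[known],
            offset=np.full(int(known.sum()), offset),
        ).fit()
        np.testing.assert_allclose(fit.coefficients, model.params, atol=1e-7)

    def test_offset_equivalence(self):
        data, labels, weights = _sim(200, 0.10, seed=11)
        fit_off = fit_weighted_logit(data, labels, weights, offset=-np.log(TAU))
        fit_zero = fit_weighted_logit(data, labels, weights, offset=0.0)
        assert fit_off.coefficients[0] - fit_zero.coefficients[0] == pytest.approx(np.log(TAU), abs=1e-7)
        np.testing.assert_allclose(fit_off.coefficients[1:], fit_zero.coefficients[1:], atol=1e-7)
        q = np.array([[1.0, 1.0], [-1.0, 0.0]])
        np.testing.assert_allclose(glm_predict(fit_off, q), glm_predict(fit_zero, q), atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_at_optimum_below_truth(self, seed):
        data, labels, weights = _sim(400, 0.10, seed=seed)
        offset = -np.log(TAU)
        fit = fit_weighted_logit(data, labels, weights, offset=offset)
        probs_fit = glm_predict(fit, data.x)
        true_fit = GLMFit(np.array(B_TRUE), np.zeros((3, 3)), offset, True, 0)
        probs_true = glm_predict(true_fit, data.x)
        assert weighted_log_loss(probs_fit, labels, weights) <= weighted_log_loss(
            probs_true, labels, weights
        ) + 1e-12

    def test_single_class_rejected(self):
        data = SurvivalData(x=np.arange(5, dtype=float), time=np.full(5, 2.0), status=np.ones(5))
        with pytest.raises(FitError):
            fit_weighted_logit(data, _labels([1, 1, 1, 1, 1]), _weights(np.ones(5)))


class TestGLMPredict:
    def test_true_coefficients_reproduce_true_probabilities(self):
        fit = GLMFit(np.array(B_TRUE), np.zeros((3, 3)), offset=-np.log(TAU), converged=True, iterations=0)
        assert glm_predict(fit, np.array([1.0, 1.0])) == pytest.approx(0.352, abs=5e-4)
        assert glm_predict(fit, np.array([1.0, 0.0])) == pytest.approx(0.248, abs=5e-4)

    def test_zero_everything_gives_half(self):
        fit = GLMFit(np.zeros(2), np.zeros((2, 2)), offset=0.0, converged=True, iterations=0)
        assert glm_predict(fit, np.array([0.3])) == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        fit = GLMFit(np.zeros(3), np.zeros((3, 3)), offset=0.0, converged=True, iterations=0)
        with pytest.raises(DataError):
            glm_predict(fit, np.array([1.0]))


class TestGLMModelSE:
    def test_zero_covariance_zero_se(self):
        fit = GLMFit(np.array([0.5, -0.2]), np.zeros((2, 2)), offset=0.0, converged=True, iterations=0)
        assert glm_model_se(fit, np.array([1.0])) == 0.0

    def test_matches_finite_difference_delta_method(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit = GLMFit(np.array([0.3, -0.7]), cov, offset=0.2, converged=True, iterations=0)
        x = np.array([0.8])

        h = 1e-6
        grad = np.zeros(2)
        for j in range(2):
            bp, bm = fit.coefficients.copy(), fit.coefficients.copy()
            bp[j] += h
            bm[j] -= h
            fp = GLMFit(bp, cov, fit.offset, True, 0)
            fm = GLMFit(bm, cov, fit.offset, True, 0)
            grad[j] = (glm_predict(fp, x) - glm_predict(fm, x)) / (2 * h)
        expected = np.sqrt(grad @ cov @ grad)
        assert glm_model_se(fit, x) == pytest.approx(expected, abs=1e-6)

    def test_nonconverged_fit_rejected(self):
        fit = GLMFit(np.zeros(2), np.zeros((2, 2)), offset=0.0, converged=False, iterations=100)
        with pytest.raises(FitError):
            glm_model_se(fit, np.array([1.0]))


class TestAFT:
    def test_parameter_recovery_at_large_n(self):
        cfg = ScenarioConfig(n=5000, lambda_cens=0.10, nsim=1, seed=0)
        fit = fit_loglogistic_aft(simulate_dataset(cfg, 21))
        ses = np.sqrt(np.diag(fit.covariance))
        for est, true, se in zip(fit.coefficients, B_TRUE, ses[:3]):
            assert abs(est - true) < 3 * se
        assert abs(np.log(fit.shape)) < 3 * ses[3]

    def test_null_effects_give_symmetric_predictions(self):
        cfg = ScenarioConfig(n=3000, lambda_cens=0.0, nsim=1, seed=0, b=(1.0, 0.0, 0.0))
        fit = fit_loglogistic_aft(simulate_dataset(cfg, 4))
        preds = aft_predict_survival(fit, np.array([[1.0, 1.0], [-1.0, 0.0]]), TAU)
        assert abs(preds[0] - preds[1]) < 0.05

    def test_closed_form_survival(self):
        fit = AFTFit(shape=1.0, coefficients=np.array(B_TRUE), covariance=np.zeros((4, 4)), converged=True)
        assert aft_predict_survival(fit, np.array([1.0, 1.0]), TAU) == pytest.approx(
            np.e / (np.e + 5), abs=1e-12
        )
        assert aft_predict_survival(fit, np.array([1.0, 0.0]), TAU) == pytest.approx(0.248, abs=5e-4)

    def test_survival_tends_to_one_as_tau_vanishes(self):
        fit = AFTFit(shape=1.0, coefficients=np.array(B_TRUE), covariance=np.zeros((4, 4)), converged=True)
        assert aft_predict_survival(fit, np.array([1.0, 1.0]), 1e-12) > 1 - 1e-9

    def test_all_censored_rejected(self):
        data = SurvivalData(x=np.zeros((5, 1)), time=np.arange(1.0, 6.0), status=np.zeros(5))
        with pytest.raises(FitError):
            fit_loglogistic_aft(data)

    def test_model_se_zero_covariance(self):
        fit = AFTFit(shape=1.0, coefficients=np.array(B_TRUE), covariance=np.zeros((4, 4)), converged=True)
        assert aft_model_se(fit, np.array([1.0, 1.0]), TAU) == 0.0

    def test_model_se_matches_finite_difference(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.2, 0.4, size=(4, 4))
        cov = a @ a.T
        fit = AFTFit(shape=1.3, coefficients=np.array(B_TRUE), covariance=cov, converged=True)
        x, tau = np.array([1.0, 1.0]), TAU

        def surv(theta):
            f = AFTFit(shape=np.exp(theta[3]), coefficients=theta[:3], covariance=cov, converged=True)
            return aft_predict_survival(f, x, tau)

        theta0 = np.concatenate([fit.coefficients, [np.log(fit.shape)]])
        h = 1e-6
        grad = np.zeros(4)
        for j in range(4):
            tp, tm = theta0.copy(), theta0.copy()
            tp[j] += h
            tm[j] -= h
            grad[j] = (surv(tp) - surv(tm)) / (2 * h)
        expected = np.sqrt(grad @ cov @ grad)
        assert aft_model_se(fit, x, tau) == pytest.approx(expected, abs=1e-6)


class TestRefitWithWeights:
    def test_weighted_mean_delegation(self):
        labels, weights = _labels([1, 0, 1]), _weights([0.5, 0.3, 0.2])
        data = SurvivalData(x=np.zeros((3, 1)), time=np.array([2.0, 0.5, 2.0]), status=np.ones(3))
        pred = refit_with_weights(WeightedClassifierSpec("weighted_mean"), data, labels, weights)
        assert pred(np.array([0.0])) == pytest.approx(weighted_mean_predict(labels, weights))

    def test_weighted_logit_delegation(self):
        data, labels, weights = _sim(150, 0.10, seed=13)
        offset = -np.log(TAU)
        spec = WeightedClassifierSpec("weighted_logit", {"offset": offset})
        pred = refit_with_weights(spec, data, labels, weights)
        fit = fit_weighted_logit(data, labels, weights, offset=offset)
        q = np.array([[1.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(pred(q), glm_predict(fit, q))

    def test_plugin_weight_doubling_equals_duplication(self):
        data, labels, weights = _sim(80, 0.10, seed=5)
        spec = WeightedClassifierSpec("plugin", {"n_estimators": 30}, seed=7)
        i = int(np.flatnonzero(~weights.zero_mask)[0])

        doubled = weights.raw.copy()
        doubled[i] *= 2
        pred_doubled = refit_with_weights(spec, data, labels, IPCWeightSet.from_raw(doubled))

        data_dup = SurvivalData(
            x=np.vstack([data.x, data.x[i : i + 1]]),
            time=np.append(data.time, data.time[i]),
            status=np.append(data.status, data.status[i]),
        )
        labels_dup = dichotomize(data_dup, TAU)
        pred_dup = refit_with_weights(
            spec, data_dup, labels_dup, IPCWeightSet.from_raw(np.append(weights.raw, weights.raw[i]))
        )
        q = np.array([[1.0, 1.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 1.0]])
        np.testing.assert_allclose(pred_doubled(q), pred_dup(q), atol=1e-12)

    def test_plugin_refit_is_deterministic(self):
        data, labels, weights = _sim(60, 0.10, seed=17)
        spec = WeightedClassifierSpec("plugin", {"n_estimators": 20}, seed=3)
        q = np.array([[1.0, 1.0], [-1.0, 0.0]])
        a = refit_with_weights(spec, data, labels, weights)(q)
        b = refit_with_weights(spec, data, labels, weights)(q)
        np.testing.assert_array_equal(a, b)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            WeightedClassifierSpec("mystery")

    def test_spec_json_round_trip(self):
        spec = WeightedClassifierSpec("weighted_logit", {"offset": -1.6}, seed=5)
        again = WeightedClassifierSpec.from_json(spec.to_json())
        assert again == spec
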