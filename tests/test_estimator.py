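import numpy as np
import pytest

from scump.estimator import (
    GaussianClassParams,
    ImpossibleObservationError,
    bayes_classify,
    class_log_densities,
    estimate_class_params,
    estimate_lambda,
    load_model,
    mixture_loglik,
    mixture_score,
    save_model,
    scump_pipeline,
)
from scump.nri import ORIENT_INCREASING, FeatureMatrix
from scump.response_data import LabeledSample, ResponseMatrix
from scump.simulate import generate_bots, generate_humans, uniform_bot

from conftest import make_calibration


def fm(values):
    values = np.atleast_2d(np.asarray(values, float))
    J = values.shape[1]
    return FeatureMatrix(values=values,
                         index_names=tuple(f"f{j}" for j in range(J)),
                         orientations=(ORIENT_INCREASING,) * J)


def two_class_params(mu0, mu1, J):
    return GaussianClassParams(mean0=np.full(J, mu0), cov0=np.eye(J),
                               mean1=np.full(J, mu1), cov1=np.eye(J),
                               n0=100, n1=100)


class TestEstimateClassParams:
    def test_two_point_mle(self):
        X = fm([[0, 0], [2, 2], [5, 5], [7, 7], [9, 9]])
        labels = np.array([0, 0, 1, 1, 1])
        params = estimate_class_params(X, labels, ridge=0.0)
        np.testing.assert_allclose(params.mean0, [1, 1])
        np.testing.assert_allclose(params.cov0, [[1, 1], [1, 1]])

    def test_missing_class_raises(self):
        X = fm([[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="class 1"):
            estimate_class_params(X, np.zeros(3, dtype=int))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4))
        labels = (rng.random(50) < 0.5).astype(int)
        params = estimate_class_params(fm(X), labels)
        for k, (mean, cov) in enumerate([(params.mean0, params.cov0),
                                         (params.mean1, params.cov1)]):
            rows = X[labels == k]
            nk = len(rows)
            m = sum(rows) / nk
            S = sum(np.outer(r - m, r - m) for r in rows) / nk
            np.testing.assert_allclose(mean, m)
            np.testing.assert_allclose(cov, S, atol=1e-12)

    def test_too_few_rows_for_covariance(self):
        X = fm([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [9.0, 9.0], [8.0, 9.0]])
        labels = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="singular"):
            estimate_class_params(X, labels)


class TestMixtureScore:
    def test_identical_densities_flat_likelihood(self):
        dens = np.array([0.5, 1.0, 2.0])
        for lam in (0.0, 0.3, 1.0):
            assert mixture_score(lam, dens, dens) == pytest.approx(0.0)

    def test_bot_favoring_single_observation_positive(self):
        for lam in (0.0, 0.5, 1.0):
            assert mixture_score(lam, [2.0], [1.0]) > 0

    def test_root_at_half_for_symmetric_ratios(self):
        # ratios {3, 1/3}: 2/(1+2*lam) = 2/(3-2*lam) at lam = 1/2
        assert mixture_score(0.5, [3.0, 1.0], [1.0, 3.0]) == pytest.approx(0.0)
        assert mixture_score(0.25, [3.0, 1.0], [1.0, 3.0]) > 0
        assert mixture_score(0.75, [3.0, 1.0], [1.0, 3.0]) < 0

    def test_both_zero_density_raises(self):
        with pytest.raises(ImpossibleObservationError):
            mixture_score(0.5, [0.0, 1.0], [0.0, 1.0])


class TestEstimateLambda:
    def test_all_rows_bot_favoring_hits_upper_endpoint(self):
        X = fm(np.full((20, 2), 5.0))
        fit = estimate_lambda(X, two_class_params(0.0, 5.0, 2))
        assert fit.lambda_hat == 1.0
        assert fit.at_endpoint

    def test_endpoint_zero_from_score_sign(self):
        # density ratios {2, 0.5, 0.1}: score(0) = 1 - 0.5 - 0.9 < 0
        logphi0 = np.zeros(3)
        logphi1 = np.log([2.0, 0.5, 0.1])
        # embed via 1-D standard normals: x with phi ratio exp(x*mu - mu^2/2)
        mu = 1.0
        x = (np.array([np.log(2.0), np.log(0.5), np.log(0.1)]) + mu**2 / 2) / mu
        fit = estimate_lambda(fm(x[:, None]), GaussianClassParams(
            mean0=np.zeros(1), cov0=np.eye(1), mean1=np.array([mu]),
            cov1=np.eye(1), n0=10, n1=10))
        assert fit.lambda_hat == 0.0
        assert fit.extra["score_at_0"] == pytest.approx(1 - 0.5 - 0.9, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        params = two_class_params(0.0, 2.0, 2)
        X = np.vstack([rng.standard_normal((120, 2)),
                       rng.standard_normal((80, 2)) + 2.0])
        fit = estimate_lambda(fm(X), params, tol=1e-10)
        logphi1, logphi0 = class_log_densities(fm(X), params)
        grid = np.linspace(0, 1, 10_001)
        ll = [mixture_loglik(g, logphi1, logphi0) for g in grid]
        assert abs(fit.lambda_hat - grid[int(np.argmax(ll))]) < 1e-4
        assert fit.loglik_at_max >= max(ll) - 1e-9

    def test_loglik_at_max_beats_endpoints(self):
        rng = np.random.default_rng(12)
        params = two_class_params(0.0, 1.5, 2)
        X = np.vstack([rng.standard_normal((60, 2)),
                       rng.standard_normal((60, 2)) + 1.5])
        fit = estimate_lambda(fm(X), params)
        logphi1, logphi0 = class_log_densities(fm(X), params)
        assert fit.loglik_at_max >= mixture_loglik(0.0, logphi1, logphi0) - 1e-9
        assert fit.loglik_at_max >= mixture_loglik(1.0, logphi1, logphi0) - 1e-9

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(13)
        params = two_class_params(0.0, 2.0, 2)
        X = np.vstack([rng.standard_normal((150, 2)),
                       rng.standard_normal((50, 2)) + 2.0])
        tol = 1e-9
        fit = estimate_lambda(fm(X), params, tol=tol)
        swapped = estimate_lambda(fm(X), params.swapped(), tol=tol)
        assert swapped.lambda_hat == pytest.approx(1.0 - fit.lambda_hat, abs=1e-6)

    def test_concavity_of_loglik(self):
        rng = np.random.default_rng(14)
        params = two_class_params(0.0, 2.5, 2)
        X = np.vstack([rng.standard_normal((40, 2)),
                       rng.standard_normal((40, 2)) + 2.5])
        logphi1, logphi0 = class_log_densities(fm(X), params)
        grid = np.linspace(0.01, 0.99, 199)
        ll = np.array([mixture_loglik(g, logphi1, logphi0) for g in grid])
        second = np.diff(ll, 2)
        assert np.all(second <= 1e-9)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 0.9])
    def test_parameter_recovery_well_separated(self, lam):
        rng = np.random.default_rng(int(lam * 100))
        n = 10_000
        n1 = int(round(n * lam))
        X = np.vstack([rng.standard_normal((n - n1, 2)),
                       rng.standard_normal((n1, 2)) + 2.5])
        fit = estimate_lambda(fm(X), two_class_params(0.0, 2.5, 2))
        assert abs(fit.lambda_hat - lam) < 0.03


class TestBayesClassify:
    def test_lambda_zero_spares_everyone(self):
        X = fm(np.full((10, 2), 3.0))
        params = two_class_params(0.0, 3.0, 2)
        fit = estimate_lambda(fm(np.zeros((5, 2))), params)
        assert fit.lambda_hat == 0.0
        report = bayes_classify(X, fit)
        assert report.flag_rate == 0.0

    def test_exact_tie_spared(self):
        from scump.estimator import GaussianMixtureFit

        params = two_class_params(-1.0, 1.0, 1)
        fit = GaussianMixtureFit(params=params, lambda_hat=0.5,
                                 loglik_at_max=0.0)
        report = bayes_classify(fm([[0.0]]), fit)  # equidistant: phi1 == phi0
        assert report.predicted[0] == 0

    def test_predictions_match_composite_threshold_oracle(self):
        rng = np.random.default_rng(17)
        params = two_class_params(0.0, 2.0, 2)
        X = np.vstack([rng.standard_normal((50, 2)),
                       rng.standard_normal((50, 2)) + 2.0])
        fit = estimate_lambda(fm(X), params)
        report = bayes_classify(fm(X), fit)
        composite = np.asarray(report.extra["composite"])
        np.testing.assert_array_equal(report.predicted,
                                      (composite > 0.0).astype(int))

    def test_decisions_invariant_to_common_density_rescaling(self):
        # oracle: recompute decisions from log densities, with and
        # without a large common offset (equivalent to rescaling phi)
        rng = np.random.default_rng(18)
        params = two_class_params(0.0, 2.0, 2)
        X = rng.standard_normal((40, 2)) + 1.0
        fit = estimate_lambda(fm(X), params)
        lam = fit.lambda_hat
        logphi1, logphi0 = class_log_densities(fm(X), params)
        base = (np.log(lam) + logphi1 > np.log1p(-lam) + logphi0)
        offset = 500.0  # e^500 rescaling would overflow raw densities
        shifted = (np.log(lam) + logphi1 + offset
                   > np.log1p(-lam) + logphi0 + offset)
        report = bayes_classify(fm(X), fit)
        np.testing.assert_array_equal(report.predicted, base.astype(int))
        np.testing.assert_array_equal(base, shifted)

    def test_far_outliers_do_not_underflow(self):
        params = two_class_params(0.0, 2.0, 4)
        X = fm(np.full((3, 4), 60.0))  # astronomically far from both classes
        fit = estimate_lambda(X, params)
        report = bayes_classify(X, fit)
        assert np.isfinite(report.scores).all()


class TestPipeline:
    def test_uncontaminated_target(self, human_model_16, calibration_16):
        target = generate_humans(human_model_16, 300, 77)
        result = scump_pipeline(calibration_16, target)
        assert result.fit.lambda_hat < 0.1
        assert result.report.flag_rate < 0.1

    def test_saturated_target(self, human_model_16, calibration_16):
        target = generate_bots(uniform_bot(), 300, 16, 78)
        result = scump_pipeline(calibration_16, target)
        assert result.fit.lambda_hat > 0.9
        assert result.report.flag_rate > 0.9

    def test_truth_adds_confusion_metrics(self, human_model_16, calibration_16):
        humans = generate_humans(human_model_16, 100, 79)
        bots = generate_bots(uniform_bot(), 100, 16, 80)
        target = ResponseMatrix(np.vstack([humans.values, bots.values]))
        truth = np.r_[np.zeros(100, int), np.ones(100, int)]
        result = scump_pipeline(calibration_16, target, truth=truth)
        assert result.report.has_truth
        assert result.report.accuracy > 0.8
        assert result.report.auc > 0.9

    def test_lambda_recovery_moderate(self, human_model_16):
        errs = []
        for seed in range(5):
            cal = make_calibration(human_model_16, 200, 2000, seed=seed)
            humans = generate_humans(human_model_16, 200, 1000 + seed)
            bots = generate_bots(uniform_bot(), 200, 16, 2000 + seed)
            target = ResponseMatrix(np.vstack([humans.values, bots.values]))
            result = scump_pipeline(cal, target)
            errs.append(result.fit.lambda_hat - 0.5)
        assert abs(np.mean(errs)) < 0.1


class TestModelSerialization:
    def test_round_trip(self, tmp_path):
        params = two_class_params(0.0, 2.0, 2)
        path = tmp_path / "model.json"
        save_model(path, params=params, indices=["mahalanobis", "person_total"],
                   settings={}, provenance="abc123")
        loaded, ref, meta = load_model(path)
        np.testing.assert_allclose(loaded.mean1, params.mean1)
        np.testing.assert_allclose(loaded.cov0, params.cov0)
        assert meta["indices"] == ["mahalanobis", "person_total"]
        assert meta["provenance"] == "abc123"

    def test_schema_version_checked(self, tmp_path):
        import json

        path = tmp_path / "model.json"
        path.write_text(json.dumps({"schema_version": 999}))
        with pytest.raises(ValueError, match="schema"):
            load_model(path)
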