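"""Prediction, evaluation metrics, cross-validation and summaries."""

import numpy as np
import pytest

import trflab as t
from trflab import InvalidArgumentError, LagSpec, UndefinedMetricError
from trflab.model import CVReport
from trflab.synthetic import KernelSpec, make_kernel, make_stimulus, simulate_response

FS = 128.0


class TestMetrics:
    def test_pearson_perfect_and_anti_correlation(self, rng):
        v = rng.standard_normal(100)
        assert t.pearson_r(v, v) == pytest.approx(1.0)
        assert t.pearson_r(v, -v) == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        # cov([1,2,3],[1,2,4]) / (sigma_a * sigma_b), computed by hand
        assert t.pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805060619659)

    def test_pearson_zero_variance_is_undefined(self):
        assert np.isnan(t.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("a, b, expected", [
        ([3.0, -1.0], [3.0, -1.0], 0.0),
        ([0.0, 0.0], [1.0, 1.0], 1.0),
        ([1.0, 2.0], [2.0, 4.0], 2.5),
    ])
    def test_mse_examples(self, a, b, expected):
        assert t.mse(a, b) == pytest.approx(expected)


class TestPredict:
    def test_training_data_reproduced_at_zero_lambda(self, noise_free_trial):
        stimulus, response, _ = noise_free_trial
        spec = LagSpec(0.0, 310.0, FS)
        m = t.fit_trial(stimulus, response, spec, "forward", 0.0, penalty="identity")
        pred = t.predict(m, stimulus, truth=response)
        np.testing.assert_allclose(pred.prediction, response, atol=1e-6)
        assert np.all(pred.r > 0.999)

    def test_zero_weight_model_predicts_bias(self, lagspec):
        m = t.TRFModel(direction="forward",
                       weights=np.zeros((1, lagspec.n_lags, 2)),
                       bias=np.array([2.5, -1.0]), lam=1.0, lagspec=lagspec)
        pred = t.predict(m, np.random.default_rng(0).standard_normal(300)).prediction
        np.testing.assert_allclose(pred, np.tile([2.5, -1.0], (300, 1)))

    def test_impulse_weights_delay_the_input(self, rng):
        spec = LagSpec(0.0, 100.0, FS)
        delay = 5
        w = np.zeros((1, spec.n_lags, 1))
        w[0, delay, 0] = 1.0
        m = t.TRFModel("forward", w, np.zeros(1), 0.0, spec)
        x = rng.standard_normal(200)
        pred = t.predict(m, x).prediction[:, 0]
        np.testing.assert_allclose(pred[delay:], x[:-delay], atol=1e-12)
        np.testing.assert_allclose(pred[:delay], 0.0, atol=1e-12)

    def test_prediction_equals_brute_force_convolution(self, rng):
        spec = LagSpec(-31.25, 62.5, FS)  # lags -4..8 exactly
        F, N = 2, 3
        w = rng.standard_normal((F, spec.n_lags, N))
        b = rng.standard_normal(N)
        m = t.TRFModel("forward", w, b, 0.0, spec)
        x = rng.standard_normal((60, F))
        pred = t.predict(m, x).prediction
        lags = spec.lags()
        direct = np.tile(b, (60, 1))
        for ti in range(60):
            for j, tau in enumerate(lags):
                if 0 <= ti - tau < 60:
                    for f in range(F):
                        direct[ti] += w[f, j] * x[ti - tau, f]
        np.testing.assert_allclose(pred, direct, atol=1e-12)

    def test_dimension_mismatch_rejected(self, lagspec, rng):
        m = t.TRFModel("forward", np.zeros((2, lagspec.n_lags, 1)),
                       np.zeros(1), 0.0, lagspec)
        with pytest.raises(InvalidArgumentError):
            t.predict(m, rng.standard_normal((100, 3)))


def _dataset(M=3, seconds=20, N=4, snr_db=0.0, seed0=0, kind="white"):
    kernel = make_kernel(KernelSpec(), 1, N, FS, seed=seed0)
    S = [make_stimulus(kind, int(seconds * FS), FS, seed=seed0 + 10 + j)
         for j in range(M)]
    R = [simulate_response(s, kernel, snr_db, seed=seed0 + 50 + j)
         for j, s in enumerate(S)]
    return S, R, kernel


GRID = 2.0 ** np.arange(0, 21, 2)


class TestCrossValidate:
    def test_single_lambda_grid_selects_it(self, lagspec):
        S, R, _ = _dataset(seed0=1)
        rep = t.cross_validate(S, R, lagspec, "forward", [8.0])
        assert rep.best_lambda_r == 8.0
        assert rep.best_lambda_mse == 8.0

    def test_noise_free_data_select_smallest_lambda(self, lagspec):
        S, R, _ = _dataset(snr_db=np.inf, seed0=2)
        rep = t.cross_validate(S, R, lagspec, "forward", [1.0, 64.0, 4096.0],
                               zscore=False)
        assert rep.best_lambda_r == 1.0

    def test_interior_optimum_beats_grid_extremes(self, lagspec):
        S, R, _ = _dataset(M=5, seconds=30, snr_db=-5.0, seed0=3)
        rep = t.cross_validate(S, R, lagspec, "forward", GRID)
        mean_r = rep.mean_r()
        best = np.nanargmax(mean_r)
        assert 0 < best < len(GRID) - 1
        assert mean_r[best] > mean_r[0] and mean_r[best] > mean_r[-1]

    def test_metrics_invariant_to_trial_order(self, lagspec):
        S, R, _ = _dataset(seed0=4)
        rep = t.cross_validate(S, R, lagspec, "forward", [1.0, 256.0])
        perm = [2, 0, 1]
        rep_p = t.cross_validate([S[i] for i in perm], [R[i] for i in perm],
                                 lagspec, "forward", [1.0, 256.0])
        np.testing.assert_allclose(np.sort(rep.r, axis=1),
                                   np.sort(rep_p.r, axis=1), atol=1e-10)
        np.testing.assert_allclose(rep.mean_r(), rep_p.mean_r(), atol=1e-10)

    def test_fewer_than_two_trials_rejected(self, lagspec):
        S, R, _ = _dataset(seed0=5)
        with pytest.raises(InvalidArgumentError):
            t.cross_validate(S[:1], R[:1], lagspec, "forward", [1.0])

    def test_trial_count_mismatch_rejected(self, lagspec):
        S, R, _ = _dataset(seed0=6)
        with pytest.raises(InvalidArgumentError):
            t.cross_validate(S, R[:2], lagspec, "forward", [1.0])


class TestSelectLambda:
    def _report(self, lambdas, mean_r):
        G = len(lambdas)
        r = np.asarray(mean_r, dtype=float)[:, None, None] * np.ones((G, 2, 1))
        return CVReport(lambdas=np.asarray(lambdas, dtype=float), r=r,
                        mse=1.0 - r)

    def test_argmax_selection(self):
        rep = self._report([1.0, 2.0, 4.0], [0.1, 0.3, 0.2])
        assert t.select_lambda(rep, "r") == 2.0

    def test_tie_breaks_to_smallest(self):
        rep = self._report([1.0, 2.0, 4.0], [0.1, 0.3, 0.3])
        assert t.select_lambda(rep, "r") == 2.0

    def test_all_undefined_raises(self):
        rep = self._report([1.0, 2.0], [np.nan, np.nan])
        with pytest.raises(UndefinedMetricError):
            t.select_lambda(rep, "r")


class TestGlobalFieldPower:
    def _model(self, w, spec):
        return t.TRFModel("forward", w, np.zeros(w.shape[2]), 1.0, spec)

    def test_identical_channels_give_zero(self, lagspec, rng):
        course = rng.standard_normal(lagspec.n_lags)
        w = np.tile(course[None, :, None], (1, 1, 4))
        np.testing.assert_allclose(
            t.global_field_power(self._model(w, lagspec)), 0.0, atol=1e-14)

    def test_two_channel_population_variance(self):
        spec = LagSpec(0.0, 0.0, FS)
        w = np.array([[[1.0, -1.0]]])  # one lag, channels +-1
        # population variance (ddof=0) of {1, -1} is 1
        np.testing.assert_allclose(t.global_field_power(self._model(w, spec)), [1.0])

    def test_channel_permutation_invariance(self, lagspec, rng):
        w = rng.standard_normal((1, lagspec.n_lags, 5))
        gfp = t.global_field_power(self._model(w, lagspec))
        gfp_p = t.global_field_power(self._model(w[:, :, [3, 1, 4, 0, 2]], lagspec))
        np.testing.assert_allclose(gfp, gfp_p)

    def test_single_channel_undefined(self, lagspec):
        with pytest.raises(InvalidArgumentError):
            t.global_field_power(self._model(np.zeros((1, lagspec.n_lags, 1)), lagspec))


class TestDecoderWeighting:
    def test_noise_channels_get_smaller_weights(self, lagspec):
        """Channels carrying no stimulus information receive decoder
        weights closer to zero than signal-bearing channels."""
        kernel = make_kernel(KernelSpec(), 1, 4, FS, seed=60)
        S, R = [], []
        rng = np.random.default_rng(61)
        for j in range(3):
            s = make_stimulus("white", int(30 * FS), FS, seed=70 + j)
            r = simulate_response(s, kernel, 5.0, seed=80 + j)
            pure_noise = rng.standard_normal((r.shape[0], 4)) * r.std(axis=0).mean()
            S.append(s)
            R.append(np.hstack([r, pure_noise]))
        dec = t.train(S, R, lagspec, "backward", 64.0, zscore=True)
        mean_abs = np.abs(dec.weights).mean(axis=(1, 2))
        assert mean_abs[:4].mean() > 2 * mean_abs[4:].mean()


class TestCrossCorrelationBaseline:
    def test_matches_trf_on_white_stimulus(self, lagspec):
        S, R, _ = _dataset(M=1, seconds=60, seed0=90)
        trf = t.fit_trial(S[0], R[0], lagspec, "forward", 0.0, penalty="identity")
        xc = t.cross_correlation_trf(S[0], R[0], lagspec)
        assert xc.weights.shape == trf.weights.shape
        assert t.pearson_r(xc.weights.ravel(), trf.weights.ravel()) > 0.99
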