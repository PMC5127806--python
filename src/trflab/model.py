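"""User-facing TRF workflow: train, predict, cross-validate, transform.

The central object is :class:`trflab.regress.TRFModel`.  Forward models
predict the multichannel neural response from a (possibly multivariate)
stimulus feature; backward models (decoders) reconstruct the stimulus
feature from the multichannel response.  The regularization parameter is
chosen by leave-one-trial-out cross-validation: a model is fitted to each
trial, the models of the M-1 training trials are averaged, and the average
is evaluated on the held-out trial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedMetricError
from .lagmat import LagSpec, _as_2d, build_lag_matrix
from .regress import (
    Direction,
    TRFModel,
    _gram,
    _orient,
    _resolve_penalty,
    _solve_gram,
    _weights_3d,
    average_models,
    fit_trial,
    penalty_matrix,
)

__all__ = [
    "CVReport",
    "Prediction",
    "predict",
    "pearson_r",
    "mse",
    "train",
    "cross_validate",
    "select_lambda",
    "transform_backward_to_forward",
    "multisensory_additive_cv",
    "global_field_power",
    "cross_correlation_trf",
    "zscore_trial",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics

def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation between two equal-length vectors.

    Returns NaN (an "undefined" flag, excluded from cross-validation
    averages) when either vector has zero variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidArgumentError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise InvalidArgumentError("need at least two samples")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        logger.warning("zero-variance input: Pearson r undefined")
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error between two equal-length vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidArgumentError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _column_metrics(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson r and MSE; r is NaN for zero-variance columns."""
    t = truth - truth.mean(axis=0)
    p = pred - pred.mean(axis=0)
    denom = np.sqrt(np.einsum("ij,ij->j", t, t) * np.einsum("ij,ij->j", p, p))
    num = np.einsum("ij,ij->j", t, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    m = np.mean((truth - pred) ** 2, axis=0)
    return r, m


def zscore_trial(x: np.ndarray) -> np.ndarray:
    """Z-score each column of a trial; zero-variance columns are centered
    only (avoids division by zero)."""
    x = _as_2d(x)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# prediction

class Prediction(NamedTuple):
    prediction: np.ndarray
    r: np.ndarray | None
    mse: np.ndarray | None


def predict(model: TRFModel, x: np.ndarray, truth: np.ndarray | None = None) -> Prediction:
    """Apply a fitted model to new input.

    For forward models ``x`` is a T x F stimulus and the prediction a
    T x N response; for backward models ``x`` is a T x N response and the
    prediction a T x F stimulus reconstruction.  If ``truth`` is given,
    per-output Pearson r and MSE are returned alongside.
    """
    x = _as_2d(x, "input")
    if x.shape[1] != model.n_inputs:
        raise InvalidArgumentError(
            f"input has {x.shape[1]} variables but the model expects {model.n_inputs}"
        )
    tau_min, tau_max = model.design_window().sample_lags()
    X = build_lag_matrix(x, tau_min, tau_max).values
    pred = X @ model.weights_2d() + model.bias
    if truth is None:
        return Prediction(pred, None, None)
    truth = _as_2d(truth, "truth")
    if truth.shape != pred.shape:
        raise InvalidArgumentError(
            f"truth shape {truth.shape} does not match prediction {pred.shape}"
        )
    r, m = _column_metrics(truth, pred)
    return Prediction(pred, r, m)


# ---------------------------------------------------------------------------
# training on multiple trials

def _check_trials(stimuli: Sequence[np.ndarray], responses: Sequence[np.ndarray]) -> None:
    if len(stimuli) != len(responses):
        raise InvalidArgumentError(
            f"got {len(stimuli)} stimuli but {len(responses)} responses"
        )
    for i, (s, r) in enumerate(zip(stimuli, responses)):
        if np.asarray(s).shape[0] != np.asarray(r).shape[0]:
            raise InvalidArgumentError(
                f"trial {i}: stimulus length {np.asarray(s).shape[0]} != "
                f"response length {np.asarray(r).shape[0]}"
            )


def train(stimuli: Sequence[np.ndarray], responses: Sequence[np.ndarray],
          spec: LagSpec, direction: Direction, lam: float,
          penalty: str = "auto", method: Literal["average", "concatenate"] = "average",
          zscore: bool = False) -> TRFModel:
    """Fit one model from M trials.

    ``method='average'`` fits each trial separately and averages the
    models; ``method='concatenate'`` sums the per-trial normal equations,
    equivalent to fitting the trials jointly while keeping the lag
    padding within trial boundaries.  For identically distributed
    stationary trials of equal length the two agree closely.
    """
    _check_trials(stimuli, responses)
    if zscore:
        stimuli = [zscore_trial(s) for s in stimuli]
        responses = [zscore_trial(r) for r in responses]
    if method == "average":
        models = [fit_trial(s, r, spec, direction, lam, penalty)
                  for s, r in zip(stimuli, responses)]
        return average_models(models)
    if method != "concatenate":
        raise InvalidArgumentError(f"unknown method: {method!r}")
    G = c = None
    n_inputs = window = kind = None
    for s, r in zip(stimuli, responses):
        x, y, window = _orient(s, r, spec, direction)
        if n_inputs is None:
            n_inputs = x.shape[1]
            kind = _resolve_penalty(penalty, direction, n_inputs)
        X = build_lag_matrix(x, *window.sample_lags()).values
        Gi, ci = _gram(X, y)
        G = Gi if G is None else G + Gi
        c = ci if c is None else c + ci
    P = penalty_matrix(kind, G.shape[0] - 1)
    coef = _solve_gram(G, c, float(lam), P)
    weights = _weights_3d(coef[1:], n_inputs, window.n_lags)
    return TRFModel(direction=direction, weights=weights, bias=coef[0],
                    lam=float(lam), lagspec=spec)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass(frozen=True)
class CVReport:
    """Leave-one-trial-out cross-validation results over a lambda grid.

    ``r`` and ``mse`` have shape (n_lambdas, n_trials, n_outputs).
    Undefined correlations (zero-variance outputs) are stored as NaN and
    excluded from the averages; ``n_undefined`` counts them.
    """

    lambdas: np.ndarray
    r: np.ndarray
    mse: np.ndarray

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.r).sum())

    def mean_r(self) -> np.ndarray:
        """Mean r per lambda: averaged across trials first, then outputs."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(np.nanmean(self.r, axis=1), axis=1)

    def mean_mse(self) -> np.ndarray:
        return np.nanmean(np.nanmean(self.mse, axis=1), axis=1)

    @property
    def best_lambda_r(self) -> float:
        return select_lambda(self, "r")

    @property
    def best_lambda_mse(self) -> float:
        return select_lambda(self, "mse")


def select_lambda(report: CVReport, criterion: Literal["r", "mse"] = "r") -> float:
    """Best lambda under the given criterion; ties break to the smallest
    lambda (the grid is stored ascending and the first optimum wins)."""
    if criterion == "r":
        scores = report.mean_r()
        pick = np.nanargmax
    elif criterion == "mse":
        scores = report.mean_mse()
        pick = np.nanargmin
    else:
        raise InvalidArgumentError(f"unknown criterion: {criterion!r}")
    if np.all(np.isnan(scores)):
        raise UndefinedMetricError("all cross-validation metrics are undefined")
    return float(report.lambdas[pick(scores)])


def _prep_cv(stimuli, responses, spec, direction, lambdas, penalty, zscore):
    _check_trials(stimuli, responses)
    M = len(stimuli)
    if M < 2:
        raise InvalidArgumentError(f"cross-validation needs at least 2 trials, got {M}")
    lambdas = np.sort(np.asarray(lambdas, dtype=float).ravel())
    if lambdas.size == 0 or np.any(lambdas < 0) or not np.all(np.isfinite(lambdas)):
        raise InvalidArgumentError("lambda grid must be non-empty, finite and non-negative")
    if zscore:
        stimuli = [zscore_trial(s) for s in stimuli]
        responses = [zscore_trial(r) for r in responses]
    xy = [_orient(s, r, spec, direction) for s, r in zip(stimuli, responses)]
    window = xy[0][2]
    kind = _resolve_penalty(penalty, direction, xy[0][0].shape[1])
    return xy, window, kind, lambdas, M


def cross_validate(stimuli: Sequence[np.ndarray], responses: Sequence[np.ndarray],
                   spec: LagSpec, direction: Direction,
                   lambdas: Sequence[float], penalty: str = "auto",
                   zscore: bool = True) -> CVReport:
    """Leave-one-trial-out cross-validation over a grid of ridge values.

    For each lambda, a model is fitted to every trial; each trial in turn
    is held out, the remaining M-1 single-trial models are averaged, and
    the average model is evaluated on the held-out trial (per-output
    Pearson r and MSE).  Data are z-scored per trial per variable by
    default, which keeps the useful lambda range data-scale independent.
    """
    xy, window, kind, lambdas, M = _prep_cv(
        stimuli, responses, spec, direction, lambdas, penalty, zscore)
    tau = window.sample_lags()
    designs = [np.column_stack([np.ones(x.shape[0]), build_lag_matrix(x, *tau).values])
               for x, _, _ in xy]
    outputs = [y for _, y, _ in xy]
    grams = [(Xt.T @ Xt, Xt.T @ y) for Xt, y in zip(designs, outputs)]
    D = designs[0].shape[1] - 1
    P = penalty_matrix(kind, D)
    O = outputs[0].shape[1]
    r = np.full((lambdas.size, M, O), np.nan)
    e = np.full((lambdas.size, M, O), np.nan)
    for g, lam in enumerate(lambdas):
        coefs = [_solve_gram(G, c, lam, P) for G, c in grams]
        total = np.sum(coefs, axis=0)
        for i in range(M):
            avg = (total - coefs[i]) / (M - 1)
            pred = designs[i] @ avg
            r[g, i], e[g, i] = _column_metrics(outputs[i], pred)
    return CVReport(lambdas=lambdas, r=r, mse=e)


# ---------------------------------------------------------------------------
# decoder weight transformation (forward-interpretable patterns)

def transform_backward_to_forward(decoder: TRFModel,
                                  responses: Sequence[np.ndarray],
                                  stimuli: Sequence[np.ndarray] | None = None,
                                  zscore: bool = False) -> TRFModel:
    """Transform decoder weights into forward-interpretable activation
    patterns via the covariance inversion A = Cov(X) W Cov(s_hat)^-1.

    ``responses`` must be the decoder's training data (the transform is
    data-dependent); ``stimuli`` is accepted for interface symmetry but
    the reconstruction covariance is computed from the decoder's own
    output.  The returned model has forward orientation (F x L x N) on
    the user-facing lag window, with the lag axis reversed back from the
    decoder's internal window; only the pattern *shape* is meaningful —
    the overall scale depends on the covariance normalization.
    """
    if decoder.direction != "backward":
        raise InvalidArgumentError("transform requires a backward model")
    if zscore:
        responses = [zscore_trial(x) for x in responses]
    tau = decoder.design_window().sample_lags()
    X = np.vstack([build_lag_matrix(_as_2d(x, "response"), *tau).values
                   for x in responses])
    W = decoder.weights_2d()
    if X.shape[1] != W.shape[0]:
        raise InvalidArgumentError(
            f"responses have lagged dimension {X.shape[1]} but decoder "
            f"weights expect {W.shape[0]}"
        )
    Xc = X - X.mean(axis=0)
    T = X.shape[0]
    shat = Xc @ W
    cov_s = np.atleast_2d((shat - shat.mean(axis=0)).T @ (shat - shat.mean(axis=0))) / (T - 1)
    try:
        rhs = np.linalg.solve(cov_s, W.T @ Xc.T @ Xc / (T - 1)).T  # = Cov(X) W inv(Cov(s))
    except np.linalg.LinAlgError:
        logger.warning("reconstruction covariance singular; using pseudo-inverse")
        rhs = (Xc.T @ (Xc @ W) / (T - 1)) @ np.linalg.pinv(cov_s)
    N, L, F = decoder.weights.shape
    A = _weights_3d(rhs, N, L)          # (N, L, F), decoder lag order
    A_fwd = A[:, ::-1, :].transpose(2, 1, 0)  # (F, L, N), forward lag order
    return TRFModel(direction="forward", weights=A_fwd,
                    bias=np.zeros(N), lam=decoder.lam, lagspec=decoder.lagspec)


# ---------------------------------------------------------------------------
# additive multisensory modeling

def multisensory_additive_cv(stim_a: Sequence[np.ndarray], stim_b: Sequence[np.ndarray],
                             responses_a: Sequence[np.ndarray],
                             responses_b: Sequence[np.ndarray],
                             responses_ab: Sequence[np.ndarray],
                             spec: LagSpec, lambdas: Sequence[float],
                             penalty: str = "auto", zscore: bool = True) -> CVReport:
    """Cross-validate an additive multisensory model.

    For each lambda and each held-out trial, unisensory forward models are
    fitted to the A-only and B-only data of the training trials, averaged,
    and summed; the summed model predicts the multisensory (AB) response
    of the held-out trial from that trial's two stimulus streams.  A
    super- or sub-additive system shows up as the additive model under- or
    over-predicting the measured AB response.
    """
    _check_trials(stim_a, responses_a)
    _check_trials(stim_b, responses_b)
    _check_trials(stim_a, responses_ab)
    xa, wa, ka, lambdas, M = _prep_cv(stim_a, responses_a, spec, "forward",
                                      lambdas, penalty, zscore)
    xb, wb, kb, _, _ = _prep_cv(stim_b, responses_b, spec, "forward",
                                lambdas, penalty, zscore)
    if zscore:
        responses_ab = [zscore_trial(r) for r in responses_ab]
    responses_ab = [_as_2d(r, "response") for r in responses_ab]
    tau = wa.sample_lags()

    def _grams(xy):
        designs = [np.column_stack([np.ones(x.shape[0]),
                                    build_lag_matrix(x, *tau).values])
                   for x, _, _ in xy]
        grams = [(Xt.T @ Xt, Xt.T @ y) for Xt, (_, y, _) in zip(designs, xy)]
        return designs, grams

    des_a, gr_a = _grams(xa)
    des_b, gr_b = _grams(xb)
    Pa = penalty_matrix(ka, des_a[0].shape[1] - 1)
    Pb = penalty_matrix(kb, des_b[0].shape[1] - 1)
    O = responses_ab[0].shape[1]
    r = np.full((lambdas.size, M, O), np.nan)
    e = np.full((lambdas.size, M, O), np.nan)
    for g, lam in enumerate(lambdas):
        ca = [_solve_gram(G, c, lam, Pa) for G, c in gr_a]
        cb = [_solve_gram(G, c, lam, Pb) for G, c in gr_b]
        ta, tb = np.sum(ca, axis=0), np.sum(cb, axis=0)
        for i in range(M):
            pred = (des_a[i] @ ((ta - ca[i]) / (M - 1))
                    + des_b[i] @ ((tb - cb[i]) / (M - 1)))
            r[g, i], e[g, i] = _column_metrics(responses_ab[i], pred)
    return CVReport(lambdas=lambdas, r=r, mse=e)


# ---------------------------------------------------------------------------
# summaries and baselines

def global_field_power(model: TRFModel) -> np.ndarray:
    """Variance of forward-model weights across channels at each lag.

    Uses the population-variance convention (ddof=0).  Returns a vector
    over lags for univariate models, else an (F, L) array.
    """
    if model.direction != "forward":
        raise InvalidArgumentError("global field power is defined for forward models")
    if model.n_outputs < 2:
        raise InvalidArgumentError("global field power needs at least 2 channels")
    gfp = model.weights.var(axis=2, ddof=0)
    return gfp[0] if gfp.shape[0] == 1 else gfp


def cross_correlation_trf(stimulus: np.ndarray, response: np.ndarray,
                          spec: LagSpec) -> TRFModel:
    """Kernel estimate by normalized cross-correlation (no decorrelation).

    Computes ``X' r / (s' s)`` per feature on mean-centered data — the
    classical reverse-correlation estimate.  For white stimuli this
    matches the ridge TRF at lambda ~ 0; for autocorrelated stimuli it
    temporally smears the kernel because the stimulus autocovariance is
    not divided out.
    """
    s = _as_2d(stimulus, "stimulus")
    rsp = _as_2d(response, "response")
    if s.shape[0] != rsp.shape[0]:
        raise InvalidArgumentError("stimulus and response must have equal length")
    s = s - s.mean(axis=0)
    rsp_c = rsp - rsp.mean(axis=0)
    tau = spec.sample_lags()
    X = build_lag_matrix(s, *tau).values
    energy = np.einsum("ij,ij->j", s, s)          # per-feature sum of squares
    if np.any(energy == 0):
        raise InvalidArgumentError("stimulus feature with zero energy")
    F = s.shape[1]
    L = spec.n_lags
    W = (X.T @ rsp_c) / np.tile(energy, L)[:, None]
    return TRFModel(direction="forward", weights=_weights_3d(W, F, L),
                    bias=rsp.mean(axis=0), lam=0.0, lagspec=spec)
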