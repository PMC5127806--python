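"""Regularized least-squares engine for TRF estimation.

Solves the penalized normal equations

    (X'X + lambda * P) w = X'Y

where ``X`` is a lagged design matrix with one prepended intercept column
and ``P`` is either the identity (ridge / Tikhonov shrinkage toward zero)
or a tridiagonal second-difference-style matrix that penalizes differences
between neighbouring lag coefficients (a smoothness prior that preserves
overall amplitude, since constant kernels lie in its null space).  The
intercept row/column of ``P`` is zero: the bias is never penalized.

Systems are solved by Cholesky factorization of the symmetric positive
(semi)definite Gram matrix, never by explicit inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .exceptions import (
    IllPosedDesignError,
    InvalidArgumentError,
    InvalidPenaltyError,
    SingularDesignError,
)
from .lagmat import LagSpec, _as_2d, build_lag_matrix

__all__ = [
    "PenaltyKind",
    "WeightSolution",
    "TRFModel",
    "penalty_matrix",
    "ridge_solve",
    "fit_trial",
    "average_models",
]

logger = logging.getLogger(__name__)

PenaltyKind = Literal["identity", "quadratic"]
Direction = Literal["forward", "backward"]


def penalty_matrix(kind: PenaltyKind, D: int) -> np.ndarray:
    """Return the (D+1) x (D+1) penalty, bias slot first and unpenalized.

    ``identity`` puts the identity on the D weight rows.  ``quadratic``
    puts the tridiagonal matrix with diagonal (1, 2, ..., 2, 1) and
    off-diagonals -1, which penalizes squared differences between
    neighbouring coefficients along the lag axis.
    """
    if D < 1:
        raise InvalidArgumentError(f"D must be >= 1, got {D}")
    P = np.zeros((D + 1, D + 1))
    if kind == "identity":
        P[1:, 1:] = np.eye(D)
    elif kind == "quadratic":
        M = 2.0 * np.eye(D) - np.eye(D, k=1) - np.eye(D, k=-1)
        M[0, 0] = 1.0
        M[-1, -1] = 1.0
        P[1:, 1:] = M
    else:
        raise InvalidArgumentError(f"unknown penalty kind: {kind!r}")
    return P


@dataclass(frozen=True)
class WeightSolution:
    """Fitted coefficients: per-output bias plus a D x O weight matrix."""

    bias: np.ndarray
    weights: np.ndarray
    lam: float


def _check_xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = _as_2d(X, "X")
    Y = _as_2d(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise InvalidArgumentError(
            f"X and Y must have equal row counts, got {X.shape[0]} and {Y.shape[0]}"
        )
    return X, Y


def _gram(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gram matrix and cross-product for the intercept-augmented design."""
    Xt = np.column_stack([np.ones(X.shape[0]), X])
    return Xt.T @ Xt, Xt.T @ Y


def _solve_gram(G: np.ndarray, c: np.ndarray, lam: float, P: np.ndarray) -> np.ndarray:
    """Solve (G + lam*P) b = c by Cholesky; returns full (D+1) x O coefs."""
    A = G + lam * P
    try:
        cf = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
        pivots = np.diag(cf[0]) ** 2
        # round-off can let the factorization "succeed" on a singular Gram
        # matrix; a vanishing relative pivot is the reliable signal
        if pivots.min() <= np.finfo(float).eps * A.shape[0] * pivots.max():
            raise scipy.linalg.LinAlgError("vanishing Cholesky pivot")
        return scipy.linalg.cho_solve(cf, c, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "normal equations are singular; increase the ridge parameter "
            f"lambda (got lambda={lam})"
        ) from exc


def ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float, P: np.ndarray) -> WeightSolution:
    """Solve the penalized least-squares problem for design ``X`` and
    outputs ``Y``.

    An intercept column of ones is prepended internally; ``P`` must be the
    (D+1) x (D+1) penalty returned by :func:`penalty_matrix` (zero bias
    row/column).

    Raises
    ------
    SingularDesignError
        If the regularized system is singular (typically lambda = 0 on a
        rank-deficient design).
    """
    X, Y = _check_xy(X, Y)
    if not np.isscalar(lam) or not np.isfinite(lam) or lam < 0:
        raise InvalidArgumentError(f"lambda must be a finite non-negative scalar, got {lam!r}")
    P = np.asarray(P, dtype=float)
    D = X.shape[1]
    if P.shape != (D + 1, D + 1):
        raise InvalidArgumentError(
            f"penalty must be ({D + 1}, {D + 1}) for a {D}-column design, got {P.shape}"
        )
    const = np.ptp(X, axis=0) == 0
    if np.any(const):
        logger.warning("design has %d constant column(s); ridge keeps them", const.sum())
    coef = _solve_gram(*_gram(X, Y), float(lam), P)
    return WeightSolution(bias=coef[0].copy(), weights=coef[1:].copy(), lam=float(lam))


@dataclass(frozen=True)
class TRFModel:
    """A fitted temporal response function or stimulus decoder.

    ``weights`` has shape (F, L, N) for forward models (stimulus feature x
    lag x response channel) and (N, L, F) for backward models (channel x
    lag x stimulus feature); the lag axis follows the ascending sample
    lags of the *design* window (see :meth:`design_window`).  ``lagspec``
    always stores the user-facing (forward-convention) window; for
    backward models the design window has the edges swapped with signs
    kept.
    """

    direction: Direction
    weights: np.ndarray
    bias: np.ndarray
    lam: float
    lagspec: LagSpec

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise InvalidArgumentError(f"unknown direction: {self.direction!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3:
            raise InvalidArgumentError("weights must be a 3-d (inputs, lags, outputs) array")
        if not np.all(np.isfinite(w)):
            raise InvalidArgumentError("weights contain non-finite entries")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", np.atleast_1d(np.asarray(self.bias, dtype=float)))
        if self.bias.shape != (w.shape[2],):
            raise InvalidArgumentError(
                f"bias must have one entry per output, got {self.bias.shape} "
                f"for {w.shape[2]} outputs"
            )
        if w.shape[1] != self.lagspec.n_lags:
            raise InvalidArgumentError(
                f"weights have {w.shape[1]} lags but the lag window resolves "
                f"to {self.lagspec.n_lags}"
            )

    @property
    def fs(self) -> float:
        return self.lagspec.fs

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_lags(self) -> int:
        return self.weights.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[2]

    def design_window(self) -> LagSpec:
        """The lag window actually applied to the model's input."""
        return self.lagspec if self.direction == "forward" else self.lagspec.reversed()

    def design_lags(self) -> np.ndarray:
        """Ascending integer sample lags of the design window (= the order
        of the weight lag axis)."""
        return self.design_window().lags()

    def weights_2d(self) -> np.ndarray:
        """Weights flattened to (F*L, O) matching the lag-major column
        layout of :func:`trflab.lagmat.build_lag_matrix`."""
        F, L, O = self.weights.shape
        return self.weights.transpose(1, 0, 2).reshape(L * F, O)


def _weights_3d(flat: np.ndarray, n_inputs: int, n_lags: int) -> np.ndarray:
    """Inverse of :meth:`TRFModel.weights_2d`."""
    O = flat.shape[1]
    return flat.reshape(n_lags, n_inputs, O).transpose(1, 0, 2)


def _resolve_penalty(penalty: str, direction: Direction, n_inputs: int) -> PenaltyKind:
    if penalty == "auto":
        # The smoothness penalty is only meaningful along a pure lag axis:
        # auto-select it for univariate forward designs, identity otherwise.
        return "quadratic" if (direction == "forward" and n_inputs == 1) else "identity"
    if penalty not in ("identity", "quadratic"):
        raise InvalidArgumentError(f"unknown penalty: {penalty!r}")
    if penalty == "quadratic" and n_inputs != 1:
        raise InvalidPenaltyError(
            "the quadratic smoothness penalty requires exactly one input "
            f"variable per lag, got {n_inputs}"
        )
    return penalty  # type: ignore[return-value]


def _orient(stimulus: np.ndarray, response: np.ndarray, spec: LagSpec,
            direction: Direction) -> tuple[np.ndarray, np.ndarray, LagSpec]:
    """Map (stimulus, response) to (design input, output, design window)."""
    s = _as_2d(stimulus, "stimulus")
    r = _as_2d(response, "response")
    if s.shape[0] != r.shape[0]:
        raise InvalidArgumentError(
            f"stimulus and response must have equal length, got {s.shape[0]} "
            f"and {r.shape[0]}"
        )
    if direction == "forward":
        return s, r, spec
    return r, s, spec.reversed()


def fit_trial(stimulus: np.ndarray, response: np.ndarray, spec: LagSpec,
              direction: Direction, lam: float,
              penalty: str = "auto") -> TRFModel:
    """Fit a single-trial TRF (forward) or decoder (backward).

    Forward models regress the multichannel response on the lagged
    stimulus; backward models regress the stimulus on the lagged response,
    with the lag window edges swapped (signs kept) so that the decoder
    integrates response samples *after* each stimulus sample.

    ``penalty='auto'`` selects the quadratic smoothness penalty for
    univariate forward fits and identity shrinkage otherwise.
    """
    x, y, window = _orient(stimulus, response, spec, direction)
    kind = _resolve_penalty(penalty, direction, x.shape[1])
    tau_min, tau_max = window.sample_lags()
    X = build_lag_matrix(x, tau_min, tau_max).values
    T, D = X.shape
    if T <= D:
        raise IllPosedDesignError(f"need T > F*L: T={T}, design columns={D}")
    sol = ridge_solve(X, y, lam, penalty_matrix(kind, D))
    weights = _weights_3d(sol.weights, x.shape[1], window.n_lags)
    return TRFModel(direction=direction, weights=weights, bias=sol.bias,
                    lam=float(lam), lagspec=spec)


def _check_compatible(models: Sequence[TRFModel]) -> None:
    if len(models) == 0:
        raise InvalidArgumentError("need at least one model")
    first = models[0]
    for m in models[1:]:
        if (m.direction != first.direction or m.weights.shape != first.weights.shape
                or m.lagspec != first.lagspec or m.lam != first.lam):
            raise InvalidArgumentError("models are incompatible (direction, "
                                       "shape, lag window and lambda must match)")


def average_models(models: Sequence[TRFModel]) -> TRFModel:
    """Element-wise mean of per-trial models sharing shape, window and lambda."""
    _check_compatible(models)
    w = np.mean([m.weights for m in models], axis=0)
    b = np.mean([m.bias for m in models], axis=0)
    return replace(models[0], weights=w, bias=b)
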