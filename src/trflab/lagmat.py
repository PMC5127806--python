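"""Time-lag windows and lagged (Toeplitz-like) design matrices.

A temporal response function relates a stimulus sample at time ``t - tau``
to the response at time ``t`` for a contiguous window of integer sample
lags ``tau_min..tau_max``.  The design matrix for that regression holds
time-shifted copies of the input, zero-padded at the edges so that no
samples outside the recording enter the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import IllPosedDesignError, InvalidArgumentError

__all__ = ["LagSpec", "LagMatrix", "ms_to_sample_lags", "build_lag_matrix"]


@dataclass(frozen=True)
class LagSpec:
    """A time-lag window in milliseconds together with the sampling rate.

    Parameters
    ----------
    tmin_ms, tmax_ms : float
        Window edges in milliseconds.  Negative lags are anticausal
        (response preceding the stimulus) and are permitted, e.g. as a
        pre-stimulus baseline.  ``tmin_ms <= tmax_ms`` is required; an
        equal pair denotes a single-lag window.
    fs : float
        Sampling rate in Hz, shared by stimulus and response.
    """

    tmin_ms: float
    tmax_ms: float
    fs: float

    def __post_init__(self) -> None:
        for name in ("tmin_ms", "tmax_ms", "fs"):
            v = getattr(self, name)
            if not (np.isscalar(v) and math.isfinite(float(v))):
                raise InvalidArgumentError(f"{name} must be a finite scalar, got {v!r}")
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if self.tmin_ms > self.tmax_ms:
            raise InvalidArgumentError(
                f"tmin_ms ({self.tmin_ms}) must not exceed tmax_ms ({self.tmax_ms})"
            )

    def sample_lags(self) -> tuple[int, int]:
        """Resolved integer sample lags ``(tau_min, tau_max)``.

        The floor/ceil rule guarantees the requested millisecond window is
        fully covered by the integer-lag window.
        """
        tau_min = math.floor(self.tmin_ms * self.fs / 1000.0)
        tau_max = math.ceil(self.tmax_ms * self.fs / 1000.0)
        return tau_min, tau_max

    @property
    def n_lags(self) -> int:
        tau_min, tau_max = self.sample_lags()
        return tau_max - tau_min + 1

    def lags(self) -> np.ndarray:
        """Ascending integer sample lags of the window."""
        tau_min, tau_max = self.sample_lags()
        return np.arange(tau_min, tau_max + 1)

    def lag_times_ms(self) -> np.ndarray:
        """Lag positions in milliseconds on the resolved sample grid."""
        return self.lags() * 1000.0 / self.fs

    def reversed(self) -> "LagSpec":
        """The window used when the mapping direction is flipped.

        The edges are swapped but their signs kept, so a forward window of
        (-100, 400) ms becomes a backward window of (-400, 100) ms.
        """
        return LagSpec(-self.tmax_ms, -self.tmin_ms, self.fs)


def ms_to_sample_lags(spec: LagSpec) -> tuple[int, int]:
    """Convert a millisecond lag window to integer sample lags."""
    return spec.sample_lags()


@dataclass(frozen=True)
class LagMatrix:
    """A zero-padded lagged design matrix.

    ``values`` is T x (F*L): L contiguous column blocks, one per lag in
    ascending ``lag_order``, each of width F (features contiguous within a
    lag block).  Entries referencing time indices outside the recording
    are exactly zero.
    """

    values: np.ndarray
    lag_order: np.ndarray
    feature_count: int = field(default=1)

    @property
    def n_lags(self) -> int:
        return len(self.lag_order)


def _as_2d(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InvalidArgumentError(f"{name} must be 1- or 2-dimensional, got {x.ndim}")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError(f"{name} contains non-finite entries")
    return x


def build_lag_matrix(x: np.ndarray, tau_min: int, tau_max: int) -> LagMatrix:
    """Build the lagged design for input ``x`` over sample lags
    ``tau_min..tau_max`` (inclusive).

    The column block for lag ``tau``, feature ``f`` holds ``x[t - tau, f]``
    with out-of-range samples set to zero.  Positive lags shift the input
    forward in time (causal influence on later response samples), negative
    lags backward.

    Raises
    ------
    IllPosedDesignError
        If the number of time samples does not exceed the lag count.
    """
    x = _as_2d(x)
    if tau_min > tau_max:
        raise InvalidArgumentError(f"tau_min ({tau_min}) > tau_max ({tau_max})")
    T, F = x.shape
    L = int(tau_max) - int(tau_min) + 1
    if T <= L:
        raise IllPosedDesignError(
            f"need more samples than lags: T={T}, L={L}"
        )
    out = np.zeros((T, F * L), dtype=float)
    for j, tau in enumerate(range(int(tau_min), int(tau_max) + 1)):
        block = out[:, j * F:(j + 1) * F]
        if tau > 0:
            block[tau:, :] = x[:T - tau, :]
        elif tau < 0:
            block[:tau, :] = x[-tau:, :]
        else:
            block[:, :] = x
    return LagMatrix(values=out, lag_order=np.arange(int(tau_min), int(tau_max) + 1),
                     feature_count=F)
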