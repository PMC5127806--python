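"""Synthetic stimulus/response generator with known ground-truth kernels.

Emulates the data regime of multi-trial continuous-speech EEG experiments:
M trials of roughly a minute each, sampled at 128 Hz, with a few dozen
response channels.  Responses are generated by convolving a known biphasic
kernel (negative deflection near 80 ms, positive near 140 ms, mimicking an
auditory N1-P2 complex) with the stimulus and adding white Gaussian noise
at a controlled per-channel SNR.  Stimuli are either white (uncorrelated
across lags), first-order autoregressive, or "speech-like" (a slowly
modulating non-negative envelope with strong autocorrelation).

Everything is reproducible bit-for-bit given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.signal

from .exceptions import InvalidArgumentError
from .lagmat import build_lag_matrix
from .regress import TRFModel  # noqa: F401  (re-exported convenience)

__all__ = [
    "KernelSpec",
    "SimConfig",
    "SimulatedDataset",
    "make_kernel",
    "make_stimulus",
    "simulate_response",
    "simulate_dataset",
]

StimulusKind = Literal["white", "ar1", "speechlike"]


@dataclass(frozen=True)
class KernelSpec:
    """Shape of the ground-truth kernel: a difference of two Gaussians.

    Defaults give a negative peak at 80 ms and a positive peak at 140 ms
    (widths chosen narrow enough that the overlap shifts neither peak by
    more than one sample at 128 Hz), over a 300 ms causal support.
    """

    duration_ms: float = 300.0
    neg_peak_ms: float = 80.0
    pos_peak_ms: float = 140.0
    neg_width_ms: float = 15.0
    pos_width_ms: float = 30.0
    amplitude: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated dataset.

    Defaults mirror the multi-trial EEG regime: fs = 128 Hz, 5 trials of
    60 s, 32 channels, univariate stimulus, SNR 0 dB.
    """

    seed: int
    fs: float = 128.0
    n_trials: int = 5
    trial_dur: float = 60.0
    n_channels: int = 32
    n_features: int = 1
    kernel: KernelSpec = field(default_factory=KernelSpec)
    stimulus_kind: StimulusKind = "white"
    ar1_rho: float = 0.95
    snr_db: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_trials < 1 or self.trial_dur <= 0:
            raise InvalidArgumentError("fs, n_trials and trial_dur must be positive")
        if self.n_channels < 1 or self.n_features < 1:
            raise InvalidArgumentError("n_channels and n_features must be >= 1")
        if not (0 <= self.ar1_rho < 1):
            raise InvalidArgumentError(f"ar1_rho must be in [0, 1), got {self.ar1_rho}")
        if self.stimulus_kind not in ("white", "ar1", "speechlike"):
            raise InvalidArgumentError(f"unknown stimulus kind: {self.stimulus_kind!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_dur * self.fs))


def make_kernel(spec: KernelSpec, n_features: int, n_channels: int, fs: float,
                seed: int) -> np.ndarray:
    """Ground-truth kernel as an (F, L, N) array over causal lags 0..L-1.

    The shared time course is a difference of Gaussians; each
    (feature, channel) pair carries a positive gain drawn uniformly from
    [0.5, 1.5], so peak latencies are identical across channels while
    amplitudes vary.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    L = int(round(spec.duration_ms * fs / 1000.0)) + 1
    t = np.arange(L) * 1000.0 / fs  # lag times in ms
    course = spec.amplitude * (
        -np.exp(-0.5 * ((t - spec.neg_peak_ms) / spec.neg_width_ms) ** 2)
        + np.exp(-0.5 * ((t - spec.pos_peak_ms) / spec.pos_width_ms) ** 2)
    )
    gains = rng.uniform(0.5, 1.5, size=(n_features, n_channels))
    return course[None, :, None] * gains[:, None, :]


def make_stimulus(kind: StimulusKind, T: int, fs: float, seed: int,
                  n_features: int = 1, rho: float = 0.95) -> np.ndarray:
    """Generate a T x F stimulus feature matrix.

    ``white``: i.i.d. standard Gaussian (zero autocorrelation at nonzero
    lags).  ``ar1``: stationary first-order autoregressive process with
    coefficient ``rho`` and unit marginal variance.  ``speechlike``: white
    noise low-pass filtered below 15 Hz (4th-order Butterworth at 4 Hz,
    zero-phase), unit variance, shifted to be non-negative — a slowly
    modulating envelope strongly correlated with itself at nonzero lags.
    """
    rng = np.random.default_rng(seed)
    if kind == "white":
        return rng.standard_normal((T, n_features))
    if kind == "ar1":
        if not (0 <= rho < 1):
            raise InvalidArgumentError(f"rho must be in [0, 1), got {rho}")
        e = rng.standard_normal((T, n_features)) * np.sqrt(1.0 - rho ** 2)
        x0 = rng.standard_normal((1, n_features))
        zi = rho * x0  # stationary start: x[0] = rho*x0 + e[0]
        x, _ = scipy.signal.lfilter([1.0], [1.0, -rho], e, axis=0, zi=zi)
        return x
    if kind == "speechlike":
        cutoff_hz = 4.0
        sos = scipy.signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
        z = scipy.signal.sosfiltfilt(sos, rng.standard_normal((T, n_features)), axis=0)
        z = z / z.std(axis=0)
        return z - z.min(axis=0)
    raise InvalidArgumentError(f"unknown stimulus kind: {kind!r}")


def simulate_response(stimulus: np.ndarray, kernel: np.ndarray, snr_db: float,
                      seed: int) -> np.ndarray:
    """Convolve the stimulus with the kernel and add channel-wise noise.

    The clean response at channel n is the lagged stimulus times the
    kernel (causal lags 0..L-1).  White Gaussian noise is scaled so that
    10*log10(var(clean)/var(noise)) equals ``snr_db`` per channel; pass
    ``snr_db=np.inf`` for a noise-free response.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.ndim == 1:
        stimulus = stimulus[:, None]
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 3 or kernel.shape[0] != stimulus.shape[1]:
        raise InvalidArgumentError(
            f"kernel must be (F, L, N) with F matching the stimulus; got "
            f"{kernel.shape} for a {stimulus.shape[1]}-feature stimulus"
        )
    F, L, N = kernel.shape
    X = build_lag_matrix(stimulus, 0, L - 1).values
    clean = X @ kernel.transpose(1, 0, 2).reshape(L * F, N)
    if np.isinf(snr_db) and snr_db > 0:
        return clean
    var_clean = clean.var(axis=0)
    if np.any(var_clean == 0):
        raise InvalidArgumentError(
            "clean response has zero variance on some channel; cannot "
            "realize a finite SNR"
        )
    noise_std = np.sqrt(var_clean / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return clean + rng.standard_normal(clean.shape) * noise_std


@dataclass(frozen=True)
class SimulatedDataset:
    """Trials plus the ground truth that generated them."""

    stimuli: list[np.ndarray]
    responses: list[np.ndarray]
    kernel: np.ndarray
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full multi-trial dataset under the given conditions.

    Per-trial seeds are spawned deterministically from ``config.seed`` via
    :class:`numpy.random.SeedSequence`, so the same config always yields
    the same dataset while trials stay mutually independent.
    """
    ss = np.random.SeedSequence(config.seed)
    kernel_seed, *trial_seeds = [int(s.generate_state(1)[0] % 2 ** 31)
                                 for s in ss.spawn(1 + 2 * config.n_trials)]
    kernel = make_kernel(config.kernel, config.n_features, config.n_channels,
                         config.fs, kernel_seed)
    stimuli, responses = [], []
    for i in range(config.n_trials):
        s = make_stimulus(config.stimulus_kind, config.n_samples, config.fs,
                          trial_seeds[2 * i], config.n_features, config.ar1_rho)
        r = simulate_response(s, kernel, config.snr_db, trial_seeds[2 * i + 1])
        stimuli.append(s)
        responses.append(r)
    return SimulatedDataset(stimuli=stimuli, responses=responses,
                            kernel=kernel, config=config)
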