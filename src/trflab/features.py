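"""Continuous stimulus features from audio.

Provides the broadband Hilbert envelope, a cochlear-scaled (Greenwood)
log-spaced filterbank spectrogram, an exponential intensity mapping for
modulated-noise stimuli, and anti-aliased resampling to the neural
sampling rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import scipy.io.wavfile
import scipy.signal

from .exceptions import AliasingError, InvalidArgumentError

__all__ = [
    "AudioSignal",
    "Filterbank",
    "read_wav",
    "hilbert_envelope",
    "greenwood_position",
    "greenwood_frequency",
    "greenwood_edges",
    "filterbank_spectrogram",
    "intensity_map",
    "resample_feature",
]

logger = logging.getLogger(__name__)

# Greenwood (1990) human cochlear map f(x) = A (10^(a x) - k) with the
# basilar-membrane position x expressed as a proportion of its length.
_GREENWOOD_A = 165.4
_GREENWOOD_ALPHA = 0.06 * 35.0  # 2.1 over the full 35 mm
_GREENWOOD_K = 0.88


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio waveform with its sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise InvalidArgumentError("audio contains non-finite samples")
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", x)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file (PCM or float) as a mono float signal in [-1, 1].

    Multichannel audio is averaged across channels.
    """
    fs, data = scipy.io.wavfile.read(str(path))
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(samples=data, fs=float(fs))


def hilbert_envelope(x: AudioSignal | np.ndarray) -> np.ndarray:
    """Amplitude envelope: modulus of the analytic signal x + j*H{x}."""
    samples = x.samples if isinstance(x, AudioSignal) else np.asarray(x, dtype=float).ravel()
    if samples.size < 2:
        raise InvalidArgumentError("need at least two samples")
    return np.abs(scipy.signal.hilbert(samples))


def greenwood_position(f: np.ndarray) -> np.ndarray:
    """Cochlear position (proportion of basilar-membrane length) of a
    frequency in Hz: x = (1/alpha) log10(f/A + k)."""
    return np.log10(np.asarray(f, dtype=float) / _GREENWOOD_A + _GREENWOOD_K) / _GREENWOOD_ALPHA


def greenwood_frequency(x: np.ndarray) -> np.ndarray:
    """Inverse Greenwood map: f = A (10^(alpha x) - k)."""
    return _GREENWOOD_A * (10.0 ** (_GREENWOOD_ALPHA * np.asarray(x, dtype=float)) - _GREENWOOD_K)


@dataclass(frozen=True)
class Filterbank:
    """F contiguous frequency bands given by F+1 ascending corner
    frequencies in Hz."""

    band_edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.band_edges, dtype=float).ravel()
        if e.size < 2 or np.any(np.diff(e) <= 0) or e[0] <= 0:
            raise InvalidArgumentError("band edges must be >= 2 positive, strictly "
                                       "ascending frequencies")
        object.__setattr__(self, "band_edges", e)

    @property
    def n_bands(self) -> int:
        return self.band_edges.size - 1


def greenwood_edges(F: int, f_lo: float, f_hi: float) -> Filterbank:
    """F+1 corner frequencies equally spaced on the Greenwood cochlear
    position scale between ``f_lo`` and ``f_hi`` (endpoints exact)."""
    if F < 1:
        raise InvalidArgumentError(f"need at least one band, got F={F}")
    if not (0 < f_lo < f_hi):
        raise InvalidArgumentError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    pos = np.linspace(greenwood_position(f_lo), greenwood_position(f_hi), F + 1)
    edges = greenwood_frequency(pos)
    edges[0], edges[-1] = f_lo, f_hi  # pin endpoints against round-off
    return Filterbank(band_edges=edges)


def filterbank_spectrogram(x: AudioSignal, fb: Filterbank) -> np.ndarray:
    """Band-wise Hilbert envelopes: a T x F matrix, bands low to high.

    Each band is isolated with a 4th-order Butterworth band-pass applied
    forward and backward (zero phase), then its envelope taken as the
    modulus of the analytic signal.
    """
    nyq = x.fs / 2.0
    if fb.band_edges[-1] >= nyq:
        raise AliasingError(
            f"filterbank upper edge {fb.band_edges[-1]:.1f} Hz reaches the "
            f"Nyquist frequency {nyq:.1f} Hz"
        )
    min_bw = x.fs / max(x.samples.size, 1)
    out = np.empty((x.samples.size, fb.n_bands))
    for j in range(fb.n_bands):
        lo, hi = fb.band_edges[j], fb.band_edges[j + 1]
        if hi - lo < min_bw:
            logger.warning("band %d (%.1f-%.1f Hz) narrower than the frequency "
                           "resolution; widening", j, lo, hi)
            half = min_bw / 2.0
            lo, hi = max(lo - half, min_bw / 10.0), min(hi + half, nyq * 0.999)
        sos = scipy.signal.butter(4, [lo, hi], btype="band", fs=x.fs, output="sos")
        band = scipy.signal.sosfiltfilt(sos, x.samples)
        out[:, j] = np.abs(scipy.signal.hilbert(band))
    return out


def intensity_map(x: np.ndarray) -> np.ndarray:
    """Exponential intensity mapping x' = 10^(2x) used to convert a
    modulating signal in [0, 1] to perceptually scaled amplitude."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("input contains non-finite values")
    return 10.0 ** (2.0 * x)


def resample_feature(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling with a zero-phase anti-aliasing low-pass at
    the output Nyquist rate.

    The output length is round(T * fs_out / fs_in).  Upsampling is
    permitted.  Identity when the rates match.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise InvalidArgumentError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    T = x.shape[0]
    # padtype="line" extrapolates the edges so constant signals survive
    y = scipy.signal.resample_poly(x, frac.numerator, frac.denominator, axis=0,
                                   padtype="line")
    n_target = int(round(T * fs_out / fs_in))
    if y.shape[0] > n_target:
        y = y[:n_target]
    elif y.shape[0] < n_target:
        pad = np.repeat(y[-1:], n_target - y.shape[0], axis=0)
        y = np.concatenate([y, pad], axis=0)
    return y
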