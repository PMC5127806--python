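# Methods

## Model and estimator

`trflab` models a multichannel neural recording r(t, n), sampled at a
common rate with a continuous stimulus feature s(t, f), as a lagged
linear convolution plus residual noise. The estimator is penalized least
squares on a lagged design matrix: time-shifted copies of the input are
arranged in contiguous column blocks, one block per integer sample lag in
ascending order, features contiguous within a block, and samples shifted
past the edges of the recording are set to zero (no wrap-around, no
trimming — every output sample is retained). A single intercept column of
ones is prepended by the regression layer; a block of mutually identical
ones-columns (one per feature) would be rank-deficient and spans the same
space, so one column is used and it is never penalized.

Millisecond lag windows resolve to integer sample lags by
floor(t_min·fs/1000) and ceil(t_max·fs/1000), so the requested window is
always fully covered; the window ends are permitted to coincide (a
single-lag window). For backward (decoding) fits the window edges are
swapped and their signs kept — a forward window of (−100, 400) ms becomes
a decoder window of (−400, 100) ms — so that the decoder integrates
response samples following each stimulus sample.

The penalized normal equations (X̃ᵀX̃ + λP) w = X̃ᵀY are solved by
Cholesky factorization (the written matrix inverse is notation, not an
algorithm); a vanishing relative pivot raises a singular-design error
advising λ > 0. λ multiplies the penalty as given — it is not rescaled by
the number of samples or the data norm; cross-validation operates on
z-scored data precisely so that one λ grid serves datasets of different
scales.

## Penalties

Two penalties are implemented, both leaving the intercept unpenalized:

* **identity** — classical ridge shrinkage toward zero. Required for
  multivariate designs (multiple features per lag, or multichannel
  decoder inputs), where a lag-smoothness penalty would smear weights
  across the non-time dimension.
* **quadratic** — a tridiagonal matrix with diagonal (1, 2, …, 2, 1) and
  off-diagonals −1 that penalizes squared differences between
  neighbouring lag coefficients. Its null space contains constant
  kernels, so smooth, large-amplitude structure survives regularization;
  the corner entries are 1 rather than 2, leaving the endpoint
  coefficients slightly less penalized, and the matrix is used exactly in
  that form.

`penalty="auto"` selects quadratic for univariate forward fits and
identity everywhere else; either choice can be forced explicitly, except
that quadratic is refused for designs with more than one variable per lag.

## Training and cross-validation

Multi-trial training either averages per-trial fits (the default: robust
to trial boundaries, and cheap to combine during cross-validation) or
sums the per-trial normal equations ("concatenate" — lag padding is kept
within trial boundaries, so no samples bleed across trials). The two
modes agree only approximately when trial Gram matrices differ; the test
suite checks relative weight RMSE < 5 % on stationary white-noise trials
rather than exact equality.

Leave-one-trial-out cross-validation fits one model per trial per λ,
averages the M−1 training models for each held-out trial, and records
per-trial, per-output Pearson r and MSE. Summaries average across trials
first, then across output variables; both granularities are exposed.
Undefined correlations (zero-variance outputs) are stored as NaN,
excluded from averages, and counted. λ ties break to the smallest value
(least bias). Z-scoring is per trial per variable, computed within each
trial (statistics are not pooled across trials); it defaults to on for
cross-validation and off for plain training/prediction. Evaluation uses
all samples including the zero-padded edge region; users who care about
edge artifacts can widen the window by guard lags (±50 ms is a reasonable
choice for visualization).

## Decoder weight transformation

Backward-model weights are not directly interpretable: informative
channels get large weights, but so can noise channels that help cancel
interference. The transformation to forward-interpretable activation
patterns is A = Σ_X W Σ_ŝ⁻¹, with Σ_X the empirical covariance of the
lagged response design (1/(T−1) normalization, computed on the
concatenated training trials), W the decoder weights and Σ_ŝ the
covariance of the decoder's own reconstruction. A singular Σ_ŝ falls back
to a pseudo-inverse with a warning. The result is re-oriented to forward
convention (feature × lag × channel, lag axis reversed back). Only the
pattern's *shape* is guaranteed — the absolute scale depends on the
covariance normalization — which is why tests compare patterns by
correlation, not amplitude.

## Additive multisensory cross-validation

Given unisensory trials (stimulus A with response to A alone, likewise B)
and multisensory trials (both stimuli with the joint response), the
additive model sums the two unisensory coefficient vectors and predicts
each held-out multisensory response from that trial's two stimulus
streams, under the same leave-one-out rotation as ordinary
cross-validation. For a truly additive system this matches a jointly
fitted bimodal model up to noise; sub-additive interactions show up as
over-prediction (higher MSE).

## Audio features

* Broadband envelope: modulus of the analytic signal x + jH{x}.
* Filterbank spectrogram: corner frequencies equally spaced on the
  Greenwood cochlear map x = (1/a)·log10(f/A + k) with the human
  constants A = 165.4, a = 2.1 (0.06 per mm over 35 mm), k = 0.88
  (Greenwood 1990); these constants are a documented choice — the map is
  standard but parameterizations vary. Each band is isolated by a
  4th-order Butterworth band-pass run forward and backward (zero phase;
  filter family and order are our choice) and its Hilbert envelope taken.
* Intensity mapping x′ = 10^(2x) for modulating signals in [0, 1]. The
  exponent convention is isolated in one function (`intensity_map`) so an
  alternative reading costs a one-line change.
* Resampling: polyphase with a zero-phase anti-aliasing low-pass at the
  output Nyquist rate, edges extrapolated linearly so constant signals
  survive; output length is round(T·fs_out/fs_in). Upsampling is allowed.

## Synthetic data

The simulator provides the ground truth that real recordings cannot:
trials are generated by convolving a known kernel with a stimulus and
adding white Gaussian noise at a per-channel variance SNR,
10·log10(var(clean)/var(noise)) = snr_db. The default kernel is a
difference of two Gaussians — a negative peak at 80 ms (width 15 ms) and
a positive peak at 140 ms (width 30 ms) on a 300 ms causal support,
mimicking an auditory N1–P2 morphology; widths are narrow enough that the
peaks' mutual overlap shifts neither peak by more than one sample at
128 Hz. Channels share the time course and differ by gains drawn
uniformly from [0.5, 1.5]. Stimuli are white Gaussian, stationary AR(1)
(default ρ = 0.95, unit marginal variance), or "speech-like": white noise
low-passed at 4 Hz (4th-order Butterworth, zero phase), scaled to unit
variance and shifted non-negative — this reproduces the strong
autocorrelation of a natural envelope at 50 ms lags (ρ̂ > 0.5) while
remaining fully synthetic. Default conditions are fs = 128 Hz, 5 trials
of 60 s, 32 channels, univariate stimulus, SNR 0 dB. Per-trial seeds are
spawned from the master seed via `numpy.random.SeedSequence`, so datasets
are bit-reproducible and trials mutually independent.

What the simulator does **not** emulate: volume conduction and spatially
correlated noise, 1/f spectra, non-stationarity, artifacts, or any
nonlinearity in the stimulus–response mapping. Passing tests therefore
demonstrate correctness of the estimator under its own model assumptions,
not performance on real recordings.

## Numerical and interface choices

* Pearson r is clipped to [−1, 1] against round-off; zero-variance inputs
  yield NaN, flagged and excluded rather than raising mid-pipeline.
* Global field power is the across-channel variance of forward weights at
  each lag, population convention (ddof = 0).
* The cross-correlation baseline is Xᵀr/(sᵀs) per feature on
  mean-centered data — identical to the λ→0 TRF when the stimulus is
  white, temporally smeared when it is not.
* Constant design columns are kept (ridge handles them) with a logged
  warning.
* HDF5 writes use `track_times=False`, so identical data produce
  byte-identical files; seeded CLI runs are bit-reproducible.
* The decoder transform accepts the training stimuli for interface
  symmetry but derives the reconstruction covariance from the decoder
  output itself; the stimuli are not needed by the formula.
* Problem sizes in the tests and the acceptance script (5 × 60 s trials
  at 128 Hz, 8–32 channels, 20 replicates for the statistical
  comparisons) were chosen so that every quantity is estimated well away
  from its decision threshold while the full run stays lightweight.

## Known limitations

Only contiguous lag windows are supported (no sparse lag sets, no
circular lagging). No significance testing of prediction accuracy, no
banded-covariance speedups, no ℓ1/elastic-net penalties or boosting. WAV
is the only audio input format; EDF/BDF ingestion of real recordings is
future work.
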