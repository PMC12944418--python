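# Methods

This note records the models behind `bedvitals`, the parameters that
matter, the numerical choices, and what the simulator does and does
not capture about real under-bed sensing.

## Signal generator

The generator reproduces the drive signal of a single-motor bed
testbed: one voice-coil stroke per heartbeat, respiration expressed as
beat-amplitude modulation.

**Beat schedule.** Beats start at t = 0 and repeat every 60/HR
seconds; the design range is 40–240 bpm. Irregular rhythms
(arrhythmia-like, e.g. atrial fibrillation) replace the constant
interval with user-supplied per-beat intervals or i.i.d. truncated
normal draws. Intervals of two sample periods or less are rejected as
unrenderable.

**Pulse shape.** Each beat contributes one positive half-cycle,
`A·sin(π·t′/W)` over `W = duty·interval` (default duty 0.5), resting
at zero the remaining fraction of the beat — the motor must return to
its ground position to strike again. The duty fraction is a free
parameter because only the need for a rest interval, not the stroke
length, is physically constrained. A square pulse is available as a
contrast waveform. Default amplitude is 256 DAC counts on a 12-bit
(0–4095) scale: a small stroke keeps the return-to-ground feasible at
high rates.

**Respiration.** A rising sawtooth with period 60/RR ramps from 0.95
to 1.0 (a 5% modulation depth) and is sampled at each beat onset; the
whole pulse of beat k is scaled by gain g_k. The ramp starts at its
minimum at t = 0, and the onset (not the pulse peak) is the sampling
point — both are arbitrary phase conventions chosen for determinism.
Because HR is generally not an integer multiple of RR, the number of
beats per breath varies and the beat-amplitude sequence traces the
sawtooth faithfully.

**Quantization.** Samples are rounded half-to-even to integer DAC
levels and clipped to [0, 4095]; signals stay integer-valued until the
channel stage.

### The per-beat sampling limit

Respiration enters the signal *only* through the per-beat gains: the
sawtooth is sampled once per heartbeat, at rate HR/60 Hz. By the
sampling theorem, respiratory rates at or above half the heart rate
are aliased — at HR 40/RR 40 the gain sequence is exactly constant,
and at HR 40/RR 32 it is indistinguishable from an 8 brpm breather.
No estimator can undo this; it is a property of the modulation
mechanism, and it bounds which HR×RR combinations are jointly
feasible (RR < HR/2). Evaluation grids in the tests and the
acceptance script respect this bound; the estimators, when handed an
aliased signal, report the alias frequency exactly as a real
undersampled system would.

## Bed channel

A linear time-invariant channel stands in for mattress, frame and
sensor coupling:

- base impulse response (default: identity single tap);
- a weight-distortion tail `w·exp(−k/(τ·fs·(1+w)))` added on top,
  with `w` the dimensionless weight factor and τ = 0.05 s: heavier
  simulated loads both strengthen and lengthen the ringing, which at
  fast heart rates keeps inter-beat troughs off the baseline
  (successive beats overlap). The mapping from added kilograms to `w`
  is deliberately left as a calibration knob — only the phenomenon,
  not its magnitude, is constrained;
- additive white Gaussian noise with standard deviation `noise_sd` in
  output units (`noise_sd_for_snr` converts a target SNR in dB to a
  noise level against a signal's AC power). The noise spectrum is
  white because nothing beyond Gaussianity is specified.

Convolution is full-length, truncated to the input length at zero
lag. All randomness is seeded; a global seed fans out to per-purpose
streams through a stable label hash, so adding one consumer never
perturbs another's draws.

## Heart-rate estimation

10 s windows (hop 1 s for streaming use):

1. z-score normalization;
2. zero-phase (forward–backward) 4th-order Butterworth band-pass
   0.1–20 Hz — the low edge removes DC wander, the high edge
   appliance noise;
3. Hilbert envelope `sqrt(x² + x_H²)`;
4. two centered moving averages of 10 samples (0.1 s at 100 Hz), then
   a sliding cubic (Savitzky–Golay, window 31) — knocks down jitter
   without flattening beat peaks;
5. sample autocorrelation
   `ACF(k) = Σ(x_i−x̄)(x_{i+k}−x̄)/Σ(x_i−x̄)²`, dominant lag m over
   the 40–240 bpm band (lags 25–150 samples at 100 Hz; ties to the
   smaller lag), `HR = 60·fs/m`. The full-signal denominator makes
   the estimate shrink linearly with lag, which is exactly what makes
   the smallest periodic lag win for a periodic signal.
6. validity: the dominant frequency must lie in 0.6–4 Hz; otherwise
   the window is flagged instead of reported.

HR is quantized to the lag grid: steps of 60·fs/m − 60·fs/(m+1),
≈0.6 bpm at 60 bpm and ≈9 bpm at 240 bpm. Tighter resolution would
require interpolating the ACF peak, which the lag-domain formula
deliberately does not do.

**Edge handling.** The FFT analytic signal is circular; on a 10 s
window its edge transients tilt the envelope enough to move the
dominant lag by several samples (verified against interior windows of
long signals, where the ACF lag is exact). The pipeline therefore
computes the Hilbert transform with a 201-tap windowed FIR
transformer, whose edge effects are confined to one second per side,
and drops 1.5 s from each end of the envelope before the ACF. The
exact FFT analytic signal remains the default of the public
`hilbert_envelope`; the ACF can also be taken on the band-passed
signal directly (`acf_source="bandpassed"`).

## Respiratory-rate estimation

50 s windows. A geophone reads velocity, so step 1 integrates: the
cumulative sum of the mean-centered signal is chest displacement up to
a random walk from sensor noise (integrated white noise of variance
σ² has Var(D_T) = σ²·T, a law the test suite checks by Monte Carlo).
The displacement is linearly detrended — a cumulative sum drifts —
and mirror-padded by 5 s so envelope and filter transients fall
outside the analysis span.

Respiration is amplitude modulation of the cardiac oscillation in
that displacement, and the pipeline demodulates it:

1. **carrier isolation** — the beat fundamental f₀ is the strongest
   spectral line in 0.55–4.3 Hz; a zero-phase band-pass keeps
   [0.52·f₀, 1.48·f₀], capped at f₀ ± 0.9 Hz. The relative band
   excludes the second harmonic while keeping modulation sidebands up
   to the per-beat sampling limit; the absolute cap drops needless
   noise bandwidth at fast heart rates (physiological sidebands never
   sit further than ≈0.7 Hz from the carrier). Without this step the
   Hilbert envelope of the raw displacement is dominated by
   harmonic-beating ripple at the beat frequency — inside the 0.1–2 Hz
   respiration band for HR ≤ 120 bpm and an order of magnitude larger
   than the 5% respiratory modulation;
2. Hilbert envelope of the isolated carrier, FFT, zero every bin
   outside 0.1–2 Hz (edges inclusive, conjugate symmetry preserved),
   inverse FFT;
3. **peak counting** — local maxima at least 1.2 s apart (the 40 brpm
   period with 20% tolerance) with prominence ≥ 0.2× the waveform's
   interquartile range; `RR = 60·P/duration`, resolution
   60/duration = 1.2 brpm at 50 s.

Between 2 and 3 the waveform is narrowed to the countable band: the
dominant respiratory line f_m is located on a Welch-averaged,
zero-padded spectrum (averaging suppresses noise excursions, the fine
grid avoids scalloping), and the waveform is band-passed to
[0.6·f_m, 1.35·f_m] before counting. Sawtooth modulation is
harmonic-rich, and on slow breaths the harmonics otherwise register
as extra peaks. Two guards keep f_m honest: a candidate steps down to
f/2 or f/3 (iterated, so a 4× lock needs two steps) only when the
lower line stands above the local continuum (ratio > 1.45) *and* its
non-coinciding harmonics independently carry at least half the
candidate's amplitude — separating a true slow fundamental from mere
period-doubling of a faster breath. Filtering for the count uses
periodic extension at the detected period, which keeps the first and
last breath countable where generic padding distorts them.

Zero peaks, or modulation below 0.5% of the carrier envelope, flags
the estimate implausible rather than reporting 0 brpm.

## Transfer-function estimation and recovery

With a chirp x over the bed and the sensed y under it,
`H = Y·conj(X)/(|X|² + ε·max|X|²)` per FFT bin — Wiener-style
regularized division, because the bare ratio Y/X explodes wherever
the excitation has no energy. ε defaults to 1e-3 (relative to the
peak of |X|²); Welch-averaged cross/auto spectra are available for
noisy recordings, and recovery interpolates a coarse H onto the
signal's grid. Recovery inverts with the same floor:
`X̂ = Y·conj(H)/(|H|² + ε·max|H|²)`. The floor matters most for
channels with in-band spectral nulls, where unregularized inversion
amplifies noise without bound.

Recovery accuracy is the maximum over lags of the normalized
cross-correlation of the two z-scored signals, each lag normalized by
its overlap (lags under half overlap excluded): 1 for a perfect —
possibly delayed and rescaled — recovery, near 0 for unrelated
signals. The convention is signed: a sign-flipped recovery does not
score high.

## Evaluation protocol

`sweep_grid` runs, per HR×RR cell: synthesize 60 s at 100 Hz, pass
through the channel with a per-cell derived seed, slide the HR
estimator (10 s windows, 1 s hop) and the RR estimator (50 s windows,
1 s hop), and record the median over valid windows — alongside the
worst window, the heatmap convention. Summaries: MAE, MAPE, error SD
(n−1), and Bland–Altman bias with ±1.96·SD limits of agreement.

The acceptance script (`scripts/acceptance.py`) sweeps
HR ∈ {40, 65, …, 240} × RR ∈ {8, 16, …, 40} restricted to the 41
jointly feasible pairs (RR < HR/2), through a channel with weight
factor 0.5 and noise at ≈20 dB SNR; and measures chirp recovery
through a 31-tap band-pass FIR at 20 dB SNR with H estimated from an
independently seeded excitation. Problem sizes (60 s signals, one
replicate per cell, 41 cells) keep a full run under ten seconds while
leaving every rate of both design ranges represented.

## What passing tests do and do not show

The simulator is faithful to the *drive* side of a bed testbed: exact
beat timing, half-sine strokes, sawtooth amplitude modulation, DAC
quantization, linear channel, white sensor noise. Real geophone
recordings differ in ways the tests cannot certify: cardiac
vibrations are wideband transients (5–20 Hz J-wave complexes) rather
than smooth half-sines; respiration also moves the chest directly
and couples nonlinearly with posture; mattresses are dispersive and
weakly nonlinear; noise is colored and includes footsteps and
appliances; subjects move. Estimator accuracy here is therefore an
upper bound under idealized mechanics, not a clinical claim. The
channel's weight factor is a qualitative knob — it reproduces
beat-overlap phenomenology, not calibrated kilograms.

## Known limitations

- RR above half the HR is unrecoverable in principle (aliasing of the
  per-beat modulation); the estimator then reports the alias.
- Harmonic-rich modulation can still capture the fundamental tracker
  in rare noisy windows (a 2× over-count); the sliding-window median
  absorbs single-window errors but not a systematically captured
  cell.
- HR resolution at the top of the band is coarse (≈9 bpm per lag step
  at 240 bpm); the validity band 0.6–4 Hz is enforced as stated even
  though the sweep band (40–240 bpm) is slightly narrower at its low
  end.
- The 0.1 Hz band-pass corner has multi-second transients; windows
  shorter than ~6 s are rejected rather than estimated.
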