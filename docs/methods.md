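# Methods

This note documents the models, numerical choices and limitations behind
`respifuse`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py`, not asserted from
elsewhere.

## Signal model and preprocessing

Respiration modulates the cardiovascular signals through three mechanisms:
beat-amplitude modulation (cardiac axis rotation and thoracic impedance for
ECG, stroke-volume variation for PPG), beat-interval modulation
(respiratory sinus arrhythmia), and baseline wander (intra-thoracic
pressure). The pipeline treats each mechanism on each channel as one
respiratory modulated component (RMC), six in total: EAM/EFM/EBW from ECG,
PAM/PFM/PBW from PPG.

Both channels are polyphase-resampled to a common 300 Hz, smoothed with a
centered 10-point moving average (reflective edges), and high-pass filtered
with a third-order Butterworth at 0.05 Hz. The high-pass is applied
forward-backward (zero phase) so fiducial timing is not skewed; the
effective attenuation is therefore the squared magnitude response, about
−84 dB for drift at 0.01 Hz. Windows are half-open `[start, start+L)` with
L = 30 s by default (configurable 30–60 s, sliding step a fraction of L);
trailing partial windows are dropped because the spectral resolution of
the final RR read-out depends on full window length.

One consequence worth knowing: a 0.05 Hz filter settles over ~20 s, so on a
30–60 s window the *baseline* components (EBW/PBW) always ride on a slow
settling transient. The transient lives below the respiratory band and is
removed downstream by VMD mode selection and RQI screening; amplitude and
interval components are unaffected (differences cancel the baseline).

## Fiducial detection

R-peaks: Pan-Tompkins chain (5–15 Hz band-pass, derivative, squaring,
150 ms moving-window integration) with adaptive signal/noise levels
(running 0.125/0.875 exponential updates, threshold = noise + 0.25 ·
(signal − noise)) and a 200 ms refractory period; each detection is mapped
back to the raw-ECG maximum within ±50 ms. Zero-phase filtering removes
the need for group-delay bookkeeping. Q waves are the minimum over the
200 ms before each R; beats whose search interval leaves the window are
dropped. Inter-beat intervals outside 0.3–2.0 s reject the later beat.

PPG onsets: local minima at least 300 ms apart, kept when at or below a
running 25th percentile of the signal over a 2 s context (the "adaptive
threshold" reading of trough detection). The systolic peak is the maximum
within 125 ms after the onset (`floor` of 0.125·fs samples, so the pairing
lag never exceeds 125 ms). Argmin/argmax ties break to the earliest index.

## RMC extraction and uniform resampling

Per cardiac cycle: EAM = ecg[R] − ecg[Q], EBW = (ecg[R] + ecg[Q])/2, both
stamped at the R time; EFM = successive R-R interval stamped at the
interval midpoint (one fewer sample than beats). PPG analogues use
onset/systolic-peak pairs. Amplitude/baseline series are offset-invariant
in the ways one expects (differences exactly, midpoints after centering).

The VMD and spectral stages need uniform sampling, so each beat series is
cubic-spline interpolated onto a 10 Hz grid and mean-subtracted. 10 Hz sits
far above the 0.75 Hz band edge while keeping a 30 s window at ~300
samples, which makes the per-window VMD cheap; spectral resolution is set
by window length, not by this rate. No extrapolation beyond the observed
beats: the pipeline intersects the six beat spans and resamples all
components onto one common grid so they can later be fused column-wise.
A window needs at least 4 usable beats per channel; channels that fail
contribute no components and are flagged, not fatal.

## VMD denoising

Each RMC is decomposed into K = 5 intrinsic mode functions by variational
mode decomposition: an ADMM scheme in which each mode is Wiener-filtered
around its center frequency, the center frequency is updated as the
spectral centroid of the mode, and (with dual step τ = 0 here) no exact
reconstruction constraint is enforced. Parameters α = 2000, τ = 0,
tol = 1e-7, at most 500 iterations, no enforced DC mode, centers
initialized uniformly over [0, fs/2); modes are returned sorted by center
frequency. K = 5 is enough for these spectrally sparse series without mode
mixing.

Two numerical choices matter:

* **Center-frequency estimation** runs on the signal extended by the
  classic even mirror (half the window reflected at each end), which
  stabilizes the centroids against boundary leakage.
* **Mode synthesis** does *not* crop a filtered mirrored signal, because
  the mirror joins sit exactly at the crop boundaries and leave a
  derivative kink there (~15% relative L2 error on a pure tone at
  α = 2000, essentially all of it in the first and last couple of
  seconds). Instead, the converged τ = 0 fixpoint is used in closed form:
  the equations `u_k = (f − Σ_{i≠k} u_i) H_k` solve to the partition
  filter bank `u_k = f · a_k / (1 + Σ_j a_j)` with
  `a_k = 1/(2α(ω − ω_k)²)`, applied directly to the unextended window.
  This reproduces a pure tone to 0.05% relative L2, reconstructs noisy
  multitone inputs to within ~4% residual, and keeps Σ‖u_k‖² ≤ ‖x‖²
  by construction (the gains partition unity).

The denoised component is the single mode whose periodogram peak
(mean-removed, Hann window, zero-padded to 4096 bins) is closest to the
input's own peak; ties go to the lower-index (lower-frequency) mode.
Non-convergence at 500 iterations is flagged but the result is still used.

## RQI screening

RQI = (power in 0.05–0.75 Hz) / (total non-DC power), computed from the
unwindowed, unpadded FFT of the series so that the two sums are plain
coefficient sums; magnitude-squared coefficients are used ("energy
concentration"), isolated in `compute_rqi` should magnitude ever be
preferred. The DC bin is excluded from the total because the series are
mean-subtracted upstream and a numerically nonzero DC residual would make
the score depend on centering precision. The ratio is identical one-sided
or two-sided by symmetry. RQI is scale-invariant and monotone in in-/out-
of-band energy.

Per window the threshold is adaptive: T = mean RQI of the available
components; components with RQI ≥ T are fused. Since the maximum is never
below the mean, at least one component always survives. Missing components
(failed extraction) are excluded from both the mean and the selection
rather than scored zero, which would bias T downward. Because VMD already
concentrates each component's energy near its own spectral peak, the six
RQIs are compressed toward the top of the scale; the mean threshold still
ranks them, which is all the selection needs.

## PCA fusion and RR estimation

The m selected components are the columns of X (L×m, common grid). X is
column-centered and, by default, scaled to unit variance per column —
interval components are measured in seconds and amplitude components in
arbitrary signal units, and covariance PCA without scaling would let
whichever has the larger numeric range dominate the first component
(`normalize_rmcs: false` restores the literal center-only behavior). The
fused waveform is the projection onto the leading eigenvector of the
column covariance; the sign is fixed so the largest-magnitude loading is
positive (PCA sign is arbitrary and irrelevant to the spectral read-out;
determinism helps testing). Eigenvalues sort descending with ties keeping
column order. A rank-zero X (all columns constant) is a degenerate-fusion
error.

RR is read from the Hann-windowed periodogram of the fused waveform,
zero-padded to 2^14 bins (~0.0006 Hz grid at 10 Hz, i.e. an RR grid of
~0.04 breaths/min — without padding, the raw 1/30 Hz resolution of a 30 s
window would contribute 2 breaths/min of quantization error on its own).
The peak search runs over the closed band [0.05, 0.75] Hz; ties go to the
lower frequency; RR = 60 · f_RR. Windows where any stage fails carry
quality flags (`no_beat`, `insufficient_beats`, `degenerate`,
`vmd_unconverged`) instead of an RR value, so coverage stays visible in
the outputs and the per-record window count always equals the segmenter's.

## Error metrics

For paired estimates/references: ME (bias), STD (sample, n−1), MAE, RMSE,
and Bland-Altman bias with 1.96·STD limits of agreement. The identity
RMSE² = ME² + STD²(n−1)/n ties them together and is verified to 1e-9.
Pairs with a missing value are excluded and counted. Cohort aggregation
reports both per-record metrics and metrics pooled over all window pairs,
since either convention appears in the literature.

## Synthetic data generator

The generator exists so that every stage has exact ground truth. One beat
process drives both channels (as in physiology): beat times integrate the
instantaneous period T(t) = 60/hr + fm_depth·sin(2π f_r t) — integral
pulse frequency modulation with sinusoidal RSA. Breathing is sinusoidal at
f_r = rr/60 (a linear RR chirp mode exercises time-varying-rate tracking).
The ECG renders a fixed Gaussian P-QRS-T template per beat with the QRS
scaled by (1 + am_depth·sin); the PPG renders each cycle as a half-cosine
rise to the systolic peak 12% into the onset-to-onset interval and a
half-cosine decay back to zero at the next onset, delayed 0.2 s after the
R wave, scaled by its own amplitude modulation, plus a fixed narrow
pre-systolic foot notch at the cycle boundary so that the waveform minimum
is sharply localized on the onset (real pulses have a steep
diastolic-to-systolic transition; a smooth zero-slope valley would let
baseline wander shift the argmin by tens of milliseconds). Sinusoidal
baseline wander and white noise at a configurable SNR are added per
channel; a reference respiration trace and reference RR channel are
bundled. Fixed templates (rather than a dynamical ECG model) keep fiducial
ground truth exact by construction.

Defaults mimic a resting adult on a bedside monitor: 8-minute record at
300 Hz, hr = 80 bpm, rr = 15 breaths/min, modulation depths 0.2 (relative
amplitude), 0.05 s (RSA), 0.1 (baseline, signal units), 20 dB SNR. The
generator refuses configurations with rr ≥ hr/2: a respiratory tone at or
above half the beat rate aliases in any beat-sampled series and is
unrecoverable by beat-domain methods in principle.

What the generator does *not* emulate — motion artifacts, arrhythmia,
waveform morphology variation, non-sinusoidal breathing, sensor dropout —
bounds what passing tests show: they validate the pipeline's mechanics and
its behavior under additive noise, not robustness to real-world artifact.
Results on the generator should be read as an upper bound on clinical
performance.

## Problem sizes used in validation

The end-to-end recovery study runs rr ∈ {6, 12, 18, 24, 30, 42} ×
hr ∈ {60, 80, 100} (the combinations with rr < hr/2), three seeds per
point, 120 s records with four non-overlapping 30 s windows each — 180
windows at 20 dB SNR. Typical results (seed 1): median |ΔRR| ≈ 0.23
breaths/min, 100% of windows within 2 breaths/min, pooled MAE ≈ 0.25
breaths/min. Oracle checks use 30 s series at 10 Hz; the VMD cross-check
runs 100 random well-separated multitone signals against an independently
coded classic implementation, agreeing on center frequencies to ~3e-5 Hz.

## Known limitations

* WFDB records are not read directly; convert to per-channel CSV first.
* The RQI spread over VMD-filtered components is narrow, so the adaptive
  mean threshold typically keeps 3–5 of 6 components; on pathological
  windows the selection degenerates gracefully to the best single one.
* Per-window processing is batch, not streaming; estimates update once per
  sliding step.
* The PPG "threshold method" parameters (25th percentile, 2 s context,
  300 ms refractory) are sensible for resting adult pulse rates; extreme
  bradycardia/tachycardia outside 40–180 bpm is untested.
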