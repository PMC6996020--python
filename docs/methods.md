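# Methods

This note documents the models, estimators and numerical choices in
`tmazephys`, what the synthetic generator does and does not emulate,
and the design decisions taken where the analysis was genuinely open.

## The synthetic session model

A session is a pair of aligned channels (hippocampus, mPFC) at 512 Hz,
a trial event table, and a 25-Hz running-speed trace, built from:

**Theta.** A frequency-modulated sinusoid with instantaneous frequency
`f(t) = theta_intercept + theta_slope · v(t)` (defaults 9.0 Hz,
0.02 Hz/(cm/s), amplitude 100 µV), where `v(t)` is the running speed
linearly upsampled to the LFP rate.  The mPFC copy is the same
waveform with its phase retarded by `phase_lead` radians (default 1.0,
hippocampus leading), so the lag is an exact phase offset at every
instant regardless of the momentary frequency.

**Gamma.** Two carriers of band-limited Gaussian noise, synthesised in
the frequency domain (flat profile across 60–120 Hz and 140–160 Hz,
default RMS 15 µV and 8 µV).  On the hippocampal channel each carrier
is multiplied by `1 + k·cos(theta phase)` with depth `k` in [0, 1]
(`pac_depth_lg`, `pac_depth_hg`, defaults 0.3); the mPFC carriers are
independent and unmodulated, so mPFC PAC is structurally absent.

**Background.** 1/f^β noise (default β = 1, total SD 40 µV) synthesised
in the frequency domain with random phases over the acquisition band
0.2–160 Hz, independent per channel.

**Coherence calibration.** The magnitude-squared coherence (msc)
between two channels sharing a component s with independent noises
n₁, n₂ is, per frequency bin,
`msc = P_s² / ((P_s + P_i1)(P_s + P_i2))`.
Because the pipeline's theta coherence is the *band mean* over
6–12 Hz, a shared pure tone alone cannot produce a target of, say,
0.8 — the off-tone bins would stay near zero.  The generator therefore
adds a shared narrowband background restricted to 6–12 Hz with the
same spectral shape as the in-band 1/f noise, scaled by
`c = √C / (1 − √C)` relative to the per-channel in-band noise power
(the symmetric solution of the closed form), which makes the in-band
msc approximately flat at the target `C`.  The mPFC copy of this
background is phase-rotated by `phase_lead` via its analytic signal,
so the phase-lag estimate sees a consistent lead across the whole
band.  The theta tone adds one nearly perfectly coherent bin, raising
the 13-bin band mean by about `(1 − C)/13`; empirically a target of
0.8 is recovered as 0.80–0.83 on 200-s signals.

**Behaviour.** Each trial has a sample and a choice run; the choice
arm differs from the sample arm with probability `alternation_prob`
(default 0.75).  Run latencies are log-normal (default log-mean 1.2,
log-SD 0.4 → median ≈ 3.3 s, matching typical well-trained mice);
running speed is a clipped Ornstein–Uhlenbeck process (mean 12 cm/s,
relaxation 2 s, SD 8 cm/s) with one immobile bout (< 2 cm/s) inserted
per pre-decision interval covering `immobility_frac` of it (default
0.15).  Defaults for session geometry are 10 trials, a 100-s
habituation segment, and 20-s inter-run intervals — a deliberately
compressed stand-in for the task's start-chamber delays that keeps
simulated sessions near 10 minutes.

**Seeding.** All randomness derives from one master seed through
`numpy.random.SeedSequence` with fixed integer keys per component,
animal and purpose; identical configuration + seed gives bit-identical
bundles, and derived integer seeds stay below 2³¹.

**What the generator does not emulate.** Theta is a pure FM sinusoid:
no waveform asymmetry or harmonics (real theta harmonics near
2×theta could inflate low-frequency PAC estimates), no theta
amplitude attenuation during immobility, no sharp-wave ripples,
movement artifacts or electrode drift (screening tests inject
amplitude spikes directly).  Passing parameter-recovery tests
therefore demonstrates estimator correctness under the stated model,
not robustness to every pathology of real recordings.

## Spectral estimation

Epochs are ±5 s around each decision-point crossing plus 1 s padding
per side (6144 samples at 512 Hz), linearly detrended and demeaned;
the padding is discarded after every convolution/filter step, leaving
the 10-s core (5120 samples).  Time-frequency power uses a 5-cycle
complex Morlet transform (grid 1–160 Hz, 0.5-Hz step; L2-normalized,
zero-mean wavelets via MNE).  Per-epoch spectra are the time average
normalized by the rectangle-rule integral over the grid, making them
dimensionless and amplitude-scale invariant; per-animal spectra are
means of per-epoch normalized spectra.

**Peak frequency.** The theta peak is the argmax over 6–12 Hz refined
by three-point parabolic interpolation (ties → lowest frequency;
result clamped into the band).  One instrumental correction matters:
an L2-normalized Morlet bank responds to a pure tone with a Gaussian
ridge carrying a 1/f amplitude tilt, which drags the maximum of the
broad 5-cycle theta bump ~0.15 Hz below the true frequency.  The peak
search therefore multiplies power by frequency first (the mean band
power is not affected).  With the correction the estimator's bias on
pure tones is < 0.05 Hz across 6.5–11.5 Hz on the 0.5-Hz grid.
Because spectra are integral-normalized, a group shift in theta
frequency mechanically shifts the *normalized* theta power share as
well; at realistic between-animal variance this is invisible, but in
low-noise simulations it can reach significance and should not be
read as an independent power effect.

**Filtering and analytic features.** Band-pass filtering uses a
401-tap linear-phase FIR (Hamming window design) applied
forward–backward, giving exactly zero net phase at double the nominal
order; 1 s is trimmed from each end afterwards.  Amplitude, phase and
instantaneous frequency come from the Hilbert analytic signal; phase
is in (−π, π] with 0 at signal peaks; instantaneous frequency is the
unwrapped-phase gradient, median-filtered over 5 samples against phase
slips, with low-amplitude stretches (< 5% of the median envelope)
flagged as unreliable.  The speed–frequency relationship is ordinary
least squares of instantaneous theta frequency on (boxcar-smoothed,
upsampled) speed over movement samples only, requiring ≥ 100 samples
and non-degenerate speed variance.

## Phase–amplitude coupling

The comodulogram is the Welch magnitude-squared coherence (1-s Hann
windows, 0.5-s overlap) between the raw signal and the mean-removed
wavelet amplitude envelope at each amplitude frequency (20–160 Hz in
4-Hz steps — a tractable default; the transform itself supports any
grid), read off at phase frequencies 2–40 Hz.  Envelope means are
removed to avoid a DC-leakage artifact at low phase frequencies.

The band-pair measure filters the signal in the phase band (6–12 Hz)
and the amplitude band, trims edges, extracts theta phase and gamma
amplitude by Hilbert transform, averages amplitude within 30 equal
phase bins over (−π, π] (left-open, right-closed), and reports the
resultant length of the bin-amplitude distribution.  For an envelope
`1 + k·cos φ` under uniform bins the measure is analytically `k/2`,
which the estimator reproduces to within ±0.01 on 200-s signals when
the modulated spectrum lies inside the amplitude band
(`generate_envelope_model` provides exactly that oracle signal, with
the carrier inset at 76–104 Hz).

**Bandwidth attenuation.** Amplitude modulation at theta frequency
f_θ places sidebands at ±f_θ around every carrier component.  When
the carrier occupies the full analysis band, components within f_θ of
a band edge lose sidebands to the band-pass filter, shrinking the
measured vector length below k/2 — by ≈ 18% for a full-width 60–120 Hz
carrier at 9 Hz theta, and by ≈ 50% for the 20-Hz-wide 140–160 Hz
band, where the amplitude bandwidth is barely above the 2·f_θ minimum
a band-pass PAC estimator needs.  This is a property of the estimator
class, not a bug; within a fixed band it is monotone in k, so group
comparisons remain valid, but absolute depths across bands of
different width are not comparable.

**Surrogate significance.** A cell-level test compares the observed
raw-signal/envelope coherence (mean over the phase band,
non-overlapping 1-s Hann windows) against envelopes with
FFT-randomized phases; `p = (1 + #{surrogate ≥ observed})/(1 + n)`
with 19 surrogates at α = 0.05.  Its type-I error on white noise is
0.04–0.05 over 1000 nulls.  One caveat: a *perfectly stationary*
sinusoidal theta is equally coherent with its own surrogates (any two
deterministic tones are window-coherent), so detection power rests on
theta frequency wandering, as it does in real recordings and in
generated sessions with varying speed.

**Peak alignment.** To decouple theta-frequency shifts from coupling
strength, PAC can be re-evaluated with the phase band centred on each
animal's own peak (peak ± 3 Hz), guarded to stay within 4–40 Hz.

## Connectivity

Coherence spectra are Welch msc with 1-s Hann windows and 0.5-s
overlap (1-Hz grid, ≥ 4 windows); band coherence is the mean over grid
points inside the band, inclusive.  Whether the study's coherence was
magnitude or magnitude-squared is ambiguous; magnitude-squared is
fixed here throughout (the magnitude variant would raise all values
monotonically without reordering groups).  The theta phase lag is the
circular mean of the per-sample phase difference between the
zero-phase-filtered 6–12 Hz channels (first minus second; positive =
hippocampus leads); a resultant length below 0.1 flags the estimate
unreliable.  Time lag = phase / 18π s.  Per-animal lags aggregate
per-epoch circular means by a second circular mean.

## Artifact screening

The original screening was visual; the automated surrogate rejects an
epoch when any sample deviates more than 6 SD from the epoch mean or
any successive-sample jump exceeds 6 SD, either channel, with a
"flat" rejection for zero variance.  On artifact-free generated
cohorts the false-rejection rate is below 2%; a 20-SD injected spike
is always caught.  Decisions and reasons are logged per epoch, and
trials excluded for LFP artifacts still contribute to the behavioural
measures.

## Group statistics

Two-sample comparisons pass both samples through Shapiro–Wilk at
α = 0.05: both normal → two-tailed t test (paired t for paired data),
otherwise Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired);
constant samples count as non-normal, and an all-zero paired
difference returns p = 1 by convention.  Alternation rates are tested
against chance (0.5, binary arm choice) with a one-sample signed-rank
test.  Residualization fits one pooled OLS of the measure on time
spent immobile across both groups and compares residuals with the
gated test; in the pipeline it is triggered when pre-decision
immobility itself differs at α = 0.05.  The Watson–Williams test uses
the standard F statistic with the `1 + 3/(8κ̂)` correction (κ̂ from the
mean within-group resultant via the usual three-regime approximation);
the validity condition (pooled within-group resultant > 0.45) is
reported as a flag rather than suppressing the result.  Longitudinal
designs are handled as per-timepoint two-sample tests — a deliberate
simplification of repeated-measures GLMs, stated in reports — and no
multiple-testing correction is applied across measures (per-comparison
p values are reported as such).

## Problem sizes and determinism

Simulation studies are sized for fast iteration: parameter-recovery
checks use 10 animals × 60-s recordings (peak frequency), 200-s
signals (PAC, coherence, phase lag), 1000 repetitions for null
calibrations, and 5 master seeds at 10 animals/group for the
qualitative replication pattern, with ~8–10 trials per animal.  The
numbered analysis scripts use 6 animals/group and 4 trials to keep the
demonstration under a few minutes.  Every analysis is deterministic
given its inputs, and every simulation is deterministic given its
seed; `scripts/acceptance.py` threads a single `--seed` through all of
its draws.

## Known limitations

* Absolute PAC depths are attenuated by sideband truncation (above);
  only within-band contrasts are interpretable.
* The comodulogram inherits the coherence estimator's upward bias at
  small window counts (≈ 1/n_windows), visible on 10-s epochs.
* The normalized-spectrum theta power is a *relative* share and
  couples mechanically to spectral shape changes elsewhere.
* The generator's immobile bouts switch speed discontinuously; no
  attempt is made to model acceleration profiles.
* EDF export is not implemented; sessions are stored as quantized
  (0.1 µV) CSV plus YAML manifests, which is lossless for analysis
  purposes to the declared precision.
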