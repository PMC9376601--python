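# Methods

## Signal model and scoring procedure

The pipeline assumes a recording is a superposition of (i) scale-free
"fractal" background motion with power spectral density ∝ 1/f^β
(postural sway, drift, broadband sensor noise), and (ii) rhythmic tremor
concentrated near a single frequency in the 3.5–10 Hz band, possibly
waxing and waning over the minute. The score is designed so that (i)
contributes ≈ 1 to the per-bin oscillatory ratio regardless of its
amplitude or slope, and (ii) contributes in proportion to its spectral
prominence above that background.

Processing per recording:

1. Each of the six channels is segmented into 8-s windows with 50%
   overlap (4-s hop). A trailing partial window is dropped. A 60-s
   recording at 100 Hz yields 14 windows per channel.
2. Per window, the mixed spectrum is a single Hann-tapered, linearly
   detrended periodogram of the full 800-sample block (0.125 Hz
   resolution). Sub-window averaging (Welch) is deliberately not used: it
   would trade away the frequency resolution that separates a narrow
   tremor peak from its surroundings.
3. The fractal spectrum is the IRASA estimate: for each
   h ∈ {1.10, 1.15, …, 1.90} (17 factors, the convention of the original
   irregular-resampling method) the block is linearly resampled to
   round(N·h) and round(N/h) samples, each resampled series is analysed
   with the same periodogram *against the original sampling rate* — which
   shifts a rhythmic peak at f₀ to f₀/h and f₀·h while leaving 1/f^β
   content statistically unchanged (the h^(1−β) and h^(β−1) amplitude
   factors cancel in the geometric mean) — and the two PSDs are
   interpolated back onto the original grid and combined bin-wise by
   geometric mean. The bin-wise median across the 17 factors is the
   fractal estimate.
4. The oscillatory ratio is mixed/fractal, with the denominator floored
   at 10⁻¹² of its maximum so bins emptied by detrending cannot produce
   division blow-ups.
5. The ratio spectrum is smoothed with a unit-sum Gaussian kernel,
   σ = 1 Hz (8 bins), truncated at ±3σ, reflected at the edges.
   Smoothing is applied to the *ratio*, not to the raw power spectra:
   smoothing before the division would partially cancel and would break
   the exact gain invariance that makes the score comparable across
   uncalibrated sensors.
6. The window index is the maximum of the smoothed ratio over 3.5–10 Hz
   (ties break to the lowest frequency); its argmax is the window's peak
   frequency.
7. All window × channel indices are pooled; k = ⌈n/3⌉ of them are kept
   (the top third — ceiling, so a short recording never loses its single
   best window) and the recording's index I is their median (midpoint
   convention for even k). The median peak frequency of the kept windows
   is reported as the dominant frequency; it is diagnostic metadata only.
8. Optionally I_dB = 10·log₁₀(I/⟨I_CTRL⟩), with ⟨I_CTRL⟩ the arithmetic
   mean index of a control cohort processed under the *same*
   configuration; the control reference stores a hash of the spectral and
   scoring settings, and the CLI refuses to mix hashes.

Pooling across time *and* channels (rather than per-channel aggregation)
reflects that tremor projects onto all six axes with unknown, posture-
dependent loadings: the top-third selection automatically concentrates on
the best-loaded channels and the high-amplitude epochs.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window length | 8 | s | 0.125 Hz resolution; resolves tremor peaks ~1 Hz apart |
| overlap | 0.5 | — | standard hop/resolution compromise |
| hset | 1.10…1.90 step 0.05 | — | convention of the irregular-resampling method |
| smoothing σ | 1 | Hz | wider than one bin (stabilizes the max), narrower than the band |
| band | 3.5–10 | Hz | covers ET (~5–8 Hz) and PD (~4–7 Hz) postural tremor |
| top fraction | 1/3 | — | robust to tremor intermittency; k = ⌈n/3⌉ |
| denominator floor | 10⁻¹²·max | — | numerical guard only; never binds on real spectra |

Resampling (both the ingestion resampler and the IRASA-internal one) is
linear: the band of interest ends at 10 Hz while sampling is at ≥ 100 Hz,
so linear-interpolation error is negligible against sensor noise.

## The synthetic-data generator

Because no patient recordings are distributed, validation runs on a
generative model of the study design:

* **Background**: per-channel 1/f^β Gaussian noise (β drawn from
  0.8–1.2), frequency-domain shaped, normalized to unit RMS. All
  amplitudes are in background-RMS units; the pipeline's gain invariance
  makes physical units irrelevant to the score.
* **Tremor**: a sinusoid at the subject's tremor frequency with (a)
  Brownian frequency jitter scaled so the instantaneous-frequency
  standard deviation reaches `freq_jitter_sd` (default 0.2 Hz) at the end
  of the recording, and (b) slow sinusoidal amplitude modulation at
  0.1 Hz with depth up to 0.5 — tremor waxes and wanes over tens of
  seconds, which is what makes the top-third selection meaningful. The
  component's RMS equals `rel_amp` (relative to the unit background). It
  projects coherently onto all six axes through fixed per-subject random
  direction cosines (linear and angular triplets drawn separately, every
  component bounded away from zero).
* **Sensors**: the finger-mounted IMU (osc_gain 1.0, noise_gain 0.2) and
  the smartphone (osc_gain 0.9, noise_gain 0.6) observe the *same*
  background and tremor streams and differ only in gain and in their
  independent wideband noise — emulating paired measurement of one limb,
  with the finger sensor the higher-SNR device.
* **Cohorts**: ET tremor frequency ~ N(6.0, 1.0) truncated to 5–8 Hz,
  relative amplitude uniform 2–5; PD ~ N(6.3, 1.3) truncated to 4–7 Hz,
  amplitude 0.5–2 (postural PD tremor is present but less pronounced);
  controls carry a weak (≤ 0.3) 8–12 Hz physiological oscillation that
  lies partly outside the scoring band, so control spectra are not pure
  noise and classification is nontrivial. A dimensionless severity
  surrogate equals the relative amplitude plus bounded uniform "rater
  noise" (±0.25), giving a rank correlation with amplitude ≥ 0.8 by
  construction; no attempt is made to mimic the item structure of
  clinical rating scales. Every draw derives from a single master seed.

What passing these tests shows: the implementation realizes the intended
mathematics (exact oracles for aggregation and AUC), the ratio statistic
is unit-free and null-calibrated, the score responds monotonically to
tremor amplitude and recovers tremor frequency, and the cohort machinery
separates groups whose spectra differ the way ET/PD/control spectra do.
What it does not show: performance on real recordings — real tremor has
harmonics, voluntary-movement artifacts, non-stationary background and
sensor clock drift, none of which the generator emulates. The published
patient-cohort statistics (AUCs, severity r²) are therefore qualitative
anchors, not reproduction targets.

## Numerical choices and degenerate inputs

* Periodograms use scipy's density scaling; Parseval holds to within the
  taper's variance inflation (checked at 5% on white noise).
* The smoothed ratio is clipped at 0 to absorb float cancellation in the
  reflected convolution.
* Ties in the window-index maximum break to the lowest frequency; ties in
  the top-third selection are resolved by stable sort order (they cannot
  affect the median of the values).
* A constant block detrends to an all-zero spectrum; its ratio is 0/floor
  = 0 and the window contributes the minimum possible index rather than
  an error.
* Recordings shorter than 16 s (two windows) and rates ≤ 20 Hz are
  rejected at construction; the band must lie below Nyquist.
* AUC is computed in rank form (Mann–Whitney, ties ½), which is exactly
  the trapezoidal area under the empirical ROC curve; the curve itself
  comes from scikit-learn for plotting and is cross-checked against the
  rank statistic at 10⁻¹².

## Validation problem sizes

The shipped validation uses 60-s recordings at 100 Hz (14 windows × 6
channels = 84 indices per recording), a 33-subject cohort (17 ET / 9 PD /
7 controls, 2 sensors × 2 postures = 132 recordings), 1000 random lists
for the aggregation oracle, 500 instances for the AUC oracle, and 20
windows per β for the fractal null. These sizes put every statistic well
past its small-sample regime while keeping the full suite runnable on a
laptop in a few minutes.

## Known limitations

* The fractal estimator assumes the background is locally well described
  by a power law over ~1–12 Hz; strong narrowband artifacts (mains hum
  aliases, voluntary rhythmic movement) would be scored as tremor.
* Because the within-window spectra are single periodograms (chi², two
  degrees of freedom), the geometric-mean-and-median combination inside
  the fractal estimator is a *median-like* level estimate: it sits below
  the mean PSD by roughly Γ(1.5)² ≈ 0.785 but centres the per-window
  oscillatory ratio on 1, which is the calibration the score relies on.
  The estimate's spectral *shape* (the 1/f^β slope) is unbiased. No
  bias correction is applied — it would shift the fractal-null ratio off
  unity while the absolute fractal level never enters the score.
* The dominant-frequency diagnostic is the median of top-window peak
  frequencies and can sit between two true peaks in multifocal tremor.
* The "below-ET" ordering of PD classification is not testable at these
  effect sizes: both patient groups separate perfectly from simulated
  controls, so the comparison saturates at AUC = 1.
* Clock-drift correction between paired physical sensors is out of
  scope; paired-sensor simulations share an exact time base.
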