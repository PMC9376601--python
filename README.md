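# tremorscore

Objective tremor quantification from smartphone and wearable inertial
sensors.

Postural tremor in essential tremor (ET) and Parkinson's disease (PD) is
usually rated on clinical scales (e.g. Fahn–Tolosa–Marín) during clinic
visits. A one-minute self-test with a phone's built-in accelerometer and
gyroscope can produce an objective, repeatable score instead — useful for
tracking symptom fluctuation at home and, eventually, for guiding
on-demand adjustment of therapies such as deep-brain stimulation.
`tremorscore` implements that scoring pipeline as a tested Python library
and command-line tool, together with a synthetic-cohort simulator used to
validate every stage (real patient recordings are not distributed with the
package).

## The score

A recording is six channels — 3-axis linear acceleration (m/s²) and
3-axis angular velocity (rad/s) — sampled at ~100 Hz for about a minute.
The pipeline:

1. **Windowing.** Each channel is cut into 50%-overlapping 8-s windows
   (4-s hop; 0.125 Hz spectral resolution).
2. **Fractal/oscillatory separation (IRASA).** Per window, the mixed power
   spectral density `S(f)` contains both scale-free 1/f^β background
   motion and rhythmic tremor. The fractal part is estimated by irregular
   resampling: for each factor `h ∈ {1.10, 1.15, …, 1.90}` the window is
   resampled by `h` and `1/h`; a rhythmic peak at `f₀` shifts to `f₀/h`
   and `f₀·h` while self-similar 1/f^β content is invariant, so the
   bin-wise geometric mean of the two resampled PSDs (median across all
   `h`) retains only the fractal floor `S_frac(f)`. The unitless
   **oscillatory ratio** `S(f)/S_frac(f)` is ≈ 1 where no rhythm is
   present and rises above 1 at tremor peaks — and is invariant to sensor
   gain.
3. **Window index.** The ratio spectrum is smoothed with a Gaussian kernel
   (σ = 1 Hz) and maximized over the tremor band 3.5–10 Hz; the maximum is
   the window's tremor index, the argmax its peak frequency.
4. **Aggregation.** All (window × channel) indices of the recording are
   pooled; the recording's tremor index `I` is the median of the top third.
5. **Normalization.** For comparison across subjects the index is
   expressed in decibels relative to the mean index ⟨I_CTRL⟩ of a control
   population: `I_dB = 10·log₁₀(I / ⟨I_CTRL⟩)`.

## Worked example

```python
import tremorscore as ts

# simulate a 60-s recording of an ET-like subject (6 Hz tremor, amplitude
# 3x the fractal background RMS) measured with a finger-mounted IMU
params = ts.SubjectParams(group="ET", tremor_freq=6.0, tremor_rel_amp=3.0, seed=42)
rec = ts.simulate_recording(params, ts.FINGER_SENSOR)

score = ts.score_recording(rec)
print(f"index = {score.index:.1f}")
print(f"dominant frequency = {score.dominant_freq:.3f} Hz")
print(f"windows used = {score.n_windows_used}/{score.n_windows_total}")
```

prints

```
index = 135.4
dominant frequency = 5.875 Hz
windows used = 28/84
```

The index of 135 means the smoothed oscillatory ratio reaches ~135× the
fractal background in the median top-third window — a strong tremor. The
dominant frequency recovers the simulated 6 Hz within one spectral bin,
and 28 = ⌈84/3⌉ of the 14 windows × 6 channels entered the median. A
matched control simulation (no tremor) scores ≈ 2–3 on the same scale, so
this subject sits at roughly +17 dB relative to controls.

The same workflow from the shell:

```bash
tremorscore simulate --out cohort/ --n-et 17 --n-pd 9 --n-ctrl 7 --seed 1
tremorscore calibrate cohort/CTRL*_phone_P1.csv --out control_ref.json
tremorscore score cohort/ET01_phone_P1.csv --control-ref control_ref.json
tremorscore report cohort/ --out report.json
```

`score` refuses to combine a recording with a control reference computed
under a different pipeline configuration (the reference carries a config
hash). `report` writes per-group ROC/AUC versus controls, severity
correlations and dB scores for every sensor × posture condition.

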